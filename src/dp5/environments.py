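"""Atomic environment descriptors and Gaussian-kernel similarities.

The descriptor is an element-channelled, Gaussian-smeared radial distribution
around a carbon centre: for channel element ``Z`` and radial grid point
``r_k``,

    D[Z, k] = sum_j  exp(-(r_k - r_ij)^2 / (2 w^2)) * fc(r_ij)

over neighbours ``j`` of element ``Z`` inside the cutoff, with the smooth
cutoff ``fc(r) = (cos(pi r / r_cut) + 1) / 2``.  Optional angular channels
histogram the angles subtended at the centre by heavy-neighbour pairs.  The
descriptor depends only on interatomic distances and angles, so it is
translation-, rotation- and neighbour-permutation-invariant by construction.
Any externally computed rotation/translation-invariant representation (e.g.
FCHL vectors) can be substituted through :func:`load_external_descriptors`.

Similarity between two environments is a Gaussian kernel on their Euclidean
distance with the pre-exponential factor fixed at one, so self-similarity is
exactly 1 and the kernel value reads directly as a similarity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import h5py
import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .chem_io import Molecule
from .exceptions import (
    DegenerateKernelError,
    DomainError,
    IncompatibleParamsError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .error_model import ErrorDatabase


@dataclass(frozen=True)
class DescriptorParams:
    cutoff: float = 5.0  # Angstrom
    n_radial_bins: int = 24
    width: float = 0.5  # Angstrom, radial smearing
    elements: tuple[str, ...] = ("C", "H", "O", "N")
    include_angular: bool = False
    n_angular_bins: int = 12
    angular_width: float = 0.25  # radians

    def __post_init__(self) -> None:
        if self.cutoff <= 0 or self.width <= 0:
            raise DomainError("cutoff and width must be positive")
        if self.n_radial_bins < 1 or self.n_angular_bins < 1:
            raise DomainError("bin counts must be >= 1")

    @property
    def params_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    @property
    def length(self) -> int:
        n = len(self.elements) * self.n_radial_bins
        if self.include_angular:
            n += self.n_angular_bins
        return n

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["elements"] = list(d["elements"])
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DescriptorParams":
        d = json.loads(text)
        d["elements"] = tuple(d["elements"])
        return cls(**d)


@dataclass(frozen=True)
class KernelParams:
    """Gaussian kernel k(d) = exp(-d^2 / (2 sigma^2)); prefactor fixed at 1."""

    sigma: float
    prefactor: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"kernel sigma must be > 0, got {self.sigma}")
        if self.prefactor != 1.0:
            raise DomainError("kernel prefactor is fixed at 1")


@dataclass
class EnvironmentDescriptor:
    vector: np.ndarray
    element: str
    params_hash: str


def _radial_grid(params: DescriptorParams) -> np.ndarray:
    step = params.cutoff / params.n_radial_bins
    return (np.arange(params.n_radial_bins) + 0.5) * step


def compute_descriptor(
    molecule: Molecule,
    conformer_index: int,
    atom_index: int,
    params: DescriptorParams,
) -> EnvironmentDescriptor:
    """Descriptor of one carbon centre in one conformer."""
    if not 0 <= atom_index < molecule.n_atoms:
        raise DomainError(f"atom index {atom_index} out of range")
    if molecule.elements[atom_index] != "C":
        raise DomainError(
            f"atom {atom_index} is {molecule.elements[atom_index]}; only carbon "
            "centres are represented"
        )
    coords = molecule.conformers[conformer_index].coordinates
    centre = coords[atom_index]
    deltas = coords - centre
    dists = np.linalg.norm(deltas, axis=1)

    vector = np.zeros(params.length)
    grid = _radial_grid(params)
    fc = 0.5 * (np.cos(np.pi * np.minimum(dists, params.cutoff) / params.cutoff) + 1.0)
    for c, element in enumerate(params.elements):
        mask = np.array(
            [
                j != atom_index
                and molecule.elements[j] == element
                and dists[j] < params.cutoff
                for j in range(molecule.n_atoms)
            ]
        )
        if not mask.any():
            continue
        r = dists[mask]
        smear = np.exp(-((grid[None, :] - r[:, None]) ** 2) / (2 * params.width**2))
        block = (smear * fc[mask][:, None]).sum(axis=0)
        vector[c * params.n_radial_bins:(c + 1) * params.n_radial_bins] = block

    if params.include_angular:
        heavy = [
            j
            for j in range(molecule.n_atoms)
            if j != atom_index
            and molecule.elements[j] != "H"
            and dists[j] < params.cutoff
        ]
        a_grid = (np.arange(params.n_angular_bins) + 0.5) * np.pi / params.n_angular_bins
        block = np.zeros(params.n_angular_bins)
        for a in range(len(heavy)):
            for b in range(a + 1, len(heavy)):
                va, vb = deltas[heavy[a]], deltas[heavy[b]]
                cosang = np.dot(va, vb) / (dists[heavy[a]] * dists[heavy[b]])
                theta = np.arccos(np.clip(cosang, -1.0, 1.0))
                block += (
                    np.exp(-((a_grid - theta) ** 2) / (2 * params.angular_width**2))
                    * fc[heavy[a]]
                    * fc[heavy[b]]
                )
        vector[-params.n_angular_bins:] = block

    return EnvironmentDescriptor(
        vector=vector, element="C", params_hash=params.params_hash
    )


def compute_descriptors(
    molecule: Molecule, conformer_index: int, params: DescriptorParams
) -> tuple[np.ndarray, np.ndarray]:
    """Descriptors for every carbon; returns (carbon_indices, N x D matrix)."""
    idx = molecule.carbon_indices
    matrix = np.stack(
        [
            compute_descriptor(molecule, conformer_index, int(i), params).vector
            for i in idx
        ]
    )
    return idx, matrix


def descriptor_distance(a: EnvironmentDescriptor, b: EnvironmentDescriptor) -> float:
    if a.params_hash != b.params_hash:
        raise IncompatibleParamsError(
            "descriptors built with different parameter sets cannot be compared"
        )
    return float(np.linalg.norm(a.vector - b.vector))


def gaussian_kernel(distance, params: KernelParams):
    distance = np.asarray(distance, dtype=float)
    if not np.all(np.isfinite(distance)):
        raise DomainError("kernel distance must be finite")
    value = np.exp(-(distance**2) / (2.0 * params.sigma**2))
    return float(value) if value.ndim == 0 else value


def kernel_weights(
    test: EnvironmentDescriptor,
    db: "ErrorDatabase",
    params: KernelParams,
    exclude_molecule: str | None = None,
) -> np.ndarray:
    """Similarity of the test environment to every database record.

    Records belonging to ``exclude_molecule`` get weight exactly 0 (the
    leave-one-out scheme).  Raises if everything is excluded or all weights
    underflow to zero.
    """
    if test.params_hash != db.params.params_hash:
        raise IncompatibleParamsError(
            "test descriptor and database use different descriptor parameters"
        )
    keep = np.ones(len(db.errors), dtype=bool)
    if exclude_molecule is not None:
        keep = db.molecule_ids != exclude_molecule
        if not keep.any():
            raise DomainError(
                f"database is empty after excluding {exclude_molecule!r}"
            )
    d = cdist(test.vector[None, :], db.descriptors)[0]
    weights = np.where(keep, np.exp(-(d**2) / (2.0 * params.sigma**2)), 0.0)
    if not (weights > 0).any():
        raise DegenerateKernelError(
            "all kernel weights underflowed to zero; use a larger kernel sigma"
        )
    return weights


def median_heuristic_sigma(
    descriptors: np.ndarray, max_sample: int = 500, seed: int = 0
) -> float:
    """Median pairwise distance over a seeded subsample (the median heuristic).

    A global length scale; tends to over-smooth when the environments are
    strongly clustered (see :func:`local_scale_sigma`, the default).
    """
    descriptors = np.asarray(descriptors, dtype=float)
    if descriptors.shape[0] > max_sample:
        rng = np.random.default_rng(seed)
        take = rng.choice(descriptors.shape[0], size=max_sample, replace=False)
        descriptors = descriptors[take]
    if descriptors.shape[0] < 2:
        return 1.0
    d = pdist(descriptors)
    d = d[d > 0]
    return float(np.median(d)) if d.size else 1.0


def local_scale_sigma(
    descriptors: np.ndarray,
    k: int = 10,
    max_sample: int = 2000,
    seed: int = 0,
) -> float:
    """Median distance to the k-th nearest neighbour (a local length scale).

    This is the default for ``sigma="auto"``: it sets the kernel width to the
    typical spacing *within* a neighbourhood of similar environments, so that
    weighting actually conditions the error density on the environment
    instead of averaging over the whole database the way the global median
    heuristic does on clustered data.
    """
    descriptors = np.asarray(descriptors, dtype=float)
    n = descriptors.shape[0]
    if n < 2:
        return 1.0
    if n > max_sample:
        rng = np.random.default_rng(seed)
        take = rng.choice(n, size=max_sample, replace=False)
        descriptors = descriptors[take]
        n = max_sample
    k = min(k, n - 1)
    d = squareform(pdist(descriptors))
    kth = np.sort(d, axis=1)[:, k]
    sigma = float(np.median(kth))
    return sigma if sigma > 0 else 1.0


def save_descriptors(
    path, descriptors: np.ndarray, elements, molecule_ids, params: DescriptorParams
) -> None:
    """Write the descriptor exchange file (HDF5)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("descriptors", data=np.asarray(descriptors, dtype=float))
        f.create_dataset(
            "elements", data=np.array(list(elements), dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "molecule_ids",
            data=np.array(list(molecule_ids), dtype=h5py.string_dtype()),
        )
        f.attrs["params_json"] = params.to_json()


def load_external_descriptors(path) -> tuple[np.ndarray, list[str], list[str], DescriptorParams]:
    """Plug-in hook: load externally computed representations (same layout)."""
    with h5py.File(path, "r") as f:
        descriptors = f["descriptors"][()]
        elements = [e.decode() for e in f["elements"][()]]
        molecule_ids = [m.decode() for m in f["molecule_ids"][()]]
        params = DescriptorParams.from_json(f.attrs["params_json"])
    return descriptors, elements, molecule_ids, params
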