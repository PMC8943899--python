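"""Synthetic corpora with environment-clustered, heavy-tailed shift errors.

The generator emulates the statistical structure the verification method
assumes: each carbon belongs to a latent environment cluster determined by
its local chemistry (heavy-neighbour count and heteroatom attachment), and
the 13C prediction error for a correctly paired spectrum is drawn from that
cluster's Student-t law (location, scale, df).  Student-t tails reflect the
heavy-tailed character of real DFT-NMR prediction errors; the default scales
put the corpus-wide mean absolute error in the 1.5-2 ppm range typical of
good DFT shift predictions.

Incorrect spectra are generated by resampling the cluster label per atom
(drawing from the marginal error mixture) and inflating the error by a
configurable factor: inflation 1 yields incorrect pairs whose per-pair MAE
distribution matches the correct pairs (the "error-indistinguishable"
regime), large inflation yields grossly wrong spectra.

Molecules are random acyclic C/H/O/N skeletons with one embedded 3D
conformer, so descriptors come from real geometries; a direct-vector mode
builds clustered descriptors without any geometry for unit-level tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chem_io import Conformer, Molecule, PeakList, rdkit_to_molecule
from .environments import DescriptorParams
from .error_model import ErrorDatabase
from .exceptions import DomainError

_VALENCE = {"C": 4, "N": 3, "O": 2}


@dataclass
class SyntheticSpec:
    """Study conditions for a synthetic corpus."""

    n_molecules: int = 50
    carbons_min: int = 6
    carbons_max: int = 10
    n_clusters: int = 4
    cluster_locations: tuple[float, ...] = (0.0, 0.5, -0.5, 1.0)  # ppm
    cluster_scales: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)  # ppm
    cluster_df: float = 5.0
    cluster_base_shifts: tuple[float, ...] = (20.0, 65.0, 110.0, 160.0)  # ppm
    shift_spread: float = 15.0  # ppm, within-cluster spread of base shifts
    heteroatom_prob: float = 0.25
    descriptor_noise: float = 0.3  # direct-vector mode only
    inflation: float = 5.0  # incorrect-pair error inflation factor
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cluster_scales) <= 0:
            raise DomainError("cluster scales must be positive")
        if self.cluster_df <= 2:
            raise DomainError("cluster df must exceed 2")
        if not (
            len(self.cluster_locations)
            == len(self.cluster_scales)
            == len(self.cluster_base_shifts)
            == self.n_clusters
        ):
            raise DomainError("per-cluster parameter lengths must equal n_clusters")
        if not 1 <= self.carbons_min <= self.carbons_max:
            raise DomainError("invalid carbon count range")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticSpec":
        d = json.loads(text)
        for key in ("cluster_locations", "cluster_scales", "cluster_base_shifts"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def expected_abs_t(df: float, scale: float = 1.0) -> float:
    """E|scale * T| for T ~ t(df), in closed form."""
    e_abs = 2 * math.sqrt(df) * math.gamma((df + 1) / 2) / (
        math.sqrt(math.pi) * (df - 1) * math.gamma(df / 2)
    )
    return scale * e_abs


def _cluster_of(molecule: Molecule, atom_index: int) -> tuple[int, bool]:
    """Latent cluster key from local chemistry: (heavy-degree, heteroatom?)."""
    heavy = 0
    hetero = False
    for i, j, _ in molecule.bonds:
        other = j if i == atom_index else i if j == atom_index else None
        if other is None:
            continue
        e = molecule.elements[other]
        if e != "H":
            heavy += 1
            if e in ("O", "N"):
                hetero = True
    return heavy, hetero


def assign_cluster(molecule: Molecule, atom_index: int, n_clusters: int) -> int:
    heavy, hetero = _cluster_of(molecule, atom_index)
    return (min(heavy, 3) + (2 if hetero else 0)) % n_clusters


def _random_skeleton(rng: np.random.Generator, n_carbons: int,
                     heteroatom_prob: float) -> list[str] | None:
    elements = ["C"] * n_carbons
    n_het = rng.binomial(max(n_carbons - 2, 1), heteroatom_prob)
    for _ in range(n_het):
        elements.append("O" if rng.random() < 0.5 else "N")
    return elements


def _build_random_molecule(
    rng: np.random.Generator, spec: SyntheticSpec, molecule_id: str
) -> Molecule:
    """Random acyclic molecule with one embedded 3D conformer."""
    for attempt in range(20):
        n_carbons = int(rng.integers(spec.carbons_min, spec.carbons_max + 1))
        elements = _random_skeleton(rng, n_carbons, spec.heteroatom_prob)
        order = list(rng.permutation(len(elements)))
        # carbons first so the backbone always has spare valence
        order.sort(key=lambda i: elements[i] != "C")
        rw = Chem.RWMol()
        free: list[int] = []
        ok = True
        for pos, src in enumerate(order):
            atom = Chem.Atom(elements[src])
            idx = rw.AddAtom(atom)
            if pos == 0:
                free.append(idx)
                continue
            candidates = [a for a in free if _spare_valence(rw, a) > 0]
            if not candidates:
                ok = False
                break
            parent = candidates[int(rng.integers(len(candidates)))]
            rw.AddBond(parent, idx, Chem.BondType.SINGLE)
            free.append(idx)
        if not ok:
            continue
        mol = rw.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            continue
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int(rng.integers(1, 2**31 - 1))
        if AllChem.EmbedMolecule(mol, params) != 0:
            continue
        return rdkit_to_molecule(mol, molecule_id=molecule_id, provenance="synthetic")
    raise DomainError("could not generate a valid molecule in 20 attempts")


def _spare_valence(rw: Chem.RWMol, idx: int) -> int:
    atom = rw.GetAtomWithIdx(idx)
    return _VALENCE[atom.GetSymbol()] - atom.GetDegree()


def _draw_error(rng: np.random.Generator, spec: SyntheticSpec, cluster: int) -> float:
    return float(
        spec.cluster_locations[cluster]
        + spec.cluster_scales[cluster] * rng.standard_t(spec.cluster_df)
    )


def generate_corpus(
    spec: SyntheticSpec,
) -> tuple[list[tuple[Molecule, PeakList]], dict]:
    """Generate molecules with calculated shifts and matching "experimental"
    peak lists; returns the corpus and a ground-truth record.

    A carbon's calculated shift is its cluster's base shift plus Gaussian
    spread; its experimental peak is that shift minus an error drawn from the
    cluster's Student-t law, so (calculated - experimental) recovers the
    drawn error for a correct pairing.
    """
    rng = np.random.default_rng(spec.seed)
    corpus: list[tuple[Molecule, PeakList]] = []
    truth: dict = {"seed": spec.seed, "spec": json.loads(spec.to_json()),
                   "molecules": {}}
    for m in range(spec.n_molecules):
        mol_id = f"syn{m:05d}"
        molecule = _build_random_molecule(rng, spec, mol_id)
        idx = molecule.carbon_indices
        clusters, shifts, errors = [], {}, {}
        for atom in idx:
            atom = int(atom)
            k = assign_cluster(molecule, atom, spec.n_clusters)
            calc = float(np.clip(
                spec.cluster_base_shifts[k] + rng.normal(0.0, spec.shift_spread),
                0.0, 220.0,
            ))
            err = _draw_error(rng, spec, k)
            clusters.append(k)
            shifts[atom] = calc
            errors[atom] = err
        molecule.conformers[0].calculated_shifts = shifts
        peaks = PeakList(
            shifts=np.array([shifts[int(a)] - errors[int(a)] for a in idx])
        )
        corpus.append((molecule, peaks))
        truth["molecules"][mol_id] = {
            "clusters": clusters,
            "errors_ppm": [errors[int(a)] for a in idx],
            "carbon_indices": [int(a) for a in idx],
        }
    return corpus, truth


def generate_incorrect_spectrum(
    molecule: Molecule,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    inflation: float | None = None,
) -> PeakList:
    """Spectrum of a hypothetical *different* molecule sharing the skeleton's
    shift pattern: per-atom errors are drawn from the cluster-marginal
    mixture (cluster resampled uniformly) and multiplied by ``inflation``.
    """
    if inflation is None:
        inflation = spec.inflation
    idx = molecule.carbon_indices
    shifts = molecule.carbon_shifts(0)
    peaks = []
    for calc in shifts:
        k = int(rng.integers(spec.n_clusters))
        peaks.append(float(calc) - inflation * _draw_error(rng, spec, k))
    return PeakList(shifts=np.array(peaks))


def make_clustered_database(
    n_records: int,
    spec: SyntheticSpec,
    params: DescriptorParams | None = None,
    seed: int | None = None,
) -> tuple[ErrorDatabase, np.ndarray]:
    """Direct-vector mode: clustered descriptors without any geometry.

    Cluster centres are far-separated points in descriptor space; records
    scatter around them with ``descriptor_noise`` and carry errors from the
    cluster's Student-t law.  Returns the database and the cluster labels.
    """
    if params is None:
        params = DescriptorParams()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    dim = params.length
    centres = np.zeros((spec.n_clusters, dim))
    for k in range(spec.n_clusters):
        centres[k, (k * 7) % dim] = 10.0
        centres[k, (k * 13 + 3) % dim] = 5.0 + k
    labels = rng.integers(spec.n_clusters, size=n_records)
    descriptors = centres[labels] + rng.normal(
        0.0, spec.descriptor_noise, size=(n_records, dim)
    )
    errors = np.array([_draw_error(rng, spec, int(k)) for k in labels])
    ids = np.array([f"vec{i:06d}" for i in range(n_records)], dtype=object)
    db = ErrorDatabase(
        descriptors=descriptors,
        errors=errors,
        molecule_ids=ids,
        params=params,
        sigma=1.0,
    )
    return db, labels
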