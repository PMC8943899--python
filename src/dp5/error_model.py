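"""Peak assignment, internal scaling, and environment-weighted error PDFs.

The central object is the bespoke per-atom error density: a weighted Gaussian
kernel density estimate over a reference database of known 13C prediction
errors, where each database record contributes in proportion to the Gaussian
kernel similarity between its atomic environment and the test atom's.  The
atomic probability is an integral of that density:

* ``window`` (default): the mass within one database-wide mean absolute error
  (eps*) of the observed scaled error, P(|X - delta| <= eps*);
* ``two_tail``: the tail mass P(|X| >= |delta|).

Both have closed forms in terms of the normal CDF, which is what the code
evaluates; tests cross-check against adaptive quadrature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import ndtr  # standard normal CDF, vectorized

from .chem_io import Molecule, PeakList
from .environments import (
    DescriptorParams,
    compute_descriptors,
    local_scale_sigma,
)
from .exceptions import DomainError, FormatError, IncompatibleParamsError

log = logging.getLogger(__name__)

BANDWIDTH_FLOOR = 0.1  # ppm


@dataclass
class Assignment:
    """Optimal matching of calculated carbon shifts to experimental peaks."""

    mapping: dict[int, float]  # carbon atom_index -> peak ppm
    unassigned_atoms: list[int]
    cost: float  # total |calc - peak| over the mapping, ppm


@dataclass
class ErrorDatabase:
    """Reference set of (environment descriptor, scaled prediction error).

    ``eps_star`` is the mean absolute prediction error of the database and is
    the integration half-width of the window scheme.
    """

    descriptors: np.ndarray  # (N, D)
    errors: np.ndarray  # (N,) scaled errors, ppm
    molecule_ids: np.ndarray  # (N,) strings
    params: DescriptorParams
    eps_star: float = None  # type: ignore[assignment]
    sigma: float | None = None  # resolved kernel length scale
    atom_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=object)
        if self.errors.size < 1:
            raise DomainError("error database must hold at least one record")
        mae = float(np.mean(np.abs(self.errors)))
        if self.eps_star is None:
            self.eps_star = mae
        elif abs(self.eps_star - mae) > 1e-9:
            raise DomainError(
                f"stored eps_star {self.eps_star} disagrees with recomputed "
                f"mean absolute error {mae}"
            )

    def __len__(self) -> int:
        return int(self.errors.size)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("descriptors", data=self.descriptors)
            f.create_dataset("errors_ppm", data=self.errors)
            f.create_dataset(
                "molecule_ids",
                data=np.array([str(m) for m in self.molecule_ids],
                              dtype=h5py.string_dtype()),
            )
            if self.atom_indices is not None:
                f.create_dataset("atom_indices", data=np.asarray(self.atom_indices))
            f.attrs["eps_star"] = self.eps_star
            f.attrs["params_json"] = self.params.to_json()
            if self.sigma is not None:
                f.attrs["sigma"] = self.sigma

    @classmethod
    def load(cls, path) -> "ErrorDatabase":
        with h5py.File(path, "r") as f:
            db = cls(
                descriptors=f["descriptors"][()],
                errors=f["errors_ppm"][()],
                molecule_ids=np.array([m.decode() for m in f["molecule_ids"][()]],
                                      dtype=object),
                params=DescriptorParams.from_json(f.attrs["params_json"]),
                eps_star=float(f.attrs["eps_star"]),
                sigma=float(f.attrs["sigma"]) if "sigma" in f.attrs else None,
                atom_indices=f["atom_indices"][()] if "atom_indices" in f else None,
            )
        return db


@dataclass
class AtomicErrorPDF:
    """Weighted Gaussian-mixture density over database error values."""

    errors: np.ndarray  # support: database error values, ppm
    weights: np.ndarray  # normalized, sum 1
    bandwidth: float  # ppm

    def pdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.errors[None, :]) / self.bandwidth
        phi = np.exp(-0.5 * z**2) / (self.bandwidth * np.sqrt(2 * np.pi))
        out = phi @ self.weights
        return out if out.size > 1 else float(out[0])

    def cdf(self, x) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.errors[None, :]) / self.bandwidth
        out = ndtr(z) @ self.weights
        return out if out.size > 1 else float(out[0])


def assign_peaks(
    calculated_shifts: np.ndarray,
    peaks: PeakList,
    atom_indices: np.ndarray | None = None,
) -> Assignment:
    """Minimum total |calc - peak| assignment (rectangular Hungarian).

    A multiplicity-m peak is expanded into m slots before matching.  When
    carbons outnumber slots, the optimal injection is used and the remaining
    atoms are flagged unassigned.
    """
    shifts = np.asarray(calculated_shifts, dtype=float)
    if shifts.size == 0:
        raise DomainError("no calculated shifts to assign")
    if atom_indices is None:
        atom_indices = np.arange(shifts.size)
    slots = np.repeat(peaks.shifts, peaks.multiplicities)
    cost = np.abs(shifts[:, None] - slots[None, :])
    rows, cols = linear_sum_assignment(cost)
    mapping = {int(atom_indices[r]): float(slots[c]) for r, c in zip(rows, cols)}
    unassigned = sorted(int(a) for a in atom_indices if int(a) not in mapping)
    return Assignment(
        mapping=mapping,
        unassigned_atoms=unassigned,
        cost=float(cost[rows, cols].sum()),
    )


def scale_errors(
    assignment: Assignment,
    calculated_shifts: dict[int, float],
) -> dict[int, float]:
    """Internally scaled prediction errors, one per assigned carbon.

    Fits delta_exp ~ a * delta_calc + b by least squares over the assigned
    atoms and returns Delta_i = (a * calc_i + b) - exp_i.  With fewer than
    three assigned atoms, or a degenerate spread of calculated shifts, the
    raw errors are returned unscaled (logged).
    """
    atoms = sorted(assignment.mapping)
    calc = np.array([calculated_shifts[a] for a in atoms])
    exp = np.array([assignment.mapping[a] for a in atoms])
    if len(atoms) < 3:
        log.warning("only %d assigned atoms; returning unscaled errors", len(atoms))
        a, b = 1.0, 0.0
    elif np.ptp(calc) < 1e-9:
        log.warning("degenerate shift spread; returning unscaled errors")
        a, b = 1.0, 0.0
    else:
        a, b = np.polyfit(calc, exp, 1)
    return {atom: float(a * c + b - e) for atom, c, e in zip(atoms, calc, exp)}


def _weighted_silverman(errors: np.ndarray, weights: np.ndarray) -> float:
    """Silverman's rule on the weighted sample, with effective sample size."""
    n_eff = weights.sum() ** 2 / np.sum(weights**2)
    mean = float(np.dot(weights, errors))
    var = float(np.dot(weights, (errors - mean) ** 2))
    sd = np.sqrt(max(var, 0.0))
    # weighted IQR via the weighted empirical CDF
    order = np.argsort(errors)
    cum = np.cumsum(weights[order])
    q25 = errors[order][np.searchsorted(cum, 0.25)]
    q75 = errors[order][np.searchsorted(cum, min(0.75, cum[-1]))]
    spread = min(sd, (q75 - q25) / 1.34) if q75 > q25 else sd
    if spread <= 0:
        return BANDWIDTH_FLOOR
    return max(0.9 * spread * n_eff ** (-0.2), BANDWIDTH_FLOOR)


def build_atomic_pdf(
    weights: np.ndarray,
    db: ErrorDatabase,
    bandwidth: float | str = "auto",
) -> AtomicErrorPDF:
    """Bespoke error density for one atom from its kernel weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != len(db):
        raise DomainError("weight vector length does not match the database")
    if np.any(weights < 0):
        raise DomainError("kernel weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise DomainError("at least one positive weight is required")
    norm = weights / total
    if bandwidth == "auto":
        if np.count_nonzero(norm) == 1:
            log.warning("single positive weight; using floor bandwidth %.2f ppm",
                        BANDWIDTH_FLOOR)
            bw = BANDWIDTH_FLOOR
        else:
            bw = _weighted_silverman(db.errors, norm)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise DomainError("bandwidth must be positive")
    return AtomicErrorPDF(errors=db.errors, weights=norm, bandwidth=bw)


def atomic_probability(
    pdf: AtomicErrorPDF,
    delta_i: float,
    eps_star: float,
    scheme: str = "window",
) -> float:
    """Probability of the observed scaled error under the bespoke density."""
    if not np.isfinite(delta_i):
        raise DomainError("scaled error must be finite")
    if eps_star <= 0:
        raise DomainError("eps_star must be positive")
    if scheme == "window":
        p = pdf.cdf(delta_i + eps_star) - pdf.cdf(delta_i - eps_star)
    elif scheme == "two_tail":
        a = abs(delta_i)
        p = 1.0 - (pdf.cdf(a) - pdf.cdf(-a))
    else:
        raise DomainError(f"unknown probability scheme {scheme!r}")
    return float(np.clip(p, 0.0, 1.0))


def build_error_database(
    corpus: list[tuple[Molecule, PeakList]],
    params: DescriptorParams,
    conformer_index: int = 0,
    sigma: float | str = "auto",
    seed: int = 0,
) -> ErrorDatabase:
    """Build the reference error database from a (molecule, spectrum) corpus.

    One record per carbon per molecule, using a single designated conformer:
    the molecule's shifts are assigned to its own peaks, internally scaled,
    and stored next to the carbon's environment descriptor.  ``sigma="auto"``
    resolves the kernel length scale by the median heuristic on the collected
    descriptors.
    """
    all_desc, all_err, all_ids, all_atoms = [], [], [], []
    params_hash = params.params_hash
    for molecule, peaks in corpus:
        if params.params_hash != params_hash:
            raise IncompatibleParamsError("descriptor params changed mid-corpus")
        shifts = molecule.carbon_shifts(conformer_index)
        idx = molecule.carbon_indices
        assignment = assign_peaks(shifts, peaks, atom_indices=idx)
        conf_shifts = {int(i): float(s) for i, s in zip(idx, shifts)}
        deltas = scale_errors(assignment, conf_shifts)
        d_idx, matrix = compute_descriptors(molecule, conformer_index, params)
        for row, atom in zip(matrix, d_idx):
            atom = int(atom)
            if atom not in deltas:
                continue  # unassigned carbon contributes no error record
            all_desc.append(row)
            all_err.append(deltas[atom])
            all_ids.append(molecule.molecule_id)
            all_atoms.append(atom)
    if not all_desc:
        raise DomainError("corpus produced no error records")
    descriptors = np.stack(all_desc)
    resolved = (
        local_scale_sigma(descriptors, seed=seed)
        if sigma == "auto"
        else float(sigma)
    )
    return ErrorDatabase(
        descriptors=descriptors,
        errors=np.array(all_err),
        molecule_ids=np.array(all_ids, dtype=object),
        params=params,
        sigma=resolved,
        atom_indices=np.array(all_atoms),
    )
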