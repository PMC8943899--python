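"""Conformer combination, molecular probability, and Bayesian calibration.

Pipeline: per-conformer atomic probabilities are Boltzmann-averaged over the
conformer ensemble; the per-atom values p_i are combined into the molecular
probability P_n as their geometric mean,

    P_n = (prod_i p_i)^(1/n),

a symmetric, idempotent-on-constants, monotone combination in which no single
atom can dominate.  P_n is then mapped to the final verification probability
by Bayes' theorem over empirical densities of P_n for known-correct and
known-incorrect structure-spectrum pairs:

    P(correct | P_n) = pi f_c(P_n) / (pi f_c(P_n) + (1 - pi) f_i(P_n)).

The class densities are boundary-corrected kernel density estimates on [0,1]
(Gaussian KDE in logit space, back-transformed with the Jacobian).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .chem_io import Molecule, PeakList
from .environments import EnvironmentDescriptor, KernelParams, kernel_weights
from .error_model import (
    Assignment,
    ErrorDatabase,
    assign_peaks,
    atomic_probability,
    build_atomic_pdf,
    scale_errors,
)
from .environments import compute_descriptors
from .exceptions import CalibrationError, DomainError

log = logging.getLogger(__name__)

GAS_CONSTANT_KJ = 8.31446e-3  # kJ / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K
PROBABILITY_FLOOR = 1e-12
DENSITY_FLOOR = 1e-12
CALIBRATION_GRID_SIZE = 512
MIN_CALIBRATION_SAMPLES = 30


@dataclass
class BoltzmannWeights:
    weights: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE


def boltzmann_weights(
    relative_energies, temperature: float = DEFAULT_TEMPERATURE
) -> BoltzmannWeights:
    """Population weights w_c proportional to exp(-E_c / RT)."""
    energies = np.asarray(relative_energies, dtype=float)
    if energies.size == 0:
        raise DomainError("no conformer energies")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    raw = np.exp(-(energies - energies.min()) / (GAS_CONSTANT_KJ * temperature))
    return BoltzmannWeights(weights=raw / raw.sum(), temperature=temperature)


def combine_conformers(
    per_conformer_atomic_p: np.ndarray, weights: BoltzmannWeights
) -> np.ndarray:
    """Boltzmann-average a (conformer x atom) probability table."""
    table = np.asarray(per_conformer_atomic_p, dtype=float)
    if table.ndim != 2 or table.shape[0] != weights.weights.size:
        raise DomainError(
            f"table shape {table.shape} does not match "
            f"{weights.weights.size} conformer weights"
        )
    return weights.weights @ table


def molecular_probability(atomic_p, n: int | None = None) -> float:
    """Geometric mean of the per-atom probabilities (floored at 1e-12)."""
    p = np.asarray(atomic_p, dtype=float)
    if n is None:
        n = p.size
    if n < 1 or p.size != n:
        raise DomainError(f"need n >= 1 atomic probabilities, got {p.size} for n={n}")
    if np.any(p <= 0):
        log.info("clipping %d non-positive atomic probabilities to %g",
                 int(np.sum(p <= 0)), PROBABILITY_FLOOR)
    p = np.clip(p, PROBABILITY_FLOOR, 1.0)
    return float(np.exp(np.mean(np.log(p))))


# ---------------------------------------------------------------------------
# Calibration


def _logit(x: np.ndarray) -> np.ndarray:
    return np.log(x) - np.log1p(-x)


CALIBRATION_BANDWIDTH_FACTOR = 1.0


def _silverman_logit_bandwidth(samples: np.ndarray, weights: np.ndarray) -> float:
    """Silverman bandwidth on the weighted logit sample (scalable factor)."""
    eps = 1e-6
    t = _logit(np.clip(samples, eps, 1 - eps))
    w = weights / weights.sum()
    n_eff = w.sum() ** 2 / np.sum(w**2)
    mean = float(np.dot(w, t))
    sd = float(np.sqrt(max(np.dot(w, (t - mean) ** 2), 1e-12)))
    return max(CALIBRATION_BANDWIDTH_FACTOR * 1.06 * sd * n_eff ** (-0.2), 1e-3)


def _logit_kde_density(
    samples: np.ndarray,
    weights: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Boundary-corrected KDE on [0,1]: Gaussian KDE in logit space.

    f(x) = sum_j w_j phi((logit x - t_j) / h) / (h x (1 - x)); the Jacobian
    factor keeps unit mass on (0,1).  Bandwidth defaults to Silverman's rule
    on the weighted logit sample.
    """
    eps = 1e-6
    t = _logit(np.clip(samples, eps, 1 - eps))
    w = weights / weights.sum()
    if bandwidth is None:
        bandwidth = _silverman_logit_bandwidth(samples, weights)
    tg = _logit(grid)
    z = (tg[:, None] - t[None, :]) / bandwidth
    phi = np.exp(-0.5 * z**2) / (bandwidth * np.sqrt(2 * np.pi))
    density = (phi @ w) / (grid * (1 - grid))
    area = np.trapezoid(density, grid)
    density = density / area  # renormalize quadrature mass on the open grid
    return np.maximum(density, DENSITY_FLOOR)


@dataclass
class CalibrationModel:
    """Empirical Bayes map from molecular probability P_n to P(correct|P_n)."""

    grid: np.ndarray  # interior grid on (0, 1)
    density_correct: np.ndarray
    density_incorrect: np.ndarray
    prior_correct: float = 0.5
    transform: str = "logit"

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_correct < 1.0:
            raise CalibrationError("prior_correct must be in (0,1)")

    def f_correct(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.density_correct)

    def f_incorrect(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.grid, self.density_incorrect)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("grid", data=self.grid)
            f.create_dataset("density_correct", data=self.density_correct)
            f.create_dataset("density_incorrect", data=self.density_incorrect)
            f.attrs["prior_correct"] = self.prior_correct
            f.attrs["transform"] = self.transform

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        with h5py.File(path, "r") as f:
            return cls(
                grid=f["grid"][()],
                density_correct=f["density_correct"][()],
                density_incorrect=f["density_incorrect"][()],
                prior_correct=float(f.attrs["prior_correct"]),
                transform=str(f.attrs["transform"]),
            )


def fit_calibration(
    correct_Pn,
    incorrect_Pn,
    incorrect_weights=None,
    prior_correct: float = 0.5,
    grid_size: int = CALIBRATION_GRID_SIZE,
) -> CalibrationModel:
    """Fit the correct/incorrect P_n densities behind the Bayes correction.

    The incorrect class accepts sampling weights (e.g. MAE-matching weights)
    so its density reflects the weighted population.  Each class needs at
    least 30 samples; anything less is refused rather than producing a junk
    calibration.
    """
    correct = np.asarray(correct_Pn, dtype=float)
    incorrect = np.asarray(incorrect_Pn, dtype=float)
    for name, s in (("correct", correct), ("incorrect", incorrect)):
        if s.size < MIN_CALIBRATION_SAMPLES:
            raise CalibrationError(
                f"{name} class has {s.size} samples; "
                f">= {MIN_CALIBRATION_SAMPLES} required"
            )
    if incorrect_weights is None:
        incorrect_weights = np.ones_like(incorrect)
    else:
        incorrect_weights = np.asarray(incorrect_weights, dtype=float)
        if np.any(incorrect_weights < 0) or incorrect_weights.sum() <= 0:
            raise CalibrationError("incorrect weights must be >= 0 and not all zero")
    grid = (np.arange(grid_size) + 0.5) / grid_size
    # one pooled bandwidth for both classes: the density *ratio* drives the
    # posterior, and mismatched bandwidths alone would fake class differences
    pooled = np.concatenate([correct, incorrect])
    pooled_w = np.concatenate([np.ones_like(correct), incorrect_weights])
    bw = _silverman_logit_bandwidth(pooled, pooled_w)
    return CalibrationModel(
        grid=grid,
        density_correct=_logit_kde_density(correct, np.ones_like(correct),
                                           grid, bandwidth=bw),
        density_incorrect=_logit_kde_density(incorrect, incorrect_weights,
                                             grid, bandwidth=bw),
        prior_correct=prior_correct,
    )


def dp5_probability(Pn: float, model: CalibrationModel) -> float:
    """Bayes posterior P(correct | P_n) under the fitted class densities."""
    if not 0.0 <= Pn <= 1.0:
        raise DomainError(f"molecular probability {Pn} outside [0,1]")
    fc = float(model.f_correct(Pn))
    fi = float(model.f_incorrect(Pn))
    pi = model.prior_correct
    denom = pi * fc + (1 - pi) * fi
    if denom <= 0:
        log.warning("both class densities vanish at Pn=%.4f; returning prior", Pn)
        return pi
    return float(pi * fc / denom)


# ---------------------------------------------------------------------------
# Full per-structure pipeline


@dataclass
class DP5Result:
    molecule_id: str
    atomic_probabilities: np.ndarray  # per carbon, Boltzmann-combined
    molecular_probability: float
    dp5: float | None
    assignment: Assignment  # for the designated (first) conformer
    scaled_errors: dict[int, float]
    conformer_weights: BoltzmannWeights
    diagnostics: np.ndarray  # (conformer, atom) probability table
    carbon_indices: np.ndarray = field(default_factory=lambda: np.array([], int))

    def to_dict(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "molecular_probability": round(self.molecular_probability, 12),
            "dp5": None if self.dp5 is None else round(self.dp5, 12),
            "conformer_weights": [round(float(w), 12)
                                  for w in self.conformer_weights.weights],
            "temperature_K": self.conformer_weights.temperature,
            "atoms": [
                {
                    "atom_index": int(a),
                    "atomic_probability": round(float(p), 12),
                    "assigned_peak_ppm": self.assignment.mapping.get(int(a)),
                    "scaled_error_ppm": self.scaled_errors.get(int(a)),
                }
                for a, p in zip(self.carbon_indices, self.atomic_probabilities)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_dp5(
    molecule: Molecule,
    peaks: PeakList,
    db: ErrorDatabase,
    model: CalibrationModel | None = None,
    scheme: str = "window",
    bandwidth: float | str = "auto",
    kernel_sigma: float | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    exclude_molecule: str | None = None,
) -> DP5Result:
    """Full verification pipeline for one candidate structure.

    For each conformer: assign shifts to peaks, internally scale the errors,
    weight the database by environment similarity, build each carbon's
    bespoke error PDF and integrate it to an atomic probability.  The
    conformer tables are Boltzmann-combined, reduced to the molecular
    probability, and (when a calibration model is given) mapped to the final
    DP5 probability.  Deterministic given inputs and configuration.
    """
    sigma = kernel_sigma if kernel_sigma is not None else db.sigma
    if sigma is None:
        raise DomainError("no kernel sigma: set one in the database or pass it")
    kparams = KernelParams(sigma=float(sigma))
    carbon_idx = molecule.carbon_indices
    n_conf = len(molecule.conformers)
    table = np.zeros((n_conf, carbon_idx.size))
    first_assignment: Assignment | None = None
    first_deltas: dict[int, float] = {}

    for c in range(n_conf):
        shifts = molecule.carbon_shifts(c)
        try:
            assignment = assign_peaks(shifts, peaks, atom_indices=carbon_idx)
            conf_shifts = {int(i): float(s) for i, s in zip(carbon_idx, shifts)}
            deltas = scale_errors(assignment, conf_shifts)
            _, matrix = compute_descriptors(molecule, c, db.params)
        except DomainError as exc:
            raise DomainError(f"conformer {c}: {exc}") from exc
        if first_assignment is None:
            first_assignment, first_deltas = assignment, deltas
        for a, atom in enumerate(carbon_idx):
            atom = int(atom)
            if atom not in deltas:
                table[c, a] = np.nan  # unassigned: excluded from combination
                continue
            desc = EnvironmentDescriptor(
                vector=matrix[a], element="C", params_hash=db.params.params_hash
            )
            weights = kernel_weights(desc, db, kparams,
                                     exclude_molecule=exclude_molecule)
            pdf = build_atomic_pdf(weights, db, bandwidth=bandwidth)
            table[c, a] = atomic_probability(pdf, deltas[atom], db.eps_star,
                                             scheme=scheme)

    weights = boltzmann_weights(molecule.relative_energies(), temperature)
    assigned_cols = ~np.any(np.isnan(table), axis=0)
    combined = np.full(carbon_idx.size, np.nan)
    if assigned_cols.any():
        combined[assigned_cols] = combine_conformers(
            table[:, assigned_cols], weights
        )
    pn = molecular_probability(combined[assigned_cols])
    dp5 = dp5_probability(pn, model) if model is not None else None
    return DP5Result(
        molecule_id=molecule.molecule_id,
        atomic_probabilities=np.where(assigned_cols, combined, 0.0),
        molecular_probability=pn,
        dp5=dp5,
        assignment=first_assignment,
        scaled_errors=first_deltas,
        conformer_weights=weights,
        diagnostics=table,
        carbon_indices=carbon_idx,
    )
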