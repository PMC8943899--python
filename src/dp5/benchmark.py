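"""Cross-validation harness: spectrum permutation, MAE matching, LOO scoring.

Correct pairs match each structure with its own spectrum; incorrect pairs
match it with the spectrum of a different molecule having the same carbon
count (permutation), or with a synthetically regenerated wrong spectrum
(regime pairs).  Two evaluation regimes mirror the method's two stress
levels:

* case 1 keeps only incorrect pairs whose maximum scaled error is below
  10 ppm (structures an experienced spectroscopist could already reject);
* case 2 keeps all incorrect pairs but importance-weights them so their MAE
  distribution matches the correct pairs' — correct and incorrect become
  indistinguishable by error size alone.

All probabilities are computed leave-one-out: the test structure's own atoms
never enter its reference database, and the calibration is refitted k-fold
so no pair is calibrated on itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.metrics import roc_auc_score

from .chem_io import Molecule, PeakList
from .dp5_core import dp5_probability, fit_calibration, run_dp5
from .error_model import (
    ErrorDatabase,
    assign_peaks,
    build_error_database,
    scale_errors,
)
from .environments import DescriptorParams
from .exceptions import CalibrationError, DomainError
from .synthetic import SyntheticSpec, generate_incorrect_spectrum

log = logging.getLogger(__name__)

CASE1_MAX_ERROR_PPM = 10.0
WEIGHT_CLIP_PERCENTILE = 99.5


@dataclass
class PairSample:
    structure_id: str
    spectrum_id: str
    label: str  # "correct" | "incorrect"
    peaks: PeakList
    mae: float
    max_error: float
    weight: float = 1.0
    pn: float | None = None
    dp5: float | None = None


@dataclass
class BenchmarkReport:
    case: str
    pairs: list[PairSample]
    auroc: float
    reliability_bins: np.ndarray  # bin midpoints
    reliability_fraction: np.ndarray  # weighted empirical fraction correct
    reliability_counts: np.ndarray
    reliability_mad: float
    max_dp5_correct: float
    n_correct: int
    n_incorrect_effective: float

    def to_dict(self) -> dict:
        return {
            "case": self.case,
            "auroc": round(self.auroc, 6),
            "reliability_mad": round(self.reliability_mad, 6),
            "max_dp5_correct": round(self.max_dp5_correct, 6),
            "n_correct": self.n_correct,
            "n_incorrect_effective": round(self.n_incorrect_effective, 3),
            "reliability": [
                {"bin_mid": float(b), "fraction_correct": float(f),
                 "count": int(c)}
                for b, f, c in zip(self.reliability_bins,
                                   self.reliability_fraction,
                                   self.reliability_counts)
                if c > 0
            ],
        }


def _pair_errors(molecule: Molecule, peaks: PeakList) -> np.ndarray:
    shifts = molecule.carbon_shifts(0)
    idx = molecule.carbon_indices
    assignment = assign_peaks(shifts, peaks, atom_indices=idx)
    deltas = scale_errors(
        assignment, {int(i): float(s) for i, s in zip(idx, shifts)}
    )
    return np.array([deltas[a] for a in sorted(deltas)])


def _make_pair(molecule: Molecule, peaks: PeakList, spectrum_id: str,
               label: str) -> PairSample:
    err = np.abs(_pair_errors(molecule, peaks))
    return PairSample(
        structure_id=molecule.molecule_id,
        spectrum_id=spectrum_id,
        label=label,
        peaks=peaks,
        mae=float(err.mean()),
        max_error=float(err.max()),
    )


def make_pairs(
    corpus: list[tuple[Molecule, PeakList]],
    case: str,
    max_incorrect_per_molecule: int | None = None,
    seed: int = 0,
) -> list[PairSample]:
    """Permute spectra among same-carbon-count molecules into labelled pairs.

    Every molecule contributes its correct pair; incorrect pairs exist only
    between molecules with equal carbon counts (optionally subsampled per
    structure, seeded).  Case 1 filters incorrect pairs at max error
    < 10 ppm with unit weights; case 2 keeps all and attaches MAE-matching
    weights.
    """
    if case not in ("case1", "case2"):
        raise DomainError(f"unknown benchmark case {case!r}")
    rng = np.random.default_rng(seed)
    by_count: dict[int, list[int]] = {}
    for i, (mol, _) in enumerate(corpus):
        by_count.setdefault(len(mol.carbon_indices), []).append(i)

    pairs: list[PairSample] = []
    for i, (mol, peaks) in enumerate(corpus):
        pairs.append(_make_pair(mol, peaks, spectrum_id=mol.molecule_id,
                                label="correct"))
        partners = [j for j in by_count[len(mol.carbon_indices)] if j != i]
        if not partners:
            log.info("%s: no same-size partner; correct pair only",
                     mol.molecule_id)
            continue
        if (max_incorrect_per_molecule is not None
                and len(partners) > max_incorrect_per_molecule):
            partners = list(rng.choice(partners, size=max_incorrect_per_molecule,
                                       replace=False))
        for j in partners:
            other_mol, other_peaks = corpus[j]
            pairs.append(_make_pair(mol, other_peaks,
                                    spectrum_id=other_mol.molecule_id,
                                    label="incorrect"))

    incorrect = [p for p in pairs if p.label == "incorrect"]
    if case == "case1":
        pairs = [p for p in pairs
                 if p.label == "correct" or p.max_error < CASE1_MAX_ERROR_PPM]
    else:
        correct_maes = np.array([p.mae for p in pairs if p.label == "correct"])
        if incorrect:
            weights = mae_matching_weights(
                correct_maes, np.array([p.mae for p in incorrect])
            )
            for p, w in zip(incorrect, weights):
                p.weight = float(w)
    return pairs


def make_regime_pairs(
    corpus: list[tuple[Molecule, PeakList]],
    spec: SyntheticSpec,
    regime: str,
    seed: int = 0,
) -> list[PairSample]:
    """One correct and one regenerated incorrect pair per molecule.

    ``regime="case1"`` uses the spec's inflation factor (grossly wrong
    spectra); ``regime="case2"`` uses inflation 1 (the error-indistinguishable
    regime) and attaches MAE-matching weights.
    """
    if regime not in ("case1", "case2"):
        raise DomainError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    inflation = spec.inflation if regime == "case1" else 1.0
    pairs: list[PairSample] = []
    for mol, peaks in corpus:
        pairs.append(_make_pair(mol, peaks, spectrum_id=mol.molecule_id,
                                label="correct"))
        wrong = generate_incorrect_spectrum(mol, spec, rng, inflation=inflation)
        pairs.append(_make_pair(mol, wrong,
                                spectrum_id=f"{mol.molecule_id}:wrong",
                                label="incorrect"))
    if regime == "case2":
        correct_maes = np.array([p.mae for p in pairs if p.label == "correct"])
        incorrect = [p for p in pairs if p.label == "incorrect"]
        weights = mae_matching_weights(
            correct_maes, np.array([p.mae for p in incorrect])
        )
        for p, w in zip(incorrect, weights):
            p.weight = float(w)
    return pairs


def mae_matching_weights(correct_maes, incorrect_maes) -> np.ndarray:
    """Importance weights forcing the incorrect-MAE distribution onto the
    correct one: w_j ~ f_correct(mae_j) / f_incorrect(mae_j) from 1-D KDEs,
    clipped at the 99.5th percentile and normalized to mean 1.
    """
    correct = np.asarray(correct_maes, dtype=float)
    incorrect = np.asarray(incorrect_maes, dtype=float)
    if correct.size == 0 or incorrect.size == 0:
        raise DomainError("both MAE samples must be nonempty")
    if correct.min() > incorrect.max() or incorrect.min() > correct.max():
        raise DomainError(
            "correct and incorrect MAE supports are disjoint; the corpora "
            "are not comparable"
        )
    f_c = gaussian_kde(correct)
    f_i = gaussian_kde(incorrect)
    dens_i = np.maximum(f_i(incorrect), 1e-300)
    w = f_c(incorrect) / dens_i
    w = np.minimum(w, np.percentile(w, WEIGHT_CLIP_PERCENTILE))
    if w.sum() <= 0:
        raise DomainError("all matching weights vanished; corpora incomparable")
    return w / w.mean()


def _reliability(labels, dp5s, weights, n_bins: int = 10):
    bins = np.linspace(0, 1, n_bins + 1)
    mids = (bins[:-1] + bins[1:]) / 2
    frac = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    which = np.clip(np.digitize(dp5s, bins) - 1, 0, n_bins - 1)
    for b in range(n_bins):
        mask = which == b
        counts[b] = int(mask.sum())
        if counts[b]:
            wsum = weights[mask].sum()
            frac[b] = float(np.sum(weights[mask] * (labels[mask] == "correct"))
                            / wsum) if wsum > 0 else 0.0
    occupied = counts > 0
    mad = float(np.mean(np.abs(frac[occupied] - mids[occupied])))
    return mids, frac, counts, mad


def loo_evaluate(
    corpus: list[tuple[Molecule, PeakList]],
    pairs: list[PairSample],
    params: DescriptorParams | None = None,
    db: ErrorDatabase | None = None,
    n_folds: int = 10,
    scheme: str = "window",
    bandwidth: float | str = "auto",
    prior_correct: float = 0.5,
    seed: int = 0,
    case: str = "custom",
) -> BenchmarkReport:
    """Score every pair leave-one-out and calibrate k-fold.

    Each pair's molecular probability is computed with the test structure's
    own database records excluded; the Bayes calibration seen by a pair is
    fitted only on pairs whose structures lie in other folds.
    """
    if params is None:
        params = DescriptorParams()
    if db is None:
        db = build_error_database(corpus, params, seed=seed)
    mols = {mol.molecule_id: mol for mol, _ in corpus}

    failures = 0
    for pair in pairs:
        try:
            result = run_dp5(
                mols[pair.structure_id], pair.peaks, db,
                scheme=scheme, bandwidth=bandwidth,
                exclude_molecule=pair.structure_id,
            )
            pair.pn = result.molecular_probability
        except DomainError as exc:  # recorded, not fatal
            failures += 1
            log.warning("pair (%s, %s) failed: %s", pair.structure_id,
                        pair.spectrum_id, exc)
    if failures:
        log.warning("%d/%d pairs failed", failures, len(pairs))
    scored = [p for p in pairs if p.pn is not None]

    # k-fold calibration refit over structures
    rng = np.random.default_rng(seed + 1)
    ids = sorted({p.structure_id for p in scored})
    fold_of = dict(zip(ids, rng.permutation(len(ids)) % n_folds))
    try:
        global_model = _fit_from_pairs(scored, None, prior_correct)
    except CalibrationError as exc:
        log.warning("corpus too small to calibrate (%s); reporting raw "
                    "molecular probabilities as scores", exc)
        global_model = None
    for k in range(n_folds):
        train = [p for p in scored if fold_of[p.structure_id] != k]
        test = [p for p in scored if fold_of[p.structure_id] == k]
        if not test:
            continue
        model = global_model
        try:
            model = _fit_from_pairs(train, None, prior_correct)
        except CalibrationError:
            log.warning("fold %d: too few training pairs; global calibration", k)
        for p in test:
            p.dp5 = dp5_probability(p.pn, model) if model is not None else p.pn

    labels = np.array([p.label for p in scored])
    dp5s = np.array([p.dp5 for p in scored])
    weights = np.array([p.weight for p in scored])
    auroc = float(roc_auc_score(labels == "correct", dp5s, sample_weight=weights))
    mids, frac, counts, mad = _reliability(labels, dp5s, weights)
    correct_dp5 = dp5s[labels == "correct"]
    return BenchmarkReport(
        case=case,
        pairs=pairs,
        auroc=auroc,
        reliability_bins=mids,
        reliability_fraction=frac,
        reliability_counts=counts,
        reliability_mad=mad,
        max_dp5_correct=float(correct_dp5.max()) if correct_dp5.size else float("nan"),
        n_correct=int(np.sum(labels == "correct")),
        n_incorrect_effective=float(weights[labels == "incorrect"].sum()),
    )


def _fit_from_pairs(pairs: list[PairSample], model, prior_correct: float):
    correct = np.array([p.pn for p in pairs if p.label == "correct"])
    incorrect = np.array([p.pn for p in pairs if p.label == "incorrect"])
    inc_w = np.array([p.weight for p in pairs if p.label == "incorrect"])
    return fit_calibration(correct, incorrect, incorrect_weights=inc_w,
                           prior_correct=prior_correct)


def rank_candidates(
    candidates: list[Molecule],
    peaks: PeakList,
    db: ErrorDatabase,
    model,
    scheme: str = "window",
    bandwidth: float | str = "auto",
) -> dict:
    """Independent DP5 per candidate plus the count-normalized dp5/k.

    Unlike enumerative ranking, candidate probabilities are NOT renormalized
    across the list; dividing by the candidate count merely keeps their sum
    within [0,1] for display.  Ties break by input order.
    """
    if len(candidates) < 2:
        raise DomainError("ranking needs at least two candidates")
    rows = []
    for c, mol in enumerate(candidates):
        try:
            result = run_dp5(mol, peaks, db, model=model, scheme=scheme,
                             bandwidth=bandwidth,
                             exclude_molecule=mol.molecule_id)
        except DomainError as exc:
            log.warning("candidate %s failed and is excluded: %s",
                        mol.molecule_id, exc)
            continue
        rows.append({
            "candidate_index": c,
            "molecule_id": mol.molecule_id,
            "molecular_probability": result.molecular_probability,
            "dp5": result.dp5,
        })
    if not rows:
        raise DomainError("every candidate failed")
    k = len(rows)
    for row in rows:
        row["dp5_normalized"] = None if row["dp5"] is None else row["dp5"] / k
    key = "dp5" if rows[0]["dp5"] is not None else "molecular_probability"
    best = max(rows, key=lambda r: (r[key], -r["candidate_index"]))
    return {"candidates": rows, "best_candidate_index": best["candidate_index"],
            "n_candidates": k}
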