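# Methods

This note records the statistical model the package implements, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Model

A candidate structure with carbons *i = 1…n*, conformers *c* with relative
energies *E_c*, calculated carbon shifts per conformer, and an experimental
¹³C peak list is scored in five stages.

**1. Assignment.** Calculated shifts are matched to experimental peaks by
minimum-total-|Δ| rectangular linear assignment (Hungarian algorithm);
multiplicity-*m* peaks are expanded to *m* slots first. If carbons outnumber
slots, the optimal injection is used and the rest are flagged unassigned
(they contribute no atomic probability and are excluded from the geometric
mean). Ties are resolved deterministically by the solver given the fixed
atom/peak ordering.

**2. Internal scaling.** Systematic slope/offset error in the calculated
shifts is removed per structure and per conformer by ordinary least squares,
δᵉˣᵖ ≈ a·δᶜᵃˡᶜ + b over assigned carbons; Δᵢ = (a·δᶜᵃˡᶜᵢ + b) − δᵉˣᵖᵢ.
With fewer than 3 assigned atoms or zero spread in calculated shifts the raw
differences are used (logged). Scaling is deliberately per conformer, keeping
the whole per-conformer pipeline intact before any Boltzmann averaging.

**3. Environment-conditioned error density.** Each carbon's environment is a
vector of element-channelled (C, H, O, N), Gaussian-smeared radial
histograms around the centre: cutoff 5 Å, 24 bins, smearing width 0.5 Å,
smooth cosine cutoff; optional angular (neighbour-pair angle) channels.
The representation depends only on internal distances/angles, so it is
invariant to translation, rotation and neighbour permutation. Only carbon
centres are represented (the method is ¹³C-only). Externally computed
invariant representations can be substituted through the HDF5 descriptor
exchange format.

Similarity between environments is the Gaussian kernel
k(d) = exp(−d²/2σ²) on Euclidean descriptor distance, with the prefactor
fixed at 1 so self-similarity is exactly 1 and k reads as a similarity. The
bespoke density for a test atom is the kernel-weighted Gaussian KDE over the
reference error database; records of the test structure itself get weight
exactly 0 under the leave-one-out scheme.

*Kernel length scale σ.* Default: the median distance to the 10th nearest
neighbour over the database (a local length-scale rule), computed on a
seeded subsample and stored in the database file. The classical global
median heuristic is also provided but is not the default: on clustered
environments the global median is dominated by between-cluster distances,
the kernel weights become near-uniform, every bespoke density collapses to
the marginal error distribution, and the environment conditioning that
defines the method stops doing anything (we measured chance-level case-2
discrimination under it). The k-NN rule sets σ to the spacing *within* a
neighbourhood of similar environments instead.

*KDE bandwidth.* Silverman's rule on the weighted sample using the effective
sample size (Σw)²/Σw², with a floor of 0.1 ppm (also used when only a single
record carries weight).

**4. Atomic and molecular probability.** The default integration scheme is
the symmetric window: pᵢ is the mass of the bespoke density within ε* of the
observed error, where ε* is the database-wide mean absolute error. ε* enters
the integral directly, making "typical-sized" errors probable and outliers
improbable *relative to their own environment* — atoms with larger errors can
legitimately score higher than atoms with smaller ones when their
environments differ. A two-tail alternative, P(|X| ≥ |Δᵢ|), is available via
configuration; both are evaluated in closed form with the normal CDF and
cross-checked against adaptive quadrature in the tests. Per-conformer
probabilities are Boltzmann-combined at 298.15 K
(R = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹) and reduced by the geometric mean
Pₙ = (∏pᵢ)^{1/n} — symmetric, equal to the common value on constant inputs,
monotone in every pᵢ, and resistant to any single atom dominating (each atom
contributes 1/n of the log). Probabilities are floored at 10⁻¹² before the
log (floor hits are logged).

**5. Empirical Bayes calibration.** Pₙ alone is not a probability of
correctness; it is calibrated against empirical densities of Pₙ for
known-correct and known-incorrect structure–spectrum pairs:
DP5 = π f_c(Pₙ) / (π f_c(Pₙ) + (1−π) f_i(Pₙ)), prior π = 0.5 by default
(correct/incorrect treated as the two a-priori-equal hypotheses; the prior is
configurable). The class densities are Gaussian KDEs in logit space,
back-transformed with the Jacobian so they live on (0,1) with unit mass
(boundary-corrected), evaluated on a 512-point grid and floored at 10⁻¹²
before the ratio. Both classes share one pooled Silverman bandwidth: the
posterior depends on the density *ratio*, and mismatched per-class
bandwidths alone would manufacture spurious class differences. The density
floor keeps the posterior strictly inside (0,1): no structure is ever
verified or refuted with probability exactly 1, and in practice the maximum
DP5 attained by correct pairs sits well below 1 — the ceiling reflects the
irreducible spread of the prediction errors themselves. The incorrect-class
KDE accepts per-sample importance weights (see the benchmark).

## Benchmark harness

Correct pairs match each structure with its own spectrum. Incorrect pairs
come either from **permutation** (spectra exchanged among molecules with the
same carbon count — the faithful construction, needing corpora large enough
that some permuted pairs have error sizes comparable to correct pairs) or
from **regenerated wrong spectra** (the synthetic generator's incorrect
mode, usable at any corpus size; the CLI default). Two regimes:

* **case 1** — incorrect pairs restricted to max scaled error < 10 ppm
  (permutation) or drawn with a 5× error inflation (regenerated): the
  "gross error" regime.
* **case 2** — all incorrect pairs kept and importance-weighted so their MAE
  distribution matches the correct pairs': w ∝ f_corr(MAE)/f_inc(MAE) from
  1-D KDEs, clipped at the 99.5th percentile and normalized to mean 1.
  Disjoint MAE supports are refused as incomparable. In this regime the
  classes cannot be told apart by error size; only the structure of *which
  environments carry which errors* remains.

All DP5 values are leave-one-out: the test structure's records are excluded
from its reference database, and the calibration is refitted k-fold (default
10 folds over structures) so no pair is scored by a calibration fitted on
itself; full per-pair refitting would be quadratic in corpus size for no
qualitative difference. Reports carry AUROC (weighted, via the pair
weights), the decile reliability curve (weighted fraction correct per
predicted-DP5 decile vs the bin midpoint), and the maximum DP5 among correct
pairs.

## Synthetic data

The generator emulates the statistical structure the method relies on, not
chemistry:

* Molecules are random acyclic C/H/O/N skeletons (6–10 carbons, single
  bonds) with one 3D conformer embedded deterministically; descriptors are
  computed from these real geometries. A direct-vector mode generates
  clustered descriptors with no geometry for unit-level tests.
* Each carbon belongs to one of 4 latent clusters keyed on its local
  chemistry (heavy-neighbour count, heteroatom attachment), so the clusters
  are recoverable from the descriptors. Calculated shifts are cluster base
  shifts (20/65/110/160 ppm) plus 15 ppm Gaussian spread — wide enough that
  optimal assignment recovers the true pairing for the large majority of
  correct-pair atoms, mirroring automated assignment accuracy on real
  spectra.
* Correct-pair errors are Student-t(5) with per-cluster location
  (0, 0.5, −0.5, 1 ppm) and scale (0.5, 1, 2, 4 ppm): heavy tails, and error
  *spread* that genuinely varies with environment. The corpus-wide MAE lands
  near 1.7 ppm, the regime of good DFT shift predictions.
* Incorrect spectra resample the cluster label per atom (drawing from the
  marginal error mixture) and multiply by an inflation factor. Inflation 1
  leaves the per-pair MAE distribution identical to correct pairs while
  destroying the error–environment association — the case-2 regime;
  inflation 5 (default) gives case-1-style gross errors.

What passing tests therefore show: the pipeline detects mispairings when
errors are large, and still detects the *broken association between error
size and environment* when error sizes are matched. What they do not show:
performance on real DFT error surfaces (whose environment dependence is more
complex than 4 t-distributed clusters), on molecules with rings, aromatics,
exchange-broadened or overlapping peaks, or with real assignment ambiguity
beyond what the optimal matcher sees.

## Numerical choices and problem sizes

* Atomic probabilities: closed-form normal-CDF sums, clipped to [0,1];
  quadrature agreement to 10⁻⁶ is asserted in tests.
* Geometric-mean floor 10⁻¹²; calibration density floor 10⁻¹²; calibration
  refused below 30 samples per class.
* Assignment/scaling degeneracies (single peak, equal shifts) fall back to
  unscaled errors with a logged warning rather than failing.
* The cross-validation studies in the tests and acceptance script use a
  500-molecule corpus (~4000 database records, 500 correct + 500 incorrect
  pairs per regime), which keeps the full double study under a minute on one
  CPU while leaving the discrimination and reliability estimates stable to a
  few hundredths.
* Every stochastic step (corpus generation, conformer embedding, fold
  assignment, σ subsampling) is driven by explicit seeds; repeated seeded
  CLI runs are byte-identical.

## Known limitations

* The descriptor is coarser than learned or physics-complete
  representations (FCHL, aSLATM); the plug-in hook exists precisely so a
  stronger representation can be dropped in without touching the statistics.
* Case-2 discrimination is real but modest (AUROC ≈ 0.55–0.6 under the
  default synthetic conditions) — consistent with the regime's design, where
  error sizes carry no signal at all.
* Calibration reliability depends on the evaluation regime; with sharply
  bimodal DP5 distributions (case 1) the decile curve is well behaved, while
  heavily weighted case-2 populations are noisier.
* ¹H shifts, multi-spectrum fusion, and any comparative (DP4-style)
  renormalization across candidates are out of scope; candidate ranking
  reports independent probabilities plus a count-normalized convenience
  value only.
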