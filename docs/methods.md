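# Methods

This note documents the models and procedures `urinmr` implements, the
defaults that matter, what the synthetic generator does and does not
emulate, and the design decisions taken where the field leaves room.

## Study design assumed

A paired longitudinal design: each subject contributes one acute-phase
and one chronic-phase urine sample, plus clinical scores (NIHSS at
baseline; FIM and CMSA hand/arm at baseline and ~6 months). All
statistics respect the pairing: differences are chronic minus acute,
cross-validation folds never split a subject's two samples, and
permutation nulls swap phase labels within subjects.

## Spectral processing

**Referencing.** The ppm axis is translated so the apex of the tallest
peak in a search window (default −0.2 to 0.2 ppm) sits at 0.000 — the
TSP reference singlet. Translation only; intensities untouched.
Spectra are then linearly interpolated onto a common descending grid
spanning the intersection of all axes.

**Alignment (RSPA).** Each spectrum is aligned to the reference
spectrum (the one maximizing mean Pearson correlation to the rest;
ties go to the lowest index) by recursive segmentation: the best
integer-gridpoint lag within ±`max_shift` (default 0.02 ppm) is found
by maximizing Pearson correlation of the overlapping parts, the
segment is translated with edge-value padding, then split at the
lowest reference trough near its midpoint and each half refined
(default depth 6, minimum segment 32 points, segments correlating
below 0.1 left unshifted). Integer shifts keep the operation exactly
invertible and reproducible; sub-gridpoint interpolation is
deliberately not performed since at realistic point densities the
sub-point error is negligible against linewidth.

**Binning.** Boundaries are placed at local minima of the
moving-average-smoothed mean spectrum (default 5-point window).
Adjacent bins are merged until each is at least `min_bin_width`
(default 0.02 ppm), dropping the shallower of the two candidate
boundaries first; maximal runs of bins whose smoothed maximum stays
below `noise_floor` (default 2% of the maximum intensity) collapse
into single noise bins. Bins partition the window exactly, boundaries
snap to grid points, and bin centers sit at the mean-spectrum apex
within the bin — so the sum of bin integrals equals the whole-window
integral and labels land on the peak position. A manual bin-editing
step common in practice is replaced by this deterministic merge rule:
manual steps are not reproducible. Water (4.70–5.00 ppm) and urea
(5.40–6.00 ppm) regions are excluded after binning (the manifest keeps
the excluded bins); both ranges are configurable since conventions
differ between labs.

**Integration.** Trapezoidal integral per bin; negative integrals are
floored at zero with a logged count.

## Preprocessing

Order: total-metabolome normalization → log transform → pareto
scaling → OLS residualization. Normalization divides each sample by
its total over the non-excluded bins, cancelling the multiplicative
urine-dilution factor. The log offset is half the smallest positive
matrix value by default (a fixed ε is available). Pareto scaling
divides centered columns by the square root of the sample standard
deviation (n − 1 denominator); constant columns map to zero. The
log-then-pareto order is a choice: pareto-then-log is undefined for
the negatives that centering produces, so the conventional
metabolomics order is the default and the other order remains
configurable. Residualization regresses every column on
[intercept, age, sex] in one least-squares solve and keeps the
residuals; it is idempotent and leaves covariate-orthogonal columns
unchanged. All statistics downstream consume the fully preprocessed
matrix.

## Univariate testing

Per bin, the Shapiro–Wilk test (α = 0.05) on the paired differences
decides between the paired *t*-test and the Wilcoxon signed-rank test;
constant differences route to the nonparametric branch. The Wilcoxon
p is exact for n ≤ 25 via the shift-algorithm dynamic programme over
doubled mid-ranks (ties handled exactly), otherwise a normal
approximation with tie and continuity corrections. Zero differences
are dropped per the standard signed-rank convention. Both raw and
Bonferroni–Holm-adjusted p-values are reported, since published tables
mix the two conventions; regulation is the sign of the median
chronic-minus-acute difference.

## VIAVC variable selection

Binary matrix resampling draws `n_resamples` (default 500) random
subsets, each variable included independently with probability 0.5
(rows with fewer than two variables are redrawn). Each subset is
scored by subject-grouped k-fold (default 10) cross-validated AUC of a
PLS-LDA model — PLS1 of the ±1 labels, components capped at 2 for
n ≈ 20 regimes, held-out scores pooled and AUC computed by pairwise
concordance. For each variable, one-sided rank-sum tests compare the
AUC distributions of subsets containing vs lacking it: significantly
higher → strongly informative, higher (or exactly tied) but not
significant → weakly informative, significantly lower → interfering,
otherwise uninformative. Uninformative and interfering variables are
dropped and the loop repeats until nothing is dropped (or fewer than
3 variables / 20 iterations remain).

Two internals deserve justification. First, the classification
contrast uses **all** resampled subsets rather than only a top
fraction: restricting to the top 10% leaves ~10-vs-10 comparisons per
variable, which is statistical noise — in planted-truth experiments
informative variables were then randomly discarded and recovery fell
to ~0.3–0.5, versus ~0.85 with the full-set contrast (a top-fraction
restriction remains available via `top_fraction`). Second, exact AUC
ties between the with/without distributions (common once the panel
saturates at AUC 1.0) classify as weakly informative: in the
saturated regime a redundant-but-informative variable shows no
contrast, and treating ties as uninformative makes the iteration
cascade below the true panel instead of reaching a fixed point.

Survivors are F-ranked by the mean AUC of the best subsets containing
them; the best subset is the F-ranked prefix maximizing double
cross-validated AUC (outer subject-grouped folds estimate performance,
inner folds pick the component count). Per-variable p-values come
from a within-pair label-permutation null (default 999 permutations)
of each survivor's single-variable cross-validated AUC, Holm-adjusted.
Re-running the entire resampling procedure per permutation would cost
n_perm × n_resamples × folds model fits and is computationally out of
reach; the single-variable statistic preserves the paired design and
calibrates correctly on null panels.

## OPLS-DA and ROC

The predictive weight is w ∝ Xᵀy (centered); each orthogonal
component takes the loading p of the current predictive score,
removes its w-component (w_orth ∝ p − (wᵀp)w), and deflates X by the
orthogonal score/loading pair — orthogonal scores are exactly
uncorrelated with y by construction. The final predictive component
is fit on the deflated matrix; with zero orthogonal components the
scores coincide with one-component PLS1. `n_orth` defaults to
whichever of 0–3 maximizes Q². Q² = 1 − PRESS/TSS over held-out
predictions with subject-grouped folds. Permutation p-values for R²Y
and Q² swap phase labels within subjects; the default 1999
permutations put the smallest attainable p at 5 × 10⁻⁴. A zero
covariance between X and y (possible under permutation) yields a
degenerate flat model with R²Y = 0 rather than a numerical error.

ROC evaluation always uses cross-validated scores, never
resubstitution. AUC is pairwise concordance (ties count ½) — equal to
Mann–Whitney U/(n₁n₀) and to the trapezoidal area under the swept
curve. The 95% CI is a stratified bootstrap percentile interval
(default 2000 replicates); accuracy is the fraction correct at score
threshold 0, the natural boundary for balanced ±1 coding — a Youden
threshold would be optimistically biased at n = 20.

## Pathway analysis

Hypergeometric upper tail P(X ≥ k) for k query hits among K pathway
members, n mapped query compounds, and background N = the library's
compound universe (configurable). Name matching is case-insensitive
through a synonym map. The impact score is the fraction of total
relative betweenness centrality (normalized by (v−1)(v−2)/2 on the
undirected, unweighted compound graph) carried by the hit nodes. The
bundled pathway library is a small synthetic stand-in with plausible
compound sets and connectivity — its p-values are structural
illustrations, not database results, and real-database p-values are
version-dependent by nature.

## Clinical correlations

The change statistic is the percent difference relative to the mean
of the two time points, bounded in (−200, 200). Three Spearman
families: acute levels vs initial scores (NIHSS, FIM, CMSA × 2);
acute levels vs score percent differences (FIM, CMSA × 2 — NIHSS has
no follow-up); metabolite percent differences vs score percent
differences. rho is Pearson on mid-ranks; p uses the
t = rho·√((n−2)/(1−rho²)) approximation on n−2 df, which reproduces
published (rho, p) pairs at n = 10 to the printed precision; an exact
permutation p is available for n ≤ 8. The significance threshold is
α/m for an m-bin panel (0.00625 at α = 0.05, m = 8). Quantile
summaries use linear interpolation between order statistics — this
convention, and pairwise deletion of missing scores, reproduce the
published cohort-table medians, IQRs and means exactly, where Tukey
hinges do not.

## Synthetic cohort generator

What it emulates: Lorentzian peaks (natural NMR lineshape; area =
height·π·HWHM) at literature chemical shifts for 13 named urinary
metabolites plus random fillers; per-sample ppm jitter (0.002 ppm sd),
Gaussian point noise, a smooth sinusoidal baseline, a TSP reference
singlet and broad water/urea humps; log-normal between-subject
concentrations (σ = 0.35) with a per-sample log-normal dilution
factor (σ = 0.3) that normalization must remove; planted chronic/acute
log₂ fold changes on an 8-metabolite panel (|FC| 0.7–1.0, signs
matching the down/up pattern of the motivating study) with σ = 0.2
within-subject noise; additive age/sex confounds on log-concentration;
and integer-valued clinical scores whose improvements follow the
percent change of a designated metabolite (pseudouridine) through a
linear link (slope 0.08 CMSA points per percent, noise 0.15, baseline
improvement 6.0 before the percent-change term), clipped and rounded
to instrument ranges.

What it does not emulate: J-coupling multiplets, pH-dependent shift
drift, correlated (colored) noise, batch effects, or realistic
inter-metabolite correlation structure. Passing recovery tests
therefore demonstrates that the pipeline's inference machinery is
correct and calibrated under known truth — not that it would achieve
the same numbers on real spectra.

Calibration choices (made once, at design time): the planted effect
sizes give OPLS-DA Q² ≈ 0.7–0.9 on default cohorts, the range typical
of strong paired metabolomics separations; the clinical-link
parameters give a mean hand improvement ≈ 0.7 points and make the
linked metabolite the top third-family correlate in ≈96% of cohorts;
initial CMSA scores center at 4 so the 7-point ceiling does not
saturate the link. Desk-scale spectra use 4096 points over
(−0.2, 9.5) ppm with 0.015 ppm HWHM linewidths — about 6 grid points
per half-width, preserving the point-density-to-linewidth ratio that
real 256k-point acquisitions have, which is what integration fidelity
actually depends on.

## Numerical choices and degenerate inputs

- Alignment shifts are integer gridpoints; correlation ties prefer the
  smallest |lag|; segments below the correlation floor stay unshifted.
- Bin-merge ties drop the boundary with the higher smoothed intensity.
- Constant columns: pareto maps them to zero; Shapiro–Wilk routes
  constant differences nonparametric with a warning; constant ROC
  scores return AUC 0.5 with a degenerate flag.
- Wilcoxon doubles mid-ranks to integers so the exact distribution is
  computed by integer convolution even under ties.
- Holm adjustment enforces the step-down running maximum and caps at 1.
- All randomness flows from `numpy.random.SeedSequence` spawns — one
  stream per pipeline stage (seed combined with the stage name), so no
  stage shares a stream and runs are byte-reproducible.

## Problem sizes used in validation

Unit and acceptance tests run at desk scale chosen to keep the suite
fast while preserving the regimes of interest: null calibration uses
200 cohorts of 10 pairs × 40 bins (8000 tests); selection recovery
uses 25 cohorts of 20 pairs with 5 planted among 200 noise variables
at moderate effect (the saturated-effect regime is exercised
separately — there a parsimonious best subset legitimately omits
redundant planted variables); the end-to-end pipeline check runs the
full spectral stage at the study's n = 10 pairs. Calibration and
recovery checks operate on generator concentration tables or the
paired-feature simulator directly where the spectral stage is not the
thing under test; the spectral stage has its own deterministic and
Monte-Carlo tests.

## Known limitations

- The RSPA and adaptive-binning parameterizations are declared
  defaults, not published values; bin counts are
  configuration-dependent.
- VIAVC here mirrors the cited method's spirit (BMR + performance
  contrast + iterative elimination), not any specific implementation's
  numeric output.
- With 10 subjects, 10-fold subject-grouped CV is leave-pair-out; Q²
  and AUC estimates at this n carry substantial variance, which the
  permutation tests quantify.
- The pathway library is a toy; impact scores depend on graph
  curation.
- No FDR control, unpaired designs, multi-class models, or score
  imputation.
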