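# urinmr

Paired urinary ¹H-NMR metabolomics analysis for longitudinal clinical
studies — built around the design of a stroke-recovery cohort in which
each subject contributes one urine sample in the acute phase (days
after the event) and one in the chronic phase (≈6 months later), plus
clinical assessments (NIHSS, FIM, CMSA hand/arm) at both ends.

The package turns exported 1D spectra into biomarker candidates and
clinical correlates:

1. **Spectral processing** — chemical-shift referencing to the TSP
   singlet (0.00 δ), recursive segment-wise peak alignment (RSPA),
   dynamic adaptive binning of the mean spectrum, water/urea region
   exclusion, trapezoidal bin integration.
2. **Preprocessing** — total-metabolome normalization (removes urine
   dilution), log transform, pareto scaling
   (x − x̄)/√s, and OLS residualization of age and sex.
3. **Univariate statistics** — per bin, a Shapiro–Wilk gate routes the
   paired differences to a paired *t*-test or an exact Wilcoxon
   signed-rank test; Bonferroni–Holm controls the family-wise error.
4. **VIAVC variable selection** — binary matrix resampling generates
   random variable subsets, each scored by subject-grouped
   cross-validated PLS-LDA AUC; contrasting subsets with vs without a
   variable classifies it (strongly/weakly informative, uninformative,
   interfering); iterating to a fixed point yields an F-ranked list and
   a best subset chosen by double (nested) cross-validation.
5. **OPLS-DA evaluation** — orthogonal projections to latent
   structures: R²Y, cross-validated Q² = 1 − PRESS/TSS, within-pair
   label-permutation p-values, and a ROC curve (concordance AUC,
   stratified-bootstrap 95% CI, accuracy) over held-out scores.
6. **Pathway analysis** — hypergeometric over-representation of the
   significant-metabolite list plus a topology impact score
   (share of relative betweenness centrality carried by the hits).
7. **Clinical correlation** — the percent-difference change statistic
   `(x₆ₘₒ − x₀)/((x₆ₘₒ + x₀)/2) × 100`, three Spearman correlation
   families (acute level vs initial score, acute level vs score change,
   metabolite change vs score change), and an α/m Bonferroni threshold.

Because cohorts like this are small and private, a first-class
**synthetic cohort generator** reproduces the study's statistical
structure — Lorentzian peaks at literature chemical shifts, ppm jitter,
baseline and noise, log-normal concentrations and dilution, planted
fold changes, age/sex confounds, and clinical scores monotonically
linked to a designated metabolite — with the full ground truth
returned for validation.

## Worked example

Cohort summary of the packaged clinical table (10 subjects):

```python
from urinmr.clinical import summarize_cohort, nihss_severity_counts
from urinmr.datasets import load_clinical_cohort

records = load_clinical_cohort()
print(summarize_cohort(records).round(2).loc[
    ["age", "nihss_initial", "acute_day", "chronic_day",
     "fim_improvement", "cmsa_hand_improvement", "cmsa_arm_improvement"]])
print(nihss_severity_counts(records))
```

```
                        n    mean     sd  median   iqr
variable
age                    10   61.50  13.24    62.0  15.0
nihss_initial           9    5.56   3.64     4.0   6.0
acute_day              10    5.50   2.51     5.0   2.0
chronic_day            10  195.40  38.79   203.0  29.5
fim_improvement         9   22.67  14.13    18.0  18.0
cmsa_hand_improvement  10    0.70   0.67     1.0   1.0
cmsa_arm_improvement   10    1.10   1.29     1.5   2.0
{'mild': 5, 'moderate': 4, 'severe': 0, 'missing': 1}
```

Mean age 61.5 ± 13.2 years; NIHSS 5.56 ± 3.64 with a 5 mild / 4
moderate split; urine collected at a median of 5 days (IQR 2) and 203
days (IQR 29.5) post-stroke; mean improvements of 22.67 FIM points and
0.70 / 1.10 CMSA hand/arm points — subjects recover, with wide
individual spread, which is exactly what the correlation stage probes.

The full pipeline runs from the shell:

```bash
urinmr run-all --seed 1 --out runs/demo
```

This simulates a default paired cohort (10 subjects, 8 planted
fold-change metabolites among 40), processes and analyzes it, and
writes every intermediate table plus `report.md` to the run directory.
On the default conditions the OPLS-DA model on the significant-bin
panel reaches Q² ≈ 0.88 and R²Y ≈ 0.92 with cross-validated ROC AUC
1.0 (values from `opls_summary.json` at seed 1): the planted
acute→chronic shift is large enough to separate phases almost
perfectly, and the permutation p (≈0.003) confirms the separation is
not a small-sample artifact.

Each stage is also a library call — see `urinmr.spectral`,
`urinmr.univariate`, `urinmr.viavc`, `urinmr.opls`,
`urinmr.pathways`, `urinmr.clinical`.

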