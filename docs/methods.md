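# Methods

## The cell-loss metric

TK1 is expressed only in proliferating cells and is released into serum when
such cells are disrupted, so the serum concentration sTK1 (ng/ml) divided by
the tumour volume V (cm³) estimates the per-volume rate of tumour cell loss:
`M = sTK1/V`, in ng·ml⁻¹·cm⁻³. Tumours are modelled as spheres, `V = πd³/6`
with d the largest diameter (cm) — the standard clinical approximation when
only one dimension is routinely recorded. Three timepoints are used:
baseline, immediately before the 2nd chemotherapy cycle, and 48 h after the
2nd cycle. The only on-treatment volume measurement is taken between the 2nd
and 3rd cycles; it serves as the denominator for both on-treatment metrics
(there is no dedicated pre-cycle-2 volume). Subtracting the baseline metric,
`ΔM = M_t − M_0`, isolates treatment-induced cell loss; ΔM is legitimately
negative when the on-treatment metric falls below baseline.

The underlying assumptions worth keeping in mind: sTK1 originates
predominantly from the tumour (a background release from normal proliferating
tissue is absorbed into the baseline), the sphere model is adequate for
relative volume comparisons, and nodal disease contributes negligibly to the
serum signal.

## Stratification and descriptive statistics

Patients are assigned to quartile groups of the baseline metric **by rank**:
sort ascending with ties broken by patient id, then cut the rank order into
four contiguous blocks whose sizes differ by at most one (larger blocks
first). For n = 104 this guarantees 26/26/26/26 regardless of ties, which a
quantile-cut-point rule cannot. Reported group boundaries are midpoints
between straddling values.

Quantiles everywhere use linear interpolation at position (n−1)·p over
0-indexed order statistics (numpy's `linear` method), centralized in
`stratify.QUANTILE_METHOD`. Other software families use different percentile
definitions; with no patient-level data to adjudicate, one common convention
is fixed and isolated so it can be switched in one place. Standard deviations
are sample (n−1) based. Categorical covariates are summarized as count
(percent) with the group's non-missing count as denominator.

## Inferential tests

All tests are two-sided; no multiple-testing correction is applied (matching
the analysis this pipeline reproduces).

* **Fisher / Freeman–Halton exact test (2×k)** — conditions on both margins
  and enumerates every 2×k table with those margins by depth-first search
  over row-1 compositions (with margin caps and a configurable table-count
  limit, default 10⁷). The two-sided p is the total multivariate-
  hypergeometric probability of tables no more likely than the observed one;
  probabilities are compared in log space with relative tolerance 1e−12.
  For k = 2 this reduces exactly to the standard two-sided Fisher test
  (verified against an independent hypergeometric enumeration and scipy for
  all small-margin tables). A zero margin returns p = 1, flagged degenerate.
* **Wilcoxon** — paired: signed-rank with zero differences dropped, exact
  2ⁿ sign enumeration on midranks for effective n ≤ 12, otherwise normal
  approximation with midrank variance and 0.5 continuity correction.
  Unpaired: rank-sum, exact null via the subset-sum counting recurrence when
  min(n, m) ≤ 10 and the pooled data are tie-free; with ties the
  tie-corrected continuity-corrected normal approximation is used at any
  size (exactness under ties would require full permutation enumeration,
  which the pipeline's sample sizes do not warrant).
* **One-way ANOVA** — F = MS_between/MS_within against F(g−1, n−g). Zero
  within-group variance is degenerate: p = 1 with equal means, p = 0
  otherwise. Covariate analyses use the pCR indicator (0/1) as the response
  and the covariate's levels as groups — a linear-probability shortcut kept
  deliberately, because it is what this analysis design prescribes, not
  because it is best practice; continuous Ki67 is binned into quartiles for
  this purpose.
* **Spearman correlation** — Pearson on midranks, p from the t
  approximation with n−2 df. Applied to (ΔM at 48 h, residual tumour volume)
  among incomplete responders; an OLS fit of log residual volume on log ΔM
  is reported alongside for transparency about the strength of the inverse
  relation.

## ROC and predictive values

Positive class = pCR; higher metric = more test-positive; a patient is
test-positive when score ≥ cut-off (inclusive, so a cut-off placed at an
observed value reproduces a step of the empirical curve). The curve sweeps
all distinct scores; AUC is the trapezoidal area, which with this convention
equals the tie-corrected rank statistic (ties count ½). The default cut-off
maximizes Youden's J = sensitivity + specificity − 1, ties broken toward
higher specificity, and is reported as the midpoint between adjacent
distinct scores; a fixed cut-off can be supplied instead. The ROC block runs
on the baseline-subtracted 48 h metric by default (raw-metric variant by
option) and is repeated on the pre-cycle-2 subset, where the cut-off is
likewise Youden-optimal — a reconstruction choice, since no published
selection rule exists for that subset.

`reconstruct_confusion` inverts rounded printed rates into the integer
confusion matrix they imply (tp = round(sens·n_pos), fp = round(fpr·n_neg),
rounding half-up at the printed precision — configurable), and
`enumerate_consistent_matrices` searches the full (n_pos+1)×(n_neg+1) grid
for every matrix whose rates round to a given set of targets. These make
published sensitivity/specificity/PPV/NPV figures auditable: e.g. margins
(24, 80) with sens 0.71 and 1−spec 0.31 force (tp, fp, fn, tn) =
(17, 25, 7, 55), hence PPV 17/42 = 40.5% and NPV 55/62 = 88.7%; margins
(15, 42) admit exactly one matrix printing PPV 77.8% and NPV 83.3%.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes, with four
latent quartile groups of equal size (round-robin assignment):

1. Baseline metric and baseline volume are drawn independently from
   per-quartile lognormals; baseline sTK1 is their product (optionally
   floored at `baseline_stk1_floor`, default 0 — a positive floor would
   distort the metric calibration of the lowest quartile, where the
   metric×volume product has wide spread).
2. The inter-cycle volume multiplies the baseline volume by a lognormal
   shrink factor with median 0.42 (a 58% decrease) and log-sd 0.30.
3. The baseline-subtracted 48 h metric ΔM is a *shifted* lognormal: sample
   L − s with L fitted to the shifted triple (median+s, q1+s, q3+s). The
   shift s = 0.02 for quartiles 1–2 (whose observed minima are negative)
   and 0 for quartiles 3–4 — the smallest mechanism producing the printed
   ranges. The 48 h sTK1 is (M₀+ΔM)×V₁, floored at 0 with ΔM recomputed.
4. The pre-cycle-2 sTK1, present with probability 1 − 47/104, is 2/3 of the
   48 h value times lognormal noise (log-sd 0.20), so the 48 h level is
   ~50% greater in the median.
5. The outcome is Bernoulli in the quartile's pCR probability (3/26, 3/26,
   6/26, 12/26; expected 24/104 = 23.1% overall). Incomplete responders get
   a residual volume `exp(−0.5 − 0.5·ln max(ΔM, 10⁻⁴) + ε)`, ε ~ N(0, 0.8²),
   giving a median residual of ~5 cm³ and a strong inverse rank relation
   with ΔM; residuals are classed pT1/pT2/pT3 by sphere-equivalent diameter
   at 2 cm and 5 cm. pCR implies residual volume 0.
6. Covariates are drawn from the published marginal frequencies (age
   N(50, 9.8²) clipped; menopause from age ≥ 51; stage from baseline
   diameter at 2/5 cm; histology, subtype, ER, PR, nodal status as
   categorical marginals; Ki67 lognormal around 30% with ~9% missing) and
   are independent of outcome by design — the reference analysis found no
   covariate association, and the generator does not model one.

The intercept/slope/noise of the residual-volume relation and the shrink and
pre-cycle-2 noise scales are the generator's only free constants; they were
chosen once for clinical plausibility (residual sizes spanning pT1–pT3, a
clearly negative metric–size correlation) and are exposed in
`GeneratorConfig`.

### Lognormal calibration and a known limitation

`lognormal_from_median_iqr(median, q1, q3)` uses the closed form
μ = ln(median), σ = ln(q3/q1)/(2·z₀.₇₅). This anchors the sampled **median**
exactly and the quartile **ratio** exactly, but the sampled quartiles are
median·(q1/q3)^½ and median·(q3/q1)^½, so the sampled IQR converges to the
configured q3 − q1 only when the triple is geometrically symmetric
(median = √(q1·q3)); the limiting ratio of sampled to configured IQR is
exactly median/√(q1·q3). For the most skewed configured triples this sits
9–15% high (e.g. the top-quartile on-treatment metric: 0.203/√(0.072·0.432)
= 1.15). The median anchor was kept because the pipeline's checks are
median-based; the alternative fit matching both printed quartiles
(μ = (ln q1 + ln q3)/2) would displace the median by the same factor. One
calibration test in the suite documents this by asserting the configured
IQRs and failing where the fit cannot reach them.

Because baseline metric profiles of adjacent latent quartiles overlap
heavily (log-sd ≈ 1 with medians ~2× apart), re-deriving quartiles from the
sampled baseline metric agrees with the latent labels only ~53% of the time
under the default profiles; with disjoint-support profiles recovery is 100%.
This is a property of the printed distributions, not of the assignment
algorithm, and it means the generator's "quartile 1" is a distributional
archetype rather than a strict order statistic of the simulated cohort.

What passing tests on synthetic cohorts do **not** show: the generator draws
the baseline metric and volume independently within quartile (their joint
dependence is unknown), has no within-cycle TK1 kinetics, no informative
missingness mechanism for the pre-cycle-2 sample, and no covariate–outcome
dependence. Results on real cohorts can differ wherever those features
matter.

## Problem sizes and determinism

The test suite and the acceptance script use: 500 synthetic cohorts of
n = 104 for the mean-AUC summary (Monte-Carlo SE ≈ 0.003), 10,000 draws for
the top-quartile median check, a 400,000-patient cohort (100,000 per
quartile) for calibration recovery, 1,000 seeded cohorts for the type-I-error
check of the quartile Fisher test (observed rate 0.048 at α = 0.05), and 200
seeds for the label-agreement estimate. All randomness flows through
numpy `default_rng` seeds; `run_analysis` itself is deterministic given the
cohort. Report rounding: percentages to 1 decimal, metrics to 4 decimals,
p-values printed at 2 decimals when ≥ 0.01 and 3 below; full-precision
values are always serialized alongside.
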