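# Methods

## Data model and conventions

A raw dataset is a probes × samples matrix of Ct cycles in [0, 40]. Ct = 40
is the OpenArray instrument ceiling and means "not detected"; undetected
wells are stored as the numeric ceiling, not as missing values, because
every filtering rule downstream is phrased on "Ct value of 40" and the most
literal qPCR workflow carries the censored 40s into normalization and
testing unchanged. `fit_group_model` tolerates NaN input for users who
prefer to mask censored wells (probes left with fewer than two finite
values per group are flagged and excluded from prior estimation), but the
default pipeline never masks.

Relative expression is defined as −ΔCt. On the Ct scale one PCR cycle is one
doubling, so −ΔCt is a log2 abundance and logFC is a plain difference of
group means; with this sign a probe less abundant in cases (higher Ct)
carries a negative logFC, the convention under which the dominant direction
in EV panels of this kind ("downregulated in cases") reads naturally. No
amplification-efficiency correction is applied.

"Greater than 40" conditions are implemented as ≥ ceiling: nothing exceeds
the ceiling, and treating exact 40s as detected would make the probe filter
vacuous.

## Filtering and reference selection

Filter order is probe → sample → probe: probes all-undetected on the full
cohort are dropped, then samples with strictly more than 80% undetected
probes, then probes that became all-undetected once those samples left. The
composite is idempotent (tested). The sample rule uses a strict inequality,
so a sample at exactly the threshold is retained.

References are the k = 4 probes with the lowest interquartile range of Ct
across all retained samples among probes undetected in at most 3 samples —
undetected counts are taken after sample filtering, since stability should
be judged on the samples actually analysed. IQR is Q3 − Q1 with
linear-interpolation quantiles and ties break lexicographically by probe id,
so the selection is deterministic across platforms. Note that a rule of this
shape can select probes that later test significant — low variance across
the pooled cohort does not imply equality of group means; the
reference-set report (undetected counts and IQRs) is emitted so users can
audit the choice.

ΔCt subtracts each sample's reference-mean Ct, which cancels any per-sample
additive offset exactly; the generator injects such offsets precisely so
tests can verify they vanish to machine precision.

## Empirical-Bayes moderated test

Per-probe pooled variances s²_g on d_g degrees of freedom are modelled as
draws from a scaled inverse-χ² prior s₀²·d₀/χ²_{d₀}. On z_g = log s²_g the
prior manifests as additive digamma/trigamma moments, so the prior is fitted
by method of moments: with e_g = z_g − ψ(d_g/2) + log(d_g/2),

    ψ′(d₀/2) = mean_g[ (e_g − ē)²·G/(G−1) − ψ′(d_g/2) ],
    s₀² = exp( ē + ψ(d₀/2) − log(d₀/2) ),

where ψ′ is inverted by Newton iteration on 1/ψ′ (nearly linear; start
0.5 + 1/y, asymptotic branches for extreme arguments). When the moment
expression is non-positive the observed spread of z is no larger than its
sampling noise: d₀ = ∞ and every probe shares s₀² = exp(ē) (the bias term
vanishes in the limit). The moderated statistic uses the shrunken variance
s̃² = (d₀s₀² + d_gs²_g)/(d₀ + d_g) on d₀ + d_g df; d₀ → 0 recovers the
ordinary pooled t exactly. The implementation is validated to machine
precision (logFC, t, p, d₀, s₀²) against the reference R implementation of
this moderation (limma) on simulated data, and the prior fit recovers known
(d₀, s₀²) from simulation within 25%/10%.

BH adjustment is delegated to statsmodels (`fdr_bh`), cross-checked in tests
against an independent step-up implementation. The significance rule is
strict on adjusted p (< 0.05) and inclusive on effect size (|logFC| ≥ 1),
matching the boundary semantics of the published rule.

## Repeated-holdout evaluation

Splits are stratified: per group, floor(0.6·n) samples train, the rest
validate (22 + 22 → 13 + 13 train, 9 + 9 validation). Stratification is a
deliberate choice where plain "random 3:2" is underspecified: unstratified
draws of small cohorts can produce single-class validation sets on which
per-repetition sensitivity and specificity are undefined. Repetition r of
probe p draws from a random stream seeded by (master seed, crc32(p), r), so
results are reproducible and independent of evaluation order; an
unstratified mode exists and redraws (bounded) until both sets contain both
classes.

The univariate logistic fit is a two-parameter Newton/IRLS (max 100
iterations, log-likelihood tolerance 1e-8). A constant feature short-circuits
to slope 0 with the training prevalence as fitted probability. Under
complete separation the slope diverges; it is capped at 500 per feature
standard deviation — beyond that the fitted probabilities are saturated and
every downstream metric is unchanged, the rank-based AUC exactly so. The
fit agrees with statsmodels GLM to 1e-6 on non-separated data (tested);
it is hand-written because the evaluator performs on the order of 10⁴–10⁵
fits per panel and a 2 × 2 Newton solve is orders of magnitude cheaper than
a general GLM object.

AUC is the Mann–Whitney statistic via mid-ranks (ties count ½), verified in
tests against exhaustive pair counting and sklearn. Classification metrics
threshold the fitted probability at 0.5, predicting "case" on ties, with
sensitivity the recall on cases. The 95% CI on AUC is the 2.5th/97.5th
percentile of the repetition AUCs — a percentile interval over split
resamplings, chosen over normal-approximation or DeLong intervals for
simplicity and because it makes no distributional assumption; with 500
repetitions the mean AUC of a moderate-effect probe is stable to < 0.02
across master seeds (tested).

## Synthetic data generator

A well is baseline_p + offset_s + δ_p·[s is case] + noise, clipped to
[0, 40] and censored to 40 above the dropout threshold; a configured
fraction of probes is never detected anywhere and a handful of
reference-like probes get near-zero well noise. The generator emulates the
features the analysis relies on — censoring at the ceiling, ~50% never
detected on a 754-probe panel with 25 + 25 samples, sample-level offsets for
normalization to remove, additive cycle-scale effects, stable reference
candidates — and deliberately not PCR efficiency curves, preamplification
bias, probe-specific dropout curves, or EV-isolation variability. Passing
tests therefore demonstrate the statistical machinery is correct under the
assumed model, not that real EV panels satisfy that model.

Defaults: baseline Ct ~ N(27, 2²) (mid-range for preamplified EV miRNA
panels), sample offset sd 1 cycle, well noise sd 0.8 cycles, dropout
threshold 35 cycles (late amplification treated as non-detection), ceiling
40. No public dispersion estimates exist for this assay class, so these are
one-time realistic choices, not fitted values. Effects are additive on the
Ct scale so that one cycle of shift is one log2 unit of logFC; censoring is
applied after effects, so strong downregulation can push a probe into
non-detection — the mechanism that produces extreme logFC values near the
detection limit. The spiked scenario places 20 effects of |δ| ∈ [2, 4]
cycles on detected, non-reference probes, 75% of them downregulated in
cases.

## Problem sizes and numerical choices

The test suite and acceptance script use study-sized panels (754 × 50) for
end-to-end checks, 500-probe 22 + 22 panels for the 20-replicate global-null
study, 500 repetitions wherever repeated-holdout statistics are asserted,
2000 simulated variances for prior recovery, and 200–500 random instances
for the brute-force comparisons of filters, BH and AUC; these sizes give
stable Monte-Carlo behaviour while keeping a full run under a minute.
Quantiles are linear-interpolation throughout; all randomness flows from
explicit `numpy` generators seeded per task (no global state); split streams
are derived per (seed, probe, repetition) as above.

## Known limitations

- Censored 40s entering the test as numeric values understate within-group
  variance for probes near the detection limit and can inflate |logFC|; this
  mirrors the literal workflow rather than a censored-likelihood model.
- The reference-selection rule can admit differentially expressed probes
  (see above); no special-casing is applied.
- No covariate adjustment (e.g. gender), no paired or multi-group designs,
  no multivariable marker combinations, delta-Ct only (no global-mean or
  rank-invariant normalization).
- The target-consensus module filters externally supplied prediction
  records; it does not query prediction databases, whose contents are not
  versioned/reproducible, so absolute target counts depend entirely on the
  supplied export.
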