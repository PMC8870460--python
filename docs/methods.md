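# Methods notes

## Scales and preprocessing

All differential-methylation thresholds in this package are defined on
the M scale, M = log2(β/(1−β)): lfc values are differences of group
mean M-values. β is clipped into [ε, 1−ε] with ε = 1e−6 before the
logit so boundary values stay finite without materially moving interior
values; the transform is then invertible to 1e−12 away from the clip
bounds.

Probes with any missing entry are discarded outright (complete-case
rows) rather than imputed. Note the consequence: with an entrywise
missing rate r and n samples, a fraction (1−r)ⁿ of probes survives, so
even r = 0.01 at n = 200 removes ~87% of probes. The σ < 1 variability
filter (sample standard deviation, n−1 denominator, strict inequality
so σ = 1 survives) is applied to the probe-level M matrix and re-applied
independently to the gene-level (avereps) matrix; it uses all retained
samples including controls.

AJCC substage labels aggregate onto parent stages (IIa, IIb → II; IIIa,
IIIb, IIIc → III; IVa → IV); samples with unknown stage are dropped.
Promoter classes from distance to the transcription start site default
to Core ≤ 100 bp and Proximal ≤ 1000 bp, which reproduces the standard
core/proximal labelling of array probe annotations; both bounds are
arguments.

Batch effects are *assessed*, not corrected: the dispersion separability
criterion (DSC) is the size-weighted mean distance of batch centroids
from the grand centroid divided by the mean within-batch
sample-to-centroid distance, with < 0.3 read as negligible batch
structure. This is the centroid-dispersion reading of the criterion;
more elaborate definitions exist but add nothing at this scale.

## The linear engine

One ordinary-least-squares fit per feature against the indicator design
[intercept | stage I..IV], so the intercept is the control mean and each
stage coefficient is exactly that stage's mean difference from control.
Variance moderation follows the standard empirical-Bayes construction:
the log sample variances are moment-matched to their theoretical
location/scale (digamma/trigamma of d_g/2), the trigamma equation is
inverted by Newton iteration to give the prior df d₀, and posterior
variances are the precision-weighted blend (d₀s₀² + d_g s²_g)/(d₀+d_g).
If the trigamma moment estimate is non-positive — the observed spread of
log-variances is no larger than sampling noise alone — the variances are
consistent with one common value and the engine falls back to d₀ = ∞
(full pooling); d₀ = 0 recovers ordinary t exactly. Zero residual
variances are floored at 1e−12 before taking logs. Tests are two-sided
throughout, and BH adjustment is applied within each contrast, not
pooled across contrasts.

The same engine runs in three modes that differ only in input matrix:
probe-level M, gene-level (avereps) M, and probe-level β ("DMP mode").
The M-scale Tier-I gate |lfc| > 2 cannot transfer to the β scale (β
differences live in (−1, 1)) or to the arbitrary scale of estimated
expression, so those two engines screen on adjusted p alone; every
M-scale gate is still enforced at consensus time through the gene-level
linear engine.

## ANOVA association engine

A fixed-effects one-way ANOVA of methylation against the five-level
phenotype (control, stages I–IV), computed on β values per the
association-tool convention, on the gene-level mean-β matrix so the
feature universe matches the M-scale fold-changes used for the stage
gate (adjusted ANOVA p < 0.001 and |stage lfc| > 2, ranked by ANOVA p).
BH is the default correction; Holm is available.

## Methylation–expression integration

Genes pass a Pearson correlation filter between per-sample mean β and
expression at |r| ≥ 0.3 — the sign is deliberately not constrained,
although repressive promoter methylation makes r < 0 the expected
pattern. Methylation states of the stage samples are modelled as a
univariate Gaussian mixture on M-values fitted by EM (K = 1..3, chosen
by BIC = −2logL + (3K−1)log n, several seeded restarts, variance floor
1e−6). A Gaussian mixture on M replaces a beta mixture on β: the EM
updates are closed-form, the monotone log-likelihood property is exact,
and the M scale is where the rest of the analysis lives; component
means are back-transformed to β for reporting. Differential methylation
(DM) per state is component mean β minus control mean β, positive =
hypermethylated. Each state is compared with controls by the
two-sided Wilcoxon rank-sum test — exact by enumeration when both
groups have ≤ 8 observations and no ties, otherwise the tie- and
continuity-corrected normal approximation — with BH across all
(gene, state) tests of a stage contrast; a correlated gene with any
state at adjusted p < 0.05 is a stage driver.

Expression-from-methylation uses per-gene univariate linear maps
trained on paired samples (genes without training methylation variance
are skipped); predictions feed the linear engine like any other matrix.

## Consensus stage-salience

Engines contribute membership votes via their per-stage top-k lists
(k = 100; rank by adjusted p, ties by |lfc| then gene id; probe-level
lists are collapsed to genes keeping each gene's best probe first). A
consensus call needs: ≥ 3 engines listing the gene for the same stage;
|lfc| > 2 vs control in the salient stage; Tier-II inter-stage p < 0.05
(strict, unadjusted — the first tier's explicit *adjusted* threshold is
not repeated here) in all three contrasts involving the stage; and a
salience margin |lfc_stage − lfc_other| > 0.4 against every other
stage. Mixture-model and ANOVA engines cannot form inter-stage
contrasts, so Tier-II gating and margins are evaluated on the
gene-level linear engine for all candidates; this also makes the call
set invariant to engine ordering. A gene qualifying for two stages
simultaneously is logged and rejected as conflicted. All thresholds
live in `TierCriteria` and tightening any of them can only shrink the
call set.

## Survival

Kaplan–Meier, log-rank and Cox fitting are delegated to lifelines; ties
are handled by Efron's method (the survival ecosystem's default).
Median survival is the first time S(t) ≤ 0.5. The risk score is the
uncentered linear predictor Σ β̂ⱼxⱼ. Maxstat evaluates the standardized
two-group log-rank statistic at every distinct score threshold keeping
both groups above the minprop = 0.1 fraction, reports the midpoint
between the winning threshold and the next distinct score, and computes
significance by permuting scores (B = 1000 by default, seeded) —
exact-by-simulation rather than an asymptotic approximation. High risk
means score > cut. Panels ("signatures") are evaluated as multivariate
Cox → weights → risk score → maxstat split → log-rank prognosis p, with
the likelihood-ratio p of the Cox fit reported as the model p. One
caution from our simulations: with moderate effect sizes the maximizing
partition sits within a few order statistics of the true changepoint,
so the cut *value* may fall just inside a risk group's score range
rather than in the gap between groups.

## Synthetic cohorts

The generator emulates what the analysis assumes about 27k-style data,
not array chemistry. Defaults: 40 controls + 40 samples per stage I–IV;
2000 genes with 1–4 probes each (~5000 probes); per-probe baseline β
drawn from Beta distributions whose means come from a hypomethylated
pool (mean U(0.08, 0.35)) and a hypermethylated pool (mean
U(0.65, 0.92), 40% of probes) with concentration U(4, 10) — a bimodal
marginal with probe-level M-standard-deviations near 1, so the σ filter
bites realistically. Planted effects are additive *in M space* (all
analysis thresholds are M-scale): every probe of a stage-salient gene
is shifted by ΔM in the target stage, stage-agnostic genes in all four
stages; shifts beyond |ΔM| = 12 are rejected as they would push β into
the clipping region. Expression is intercept + slope·(mean β) + N(0,
σ²) with slope −10 for planted genes (repression) and independent noise
otherwise; missing entries are injected uniformly at random; substage
labels are drawn with a realistic lettered-substage composition; event
times are exponential with hazard h₀·exp(Σ coef·M) over the planted
prognostic genes (h₀ = 1/1000 per day) and censoring is an independent
exponential whose rate is solved by root-finding so the expected
censored fraction hits the target (default 0.2).

What the generator does *not* model — probe cross-reactivity, SNP
artefacts, real batch effects, non-exponential hazards, spatially
correlated probes — bounds what a passing test shows: the pipeline
recovers the signal structure it assumes, at the planted effect sizes,
under clean noise. It says nothing about robustness to array artefacts.

## Problem sizes and numerical choices

Simulation-based tests use the sizes at which their statistical claims
are sharp: planted-recovery runs use the default cohort (40/group,
2000 genes, ΔM = 3, inter-stage margins ≥ 0.8 by construction);
null-specificity uses 100 smaller cohorts (20/group, 400 genes);
calibration checks use 10000-feature null matrices; maxstat calibration
uses B = 199 permutations at n = 40 over several hundred replicates.
EM convergence is |Δ logL| < 1e−8 with ≤ 300 iterations; Cox Newton
iterations and tolerances are lifelines defaults; matrix OLS uses the
explicit normal equations (the design is a full-rank 5-column
indicator, conditioning is not an issue). Identifiers are
case-sensitive; duplicate probe or sample ids are rejected at read
time.

## Known limitations

* No DMR (region-level) calling and no external annotation/gene-set
  retrieval; enrichment takes user-supplied gene sets.
* No batch correction; the DSC/PCA diagnostics only flag problems.
* The mixture engine assumes expression is available for the same
  samples; without it, the pipeline runs with the four
  methylation-only engines.
* Stage groups must all be non-empty for the design to be full rank;
  cohorts missing a stage are rejected rather than refitted with a
  reduced design.
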