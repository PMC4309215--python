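# Methods

This note documents the statistical model behind `refstab`, the conventions
the implementation fixes where the underlying procedure is usually left
unstated, and what the synthetic-data generator does and does not emulate.

## Data model and scales

The unit of input is a probes × arrays matrix of microarray fluorescence
intensities (FI) with an explicit scale flag. All downstream statistics are
defined on **linear** FI (log2 input is back-calculated as v → 2^v before
aggregation); the candidate matrices of the ranking algorithms are on the
**log2** scale, where multiplicative expression changes become additive.
Missing values are rejected rather than imputed, and a matrix that is
already linear cannot be "linearized" again — scale bugs surface as errors,
not as silently squared data.

Quantile normalization replaces each array's sorted value vector with the
across-array mean of sorted vectors, preserving within-array ranks. Tied
values within an array receive the mean of the reference values at the
ranks they occupy (the same convention as limma's `normalizeQuantiles`,
against which the implementation is cross-checked in the test suite). The
transform is idempotent and is exposed separately because upstream
summarization (RMA background correction and outlier-probe down-weighting)
is vendor-side and assumed already done; only the quantile step is part of
this pipeline.

Per-array QC uses a five-number summary at the 9th/25th/50th/75th/91st
percentiles with linear interpolation between closest ranks.

## Probe-to-gene aggregation

The most consequential convention in the pipeline is what counts as a
replicate. Each probe's replicate arrays within one gravity condition are
first averaged; the resulting **per-probe condition means are the
replicates** that enter the gene-level mean, SD and n — so n is the probe
count, not the array count. This matches the small SDs of published
gene-level summary tables (probe-to-probe scatter, not array-to-array
scatter) and makes gene summaries comparable between conditions with
unequal array counts. For a balanced design the alternative (pooling all
probe × array values) gives the same means; it differs in SD and df.

Rules, in order:

* **Outlier trimming** (off by default): probes whose condition mean lies
  outside median ± 3·MAD of the gene's probes, per condition, unioned
  across conditions, are dropped. The default is `"none"` because the
  procedure being reproduced names no trimming rule; the MAD rule is the
  robust, parameter-light option for new data.
* **≥ 3 probes**: genes with fewer than three retained probes get status
  `too_few_probes` and no summaries — a status, not an error, because the
  partition of genes into stable/sensitive/unassignable is itself a result.
* **High-variance exclusion**: genes whose inter-probe CV (100·sd/mean)
  exceeds 100% in any condition are flagged `high_variance_excluded`.
  The threshold is deliberately permissive — it catches probes that
  plainly measure different things (cross-hybridization, mis-annotation)
  while leaving ordinary probe-affinity spread alone. An explicit
  exclusion list is also accepted, mirroring published analyses that name
  the excluded genes rather than a rule.

SDs are sample SDs (n−1) throughout.

## CV screen

Per campaign, CV% = 100 · sample SD / mean over the **per-condition gene
means** (4 values on the parabolic-flight campaign, 3 on the rocket), on
the linear scale. Thresholds follow the usual heterogeneous/homogeneous
group convention: a gene passes with CV strictly below 50% (heterogeneous,
the default — rapid gravity transitions make flight samples heterogeneous)
or 25% (homogeneous). Comparisons are strict: CV = 25.0 fails the 25%
screen. The CV is scale-invariant, so the linear/log2 choice matters only
through the nonlinearity of the mean; the computation records which values
it ran on.

## Pairwise testing and verdicts

Each campaign contributes an ordered list of condition contrasts. Per gene
and contrast an unpaired two-tailed Welch t-test runs on the summary
statistics (mean, SD, n across probes):

    t  = (x̄₁ − x̄₂) / √(s₁²/n₁ + s₂²/n₂)
    df = (s₁²/n₁ + s₂²/n₂)² / [ (s₁²/n₁)²/(n₁−1) + (s₂²/n₂)²/(n₂−1) ]

with df left unrounded. Two degenerate groups with zero SD and equal means
give p = 1 by convention. A gene is marked '−' on a contrast when
p < α = 0.05 and '+' otherwise; **g-stable** means '+' on every contrast of
every campaign, and genes failing the probe-count or variance rules are
**unassigned**. A one-way ANOVA across all conditions (on the per-probe
condition means) with Benjamini–Hochberg FDR across genes is reported as a
stricter screen but does not gate the verdict matrix, which reflects the
unadjusted pairwise tests.

Because the same probes appear in both groups of a contrast, the unpaired
test ignores the pairing and is conservative when probe affinities vary;
and the Welch–Satterthwaite approximation is additionally conservative at
n = 3 (empirical type-I ≈ 0.033 at α = 0.05 for normal data). Both biases
push toward '+' calls, i.e. toward failing to flag weak g-sensitivity —
the appropriate direction for a screen whose output is a *shortlist of
stable genes*, but worth remembering when interpreting '+' entries near
the boundary. The null-calibration check in the acceptance suite therefore
runs at 7 probes per gene (the upper end of observed probe counts, where
the approximation is accurate).

## Ranking algorithms

All four scores are computed on a genes × samples log2 candidate matrix;
lower is more stable.

* **geNorm**: M_j = mean over partners k of SD across samples of
  (log2 x_j − log2 x_k); stepwise exclusion removes the highest-M gene and
  recomputes until two remain (ties drop the lexicographically larger
  symbol); the final pair is ordered by full-set initial M. Pairwise
  variation V(n/n+1) is the SD across samples of log2(NF_n/NF_{n+1}) with
  NF_k the geometric mean of the k most stable genes.
* **Comparative ΔCt**: the same all-pairs mean-SD statistic without
  exclusion; on log2 input it coincides exactly with the initial geNorm M
  (asserted to 1e-10 in the tests — the two are implemented independently).
* **NormFinder (grouped variant)**: on the gene- and sample-centered log2
  matrix z, per gene and group the intergroup bias d (the group mean of z)
  and intragroup variance σ² are estimated, and the stability value is
  mean over groups of √(d² + σ²/n_g). This keeps the original method's
  structure — penalize systematic between-condition shifts and
  within-condition scatter together — with the exact combination fixed
  here and validated against a by-definition oracle rather than against
  any published output. Without group labels the score falls back to the
  SD of the centered residuals.
* **BestKeeper**: per-gene SD and CV of log2 values plus the Pearson
  correlation with the BestKeeper index (per-sample geometric mean over
  candidates). Originally defined on qPCR crossing points; applied here to
  log2 fluorescence as an adaptation, ranked by SD. The CV variant is the
  one scale-sensitive score in the package and is documented as such.

The composite order is the geometric mean of per-method ranks (the
RefFinder convention); all rank ties break lexicographically by gene
symbol so orderings are reproducible.

## Synthetic data

The generator emulates the structure of the two flight campaigns:

    value(probe p, gene g, array a in condition c)
        = baseline_fi(g) · 2^( probe_effect(p) + log2 fc(g,c) + ε ),
    ε ~ N(0, noise_sd_log2),  probe_effect ~ N(0, probe_affinity_sd)

with per-campaign replicate defaults (PFC: 6 H/W, 8 1g, 6 1.8g, 8 µg;
TEXUS: 6 H/W, 5 BL, 7 µg), baselines log-uniform over ~2–25,000 FI (the
observed dynamic range from ALB at ~18–40 to GAPDH at ~21,000–25,000),
2–6 probes per gene, and condition fold changes of ~20–40% for g-sensitive
genes. Default spreads (probe_affinity_sd 0.25, noise_sd_log2 0.15) put
simulated inter-probe SDs in the 1–50%-of-mean range seen in real summary
tables. All randomness flows from one `numpy.random.default_rng(seed)`
(PCG64), so studies regenerate bit-identically. Under the lognormal model
the per-condition sample mean converges to baseline·exp((sd·ln2)²/2), which
the tests verify at n = 10,000 arrays.

The `flight_study_specs` preset ships 99 genes — 20 housekeeping-like, 47
ABC-transporter-like, 32 tRNA-synthetase-like — with planted labels:
8 stable and 9 sensitive genes with well-behaved probes, and 82
unassignable (two-probe genes, plus genes given deliberately discordant
probe affinities, fixed at ±3 log2 so their exclusion is deterministic).
Probe counts and labels are exact by construction; everything else is
drawn from the preset's distributions.

What the generator does **not** emulate: scanner-level artifacts, spatial
effects, RMA summarization inputs, probe-sequence biases, correlated noise
between genes, and batch/flight-day effects. Passing tests on synthetic
data therefore demonstrate that the statistics behave as specified under
the lognormal model — not that the model captures every failure mode of
real arrays.

## Problem sizes and numerical choices

The statistical-guarantee checks use sizes chosen to make their Monte-Carlo
error small relative to the asserted margins: 1,500 null genes for type-I
calibration (99% binomial band ±1.45 pp around α), 200 replicate studies
for the planted-fold-change power check, and 100 studies × 10 genes for the
rank-separation check. Tolerances: exact structural identities at 1e-10
(geNorm ≡ ΔCt), transform inverses at 1e-12 relative, quantile-normalization
idempotence at 1e-9 relative, and p-values against the numerical
t-integration oracle at 1e-6.

Degenerate inputs are handled explicitly rather than propagated: zero-SD
Welch groups (p = 1 when means agree, p = 0 otherwise), all-identical ANOVA
groups (p = 1), zero-variance BestKeeper correlations (NaN, flagged), and
single-array quantile normalization (error).

## Known limitations

* Gene-level summaries alone cannot drive the ANOVA or the four ranking
  algorithms; those stages need probe-level (or simulated) data.
* The per-probe supplementary tables of the original study were never
  publicly archived, so the package can reproduce the published gene-level
  verdict matrix and p-value anchors exactly, but the full 100-gene
  partition can only be exercised structurally on synthetic data.
* p-values recomputed from *printed* (rounded) means and SDs can flip a
  verdict when the underlying p sits within roughly ±0.02 of α; reproduction
  checks therefore require agreement only where the printed p lies outside
  [0.03, 0.07].
* The verdict matrix uses unadjusted pairwise p-values by design; with
  seven contrasts per gene the family-wise '−' rate for a truly stable gene
  is ≈ 1 − 0.95⁷ ≈ 30% under independence, which is why the ANOVA+FDR pass
  is reported alongside for stricter use.
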