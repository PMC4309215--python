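# refstab

Reference-gene stability screening for gene-expression studies in altered
gravity.

## The problem

Differential expression measurements — qPCR or microarray — are normalized
against reference ("housekeeping") genes that are assumed constant across
experimental conditions. That assumption was established at normal gravity;
on parabolic-flight and sounding-rocket platforms, where immune cells
experience seconds to minutes of hypergravity and microgravity, classical
reference genes such as TBP or RPLP0 can themselves respond to the gravity
change and silently bias every normalized result. `refstab` implements the
screening pipeline used to identify gravity-stable reference genes from
probe-level microarray fluorescence of myelomonocytic (U937) cells flown on
two platforms:

* **PFC** (parabolic flight): conditions H/W (hardware ground control),
  1 g in-flight, 1.8 g, and µg (~20 s), contrasted as H/W–1g, 1g–1.8g,
  1.8g–µg, 1g–µg;
* **TEXUS** (sounding rocket): H/W, BL (post-launch hyper-g baseline), and
  µg (~378 s), contrasted as H/W–BL, BL–µg, H/W–µg.

## The method

Starting from a probes × arrays matrix of fluorescence intensities (FI,
log2 or linear) and an array → (campaign, condition) design:

1. **Aggregation** — log2 values are back-calculated to linear FI; each
   probe's replicate arrays are averaged per condition; genes represented by
   at least three probes get a per-condition mean, sample SD (n−1) and n
   across probes, and genes whose probes disagree wildly (inter-probe
   CV > 100% in any condition) are excluded.
2. **CV screen** — per campaign, the coefficient of variation
   CV% = 100·s/x̄ across the condition means; a gene passes if CV is
   strictly below 50% (heterogeneous groups; 25% for homogeneous ones).
3. **Pairwise testing** — an unpaired two-tailed Welch t-test per condition
   contrast, t = (x̄₁−x̄₂)/√(s₁²/n₁+s₂²/n₂) with Welch–Satterthwaite
   degrees of freedom; a one-way ANOVA with Benjamini–Hochberg FDR across
   genes is computed alongside.
4. **Verdict matrix** — '−' where p < 0.05, '+' otherwise; a gene is
   g-stable iff it is '+' on every contrast of every campaign, and
   unassigned when it fails the probe-count or variance rules.
5. **Stability ranking** — geNorm M (with stepwise exclusion and pairwise
   variation V(n/n+1)), NormFinder-style variance decomposition, BestKeeper
   SD/correlation, and the comparative ΔCt score, combined into a composite
   order by the geometric mean of ranks.

A synthetic-data module generates probe-level studies with known ground
truth (lognormal noise, per-probe affinities, planted condition fold
changes) so that every stage is testable without any external download.

## Worked example

The packaged tables carry the published per-condition summaries (mean FI,
SD across probes, probe count) of 12 candidate genes over both campaigns:

```python
import refstab as rs
from refstab.datasets import load_flight_summaries

res = rs.ReferenceGeneStudy.from_condition_summaries(load_flight_summaries()).fit()
print(res.counts)
print(sorted(res.stable_genes))
print(res.tests.query("gene_symbol=='TBP' and campaign=='TEXUS'")
      [["condition_a", "condition_b", "t", "df", "p"]].to_string(index=False))
```

prints

```
{'stable': 6, 'sensitive': 6, 'unassigned': 0}
['ABCC1', 'ALB', 'B4GALT6', 'GAPDH', 'HMBS', 'YWHAZ']
condition_a condition_b         t       df        p
        H/W          BL -4.272085 3.137526 0.021504
         BL          ug  6.241533 2.174609 0.020074
        H/W          ug  2.486262 2.549776 0.103710
```

Six of the twelve candidates (ALB, B4GALT6, GAPDH, HMBS, YWHAZ, ABCC1) are
g-stable across all seven contrasts, while TBP responds significantly to
the launch phase (H/W vs BL, p ≈ 0.0215) and to the transition into
microgravity (BL vs µg, p ≈ 0.0201) — exactly the pattern that disqualifies
it as a normalization gene on these platforms.

Probe-level data (real or simulated) unlock the remaining stages:

```python
specs = rs.flight_study_specs(seed=1)          # 99-gene synthetic panel
sim = rs.generate_study(specs, campaign="PFC", seed=1)
res = rs.ReferenceGeneStudy(sim.matrix, sim.design).fit()
print(res.counts)                             # {'stable': 10, 'sensitive': 7, 'unassigned': 82}
res.ranking["PFC"]                            # four-algorithm + composite ranking
print(rs.recovery_report(sim, res.verdicts))  # confusion vs planted truth
```

The same pipeline is scriptable from the shell:

```bash
refstab simulate --preset flight-study --seed 1 \
    --out-matrix expr.tsv --out-design design.tsv --out-truth truth.tsv
refstab aggregate --input expr.tsv --design design.tsv --output summaries.tsv
refstab screen --summaries summaries.tsv --output cv.tsv
refstab test --summaries summaries.tsv --output welch.tsv
```

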