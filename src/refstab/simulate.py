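"""Synthetic probe-level expression studies with known ground truth.

The generator emulates the structure of the two flight campaigns: a linear
fluorescence range of roughly 2 to 25,000 units, 2-6 probes per gene,
5-9 replicate arrays per gravity condition, and multiplicative condition
effects of ~20-40% for g-sensitive genes.  The noise model is lognormal
(additive in log2):

    value(probe p of gene g, array a in condition c)
        = baseline_fi(g) * 2 ** (probe_effect(p) + condition_log2fc(g, c) + eps)

with eps ~ Normal(0, noise_sd_log2) drawn independently per (probe, array)
and probe_effect(p) ~ Normal(0, probe_affinity_sd) drawn once per probe.
All randomness comes from one ``numpy.random.default_rng(seed)`` (PCG64),
so a seed reproduces a study bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, StudyDesign

__all__ = [
    "GeneSpec",
    "SimulatedStudy",
    "make_design",
    "generate_study",
    "flight_study_specs",
    "recovery_report",
]

# replicate arrays per condition in the two campaigns
DEFAULT_REPLICATES = {
    "PFC": {"H/W": 6, "1g": 8, "1.8g": 6, "ug": 8},
    "TEXUS": {"H/W": 6, "BL": 5, "ug": 7},
}


@dataclass(frozen=True)
class GeneSpec:
    """Ground-truth parameters of one simulated gene."""

    gene_symbol: str
    baseline_fi: float
    n_probes: int
    probe_affinity_sd: float = 0.25
    condition_fold_changes: Mapping[str, float] = field(default_factory=dict)
    noise_sd_log2: float = 0.15
    truth_label: str = ""  # stable | sensitive | high_variance | too_few_probes
    probe_effects: tuple[float, ...] | None = None  # fixed log2 offsets; overrides the random draw

    def __post_init__(self) -> None:
        if self.baseline_fi <= 0:
            raise ValueError("baseline_fi must be > 0")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.probe_effects is not None and len(self.probe_effects) != self.n_probes:
            raise ValueError("probe_effects must have one entry per probe")
        if self.probe_affinity_sd < 0 or self.noise_sd_log2 < 0:
            raise ValueError("spread parameters must be >= 0")
        if any(fc <= 0 for fc in self.condition_fold_changes.values()):
            raise ValueError("fold changes must be > 0")
        if not self.truth_label:
            if self.n_probes < 3:
                label = "too_few_probes"
            elif any(fc != 1.0 for fc in self.condition_fold_changes.values()):
                label = "sensitive"
            else:
                label = "stable"
            object.__setattr__(self, "truth_label", label)


@dataclass
class SimulatedStudy:
    matrix: ExpressionMatrix  # linear scale
    design: StudyDesign
    truth: pd.DataFrame  # one row per gene: baseline, n_probes, label, ...
    seed: int


def make_design(
    campaign: str = "PFC", replicates: Mapping[str, int] | None = None
) -> StudyDesign:
    """Build a campaign design with ``replicates`` arrays per condition."""
    reps = dict(replicates) if replicates is not None else DEFAULT_REPLICATES[campaign]
    if any(r < 2 for r in reps.values()):
        raise ValueError("need >= 2 replicate arrays per condition")
    safe = {c: c.replace("/", "").replace(".", "_") for c in reps}
    mapping = {
        f"{campaign}_{safe[cond]}_{i + 1}": cond
        for cond in reps
        for i in range(reps[cond])
    }
    return StudyDesign(campaign, mapping)


def generate_study(
    specs: Sequence[GeneSpec],
    design: StudyDesign | None = None,
    campaign: str = "PFC",
    replicates: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a probe-level expression matrix for one campaign."""
    if design is None:
        design = make_design(campaign, replicates)
    if not specs:
        raise ValueError("need at least one gene spec")
    arrays = design.arrays
    cond_idx = np.array([design.conditions.index(design.condition_of_array[a]) for a in arrays])
    rng = np.random.default_rng(seed)
    probe_ids, symbols, rows = [], [], []
    truth_rows = []
    for spec in specs:
        log2fc = np.array(
            [np.log2(spec.condition_fold_changes.get(c, 1.0)) for c in design.conditions]
        )
        if spec.probe_effects is not None:
            probe_effects = np.asarray(spec.probe_effects, dtype=float)
        else:
            probe_effects = rng.normal(0.0, spec.probe_affinity_sd, size=spec.n_probes)
        noise = rng.normal(0.0, spec.noise_sd_log2, size=(spec.n_probes, len(arrays)))
        exponent = probe_effects[:, None] + log2fc[cond_idx][None, :] + noise
        values = spec.baseline_fi * np.exp2(exponent)
        for p in range(spec.n_probes):
            probe_ids.append(f"{spec.gene_symbol}_p{p + 1}")
            symbols.append(spec.gene_symbol)
            rows.append(values[p])
        truth_rows.append(
            {
                "gene_symbol": spec.gene_symbol,
                "baseline_fi": spec.baseline_fi,
                "n_probes": spec.n_probes,
                "probe_affinity_sd": spec.probe_affinity_sd,
                "noise_sd_log2": spec.noise_sd_log2,
                "max_abs_log2fc": float(np.max(np.abs(log2fc))) if len(log2fc) else 0.0,
                "truth_label": spec.truth_label,
            }
        )
    values_df = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="probe_id"), columns=arrays
    )
    matrix = ExpressionMatrix(
        values_df, pd.Series(symbols, index=values_df.index, name="gene_symbol"), "linear"
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_symbol")
    return SimulatedStudy(matrix, design, truth, seed)


def flight_study_specs(seed: int = 0, campaign: str = "PFC") -> list[GeneSpec]:
    """A 99-gene preset shaped like the flight study's candidate panel.

    20 housekeeping-like genes, 47 ABC-transporter-like genes and 32
    tRNA-synthetase-like genes, with planted labels: 8 stable and 9
    g-sensitive genes carry >= 3 well-behaved probes; the remainder are
    unassignable (2 probes, or >= 3 probes with grossly discordant
    affinities).  Baselines are log-uniform over ~2..25,000 FI.
    """
    rng = np.random.default_rng(seed)
    conditions = ("1.8g", "ug") if campaign == "PFC" else ("BL", "ug")

    def baseline() -> float:
        return float(2.0 ** rng.uniform(1.0, 14.6))  # ~2 .. ~25,000

    def fold_changes() -> dict[str, float]:
        cond = conditions[rng.integers(0, len(conditions))]
        fc = float(rng.uniform(1.25, 1.4))
        if rng.random() < 0.5:
            fc = 1.0 / fc
        return {cond: fc}

    def spec(sym: str, label: str) -> GeneSpec:
        if label == "stable":
            return GeneSpec(sym, baseline(), int(rng.integers(3, 7)),
                            probe_affinity_sd=0.2, noise_sd_log2=0.12,
                            truth_label="stable")
        if label == "sensitive":
            return GeneSpec(sym, baseline(), int(rng.integers(3, 7)),
                            probe_affinity_sd=0.2,
                            condition_fold_changes=fold_changes(),
                            noise_sd_log2=0.12, truth_label="sensitive")
        if label == "high_variance":
            n = int(rng.integers(3, 5))
            # grossly discordant probe affinities: inter-probe CV far above
            # the 100% exclusion threshold in every condition
            effects = tuple(np.linspace(-3.0, 3.0, n))
            return GeneSpec(sym, baseline(), n, probe_affinity_sd=2.0,
                            probe_effects=effects, noise_sd_log2=0.2,
                            truth_label="high_variance")
        return GeneSpec(sym, baseline(), 2, probe_affinity_sd=0.25,
                        noise_sd_log2=0.15, truth_label="too_few_probes")

    # composition: (prefix, total, n_stable, n_sensitive, n_high_variance)
    plan = [("HKG", 20, 5, 2, 2), ("ABC", 47, 3, 6, 10), ("TRS", 32, 0, 1, 3)]
    specs = []
    for prefix, total, n_stab, n_sens, n_hv in plan:
        labels = (
            ["stable"] * n_stab
            + ["sensitive"] * n_sens
            + ["high_variance"] * n_hv
            + ["too_few_probes"] * (total - n_stab - n_sens - n_hv)
        )
        for i, label in enumerate(labels):
            specs.append(spec(f"{prefix}{i + 1:02d}", label))
    return specs


def recovery_report(study: SimulatedStudy, verdicts: pd.DataFrame) -> pd.DataFrame:
    """Confusion table: planted truth label x pipeline overall verdict.

    ``verdicts`` is the verdict-matrix frame (index gene_symbol, column
    ``overall``).  Genes absent from the verdict frame count as unassigned.
    """
    truth = study.truth["truth_label"]
    predicted = verdicts["overall"].reindex(truth.index).fillna("unassigned")
    table = pd.crosstab(truth, predicted)
    table.index.name = "truth_label"
    table.columns.name = "verdict"
    return table
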