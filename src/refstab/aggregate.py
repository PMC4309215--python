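"""Probe-to-gene aggregation.

A gene enters the statistics only if it is represented by at least three
probes (after optional outlier trimming).  For each retained probe, its
replicate arrays within one gravity condition are first averaged; the
per-probe condition means are then the replicates that yield the gene-level
mean FI, SD (sample SD, n-1 divisor) and n per condition.  Genes whose probes
disagree wildly (inter-probe CV above a threshold in any condition) are
flagged and excluded from downstream screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, StudyDesign

__all__ = [
    "GeneProbeSet",
    "condense_probe_values",
    "detect_probe_outliers",
    "aggregate_gene",
    "exclude_high_variance",
    "aggregate_study",
]

SUMMARY_COLUMNS = ["gene_symbol", "campaign", "condition", "mean_fi", "sd", "n"]


@dataclass
class GeneProbeSet:
    """Bookkeeping for one gene's probes through the aggregation rules."""

    gene_symbol: str
    probe_ids: list[str]
    status: str = "eligible"  # eligible | too_few_probes | high_variance_excluded | outlier_trimmed
    removed_probes: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.probe_ids)


def condense_probe_values(
    matrix: ExpressionMatrix, design: StudyDesign, gene: str
) -> pd.DataFrame:
    """Per-probe, per-condition means for one gene.

    Returns a probes x conditions DataFrame: the mean of each probe's values
    over the arrays assigned to each condition.
    """
    if matrix.scale != "linear":
        raise ValueError("condense_probe_values expects a linear-scale matrix")
    probes = matrix.probes_of_gene(gene)
    if not probes:
        raise ValueError(f"gene {gene!r} has no probes in the matrix")
    cols = {}
    for cond in design.conditions:
        arrays = design.arrays_for(cond)
        if not arrays:
            raise ValueError(f"condition {cond!r} has no arrays in the design")
        cols[cond] = matrix.values.loc[probes, arrays].mean(axis=1)
    return pd.DataFrame(cols)


def detect_probe_outliers(
    probe_condition_means: pd.DataFrame, rule: str = "mad", nmad: float = 3.0
) -> tuple[list[str], list[str]]:
    """Flag probes whose condition means are outliers among the gene's probes.

    ``rule="mad"`` removes probes lying outside median +/- ``nmad`` * MAD of
    the gene's probes in any condition (union over conditions).
    ``rule="none"`` retains everything.

    Returns ``(retained_probe_ids, removed_probe_ids)``.
    """
    probes = list(probe_condition_means.index)
    if rule == "none":
        return probes, []
    if rule != "mad":
        raise ValueError(f"unknown outlier rule {rule!r}")
    if len(probes) < 3:
        return probes, []
    removed: set[str] = set()
    for cond in probe_condition_means.columns:
        vals = probe_condition_means[cond]
        med = vals.median()
        mad = (vals - med).abs().median()
        if mad == 0:
            continue
        off = vals.index[(vals - med).abs() > nmad * mad]
        removed.update(off)
    retained = [p for p in probes if p not in removed]
    return retained, [p for p in probes if p in removed]


def aggregate_gene(
    probe_condition_means: pd.DataFrame,
    gene: str,
    campaign: str = "",
    min_probes: int = 3,
) -> tuple[pd.DataFrame, GeneProbeSet]:
    """Gene-level mean/SD/n per condition from per-probe condition means.

    Genes with fewer than ``min_probes`` retained probes get status
    ``too_few_probes`` and an empty summary frame (ineligibility is a status,
    not an error).  SD is the sample SD across probes (n-1 divisor).
    """
    probes = list(probe_condition_means.index)
    probe_set = GeneProbeSet(gene, probes)
    if len(probes) < min_probes:
        probe_set.status = "too_few_probes"
        return pd.DataFrame(columns=SUMMARY_COLUMNS), probe_set
    rows = []
    for cond in probe_condition_means.columns:
        vals = probe_condition_means[cond].to_numpy(dtype=float)
        rows.append(
            {
                "gene_symbol": gene,
                "campaign": campaign,
                "condition": cond,
                "mean_fi": float(vals.mean()),
                "sd": float(vals.std(ddof=1)),
                "n": len(vals),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS), probe_set


def exclude_high_variance(
    summaries: pd.DataFrame,
    threshold: float = 100.0,
    exclude_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Drop genes whose probes disagree too strongly.

    A gene is flagged ``high_variance_excluded`` when its inter-probe CV
    (100 * sd / mean_fi) exceeds ``threshold`` percent in any condition, or
    when it is named in ``exclude_genes`` (explicit list mirroring a published
    exclusion).  Returns the passing summary rows and a {gene: status} map of
    the flagged genes.
    """
    if threshold <= 0:
        raise ValueError("variance threshold must be > 0")
    exclude = set(exclude_genes)
    flagged: dict[str, str] = {}
    for gene, sub in summaries.groupby("gene_symbol", sort=False):
        cv = 100.0 * sub["sd"] / sub["mean_fi"]
        if gene in exclude or (cv > threshold).any():
            flagged[gene] = "high_variance_excluded"
    passing = summaries[~summaries["gene_symbol"].isin(flagged)].reset_index(drop=True)
    return passing, flagged


def aggregate_study(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    genes: Sequence[str] | None = None,
    min_probes: int = 3,
    outlier_rule: str = "none",
    variance_threshold: float = 100.0,
    exclude_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, GeneProbeSet], dict[str, pd.DataFrame]]:
    """Run the full aggregation path for every gene of one campaign.

    Returns ``(summaries, probe_sets, probe_level)`` where ``summaries`` has
    columns gene_symbol/campaign/condition/mean_fi/sd/n for eligible genes,
    ``probe_sets`` records per-gene statuses, and ``probe_level`` holds the
    retained per-probe condition means per eligible gene (the replicate sets
    the Welch tests run on).
    """
    gene_list = list(genes) if genes is not None else matrix.genes
    frames: list[pd.DataFrame] = []
    probe_sets: dict[str, GeneProbeSet] = {}
    probe_level: dict[str, pd.DataFrame] = {}
    for gene in gene_list:
        condensed = condense_probe_values(matrix, design, gene)
        retained, removed = detect_probe_outliers(condensed, rule=outlier_rule)
        condensed = condensed.loc[retained]
        summary, probe_set = aggregate_gene(
            condensed, gene, campaign=design.campaign, min_probes=min_probes
        )
        if removed and probe_set.status == "eligible":
            probe_set.status = "outlier_trimmed"
        probe_set.removed_probes = removed
        probe_sets[gene] = probe_set
        if not summary.empty:
            frames.append(summary)
            probe_level[gene] = condensed
    summaries = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SUMMARY_COLUMNS)
    )
    summaries, flagged = exclude_high_variance(
        summaries, threshold=variance_threshold, exclude_genes=exclude_genes
    )
    for gene, status in flagged.items():
        probe_sets[gene].status = status
        probe_level.pop(gene, None)
    return summaries, probe_sets, probe_level
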