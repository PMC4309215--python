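"""Pairwise Welch tests, one-way ANOVA with FDR, and the g-stable /
g-sensitive verdict matrix.

For every condition contrast of a campaign, the gene-level summaries
(mean FI, SD, n across probes) feed an unpaired two-tailed t-test with the
Welch correction for unequal variances.  A gene is marked '-' (g-sensitive)
on a contrast when p < alpha and '+' otherwise; a gene is overall g-stable
iff every contrast of every campaign is '+'.  A one-way ANOVA across all
conditions with Benjamini-Hochberg FDR control is computed alongside as a
stricter screen, but does not gate the verdict matrix, which mirrors the
unadjusted pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlphaConfig",
    "TestResult",
    "VerdictRow",
    "welch_t_test",
    "welch_table",
    "anova_fdr",
    "classify_gene",
    "verdict_matrix",
]

TEST_COLUMNS = [
    "gene_symbol",
    "campaign",
    "condition_a",
    "condition_b",
    "t",
    "df",
    "p",
    "significant",
]


@dataclass(frozen=True)
class AlphaConfig:
    alpha: float = 0.05
    anova_fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    gene_symbol: str
    contrast: tuple[str, str]
    t: float
    df: float
    p: float
    significant: bool


@dataclass(frozen=True)
class VerdictRow:
    gene_symbol: str
    symbols: tuple[str, ...]  # '+'/'-' per contrast, campaign order preserved
    overall: str  # "stable" | "sensitive" | "unassigned"


def welch_t_test(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.05,
    gene_symbol: str = "",
    contrast: tuple[str, str] = ("a", "b"),
) -> TestResult:
    """Unpaired two-tailed t-test with Welch correction, from summary stats.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); df by Welch-Satterthwaite,
    left unrounded.  Two groups with zero SD and equal means give t = 0,
    p = 1 by convention.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("Welch test needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if v1 + v2 == 0:
        if mean1 == mean2:
            return TestResult(gene_symbol, contrast, 0.0, float(n1 + n2 - 2), 1.0, False)
        return TestResult(gene_symbol, contrast, np.inf if mean1 > mean2 else -np.inf,
                          float(n1 + n2 - 2), 0.0, True)
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult(gene_symbol, contrast, float(t), float(df), p, p < alpha)


def welch_table(
    summaries: pd.DataFrame,
    contrasts_by_campaign: Mapping[str, Sequence[tuple[str, str]]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch tests for every gene over its campaign's contrasts.

    ``summaries``: gene-condition summary frame (gene_symbol, campaign,
    condition, mean_fi, sd, n).  Missing conditions raise.
    """
    rows = []
    for (gene, campaign), sub in summaries.groupby(
        ["gene_symbol", "campaign"], sort=False
    ):
        by_cond = sub.set_index("condition")
        for a, b in contrasts_by_campaign[campaign]:
            for cond in (a, b):
                if cond not in by_cond.index:
                    raise ValueError(
                        f"gene {gene!r} lacks condition {cond!r} in campaign {campaign!r}"
                    )
            ra, rb = by_cond.loc[a], by_cond.loc[b]
            res = welch_t_test(
                ra["mean_fi"], ra["sd"], int(ra["n"]),
                rb["mean_fi"], rb["sd"], int(rb["n"]),
                alpha=alpha, gene_symbol=gene, contrast=(a, b),
            )
            rows.append(
                {
                    "gene_symbol": gene,
                    "campaign": campaign,
                    "condition_a": a,
                    "condition_b": b,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "significant": res.significant,
                }
            )
    return pd.DataFrame(rows, columns=TEST_COLUMNS)


def anova_fdr(
    groups_by_gene: Mapping[str, Sequence[Sequence[float]]],
    config: AlphaConfig | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per gene across condition groups, BH-adjusted q-values.

    ``groups_by_gene`` maps each gene to its per-condition replicate vectors.
    Degenerate groups (fewer than 2 replicates) raise, naming the gene.
    All-identical groups get p = 1 (zero between- and within-group variance).
    """
    config = config or AlphaConfig()
    genes, pvals, fvals = [], [], []
    for gene, groups in groups_by_gene.items():
        if len(groups) < 2:
            raise ValueError(f"gene {gene!r}: ANOVA needs >= 2 groups")
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"gene {gene!r}: every group needs >= 2 replicates")
        flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
        if np.ptp(flat) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
        genes.append(gene)
        fvals.append(float(f))
        pvals.append(float(p))
    if genes:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    return pd.DataFrame(
        {
            "gene_symbol": genes,
            "F": fvals,
            "p": pvals,
            "q": qvals,
            "significant_fdr": [q < config.anova_fdr_q for q in qvals],
        }
    )


def classify_gene(
    pvalues: Sequence[float], gene_symbol: str, alpha: float = 0.05, eligible: bool = True
) -> VerdictRow:
    """'-' where p < alpha, '+' otherwise; stable iff no '-' anywhere."""
    if not eligible:
        return VerdictRow(gene_symbol, (), "unassigned")
    if len(pvalues) == 0:
        raise ValueError(f"gene {gene_symbol!r}: no contrast results to classify")
    symbols = tuple("-" if p < alpha else "+" for p in pvalues)
    overall = "stable" if all(s == "+" for s in symbols) else "sensitive"
    return VerdictRow(gene_symbol, symbols, overall)


def verdict_matrix(
    tests: pd.DataFrame,
    alpha: float = 0.05,
    unassigned_genes: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """g-stable/g-sensitive matrix over all campaigns plus verdict counts.

    Returns a genes x contrasts frame of '+'/'-' symbols (columns labelled
    ``campaign: a vs b``, campaign order as encountered) with an ``overall``
    column, and the counts of stable / sensitive / unassigned genes.
    """
    columns: list[str] = []
    per_gene: dict[str, dict[str, str]] = {}
    pvecs: dict[str, list[float]] = {}
    for _, row in tests.iterrows():
        label = f"{row['campaign']}: {row['condition_a']} vs {row['condition_b']}"
        if label not in columns:
            columns.append(label)
        g = row["gene_symbol"]
        per_gene.setdefault(g, {})[label] = "-" if row["p"] < alpha else "+"
        pvecs.setdefault(g, []).append(row["p"])
    records = {}
    for gene, syms in per_gene.items():
        missing = [c for c in columns if c not in syms]
        if missing:
            raise ValueError(f"gene {gene!r} missing contrast(s): {missing}")
        verdict = classify_gene(pvecs[gene], gene, alpha=alpha)
        records[gene] = {**syms, "overall": verdict.overall}
    for gene in unassigned_genes:
        records[gene] = {c: "" for c in columns}
        records[gene]["overall"] = "unassigned"
    matrix = pd.DataFrame.from_dict(records, orient="index", columns=columns + ["overall"])
    matrix.index.name = "gene_symbol"
    counts = {
        "stable": int((matrix["overall"] == "stable").sum()),
        "sensitive": int((matrix["overall"] == "sensitive").sum()),
        "unassigned": int((matrix["overall"] == "unassigned").sum()),
    }
    return matrix, counts
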