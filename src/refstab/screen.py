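"""Coefficient-of-variation stability screen.

The first stability filter is the coefficient of variation of a gene's
per-condition mean FI across the gravity conditions of one campaign
(4 values for a parabolic-flight campaign, 3 for a sounding-rocket one):
``CV% = 100 * sample SD / mean``.  A gene passes when its CV lies strictly
below the threshold for the declared group type — 25% for homogeneous
sample groups, 50% for heterogeneous ones.  Rapid gravity transitions make
flight samples heterogeneous, so the heterogeneous threshold is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenConfig",
    "CvRecord",
    "cv_percent",
    "screen_gene",
    "cv_table",
    "threshold_counts",
    "heatmap_matrix",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the CV screen (percent)."""

    cv_threshold_homogeneous: float = 25.0
    cv_threshold_heterogeneous: float = 50.0
    group_type: str = "heterogeneous"

    def __post_init__(self) -> None:
        if not 0 < self.cv_threshold_homogeneous < self.cv_threshold_heterogeneous:
            raise ValueError("need 0 < homogeneous threshold < heterogeneous threshold")
        if self.group_type not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown group type {self.group_type!r}")

    @property
    def threshold(self) -> float:
        if self.group_type == "homogeneous":
            return self.cv_threshold_homogeneous
        return self.cv_threshold_heterogeneous


@dataclass(frozen=True)
class CvRecord:
    gene_symbol: str
    campaign: str
    cv_percent: float
    group_type: str
    verdict: str  # "pass" | "fail"


def cv_percent(values: Sequence[float] | np.ndarray) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean")
    return float(100.0 * vals.std(ddof=1) / mean)


def screen_gene(cv: float, config: ScreenConfig | None = None) -> str:
    """Pass/fail verdict: pass iff CV is strictly below the group threshold."""
    config = config or ScreenConfig()
    return "pass" if cv < config.threshold else "fail"


def cv_table(
    summaries: pd.DataFrame, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-gene, per-campaign CV across condition means, with verdicts.

    ``summaries`` is a gene-condition summary frame (columns gene_symbol,
    campaign, condition, mean_fi).  The CV is computed across each campaign's
    per-condition gene means on the linear scale.
    """
    config = config or ScreenConfig()
    rows = []
    for (gene, campaign), sub in summaries.groupby(
        ["gene_symbol", "campaign"], sort=False
    ):
        cv = cv_percent(sub["mean_fi"].to_numpy())
        rows.append(
            {
                "gene_symbol": gene,
                "campaign": campaign,
                "cv_percent": cv,
                "group_type": config.group_type,
                "verdict": screen_gene(cv, config),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_symbol", "campaign", "cv_percent", "group_type", "verdict"]
    )


def threshold_counts(
    cv_values: Iterable[float], thresholds: tuple[float, float] = (25.0, 50.0)
) -> dict[str, int]:
    """Counts of CVs below/between/above the two screen thresholds."""
    lo, hi = thresholds
    vals = np.asarray(list(cv_values), dtype=float)
    return {
        "below_lower": int((vals < lo).sum()),
        "between": int(((vals >= lo) & (vals < hi)).sum()),
        "above_upper": int((vals >= hi).sum()),
        "total": int(vals.size),
    }


def heatmap_matrix(summaries: pd.DataFrame, campaign: str | None = None) -> pd.DataFrame:
    """Genes x conditions matrix of mean FI (plain export; no rendering)."""
    sub = summaries if campaign is None else summaries[summaries["campaign"] == campaign]
    return sub.pivot_table(
        index="gene_symbol", columns="condition", values="mean_fi", sort=False
    )
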