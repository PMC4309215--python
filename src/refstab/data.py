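"""Expression-matrix container, delimited-table IO, scale transforms and
quantile normalization.

The central object is :class:`ExpressionMatrix`: a probes x arrays table of
microarray fluorescence intensities (FI) together with a probe -> gene-symbol
map and an explicit scale flag (``"log2"`` or ``"linear"``).  Downstream
statistics in this package are defined on linear FI, so the scale is tracked
explicitly and silent double transforms are rejected.

:class:`StudyDesign` assigns each array to a gravity condition of one flight
campaign and fixes the ordered list of condition contrasts that the
differential tests run over.  Two standard campaign layouts are provided:

* ``PFC`` (parabolic flight): conditions H/W (hardware ground control),
  1g (in-flight control), 1.8g (pull-up hypergravity), ug (microgravity);
  contrasts H/W-1g, 1g-1.8g, 1.8g-ug, 1g-ug.
* ``TEXUS`` (sounding rocket): conditions H/W, BL (post-launch baseline),
  ug; contrasts H/W-BL, BL-ug, H/W-ug.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "StudyDesign",
    "BoxplotSummary",
    "PFC_CONDITIONS",
    "PFC_CONTRASTS",
    "TEXUS_CONDITIONS",
    "TEXUS_CONTRASTS",
    "read_expression_table",
    "write_expression_table",
    "read_design_table",
    "write_design_table",
    "to_linear",
    "to_log2",
    "quantile_normalize",
    "boxplot_summary",
]

PFC_CONDITIONS: tuple[str, ...] = ("H/W", "1g", "1.8g", "ug")
PFC_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("H/W", "1g"),
    ("1g", "1.8g"),
    ("1.8g", "ug"),
    ("1g", "ug"),
)
TEXUS_CONDITIONS: tuple[str, ...] = ("H/W", "BL", "ug")
TEXUS_CONTRASTS: tuple[tuple[str, str], ...] = (
    ("H/W", "BL"),
    ("BL", "ug"),
    ("H/W", "ug"),
)

_CAMPAIGN_LAYOUTS = {
    "PFC": (PFC_CONDITIONS, PFC_CONTRASTS),
    "TEXUS": (TEXUS_CONDITIONS, TEXUS_CONTRASTS),
}


@dataclass
class ExpressionMatrix:
    """Probes x arrays fluorescence matrix with gene annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Fluorescence intensities, index = probe ids (unique accession
        strings), columns = array ids.
    gene_symbols : pandas.Series
        Gene symbol per probe, indexed like ``values``.
    scale : {"log2", "linear"}
        Scale the values are on.  Linear values must be strictly positive.
    """

    values: pd.DataFrame
    gene_symbols: pd.Series
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe id(s): {', '.join(map(str, dupes))}")
        self.gene_symbols = self.gene_symbols.reindex(self.values.index)
        if self.gene_symbols.isna().any():
            missing = self.gene_symbols.index[self.gene_symbols.isna()]
            raise ValueError(f"probe(s) without gene symbol: {', '.join(missing)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale == "linear" and (arr <= 0).any():
            raise ValueError("linear-scale values must be > 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def arrays(self) -> list[str]:
        return list(self.values.columns)

    def probes_of_gene(self, gene_symbol: str) -> list[str]:
        mask = self.gene_symbols == gene_symbol
        return list(self.gene_symbols.index[mask])

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.gene_symbols:
            seen.setdefault(g)
        return list(seen)

    def copy_with(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.gene_symbols.copy(), scale or self.scale)


@dataclass
class StudyDesign:
    """Array -> condition assignment for one flight campaign."""

    campaign: str
    condition_of_array: dict[str, str]
    conditions: tuple[str, ...] | None = None
    contrasts: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if self.conditions is None or self.contrasts is None:
            if self.campaign not in _CAMPAIGN_LAYOUTS:
                raise ValueError(
                    f"campaign {self.campaign!r} has no standard layout; "
                    "pass conditions and contrasts explicitly"
                )
            conditions, contrasts = _CAMPAIGN_LAYOUTS[self.campaign]
            self.conditions = conditions if self.conditions is None else self.conditions
            self.contrasts = contrasts if self.contrasts is None else self.contrasts
        self.conditions = tuple(self.conditions)
        self.contrasts = tuple(tuple(c) for c in self.contrasts)
        known = set(self.conditions)
        for array, cond in self.condition_of_array.items():
            if cond not in known:
                raise ValueError(f"array {array!r} mapped to unknown condition {cond!r}")
        for a, b in self.contrasts:
            if a not in known or b not in known:
                raise ValueError(f"contrast ({a!r}, {b!r}) references undeclared condition")

    @property
    def arrays(self) -> list[str]:
        return list(self.condition_of_array)

    def arrays_for(self, condition: str) -> list[str]:
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        return [a for a, c in self.condition_of_array.items() if c == condition]

    def contrast_labels(self) -> list[str]:
        return [f"{a} vs {b}" for a, b in self.contrasts]


@dataclass(frozen=True)
class BoxplotSummary:
    """Five-number per-array QC summary (9th/25th/50th/75th/91st percentile)."""

    p9: float
    p25: float
    p50: float
    p75: float
    p91: float

    def __post_init__(self) -> None:
        vals = (self.p9, self.p25, self.p50, self.p75, self.p91)
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ValueError("percentiles must be non-decreasing")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.p9, self.p25, self.p50, self.p75, self.p91)


# ---------------------------------------------------------------------------
# Delimited-table IO


def read_expression_table(
    source: str | Path, scale_hint: str = "linear", sep: str = "\t"
) -> ExpressionMatrix:
    """Read a probe-level expression table.

    Layout: header row names the arrays; first two columns are ``probe_id``
    and ``gene_symbol``; remaining columns are numeric FI values.
    """
    df = pd.read_csv(source, sep=sep, dtype={0: str, 1: str})
    if df.shape[1] < 3 or df.empty:
        raise ValueError("empty or malformed expression table (need probe_id, gene_symbol, >=1 array)")
    probe_col, symbol_col = df.columns[:2]
    arrays = list(df.columns[2:])
    values = df[arrays].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric value at probe {df[probe_col].iloc[bad[0]]!r}, array {arrays[bad[1]]!r}"
        )
    values.index = pd.Index(df[probe_col], name="probe_id")
    symbols = pd.Series(df[symbol_col].to_numpy(), index=values.index, name="gene_symbol")
    return ExpressionMatrix(values, symbols, scale_hint)


def write_expression_table(matrix: ExpressionMatrix, target: str | Path, sep: str = "\t") -> None:
    out = matrix.values.copy()
    out.insert(0, "gene_symbol", matrix.gene_symbols)
    out.index.name = "probe_id"
    out.reset_index().to_csv(target, sep=sep, index=False)


def read_design_table(source: str | Path, sep: str = "\t") -> list[StudyDesign]:
    """Read an array design table (columns array_id, campaign, condition).

    Returns one :class:`StudyDesign` per campaign, in order of appearance.
    Campaigns named ``PFC`` or ``TEXUS`` get their standard condition order
    and contrasts; any other campaign gets conditions in order of appearance
    and all consecutive condition pairs as contrasts.
    """
    df = pd.read_csv(source, sep=sep, dtype=str)
    required = {"array_id", "campaign", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table needs columns {sorted(required)}")
    designs = []
    for campaign in df["campaign"].drop_duplicates():
        sub = df[df["campaign"] == campaign]
        mapping = dict(zip(sub["array_id"], sub["condition"]))
        if campaign in _CAMPAIGN_LAYOUTS:
            designs.append(StudyDesign(campaign, mapping))
        else:
            conditions = tuple(sub["condition"].drop_duplicates())
            contrasts = tuple(zip(conditions, conditions[1:]))
            designs.append(StudyDesign(campaign, mapping, conditions, contrasts))
    return designs


def write_design_table(designs: Iterable[StudyDesign], target: str | Path, sep: str = "\t") -> None:
    rows = [
        {"array_id": a, "campaign": d.campaign, "condition": c}
        for d in designs
        for a, c in d.condition_of_array.items()
    ]
    pd.DataFrame(rows).to_csv(target, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Scale transforms


def to_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Back-calculate log2 FI to linear FI (v -> 2**v)."""
    if matrix.scale != "log2":
        raise ValueError("matrix is already on the linear scale")
    return matrix.copy_with(np.exp2(matrix.values), scale="linear")


def to_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Transform linear FI to log2 FI."""
    if matrix.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    return matrix.copy_with(np.log2(matrix.values), scale="log2")


# ---------------------------------------------------------------------------
# Quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Across-array quantile normalization.

    Every array's sorted value vector is replaced by the across-array mean of
    the sorted vectors, so all arrays share one empirical distribution while
    within-array ranks are preserved.  Tied values within an array receive the
    mean of the reference values at the ranks they occupy.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    x = matrix.values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="mergesort")
        normalized = np.empty_like(col)
        normalized[order] = reference
        # ties: average the reference values over each run of equal inputs
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    normalized[order[start:end]] = reference[start:end].mean()
                start = end
        out[:, j] = normalized
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values)


def boxplot_summary(array_values: Sequence[float] | np.ndarray) -> BoxplotSummary:
    """Five-number summary of one array (9/25/50/75/91th percentiles).

    Percentiles use linear interpolation between closest ranks.
    """
    vals = np.asarray(array_values, dtype=float)
    if vals.size < 2:
        raise ValueError("boxplot summary needs at least 2 values")
    if not np.isfinite(vals).all():
        raise ValueError("values must be finite")
    p = np.percentile(vals, [9, 25, 50, 75, 91], method="linear")
    return BoxplotSummary(*map(float, p))


def boxplot_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-array :func:`boxplot_summary`, one row per array."""
    rows = {a: boxplot_summary(matrix.values[a]) for a in matrix.arrays}
    return pd.DataFrame(
        {a: s.as_tuple() for a, s in rows.items()},
        index=["p9", "p25", "p50", "p75", "p91"],
    ).T.rename_axis("array_id")
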