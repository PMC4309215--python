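"""Reference-gene stability ranking: geNorm, NormFinder, BestKeeper, the
comparative delta-Ct method, and a composite ordering.

All four algorithms operate on a candidate matrix: genes x samples of log2
expression (a pandas DataFrame, genes in the index), optionally with a group
label per sample.  Lower scores mean more stable throughout.

* geNorm M: the mean, over all other candidates k, of the SD across samples
  of the pairwise log ratio log2(x_j) - log2(x_k).  Genes are excluded
  stepwise (worst M first, recomputing after each removal) down to the final
  pair; the pairwise variation V(n/n+1) is the SD across samples of
  log2(NF_n / NF_{n+1}), where NF_k is the geometric mean of the k most
  stable genes, and indicates how many reference genes suffice.
* Comparative delta-Ct: the same all-pairs mean-SD statistic without the
  stepwise exclusion; on log2 input it coincides exactly with the initial
  geNorm M.
* NormFinder (grouped variant): a variance decomposition of the gene- and
  sample-centered log2 matrix into a per-group intergroup bias d and an
  intragroup variance sigma^2 per gene; the stability value combines both as
  mean_g sqrt(d^2 + sigma^2 / n_g).  Without groups it falls back to the SD
  of the gene's centered residuals.
* BestKeeper: per-gene SD and CV of the log2 values, plus the Pearson
  correlation of each gene with the BestKeeper index (the per-sample
  geometric mean over all candidates).  Defined on qPCR crossing points in
  its original form; applied here to log2 fluorescence, where SD is the
  primary score.

The composite rank is the geometric mean of the per-method ranks (ascending,
ties broken lexicographically by gene symbol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "genorm",
    "GenormResult",
    "normfinder",
    "bestkeeper",
    "delta_ct_score",
    "composite_rank",
    "rank_candidates",
]


def _check_matrix(matrix: pd.DataFrame, min_genes: int) -> None:
    if matrix.shape[0] < min_genes:
        raise ValueError(f"need at least {min_genes} candidate genes")
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if not np.isfinite(matrix.to_numpy(dtype=float)).all():
        raise ValueError("candidate matrix must be finite")


def _pairwise_m(matrix: pd.DataFrame) -> pd.Series:
    """Mean over partners of the SD across samples of the pairwise log ratio."""
    x = matrix.to_numpy(dtype=float)
    genes = matrix.index
    # SD of (x_j - x_k) across samples for every ordered pair
    diffs = x[:, None, :] - x[None, :, :]
    sds = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(sds, 0.0)
    m = sds.sum(axis=1) / (len(genes) - 1)
    return pd.Series(m, index=genes, name="M")


def _ordinal_ranks(scores: pd.Series) -> pd.Series:
    """Ascending ranks 1..G; ties broken lexicographically by gene symbol."""
    order = sorted(scores.index, key=lambda g: (scores[g], g))
    return pd.Series({g: i + 1 for i, g in enumerate(order)}, name="rank").reindex(scores.index)


@dataclass
class GenormResult:
    m: pd.Series                 # initial M per gene (full candidate set)
    ranking: list[str]           # most stable first (stepwise-exclusion order)
    ranks: pd.Series             # 1..G per gene, from the stepwise ranking
    pairwise_variation: pd.Series  # V(n/n+1), index "V2/3", "V3/4", ...


def genorm(matrix: pd.DataFrame) -> GenormResult:
    """geNorm stability values with stepwise exclusion and V(n/n+1)."""
    _check_matrix(matrix, 3)
    initial_m = _pairwise_m(matrix)
    remaining = list(matrix.index)
    removal_order: list[str] = []
    while len(remaining) > 2:
        m = _pairwise_m(matrix.loc[remaining])
        # remove the least stable gene; M ties drop the lexicographically larger
        worst = max(remaining, key=lambda g: (m[g], g))
        removal_order.append(worst)
        remaining.remove(worst)
    # final pair ordered by initial M, then symbol
    final_pair = sorted(remaining, key=lambda g: (initial_m[g], g))
    ranking = final_pair + removal_order[::-1]
    ranks = pd.Series(
        {g: i + 1 for i, g in enumerate(ranking)}, name="rank"
    ).reindex(matrix.index)

    # pairwise variation from normalization factors of the k most stable genes
    v = {}
    log_nf_prev = matrix.loc[ranking[:2]].mean(axis=0)
    for k in range(3, len(ranking) + 1):
        log_nf = matrix.loc[ranking[:k]].mean(axis=0)
        v[f"V{k - 1}/{k}"] = float((log_nf_prev - log_nf).std(ddof=1))
        log_nf_prev = log_nf
    return GenormResult(initial_m, ranking, ranks, pd.Series(v, name="V", dtype=float))


def delta_ct_score(matrix: pd.DataFrame) -> pd.Series:
    """Comparative delta-Ct stability: mean SD of a gene's pairwise differences.

    Computed by direct enumeration of gene pairs (structurally identical to
    the initial geNorm M on log2 input).
    """
    _check_matrix(matrix, 3)
    genes = list(matrix.index)
    scores = {}
    for g in genes:
        sds = [
            float((matrix.loc[g] - matrix.loc[k]).std(ddof=1))
            for k in genes
            if k != g
        ]
        scores[g] = float(np.mean(sds))
    return pd.Series(scores, name="delta_ct").reindex(matrix.index)


def normfinder(matrix: pd.DataFrame, groups: Sequence[str] | pd.Series | None = None) -> pd.Series:
    """NormFinder-style stability value per gene (lower = more stable)."""
    _check_matrix(matrix, 2)
    x = matrix.to_numpy(dtype=float)
    # center genes and samples: remove overall expression level differences
    z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
    if groups is None:
        rho = z.std(axis=1, ddof=1)
        return pd.Series(rho, index=matrix.index, name="normfinder")
    groups = pd.Series(np.asarray(groups), index=matrix.columns)
    labels = groups.drop_duplicates().tolist()
    if len(labels) < 2:
        raise ValueError("NormFinder grouped variant needs >= 2 groups")
    rho = np.zeros(matrix.shape[0])
    for lab in labels:
        cols = np.flatnonzero((groups == lab).to_numpy())
        if len(cols) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 samples")
        zg = z[:, cols]
        d = zg.mean(axis=1)            # intergroup bias of each gene in this group
        sigma2 = zg.var(axis=1, ddof=1)  # intragroup variance
        rho += np.sqrt(d**2 + sigma2 / len(cols))
    rho /= len(labels)
    return pd.Series(rho, index=matrix.index, name="normfinder")


def bestkeeper(matrix: pd.DataFrame) -> pd.DataFrame:
    """BestKeeper descriptors: SD and CV of log2 values, r vs the index.

    The BestKeeper index is the per-sample geometric mean over all candidate
    genes (arithmetic mean on the log2 scale).  A zero-variance gene or index
    leaves the correlation undefined (NaN).
    """
    _check_matrix(matrix, 2)
    sd = matrix.std(axis=1, ddof=1)
    mean = matrix.mean(axis=1)
    cv = 100.0 * sd / mean
    index = matrix.mean(axis=0)
    r = {}
    idx_sd = index.std(ddof=1)
    for g in matrix.index:
        if sd[g] == 0 or idx_sd == 0:
            r[g] = np.nan
        else:
            r[g] = float(np.corrcoef(matrix.loc[g], index)[0, 1])
    return pd.DataFrame(
        {"sd_log2": sd, "cv_percent": cv, "pearson_r": pd.Series(r)}
    ).reindex(matrix.index)


def composite_rank(ranks_by_method: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Geometric mean of per-method ranks, ascending; ties lexicographic."""
    if not ranks_by_method:
        raise ValueError("need at least one method ranking")
    frames = pd.DataFrame(ranks_by_method)
    if frames.isna().any().any():
        raise ValueError("rankings cover different gene sets")
    geo = np.exp(np.log(frames.to_numpy(dtype=float)).mean(axis=1))
    out = frames.copy()
    out["geomean_rank"] = geo
    out["composite_rank"] = _ordinal_ranks(pd.Series(geo, index=frames.index))
    return out.sort_values("composite_rank")


def rank_candidates(
    matrix: pd.DataFrame, groups: Sequence[str] | pd.Series | None = None
) -> pd.DataFrame:
    """Run all four algorithms and the composite ordering.

    Returns a frame with each method's score and rank plus the composite;
    sorted most stable first.  BestKeeper is ranked by its SD of log2 values.
    """
    gn = genorm(matrix)
    nf = normfinder(matrix, groups)
    bk = bestkeeper(matrix)
    dc = delta_ct_score(matrix)
    ranks = {
        "genorm": gn.ranks,
        "normfinder": _ordinal_ranks(nf),
        "bestkeeper": _ordinal_ranks(bk["sd_log2"]),
        "delta_ct": _ordinal_ranks(dc),
    }
    out = composite_rank(ranks)
    out.insert(0, "genorm_m", gn.m)
    out.insert(1, "normfinder_rho", nf)
    out.insert(2, "bestkeeper_sd", bk["sd_log2"])
    out.insert(3, "bestkeeper_r", bk["pearson_r"])
    out.insert(4, "delta_ct_score", dc)
    out.index.name = "gene_symbol"
    return out
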