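"""Model/Results front door for the reference-gene stability pipeline.

:class:`ReferenceGeneStudy` is built from data — either a probe-level
:class:`~refstab.data.ExpressionMatrix` plus one or more campaign designs,
or directly from gene-level condition summaries (mean FI, SD, n) as printed
in publication tables.  ``fit()`` runs the full analysis and returns a
:class:`StabilityResults` carrying the per-gene coefficients of variation,
pairwise Welch tests, the g-stable/g-sensitive verdict matrix, the ANOVA/FDR
screen and the four-algorithm stability ranking, with a ``summary()`` table.

Typical use::

    study = ReferenceGeneStudy(matrix, design)          # probe-level data
    res = study.fit()
    print(res.summary())
    res.verdicts          # '+'/'-' matrix with an 'overall' column
    res.ranking["PFC"]    # geNorm/NormFinder/BestKeeper/delta-Ct + composite
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import aggregate as _agg
from . import screen as _screen
from . import testing as _testing
from . import ranking as _ranking
from .data import ExpressionMatrix, StudyDesign, to_linear

__all__ = ["ReferenceGeneStudy", "StabilityResults"]


class ReferenceGeneStudy:
    """Reference-gene stability analysis of one or more flight campaigns.

    Parameters
    ----------
    matrix : ExpressionMatrix, optional
        Probe-level fluorescence (log2 or linear; converted to linear
        internally).  Required unless ``summaries`` is given.
    designs : StudyDesign or sequence of StudyDesign
        One design per campaign; arrays must be columns of ``matrix``.
    summaries : pandas.DataFrame, optional
        Gene-level condition summaries with columns gene_symbol, campaign,
        condition, mean_fi, sd, n — the publication-table entry point.  CV
        screening, Welch testing and classification run on these; probe-level
        stages (aggregation, ANOVA, ranking) are skipped.
    candidates : sequence of str, optional
        Genes entering the stability ranking (default: all eligible genes).
    alpha : float
        Significance level of the pairwise tests (default 0.05).
    group_type : {"heterogeneous", "homogeneous"}
        CV threshold regime (50% vs 25%).
    min_probes, outlier_rule, variance_threshold, exclude_genes
        Aggregation rules, see :mod:`refstab.aggregate`.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix | None = None,
        designs: StudyDesign | Sequence[StudyDesign] | None = None,
        *,
        summaries: pd.DataFrame | None = None,
        contrasts: Mapping[str, Sequence[tuple[str, str]]] | None = None,
        candidates: Sequence[str] | None = None,
        alpha: float = 0.05,
        group_type: str = "heterogeneous",
        min_probes: int = 3,
        outlier_rule: str = "none",
        variance_threshold: float = 100.0,
        exclude_genes: Iterable[str] = (),
    ) -> None:
        if (matrix is None) == (summaries is None):
            raise ValueError("provide exactly one of matrix or summaries")
        if isinstance(designs, StudyDesign):
            designs = [designs]
        self.matrix = matrix
        self.designs = list(designs) if designs else []
        if matrix is not None and not self.designs:
            raise ValueError("probe-level input needs at least one StudyDesign")
        self.summaries = summaries
        if summaries is not None:
            if contrasts is None:
                from .datasets import flight_contrasts

                contrasts = flight_contrasts()
            self.contrasts = dict(contrasts)
        else:
            self.contrasts = {d.campaign: d.contrasts for d in self.designs}
        self.candidates = list(candidates) if candidates is not None else None
        self.alpha = alpha
        self.screen_config = _screen.ScreenConfig(group_type=group_type)
        self.min_probes = min_probes
        self.outlier_rule = outlier_rule
        self.variance_threshold = variance_threshold
        self.exclude_genes = tuple(exclude_genes)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tables(
        cls, expression_path, design_path, scale: str = "log2", **kwargs
    ) -> "ReferenceGeneStudy":
        """Build from a probe-level expression TSV and a design TSV."""
        from .data import read_design_table, read_expression_table

        matrix = read_expression_table(expression_path, scale_hint=scale)
        designs = read_design_table(design_path)
        return cls(matrix, designs, **kwargs)

    @classmethod
    def from_condition_summaries(
        cls,
        summaries: pd.DataFrame,
        contrasts: Mapping[str, Sequence[tuple[str, str]]] | None = None,
        **kwargs,
    ) -> "ReferenceGeneStudy":
        """Build from gene-level mean/SD/n summaries (publication tables)."""
        return cls(summaries=summaries, contrasts=contrasts, **kwargs)

    # -- fitting ----------------------------------------------------------

    def fit(self) -> "StabilityResults":
        if self.summaries is not None:
            return self._fit_from_summaries(self.summaries)
        matrix = self.matrix
        if matrix.scale == "log2":
            matrix = to_linear(matrix)
        all_summaries, statuses = [], {}
        probe_level: dict[str, dict[str, pd.DataFrame]] = {}
        for design in self.designs:
            sub = ExpressionMatrix(
                matrix.values[design.arrays], matrix.gene_symbols, "linear"
            )
            summaries, probe_sets, probes = _agg.aggregate_study(
                sub,
                design,
                min_probes=self.min_probes,
                outlier_rule=self.outlier_rule,
                variance_threshold=self.variance_threshold,
                exclude_genes=self.exclude_genes,
            )
            all_summaries.append(summaries)
            probe_level[design.campaign] = probes
            for gene, ps in probe_sets.items():
                # a gene ineligible in any campaign is ineligible overall
                if gene not in statuses or ps.status != "eligible":
                    statuses[gene] = ps.status
        summaries = pd.concat(all_summaries, ignore_index=True)
        eligible = sorted(g for g, s in statuses.items() if s in ("eligible", "outlier_trimmed"))
        summaries = summaries[summaries["gene_symbol"].isin(eligible)].reset_index(drop=True)
        res = self._fit_from_summaries(
            summaries, unassigned=[g for g, s in statuses.items() if g not in eligible]
        )
        res.gene_status = pd.Series(statuses, name="status").sort_index()
        # ANOVA + FDR on per-probe condition means, per campaign
        anova = {}
        for design in self.designs:
            groups = {
                gene: [df[c].to_numpy() for c in design.conditions]
                for gene, df in probe_level[design.campaign].items()
                if gene in eligible
            }
            if groups:
                anova[design.campaign] = _testing.anova_fdr(
                    groups, _testing.AlphaConfig(alpha=self.alpha)
                )
        res.anova = anova
        # four-algorithm ranking on gene-level log2 expression per array
        ranking = {}
        for design in self.designs:
            cand = self.candidates or eligible
            cand = [g for g in cand if g in eligible]
            if len(cand) < 3:
                continue
            rows = {}
            for gene in cand:
                probes = matrix.probes_of_gene(gene)
                rows[gene] = np.log2(matrix.values.loc[probes, design.arrays]).mean(axis=0)
            cm = pd.DataFrame(rows).T
            groups = [design.condition_of_array[a] for a in design.arrays]
            ranking[design.campaign] = _ranking.rank_candidates(cm, groups)
        res.ranking = ranking
        res.probe_level = probe_level
        return res

    def _fit_from_summaries(
        self, summaries: pd.DataFrame, unassigned: Sequence[str] = ()
    ) -> "StabilityResults":
        cv = _screen.cv_table(summaries, self.screen_config)
        tests = _testing.welch_table(summaries, self.contrasts, alpha=self.alpha)
        verdicts, counts = _testing.verdict_matrix(
            tests, alpha=self.alpha, unassigned_genes=unassigned
        )
        return StabilityResults(
            model=self,
            condition_summaries=summaries,
            cv=cv,
            tests=tests,
            verdicts=verdicts,
            counts=counts,
        )


@dataclass
class StabilityResults:
    """Fitted output of :class:`ReferenceGeneStudy`."""

    model: ReferenceGeneStudy
    condition_summaries: pd.DataFrame
    cv: pd.DataFrame
    tests: pd.DataFrame
    verdicts: pd.DataFrame
    counts: dict[str, int]
    gene_status: pd.Series | None = None
    anova: dict[str, pd.DataFrame] = field(default_factory=dict)
    ranking: dict[str, pd.DataFrame] = field(default_factory=dict)
    probe_level: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)

    @property
    def stable_genes(self) -> list[str]:
        return list(self.verdicts.index[self.verdicts["overall"] == "stable"])

    @property
    def sensitive_genes(self) -> list[str]:
        return list(self.verdicts.index[self.verdicts["overall"] == "sensitive"])

    def summary(self) -> str:
        """Human-readable report of the screen, tests and ranking."""
        lines = [
            "Reference-gene stability analysis",
            "=" * 70,
            f"genes classified: {len(self.verdicts)}   "
            f"stable: {self.counts['stable']}   "
            f"sensitive: {self.counts['sensitive']}   "
            f"unassigned: {self.counts['unassigned']}",
            f"alpha = {self.model.alpha}, CV threshold = "
            f"{self.model.screen_config.threshold:g}% ({self.model.screen_config.group_type})",
            "",
            "Coefficient of variation across gravity conditions (%)",
            "-" * 70,
            self.cv.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
            "",
            "g-stable (+) / g-sensitive (-) verdicts",
            "-" * 70,
            self.verdicts.to_string(),
        ]
        for campaign, table in self.ranking.items():
            lines += [
                "",
                f"Stability ranking ({campaign}; lower = more stable)",
                "-" * 70,
                table.to_string(float_format=lambda v: f"{v:.3f}"),
            ]
        return "\n".join(lines)
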