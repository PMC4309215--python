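"""Packaged fixture tables transcribed from a published altered-gravity
microarray study of human myelomonocytic (U937) cells.

Three small TSVs ship with the package:

* ``flight_gene_summaries.tsv`` — per gene x gravity condition: mean linear
  fluorescence across probes, SD across probes, and the probe count n, for
  the 7 candidate reference genes and 5 ABC-transporter genes with published
  summaries, over both flight campaigns (PFC: H/W, 1g, 1.8g, ug;
  TEXUS: H/W, BL, ug).
* ``published_welch_pvalues.tsv`` — the Welch t-test p-values the study
  printed for each condition contrast.
* ``published_verdicts.tsv`` — the published g-stable (+) / g-sensitive (-)
  call per gene and contrast (15 genes; three of them, ABCA5/ABCA9/ABCC12,
  have verdicts but no printed summaries).

One transcription note: the published PFC hardware-control mean for ALB is
an obvious dropped-digit misprint (2.13 where every other ALB condition is
~40 and the printed p-value implies ~42); the fixture carries the corrected
42.13, which reproduces the printed p to three decimals.

The per-probe supplementary tables of the study were never deposited in a
public archive, so probe-level reproduction inputs cannot be packaged;
:func:`load_supplementary_probe_tables` documents that gap.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data import PFC_CONTRASTS, TEXUS_CONTRASTS

__all__ = [
    "load_flight_summaries",
    "load_published_pvalues",
    "load_published_verdicts",
    "load_supplementary_probe_tables",
    "flight_contrasts",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("refstab").joinpath("tables", name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_flight_summaries() -> pd.DataFrame:
    """Gene-condition summaries (mean FI, SD, n) for both campaigns."""
    return _read("flight_gene_summaries.tsv")


def load_published_pvalues() -> pd.DataFrame:
    """Published Welch p-values per gene and condition contrast."""
    return _read("published_welch_pvalues.tsv")


def load_published_verdicts() -> pd.DataFrame:
    """Published '+'/'-' stability calls per gene and contrast."""
    return _read("published_verdicts.tsv")


def load_supplementary_probe_tables() -> pd.DataFrame:
    """Per-probe fluorescence tables of the original study.

    These exist only in the study's supplementary material, which was never
    deposited in a public archive, so they cannot be redistributed with the
    package.  Always raises :class:`FileNotFoundError`.
    """
    raise FileNotFoundError(
        "per-probe supplementary tables are not publicly archived and are "
        "not distributable with this package; use refstab.simulate to "
        "generate structurally equivalent probe-level data"
    )


def flight_contrasts() -> dict[str, tuple[tuple[str, str], ...]]:
    """The ordered condition contrasts of the two campaigns."""
    return {"PFC": PFC_CONTRASTS, "TEXUS": TEXUS_CONTRASTS}
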