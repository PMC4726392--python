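"""Per-base coverage statistics qualifying the panel.

Works from a long-format per-base depth table (gene, pos, sample, depth)
rather than alignments, so the module is exercisable without BAMs.  The
headline statistics are the percentage of coding bases covered by at least
10 reads — per gene and sample, per sample, and pooled — and the fraction
of genes whose every base reaches the threshold.  Per-gene distributions
across samples are summarized with quartile box-plot statistics using the
1.5 x IQR outlier rule (quartiles by linear interpolation between order
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthTable",
    "QcSummary",
    "pct_covered",
    "compute_qc",
    "gene_boxplot_stats",
    "fully_covered_fraction",
    "read_depth_table",
    "write_depth_table",
]


class DepthTable:
    """Per-base depths over the coding bases of each gene, per sample."""

    def __init__(self, df: pd.DataFrame):
        required = {"gene", "pos", "sample", "depth"}
        if not required.issubset(df.columns):
            raise ValueError(f"depth table needs columns {sorted(required)}")
        if (df["depth"] < 0).any():
            raise ValueError("negative depth in depth table")
        counts = df.groupby(["gene", "sample"], sort=False)["pos"].count().unstack()
        if counts.isna().any().any() or counts.nunique(axis=1).gt(1).any():
            raise ValueError("per-gene base count must be constant across samples")
        self.df = df.reset_index(drop=True)

    @property
    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def depths(self, gene: str, sample: str) -> np.ndarray:
        sel = self.df[(self.df["gene"] == gene) & (self.df["sample"] == sample)]
        return sel["depth"].to_numpy()


@dataclass
class QcSummary:
    """Coverage-QC statistics at one depth threshold."""

    threshold: int
    #: per (gene, sample) percent of bases >= threshold (genes x samples)
    pct_by_gene_sample: pd.DataFrame
    #: per-sample mean depth over all covered bases
    mean_depth_by_sample: pd.Series
    #: per-sample percent of bases >= threshold
    pct_by_sample: pd.Series
    #: cohort-pooled per-base statistics, labelled explicitly because mean
    #: and range mix per-sample and per-base views: mean over all (base,
    #: sample) pairs and the (min, max) single-base depth observed
    pooled_mean_depth: float = 0.0
    pooled_depth_range: tuple = (0, 0)

    @property
    def genes(self) -> list[str]:
        return list(self.pct_by_gene_sample.index)

    @property
    def samples(self) -> list[str]:
        return list(self.pct_by_gene_sample.columns)


def pct_covered(depths: Sequence[float], threshold: int = 10) -> float:
    """Percent of bases with depth >= threshold (inclusive)."""
    arr = np.asarray(depths)
    if arr.size == 0:
        raise ValueError("empty depth vector")
    return 100.0 * float(np.count_nonzero(arr >= threshold)) / arr.size


def compute_qc(table: DepthTable, threshold: int = 10) -> QcSummary:
    df = table.df
    covered = df.assign(ok=(df["depth"] >= threshold))
    pct = (covered.groupby(["gene", "sample"])["ok"].mean() * 100.0).unstack()
    pct = pct.sort_index(axis=0).sort_index(axis=1)
    mean_depth = df.groupby("sample")["depth"].mean().sort_index()
    pct_sample = (covered.groupby("sample")["ok"].mean() * 100.0).sort_index()
    return QcSummary(
        threshold=threshold,
        pct_by_gene_sample=pct,
        mean_depth_by_sample=mean_depth,
        pct_by_sample=pct_sample,
        pooled_mean_depth=float(df["depth"].mean()),
        pooled_depth_range=(int(df["depth"].min()), int(df["depth"].max())),
    )


def gene_boxplot_stats(qc: QcSummary, gene: str) -> dict:
    """Five-number summary across samples of a gene's percent-covered.

    Quartiles use linear interpolation between order statistics; a sample
    is an outlier when its value is below Q1 - 1.5 IQR or above
    Q3 + 1.5 IQR.
    """
    values = qc.pct_by_gene_sample.loc[gene].dropna().to_numpy()
    if values.size == 0:
        raise ValueError(f"no samples for gene {gene}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = np.sort(values[(values < lo) | (values > hi)])
    inliers = values[(values >= lo) & (values <= hi)]
    return {
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(values.max()),
        "iqr": float(iqr),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(x) for x in outliers],
    }


def fully_covered_fraction(qc: QcSummary, per_sample: bool = False):
    """Percent of genes whose every base reaches the threshold.

    Pooled mode (default) requires full coverage in *every* sample;
    ``per_sample=True`` returns the per-sample percentages instead.
    """
    full = qc.pct_by_gene_sample >= 100.0
    if per_sample:
        return full.mean(axis=0) * 100.0
    return float(full.all(axis=1).mean() * 100.0)


def read_depth_table(path) -> DepthTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str,
                                            "pos": np.int64, "depth": np.int64})
    return DepthTable(df)


def write_depth_table(table: DepthTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def write_qc_table(qc: QcSummary, path) -> None:
    qc.pct_by_gene_sample.rename_axis("gene").to_csv(path, sep="\t")
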