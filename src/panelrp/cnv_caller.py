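"""Exon-level CNV detection from cross-sample coverage ratios.

High uniform on-target coverage lets copy-number changes be read straight
off the depth matrix of a sequencing run: each sample's target depths are
library-size normalized (divided by the sample's median target depth) and
then divided, target by target, by the median normalized depth of the
other samples of the same run.  A heterozygous deletion halves a target's
ratio (~0.5); a heterozygous duplication raises it (~1.5).  A target is
called deleted when its ratio falls strictly below 0.7 and duplicated when
it rises strictly above 1.2; adjacent same-gene, same-direction calls are
merged into one event.  Targets whose run-mate median raw depth is below
100x are masked out to avoid false positives in poorly captured regions.

Mirroring the diagnostic workflow, calling can be restricted to the
(sample, gene) pairs where the sample already carries a single heterozygous
pathogenic small variant — i.e. the second allele is being hunted.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import CoverageError, CoverageMatrix, Panel

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageMatrix",
    "RatioTrack",
    "CnvCall",
    "normalize",
    "compute_ratios",
    "call_cnvs",
    "call_cnvs_for_run",
    "restrict_to_candidates",
]


@dataclass
class RatioTrack:
    """Per-target relative coverage ratios for one test sample.

    ``ratio`` is NaN where undefined (reference median zero); ``eligible``
    is the sample-independent >=min_ref_coverage mask.
    """

    sample: str
    ratio: pd.Series
    eligible: pd.Series


@dataclass(frozen=True)
class CnvCall:
    """One contiguous deletion/duplication event in one sample."""

    sample: str
    gene: str
    targets: tuple
    type: str  # "deletion" | "duplication"
    mean_ratio: float

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def first(self) -> str:
        return self.targets[0]

    @property
    def last(self) -> str:
        return self.targets[-1]

    @property
    def span(self) -> str:
        """Exon span in reporting form, e.g. ``Ex13-14`` or ``Ex19``."""
        first = self.first.rsplit("_", 1)[-1].lstrip("exdi")
        last = self.last.rsplit("_", 1)[-1].lstrip("exdi")
        return f"Ex{first}" if first == last else f"Ex{first}-{last}"


def normalize(matrix: CoverageMatrix) -> pd.DataFrame:
    """Library-size correction: divide each sample by its median target depth."""
    if len(matrix.samples) < 2:
        raise CoverageError("ratio computation needs at least 2 samples per run")
    medians = matrix.depth.median(axis=0)
    zero = medians[medians <= 0]
    if not zero.empty:
        raise CoverageError(f"sample(s) with non-positive median depth: {list(zero.index)}")
    return matrix.depth / medians


def compute_ratios(
    matrix: CoverageMatrix,
    test_sample: str,
    min_ref_coverage: int = 100,
    min_run_mates: int = 3,
) -> RatioTrack:
    """Relative coverage ratio of one sample against its run-mates.

    ratio[t] = normalized(test, t) / median over run-mates of normalized(., t);
    a target is eligible iff the run-mates' median *raw* depth is
    >= ``min_ref_coverage``.
    """
    if test_sample not in matrix.samples:
        raise CoverageError(f"sample {test_sample!r} not in coverage matrix")
    mates = [s for s in matrix.samples if s != test_sample]
    if len(mates) < min_run_mates:
        _warnings.warn(
            f"only {len(mates)} run-mate(s) for {test_sample}; "
            f"ratios are unreliable below {min_run_mates}",
            stacklevel=2)
    norm = normalize(matrix)
    ref = norm[mates].median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = norm[test_sample] / ref
    ratio[ref <= 0] = np.nan
    eligible = (matrix.depth[mates].median(axis=1) >= min_ref_coverage) & (ref > 0)
    return RatioTrack(sample=test_sample, ratio=ratio, eligible=eligible)


def call_cnvs(
    track: RatioTrack,
    panel: Panel,
    del_threshold: float = 0.7,
    dup_threshold: float = 1.2,
    genes: Optional[Sequence[str]] = None,
) -> list[CnvCall]:
    """Threshold eligible targets and merge adjacent same-gene calls.

    Strict inequalities: a ratio must fall *below* ``del_threshold`` or rise
    *above* ``dup_threshold``.  Only targets adjacent in the panel's
    per-gene target order merge; no gap tolerance.  ``genes`` limits
    calling to a subset of genes (restricted mode).
    """
    calls: list[CnvCall] = []
    for gene in (genes if genes is not None else panel.genes):
        run_targets: list[str] = []
        run_type: Optional[str] = None
        for region in panel.regions_for_gene(gene):
            label = region.label
            r = track.ratio.get(label, np.nan)
            ok = bool(track.eligible.get(label, False)) and np.isfinite(r)
            if ok and r < del_threshold:
                state = "deletion"
            elif ok and r > dup_threshold:
                state = "duplication"
            else:
                state = None
            if state == run_type and state is not None:
                run_targets.append(label)
            else:
                if run_type is not None:
                    calls.append(_make_call(track, gene, run_targets, run_type))
                run_targets = [label] if state else []
                run_type = state
        if run_type is not None:
            calls.append(_make_call(track, gene, run_targets, run_type))
    return calls


def _make_call(track: RatioTrack, gene: str, targets: list[str], kind: str) -> CnvCall:
    mean_ratio = float(np.mean([track.ratio[t] for t in targets]))
    return CnvCall(sample=track.sample, gene=gene, targets=tuple(targets),
                   type=kind, mean_ratio=mean_ratio)


def restrict_to_candidates(
    calls_by_sample: Mapping[str, Sequence[CnvCall]],
    case_table: Mapping[str, Sequence[str]],
) -> dict[str, list[CnvCall]]:
    """Keep only calls in genes where the sample has one het pathogenic SNV."""
    out: dict[str, list[CnvCall]] = {}
    for sample, calls in calls_by_sample.items():
        allowed = set(case_table.get(sample, ()))
        kept = [c for c in calls if c.gene in allowed]
        if kept:
            out[sample] = kept
    return out


def call_cnvs_for_run(
    matrix: CoverageMatrix,
    panel: Panel,
    case_table: Optional[Mapping[str, Sequence[str]]] = None,
    del_threshold: float = 0.7,
    dup_threshold: float = 1.2,
    min_ref_coverage: int = 100,
    min_run_mates: int = 3,
) -> dict[str, list[CnvCall]]:
    """Call CNVs for every sample of a run.

    With ``case_table`` (sample -> genes carrying exactly one pathogenic het
    small variant) the analysis runs in restricted mode: only those
    (sample, gene) pairs are examined.  Without it, every sample is called
    over the whole panel.
    """
    out: dict[str, list[CnvCall]] = {}
    samples = case_table.keys() if case_table is not None else matrix.samples
    for sample in samples:
        genes = None
        if case_table is not None:
            genes = sorted(set(case_table[sample]))
            if not genes:
                continue
        track = compute_ratios(matrix, sample, min_ref_coverage, min_run_mates)
        calls = call_cnvs(track, panel, del_threshold, dup_threshold, genes=genes)
        if calls:
            out[sample] = calls
    return out
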