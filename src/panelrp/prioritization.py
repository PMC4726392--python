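"""Six-stage variant prioritization cascade with multi-predictor consensus.

Candidate disease alleles are selected by applying, in fixed order:

1. region filter — keep variants inside the flanked coding targets or at a
   whitelisted deep-intronic position; drop intergenic/UTR/off-target calls;
2. frequency filter — keep variants whose highest recorded population
   frequency (1000 Genomes, EVS, ExAC) is <= 0.005, or with no recorded
   frequency at all;
3. known-mutation lookup — an rs identifier together with an HGMD or LOVD
   record makes the variant a known pathogenic mutation (terminal); a
   variant with no rs identifier is tagged novel;
4. consequence rule — nonsense, frameshift and canonical splice-site
   variants are pathogenic outright, regardless of predictors;
5. population-control screen — novel missense / non-canonical splice
   variants seen in the healthy-control exome set are benign;
6. in-silico consensus — the remaining missense and non-canonical splice
   variants are voted on by independent predictors; at least two damaging
   votes make a variant potentially pathogenic.

Every input variant ends with exactly one terminal label plus the evidence
trail of the criteria that fired.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .panel_io import (
    ALIGN_GVGD_CLASSES,
    AnnotatedVariant,
    AnnotationError,
    Config,
    LOF_CONSEQUENCES,
    MISSENSE_PREDICTORS,
    Panel,
    POLYPHEN_DAMAGING,
    PredictorProfile,
    SPLICE_PREDICTORS,
)

__all__ = [
    "LABELS",
    "CANDIDATE_LABELS",
    "PathogenicityLabel",
    "ClassifiedVariant",
    "StageCount",
    "CascadeReport",
    "filter_by_region",
    "filter_by_maf",
    "classify_known",
    "classify_by_consequence",
    "screen_population_controls",
    "consensus_missense",
    "consensus_splice",
    "run_cascade",
]

LABELS = (
    "known_pathogenic",
    "lof_pathogenic",
    "potentially_pathogenic",
    "benign_population",
    "benign_frequency",
    "out_of_region",
    "uncertain",
)

#: labels retained as candidate disease alleles downstream
CANDIDATE_LABELS = frozenset(
    {"known_pathogenic", "lof_pathogenic", "potentially_pathogenic"})


@dataclass(frozen=True)
class PathogenicityLabel:
    value: str
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if self.value not in LABELS:
            raise ValueError(f"unknown label {self.value!r}")
        if self.value != "uncertain" and not self.evidence:
            raise ValueError(f"label {self.value} requires non-empty evidence")

    @property
    def is_candidate(self) -> bool:
        return self.value in CANDIDATE_LABELS


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: AnnotatedVariant
    label: PathogenicityLabel

    @property
    def is_candidate(self) -> bool:
        return self.label.is_candidate


@dataclass(frozen=True)
class StageCount:
    stage: str
    n_in: int
    n_labeled: int   # variants terminally labeled at this stage
    n_forward: int   # variants forwarded to the next stage


@dataclass
class CascadeReport:
    """Stage-by-stage accounting plus the terminal label of every variant."""

    stages: list[StageCount] = field(default_factory=list)
    classified: list[ClassifiedVariant] = field(default_factory=list)

    @property
    def labels(self) -> dict:
        return {cv.variant.key: cv.label for cv in self.classified}

    @property
    def candidates(self) -> list[ClassifiedVariant]:
        return [cv for cv in self.classified if cv.is_candidate]

    def count(self, label: str) -> int:
        return sum(cv.label.value == label for cv in self.classified)


# --------------------------------------------------------------------------
# stages 1-2: region and frequency filters
# --------------------------------------------------------------------------

_REGION_EXCLUDED = frozenset({"intergenic", "utr", "deep_intronic"})


def _is_whitelisted(v: AnnotatedVariant, config: Config) -> bool:
    return any(g == v.gene and c == v.chrom and p == v.pos
               for g, c, p in config.deep_intronic_whitelist)


def filter_by_region(
    variants: Sequence[AnnotatedVariant], panel: Panel, config: Optional[Config] = None,
) -> tuple[list[AnnotatedVariant], list[ClassifiedVariant]]:
    """Stage 1: coding targets (exons +/- flank) plus the deep-intronic whitelist.

    Returns ``(retained, out_of_region)``.
    """
    config = config or Config()
    retained, dropped = [], []
    for v in variants:
        if v.chrom is None or v.pos is None:
            raise AnnotationError("variant without coordinates cannot be region-filtered")
        if _is_whitelisted(v, config):
            retained.append(v)
            continue
        in_target = any(r.region_class == "coding_exon_flanked"
                        for r in panel.regions_at(v.chrom, v.pos))
        if in_target and v.consequence not in _REGION_EXCLUDED:
            retained.append(v)
        else:
            dropped.append(ClassifiedVariant(
                v, PathogenicityLabel("out_of_region", ("criterion1:outside_target",))))
    return retained, dropped


def filter_by_maf(
    variants: Sequence[AnnotatedVariant], threshold: float = 0.005,
) -> tuple[list[AnnotatedVariant], list[ClassifiedVariant]]:
    """Stage 2: retain iff max recorded MAF <= threshold or no MAF recorded."""
    retained, dropped = [], []
    for v in variants:
        if v.maf and max(v.maf.values()) > threshold:
            worst = max(v.maf, key=v.maf.get)
            dropped.append(ClassifiedVariant(v, PathogenicityLabel(
                "benign_frequency",
                (f"criterion2:maf_{worst}={v.maf[worst]:g}>{threshold:g}",))))
        else:
            retained.append(v)
    return retained, dropped


# --------------------------------------------------------------------------
# stages 3-5
# --------------------------------------------------------------------------

def classify_known(v: AnnotatedVariant) -> Optional[PathogenicityLabel]:
    """Stage 3: rs identifier plus an HGMD/LOVD record -> known pathogenic.

    Returns a terminal label, or None to continue the cascade (variants
    without an rs number continue as novel rare variants).
    """
    if v.rs_id is not None and (v.in_hgmd or v.in_lovd):
        dbs = [name for name, hit in (("HGMD", v.in_hgmd), ("LOVD", v.in_lovd)) if hit]
        return PathogenicityLabel(
            "known_pathogenic", (f"criterion3:rs={v.rs_id}", f"criterion3:{'+'.join(dbs)}"))
    return None


def classify_by_consequence(v: AnnotatedVariant) -> Optional[PathogenicityLabel]:
    """Stage 4: nonsense / frameshift / canonical splice -> pathogenic."""
    if v.consequence in LOF_CONSEQUENCES:
        return PathogenicityLabel("lof_pathogenic", (f"criterion4:{v.consequence}",))
    return None


_CONSENSUS_CONSEQUENCES = frozenset({"missense", "noncanonical_splice"})


def screen_population_controls(
    v: AnnotatedVariant, config: Optional[Config] = None,
) -> Optional[PathogenicityLabel]:
    """Stage 5: novel missense/splice variants seen in control exomes are benign.

    Only *novel* (no rs id) missense and non-canonical splice variants are
    screened; anything else passes through untouched.
    """
    config = config or Config()
    if not (v.is_novel and v.consequence in _CONSENSUS_CONSEQUENCES):
        return None
    if v.spv_present:
        if config.spv_policy == "any_presence":
            return PathogenicityLabel("benign_population", ("criterion5:in_spv_controls",))
        if v.spv_freq is not None and v.spv_freq > config.spv_freq_threshold:
            return PathogenicityLabel(
                "benign_population",
                (f"criterion5:spv_freq={v.spv_freq:g}>{config.spv_freq_threshold:g}",))
    return None


# --------------------------------------------------------------------------
# stage 6: predictor consensus
# --------------------------------------------------------------------------

def _agvgd_votes(cls: str, min_class: str) -> bool:
    return ALIGN_GVGD_CLASSES.index(cls) >= ALIGN_GVGD_CLASSES.index(min_class)


def consensus_missense(
    profile: PredictorProfile, min_votes: int = 2, agvgd_min_class: str = "C35",
) -> tuple[bool, int, tuple]:
    """Count damaging votes among the four missense predictors.

    Per-tool damaging mapping: SIFT call "D"; PolyPhen "Pos.D" or "Pr.D";
    Align GVGD class >= ``agvgd_min_class`` (default C35 — C0/C15/C25 are
    "less likely pathogenic" and do not vote); MutationTaster "D".
    Returns ``(flagged, n_votes, voters)``; deterministic and independent
    of the order predictions were recorded in.
    """
    if profile.n_missense_entries() == 0:
        raise AnnotationError("missense consensus requires at least one predictor entry")
    voters = []
    if profile.sift is not None and profile.sift.call == "D":
        voters.append("SIFT")
    if profile.polyphen is not None and profile.polyphen.call in POLYPHEN_DAMAGING:
        voters.append("PolyPhen")
    if profile.align_gvgd is not None and _agvgd_votes(profile.align_gvgd, agvgd_min_class):
        voters.append("AlignGVGD")
    if profile.mutation_taster == "D":
        voters.append("MutationTaster")
    return len(voters) >= min_votes, len(voters), tuple(voters)


_SPLICE_NAMES = {"hsf": "HSF", "bdgp": "BDGP", "ast": "AST", "netgene2": "NetGene2"}


def consensus_splice(
    profile: PredictorProfile, min_votes: int = 2, drop_fraction: float = 0.10,
) -> tuple[bool, int, tuple]:
    """Count damaging votes among the splice predictors.

    A score-based tool votes damaging when it reports loss of the natural
    site, creation of a new cryptic site, or a relative score drop
    ``(wt - mut)/wt >= drop_fraction``.  ESEfinder votes on loss of a
    splicing-enhancer motif.
    """
    if profile.n_splice_entries() == 0:
        raise AnnotationError("splice consensus requires at least one predictor entry")
    voters = []
    for tool, name in _SPLICE_NAMES.items():
        entry = getattr(profile, tool)
        if entry is None:
            continue
        if entry.site_lost or entry.cryptic_site:
            voters.append(name)
            continue
        if entry.wt is not None and entry.mut is not None:
            if entry.wt <= 0:
                raise AnnotationError(f"{name}: wild-type splice score must be > 0")
            if (entry.wt - entry.mut) / entry.wt >= drop_fraction:
                voters.append(name)
    if profile.esefinder_motif_lost:
        voters.append("ESEfinder")
    return len(voters) >= min_votes, len(voters), tuple(voters)


# --------------------------------------------------------------------------
# the full cascade
# --------------------------------------------------------------------------

def run_cascade(
    variants: Sequence[AnnotatedVariant], panel: Panel, config: Optional[Config] = None,
) -> CascadeReport:
    """Apply stages 1-6 in order; every variant gets exactly one label."""
    config = config or Config()
    report = CascadeReport()
    n0 = len(variants)

    current, dropped = filter_by_region(variants, panel, config)
    report.classified.extend(dropped)
    report.stages.append(StageCount("region", n0, len(dropped), len(current)))

    n_in = len(current)
    current, dropped = filter_by_maf(current, config.maf_threshold)
    report.classified.extend(dropped)
    report.stages.append(StageCount("maf", n_in, len(dropped), len(current)))

    def _stage(name, func):
        nonlocal current
        n_in = len(current)
        forward, labeled = [], []
        for v in current:
            label = func(v)
            if label is None:
                forward.append(v)
            else:
                labeled.append(ClassifiedVariant(v, label))
        report.classified.extend(labeled)
        report.stages.append(StageCount(name, n_in, len(labeled), len(forward)))
        current = forward

    _stage("known_db", classify_known)
    _stage("consequence", classify_by_consequence)
    _stage("population_controls", lambda v: screen_population_controls(v, config))

    n_in = len(current)
    labeled = []
    for v in current:
        label = _consensus_label(v, config)
        labeled.append(ClassifiedVariant(v, label))
    report.classified.extend(labeled)
    report.stages.append(StageCount("consensus", n_in, len(labeled), 0))

    assert len(report.classified) == n0, "cascade must classify every input variant"
    return report


def _consensus_label(v: AnnotatedVariant, config: Config) -> PathogenicityLabel:
    if v.consequence == "missense":
        flagged, votes, voters = consensus_missense(
            v.predictors, config.min_damaging_votes, config.agvgd_min_class)
    elif v.consequence == "noncanonical_splice":
        flagged, votes, voters = consensus_splice(
            v.predictors, config.min_damaging_votes, config.splice_drop_fraction)
    else:
        # synonymous / other variants surviving stages 1-5: no consensus route
        return PathogenicityLabel("uncertain", (f"no_rule:{v.consequence}",))
    if flagged:
        return PathogenicityLabel(
            "potentially_pathogenic",
            (f"criterion6:votes={votes}", "criterion6:" + "+".join(voters)))
    return PathogenicityLabel(
        "uncertain", (f"criterion6:votes={votes}<{config.min_damaging_votes}",))
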