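"""Data model and file I/O for the targeted retinal-dystrophy gene panel.

The pipeline consumes four plain-text artefacts:

* a BED file of capture targets (coding exons plus a fixed intronic flank,
  and a handful of whitelisted deep-intronic positions),
* a gene table assigning each panel gene its inheritance capabilities
  (AR / AD / XL) and an optional dominant-hotspot codon interval,
* per-sample VCFs accompanied by a sidecar annotation TSV keyed by
  (chrom, pos, ref, alt) that carries consequences, population frequencies,
  database memberships and in-silico predictor scores,
* a targets x samples coverage matrix (one sequencing run per file).

Annotations travel in a flat TSV rather than VCF INFO on purpose: the
upstream annotators the pipeline is agnostic to (VEP, VariantStudio, ...)
emit mutually incompatible INFO dialects, while a keyed table is
dialect-free.  A missing annotation is represented as *absent* (``None``),
never coerced to 0 — the frequency filter treats "no recorded MAF" as a
pass, so the distinction is load-bearing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "PanelError",
    "AnnotationError",
    "CoverageError",
    "TargetRegion",
    "GeneInfo",
    "Panel",
    "MissenseCall",
    "SpliceScores",
    "PredictorProfile",
    "AnnotatedVariant",
    "CoverageMatrix",
    "Config",
    "read_panel",
    "write_panel_bed",
    "write_gene_table",
    "read_variants",
    "write_vcf",
    "write_annotation_table",
    "read_coverage_matrix",
    "write_coverage_matrix",
    "read_family_table",
    "write_family_table",
]


class PanelError(ValueError):
    """Malformed or inconsistent panel definition (BED / gene table)."""


class AnnotationError(ValueError):
    """Malformed variant annotation input."""


class CoverageError(ValueError):
    """Malformed coverage-matrix input."""


# --------------------------------------------------------------------------
# panel model
# --------------------------------------------------------------------------

REGION_CLASSES = ("coding_exon_flanked", "deep_intronic_whitelist")

Zygosity = Literal["het", "hom", "hemi"]

CONSEQUENCES = (
    "nonsense",
    "frameshift",
    "canonical_splice",
    "noncanonical_splice",
    "missense",
    "synonymous",
    "utr",
    "intergenic",
    "deep_intronic",
    "other",
)

#: consequence classes treated as loss-of-function by the cascade
LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice"})


@dataclass(frozen=True)
class TargetRegion:
    """One capture target, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    gene: str
    label: str
    region_class: str = "coding_exon_flanked"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise PanelError(
                f"target {self.label}: start ({self.start}) must be < end ({self.end})"
            )
        if self.region_class not in REGION_CLASSES:
            raise PanelError(f"target {self.label}: unknown region class {self.region_class!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether the 1-based position ``pos`` falls inside this region."""
        return chrom == self.chrom and self.start <= pos - 1 < self.end


@dataclass(frozen=True)
class GeneInfo:
    """Inheritance capabilities of one panel gene.

    ``ad_hotspot`` is a closed codon interval inside which a single
    truncating allele is compatible with dominant disease (used for RP1).
    """

    symbol: str
    inheritance: frozenset = frozenset({"AR"})
    ad_hotspot: Optional[tuple[int, int]] = None

    @property
    def is_xl(self) -> bool:
        return "XL" in self.inheritance

    @property
    def is_ar(self) -> bool:
        return "AR" in self.inheritance

    @property
    def is_ad(self) -> bool:
        return "AD" in self.inheritance


class Panel:
    """The capture design: ordered target regions plus the gene table."""

    def __init__(self, regions: Sequence[TargetRegion], genes: Mapping[str, GeneInfo],
                 flank_bp: int = 20):
        regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
        labels = [r.label for r in regions]
        if len(set(labels)) != len(labels):
            dupes = {l for l in labels if labels.count(l) > 1}
            raise PanelError(f"duplicate target labels: {sorted(dupes)}")
        for r in regions:
            if r.gene not in genes:
                raise PanelError(f"target {r.label}: gene {r.gene!r} absent from gene table")
        self.regions: list[TargetRegion] = list(regions)
        self.genes: dict[str, GeneInfo] = dict(genes)
        self.flank_bp = int(flank_bp)
        self._by_label = {r.label: r for r in self.regions}
        self._trees: dict[str, IntervalTree] = {}
        for r in self.regions:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
        logger.info("panel loaded: %d regions, %d genes, %d bp total span",
                    self.n_regions, len(self.genes), self.total_bp)

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def total_bp(self) -> int:
        return sum(len(r) for r in self.regions)

    def region(self, label: str) -> TargetRegion:
        return self._by_label[label]

    def regions_for_gene(self, gene: str) -> list[TargetRegion]:
        """Targets of one gene in panel (exon) order."""
        return [r for r in self.regions if r.gene == gene]

    def regions_at(self, chrom: str, pos: int) -> list[TargetRegion]:
        """Targets overlapping a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in sorted(tree.at(pos - 1))]

    def __eq__(self, other) -> bool:
        return (isinstance(other, Panel)
                and self.regions == other.regions
                and self.genes == other.genes
                and self.flank_bp == other.flank_bp)


# --------------------------------------------------------------------------
# predictor profiles and annotated variants
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MissenseCall:
    """One missense predictor's categorical call plus optional raw score."""

    call: str
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise AnnotationError(f"predictor score must be non-negative, got {self.score}")


@dataclass(frozen=True)
class SpliceScores:
    """Wild-type/mutant site scores for one splice predictor.

    ``site_lost`` marks depletion of the natural site; ``cryptic_site``
    marks creation of a new cryptic donor/acceptor, which counts as a
    site-level change for voting purposes.
    """

    wt: Optional[float] = None
    mut: Optional[float] = None
    site_lost: bool = False
    cryptic_site: bool = False


ALIGN_GVGD_CLASSES = ("C0", "C15", "C25", "C35", "C45", "C55", "C65")
POLYPHEN_DAMAGING = frozenset({"Pos.D", "Pr.D"})

MISSENSE_PREDICTORS = ("sift", "polyphen", "align_gvgd", "mutation_taster")
SPLICE_PREDICTORS = ("hsf", "bdgp", "ast", "netgene2")


@dataclass(frozen=True)
class PredictorProfile:
    """In-silico predictions attached to a variant; every entry optional.

    Missense tools: SIFT (D/T), PolyPhen-2 (B / Pos.D / Pr.D),
    Align GVGD (C0..C65), MutationTaster (D/P).  Splice tools: HSF, BDGP,
    AST and NetGene2 each as wild-type/mutant scores, plus ESEfinder as a
    splicing-enhancer motif-loss flag.
    """

    sift: Optional[MissenseCall] = None
    polyphen: Optional[MissenseCall] = None
    align_gvgd: Optional[str] = None
    mutation_taster: Optional[str] = None
    hsf: Optional[SpliceScores] = None
    bdgp: Optional[SpliceScores] = None
    ast: Optional[SpliceScores] = None
    netgene2: Optional[SpliceScores] = None
    esefinder_motif_lost: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.align_gvgd is not None and self.align_gvgd not in ALIGN_GVGD_CLASSES:
            raise AnnotationError(f"unknown Align GVGD class {self.align_gvgd!r}")

    def n_missense_entries(self) -> int:
        return sum(getattr(self, p) is not None for p in MISSENSE_PREDICTORS)

    def n_splice_entries(self) -> int:
        n = sum(getattr(self, p) is not None for p in SPLICE_PREDICTORS)
        return n + (self.esefinder_motif_lost is not None)


VariantKey = tuple[str, int, str, str]

MAF_DATABASES = ("1000G", "EVS", "ExAC")


@dataclass
class AnnotatedVariant:
    """One called variant in one sample, with its sidecar annotations.

    ``maf`` holds only the databases that actually report a frequency;
    an absent entry means "no value recorded", which the frequency filter
    treats as a pass.
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    gene: str
    consequence: str
    sample: str
    zygosity: Zygosity = "het"
    rs_id: Optional[str] = None
    maf: dict = field(default_factory=dict)
    in_hgmd: Optional[bool] = None
    in_lovd: Optional[bool] = None
    spv_present: Optional[bool] = None
    spv_freq: Optional[float] = None
    predictors: PredictorProfile = field(default_factory=PredictorProfile)
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise AnnotationError(
                f"{self.key}: unknown consequence {self.consequence!r}")
        if self.pos < 1:
            raise AnnotationError(f"{self.key}: VCF positions are 1-based, got {self.pos}")
        for db, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise AnnotationError(f"{self.key}: MAF {db}={f} outside [0, 1]")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_novel(self) -> bool:
        """Novel rare variant in the cascade's sense: no rs identifier."""
        return self.rs_id is None

    @property
    def is_lof(self) -> bool:
        return self.consequence in LOF_CONSEQUENCES

    @property
    def codon(self) -> Optional[int]:
        """Affected codon parsed from an HGVS-style protein change, if any."""
        import re

        if not self.protein_change:
            return None
        m = re.search(r"p\.[A-Za-z*]+?(\d+)", self.protein_change)
        return int(m.group(1)) if m else None


# --------------------------------------------------------------------------
# coverage matrix
# --------------------------------------------------------------------------

class CoverageMatrix:
    """Targets x samples mean read depths for one sequencing run."""

    def __init__(self, depth: pd.DataFrame):
        if depth.index.has_duplicates:
            dupes = depth.index[depth.index.duplicated()].tolist()
            raise CoverageError(f"duplicate target labels: {dupes}")
        if depth.columns.has_duplicates:
            raise CoverageError("duplicate sample ids in coverage matrix")
        if depth.isna().any().any():
            t, s = next(
                (t, s) for t in depth.index for s in depth.columns
                if pd.isna(depth.at[t, s]))
            raise CoverageError(f"missing depth at target {t!r}, sample {s!r}")
        arr = depth.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CoverageError("coverage matrix must be numeric")
        if (arr < 0).any():
            raise CoverageError("negative depth in coverage matrix")
        if not np.allclose(arr, np.round(arr)):
            raise CoverageError("non-integer depth in coverage matrix")
        self.depth = depth.astype(np.int64)

    @property
    def targets(self) -> list[str]:
        return list(self.depth.index)

    @property
    def samples(self) -> list[str]:
        return list(self.depth.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.depth.shape

    def __eq__(self, other) -> bool:
        return isinstance(other, CoverageMatrix) and self.depth.equals(other.depth)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class Config:
    """All tunable thresholds of the pipeline, in one place.

    Defaults reproduce the published protocol: MAF <= 0.005, two-predictor
    consensus, deletion/duplication ratio cut-offs 0.7/1.2 with a >=100x
    run-mate mask, and the >=10-read coverage-QC threshold.
    """

    maf_threshold: float = 0.005
    min_damaging_votes: int = 2
    splice_drop_fraction: float = 0.10
    del_threshold: float = 0.7
    dup_threshold: float = 1.2
    min_ref_coverage: int = 100
    min_run_mates: int = 3
    qc_depth_threshold: int = 10
    #: "any_presence": any hit in the population-control exomes excludes;
    #: "frequency": exclude only above ``spv_freq_threshold``
    spv_policy: str = "any_presence"
    spv_freq_threshold: float = 0.01
    #: minimum Align GVGD class that counts as a damaging vote
    agvgd_min_class: str = "C35"
    flank_bp: int = 20
    #: (gene, chrom, pos) whitelisted deep-intronic positions
    deep_intronic_whitelist: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.del_threshold < 1 < self.dup_threshold):
            raise ValueError("need del_threshold < 1 < dup_threshold, both positive")
        for name in ("maf_threshold", "splice_drop_fraction", "min_ref_coverage",
                     "qc_depth_threshold", "min_damaging_votes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spv_policy not in ("any_presence", "frequency"):
            raise ValueError(f"unknown SPV exclusion policy {self.spv_policy!r}")
        if self.agvgd_min_class not in ALIGN_GVGD_CLASSES:
            raise ValueError(f"unknown Align GVGD class {self.agvgd_min_class!r}")
        self.deep_intronic_whitelist = [tuple(x) for x in self.deep_intronic_whitelist]

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {**self.__dict__,
                "deep_intronic_whitelist": [list(x) for x in self.deep_intronic_whitelist]}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# --------------------------------------------------------------------------
# panel I/O
# --------------------------------------------------------------------------

def read_panel(bed_path, gene_table_path, config: Optional[Config] = None) -> Panel:
    """Load a Panel from a 6-column BED plus a gene table.

    BED name fields are target labels of the form ``GENE_ex<N>`` (or
    ``GENE_di<N>`` for whitelisted deep-intronic targets).  Coordinates are
    0-based half-open; flanks are assumed already baked into the intervals.
    """
    config = config or Config()
    genes = _read_gene_table(gene_table_path)
    regions: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise PanelError(f"{bed_path}, line {lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, label = fields[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(
                    f"{bed_path}, line {lineno}: non-integer coordinates") from exc
            gene, _, suffix = label.rpartition("_")
            if not gene:
                raise PanelError(
                    f"{bed_path}, line {lineno}: label {label!r} not of form GENE_exN")
            region_class = ("deep_intronic_whitelist" if suffix.startswith("di")
                            else "coding_exon_flanked")
            if gene not in genes:
                raise PanelError(
                    f"{bed_path}, line {lineno}: gene {gene!r} absent from gene table")
            try:
                regions.append(TargetRegion(chrom, start, end, gene, label, region_class))
            except PanelError as exc:
                raise PanelError(f"{bed_path}, line {lineno}: {exc}") from exc
    return Panel(regions, genes, flank_bp=config.flank_bp)


def _read_gene_table(path) -> dict[str, GeneInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "inheritance"}
    if not required.issubset(df.columns):
        raise PanelError(f"gene table {path} must have columns {sorted(required)}")
    genes: dict[str, GeneInfo] = {}
    for _, row in df.iterrows():
        inh = frozenset(m.strip() for m in row["inheritance"].split(",") if m.strip())
        if not inh.issubset({"AR", "AD", "XL"}):
            raise PanelError(f"gene {row['gene']}: unknown inheritance tags {sorted(inh)}")
        hotspot = None
        if "ad_hotspot_start" in df.columns and pd.notna(row.get("ad_hotspot_start")):
            hotspot = (int(row["ad_hotspot_start"]), int(row["ad_hotspot_end"]))
        genes[row["gene"]] = GeneInfo(row["gene"], inh, hotspot)
    return genes


def write_panel_bed(panel: Panel, path) -> None:
    with open(path, "w") as fh:
        for r in panel.regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\t0\t+\n")


def write_gene_table(genes: Mapping[str, GeneInfo], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tinheritance\tad_hotspot_start\tad_hotspot_end\n")
        for g in genes.values():
            inh = ",".join(sorted(g.inheritance))
            hs = (str(g.ad_hotspot[0]), str(g.ad_hotspot[1])) if g.ad_hotspot else ("", "")
            fh.write(f"{g.symbol}\t{inh}\t{hs[0]}\t{hs[1]}\n")


# --------------------------------------------------------------------------
# variant I/O
# --------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "protein_change",
    "rs_id", "maf_1000g", "maf_evs", "maf_exac", "hgmd", "lovd",
    "spv_present", "spv_freq",
    "sift_call", "sift_score", "polyphen_call", "polyphen_score",
    "align_gvgd", "mutation_taster",
    "hsf_wt", "hsf_mut", "hsf_site_lost", "hsf_cryptic",
    "bdgp_wt", "bdgp_mut", "bdgp_site_lost", "bdgp_cryptic",
    "ast_wt", "ast_mut", "ast_site_lost", "ast_cryptic",
    "netgene2_wt", "netgene2_mut", "netgene2_site_lost", "netgene2_cryptic",
    "esefinder_motif_lost",
]

_MANDATORY_ANN = ("chrom", "pos", "ref", "alt", "gene", "consequence")


def _opt_float(row, col, key) -> Optional[float]:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    try:
        return float(val)
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"{key}: unparsable value {val!r} in column {col}") from exc


def _opt_bool(row, col) -> Optional[bool]:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    return str(val).strip() in ("1", "true", "True", "yes")


def _opt_str(row, col) -> Optional[str]:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
        return None
    return str(val)


def _splice_entry(row, tool, key) -> Optional[SpliceScores]:
    wt = _opt_float(row, f"{tool}_wt", key)
    mut = _opt_float(row, f"{tool}_mut", key)
    lost = _opt_bool(row, f"{tool}_site_lost")
    cryptic = _opt_bool(row, f"{tool}_cryptic")
    if wt is None and mut is None and lost is None and cryptic is None:
        return None
    return SpliceScores(wt=wt, mut=mut, site_lost=bool(lost), cryptic_site=bool(cryptic))


def _profile_from_row(row, key) -> PredictorProfile:
    sift_call = _opt_str(row, "sift_call")
    poly_call = _opt_str(row, "polyphen_call")
    return PredictorProfile(
        sift=MissenseCall(sift_call, _opt_float(row, "sift_score", key)) if sift_call else None,
        polyphen=(MissenseCall(poly_call, _opt_float(row, "polyphen_score", key))
                  if poly_call else None),
        align_gvgd=_opt_str(row, "align_gvgd"),
        mutation_taster=_opt_str(row, "mutation_taster"),
        hsf=_splice_entry(row, "hsf", key),
        bdgp=_splice_entry(row, "bdgp", key),
        ast=_splice_entry(row, "ast", key),
        netgene2=_splice_entry(row, "netgene2", key),
        esefinder_motif_lost=_opt_bool(row, "esefinder_motif_lost"),
    )


def read_annotation_table(path) -> dict[VariantKey, dict]:
    """Load the sidecar annotation TSV keyed by (chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in _MANDATORY_ANN if c not in df.columns]
    if missing:
        raise AnnotationError(f"annotation table {path} lacks columns {missing}")
    table: dict[VariantKey, dict] = {}
    for _, row in df.iterrows():
        key = (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))
        table[key] = row.to_dict()
    return table


def read_variants(vcf_path, annotation_tsv_path) -> tuple[list[AnnotatedVariant], list[str]]:
    """Read one VCF plus its annotation table into AnnotatedVariants.

    Returns ``(variants, warnings)``; a VCF key missing from the annotation
    table is reported in ``warnings`` and skipped, never silently defaulted.
    Emits one variant per ALT allele per carrier sample.
    """
    from cyvcf2 import VCF

    ann = read_annotation_table(annotation_tsv_path)
    variants: list[AnnotatedVariant] = []
    warnings: list[str] = []
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for rec in vcf:
        for ai, alt in enumerate(rec.ALT, start=1):
            key = (rec.CHROM, rec.POS, rec.REF, alt)
            row = ann.get(key)
            if row is None:
                warnings.append(f"no annotation for {rec.CHROM}:{rec.POS} {rec.REF}>{alt}")
                continue
            for si, sample in enumerate(samples):
                alleles = [a for a in rec.genotypes[si][:-1] if a != -1]
                n_alt = sum(a == ai for a in alleles)
                if n_alt == 0:
                    continue
                if len(alleles) == 1:
                    zyg: Zygosity = "hemi"
                elif n_alt == len(alleles):
                    zyg = "hom"
                else:
                    zyg = "het"
                maf = {}
                for db, col in (("1000G", "maf_1000g"), ("EVS", "maf_evs"),
                                ("ExAC", "maf_exac")):
                    val = _opt_float(row, col, key)
                    if val is not None:
                        maf[db] = val
                variants.append(AnnotatedVariant(
                    chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt,
                    gene=str(row["gene"]), consequence=str(row["consequence"]),
                    sample=sample, zygosity=zyg,
                    rs_id=_opt_str(row, "rs_id"),
                    maf=maf,
                    in_hgmd=_opt_bool(row, "hgmd"),
                    in_lovd=_opt_bool(row, "lovd"),
                    spv_present=_opt_bool(row, "spv_present"),
                    spv_freq=_opt_float(row, "spv_freq", key),
                    predictors=_profile_from_row(row, key),
                    protein_change=_opt_str(row, "protein_change"),
                ))
    for w in warnings:
        logger.warning(w)
    return variants, warnings


def write_vcf(path, records: Iterable[tuple], sample: str,
              contigs: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Write a minimal single-sample VCF 4.2.

    ``records`` are ``(chrom, pos, rs_id, ref, alt, genotype)`` tuples with
    genotype one of ``0/1``, ``1/1`` or ``1`` (hemizygous).
    """
    records = sorted(records, key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in contigs or []:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, pos, rs, ref, alt, gt in records:
            fh.write(f"{chrom}\t{pos}\t{rs or '.'}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def _fmt(val) -> str:
    if val is None:
        return ""
    if isinstance(val, bool):
        return "1" if val else "0"
    if isinstance(val, float):
        return repr(val)
    return str(val)


def annotation_row(v: AnnotatedVariant) -> dict:
    """Flatten one AnnotatedVariant into an annotation-table row."""
    p = v.predictors
    row = {
        "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "gene": v.gene, "consequence": v.consequence,
        "protein_change": v.protein_change, "rs_id": v.rs_id,
        "maf_1000g": v.maf.get("1000G"), "maf_evs": v.maf.get("EVS"),
        "maf_exac": v.maf.get("ExAC"),
        "hgmd": v.in_hgmd, "lovd": v.in_lovd,
        "spv_present": v.spv_present, "spv_freq": v.spv_freq,
        "sift_call": p.sift.call if p.sift else None,
        "sift_score": p.sift.score if p.sift else None,
        "polyphen_call": p.polyphen.call if p.polyphen else None,
        "polyphen_score": p.polyphen.score if p.polyphen else None,
        "align_gvgd": p.align_gvgd, "mutation_taster": p.mutation_taster,
        "esefinder_motif_lost": p.esefinder_motif_lost,
    }
    for tool in SPLICE_PREDICTORS:
        entry = getattr(p, tool)
        row[f"{tool}_wt"] = entry.wt if entry else None
        row[f"{tool}_mut"] = entry.mut if entry else None
        row[f"{tool}_site_lost"] = entry.site_lost if entry else None
        row[f"{tool}_cryptic"] = entry.cryptic_site if entry else None
    return row


def write_annotation_table(variants: Iterable[AnnotatedVariant], path) -> None:
    seen: dict[VariantKey, dict] = {}
    for v in variants:
        seen.setdefault(v.key, annotation_row(v))
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for key in sorted(seen):
            row = seen[key]
            fh.write("\t".join(_fmt(row.get(c)) for c in ANNOTATION_COLUMNS) + "\n")


# --------------------------------------------------------------------------
# coverage-matrix I/O
# --------------------------------------------------------------------------

def read_coverage_matrix(tsv_path) -> CoverageMatrix:
    """Read a targets x samples depth matrix (first column = target labels)."""
    df = pd.read_csv(tsv_path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    try:
        return CoverageMatrix(df)
    except CoverageError as exc:
        raise CoverageError(f"{tsv_path}: {exc}") from exc


def write_coverage_matrix(matrix: CoverageMatrix, path) -> None:
    matrix.depth.rename_axis("target").to_csv(path, sep="\t")


# --------------------------------------------------------------------------
# family-table I/O (thin: the case model lives in case_resolution)
# --------------------------------------------------------------------------

FAMILY_COLUMNS = ["family", "index_sample", "index_sex", "declared_inheritance",
                  "prior_gene", "prior_chrom", "prior_pos", "prior_ref", "prior_alt"]


def read_family_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    missing = [c for c in ("family", "index_sample") if c not in df.columns]
    if missing:
        raise AnnotationError(f"family table {path} lacks columns {missing}")
    return df


def write_family_table(rows: Iterable[Mapping], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(FAMILY_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in FAMILY_COLUMNS) + "\n")
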