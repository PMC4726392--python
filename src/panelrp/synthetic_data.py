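"""Seed-reproducible synthetic cohorts with known truth.

Generates everything the pipeline consumes — a structurally faithful
75-gene capture panel (1127 targets: 1123 flanked coding exons plus four
whitelisted deep-intronic positions), per-sample VCFs with sidecar
annotation tables, per-run coverage matrices with spiked copy-number
events, a family table and a machine-readable truth record — so the whole
analysis is exercisable and scoreable without any external data.

The statistical structure emulated:

* families carry 0-2 causal alleles in recessive RD genes according to a
  configurable scenario mix (homozygous, compound het, het SNV + het CNV,
  single allele, hemizygous X-linked male, dominant-hotspot, none);
* causal variants draw predictor profiles from a *damaging* class (SIFT
  near 0, PolyPhen near 1, Align GVGD >= C45, MutationTaster D) with a
  per-predictor confusion probability, so the two-vote consensus rather
  than any single tool is what is exercised; background variants draw from
  the benign class, with common variants above the MAF threshold and rare
  benign ones partly present in the population-control exomes;
* per-target coverage is negative-binomial on read counts (depth = reads x
  read_length / target_length), near-Poisson by default; heterozygous
  deletions and duplications multiply the expected reads by copy/2
  (ratios ~0.5 and ~1.5).

Variant coordinates live on a toy genome declared by the synthetic panel;
no reference sequence is required.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    AnnotatedVariant,
    Config,
    CoverageMatrix,
    GeneInfo,
    MissenseCall,
    Panel,
    PredictorProfile,
    SpliceScores,
    TargetRegion,
    annotation_row,
    write_annotation_table,
    write_coverage_matrix,
    write_family_table,
    write_gene_table,
    write_panel_bed,
    write_vcf,
)

__all__ = [
    "PANEL_GENES",
    "build_panel",
    "SimConfig",
    "ValidationSpec",
    "SyntheticTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_validation_set",
    "generate_depth_tracks",
    "simulate_cnv_run",
    "score_against_truth",
    "check_truth_consistency",
]


# --------------------------------------------------------------------------
# the synthetic panel: 75 RD genes, 1123 exon targets + 4 deep-intronic
# --------------------------------------------------------------------------

N_PANEL_REGIONS = 1127
_N_EXON_TARGETS = 1123

# (symbol, inheritance tags, exon count); exon counts for the named disease
# genes approximate the real transcripts, fillers are balanced below
_NAMED_GENES = [
    ("USH2A", "AR", 72), ("EYS", "AR", 43), ("CEP290", "AR", 54), ("ABCA4", "AR", 50),
    ("CNGB1", "AR", 33), ("CNGA1", "AR", 11), ("PDE6A", "AR", 22), ("PDE6B", "AR", 22),
    ("PRCD", "AR", 3), ("RDH12", "AR", 7), ("CERKL", "AR", 13), ("GUCY2D", "AR", 20),
    ("CRB1", "AR", 12), ("MERTK", "AR", 19), ("RPE65", "AR", 14), ("TULP1", "AR", 15),
    ("RP1", "AR,AD", 4), ("PRPF31", "AD", 14), ("SNRNP200", "AD", 45), ("CA4", "AD", 8),
    ("RP2", "XL", 5), ("RPGR", "XL", 19), ("OFD1", "XL", 23),
]

_FILLER_GENES = [
    "BEST1", "C2orf71", "C8orf37", "CLRN1", "CRX", "DHDDS", "FAM161A", "FSCN2",
    "GRK1", "IDH3B", "IFT140", "IMPDH1", "IMPG2", "KIZ", "KLHL7", "LRAT",
    "MAK", "NEK2", "NR2E3", "NRL", "PDE6G", "PRPF3", "PRPF6", "PRPF8",
    "PROM1", "RBP3", "RGR", "RLBP1", "ROM1", "RP9", "RPGRIP1", "SAG",
    "SEMA4A", "SLC7A14", "SPATA7", "TOPORS", "TTC8", "ARL6", "ARL2BP", "BBS1",
    "BBS2", "CYP4V2", "EMC1", "FLVCR1", "HGSNAT", "KIAA1549", "MVK", "NEUROD1",
    "OAT", "POMGNT1", "ZNF513", "USH1C",
]

#: dominant hotspot for RP1 (codon interval; config, not biology ground truth)
RP1_AD_HOTSPOT = (500, 1053)

#: genes carrying a whitelisted deep-intronic mutation
DEEP_INTRONIC_GENES = ("CEP290", "OFD1", "PRPF31", "USH2A")


def _gene_defs() -> list[tuple[str, str, int]]:
    defs = list(_NAMED_GENES)
    remaining = _N_EXON_TARGETS - sum(n for _, _, n in defs)
    counts = [10 + (i % 4) for i in range(len(_FILLER_GENES))]
    counts[-1] += remaining - sum(counts)
    defs.extend((name, "AR", n) for name, n in zip(_FILLER_GENES, counts))
    assert sum(n for _, _, n in defs) == _N_EXON_TARGETS
    assert len(defs) == 75
    return defs


PANEL_GENES = _gene_defs()

_FLANK = 20
_INTRON = 1300
_GENE_GAP = 5000


def build_panel(flank_bp: int = _FLANK) -> tuple[Panel, list[tuple[str, str, int]]]:
    """Lay the 75 genes out on a toy genome.

    Returns ``(panel, whitelist)`` where ``whitelist`` is the list of
    (gene, chrom, 1-based pos) deep-intronic whitelisted positions.
    X-linked genes live on chrX so hemizygosity is meaningful; the rest are
    spread round-robin over the autosomes.
    """
    genes: dict[str, GeneInfo] = {}
    regions: list[TargetRegion] = []
    whitelist: list[tuple[str, str, int]] = []
    cursors: dict[str, int] = {}
    auto = 0
    for gi, (symbol, inh_s, n_exons) in enumerate(PANEL_GENES):
        inh = frozenset(inh_s.split(","))
        hotspot = RP1_AD_HOTSPOT if symbol == "RP1" else None
        genes[symbol] = GeneInfo(symbol, inh, hotspot)
        if "XL" in inh:
            chrom = "chrX"
        else:
            chrom = f"chr{auto % 22 + 1}"
            auto += 1
        start = cursors.get(chrom, 10_000)
        for e in range(1, n_exons + 1):
            coding = 150 + ((gi * 31 + e * 17) % 250)
            ex_start = start + (e - 1) * _INTRON
            regions.append(TargetRegion(
                chrom, ex_start, ex_start + coding + 2 * flank_bp,
                symbol, f"{symbol}_ex{e}"))
        if symbol in DEEP_INTRONIC_GENES:
            # park the whitelisted deep-intronic target mid-intron after exon 1
            di_start = start + _INTRON - 600
            regions.append(TargetRegion(chrom, di_start, di_start + 50,
                                        symbol, f"{symbol}_di1",
                                        "deep_intronic_whitelist"))
            whitelist.append((symbol, chrom, di_start + 26))
        cursors[chrom] = start + n_exons * _INTRON + _GENE_GAP
    panel = Panel(regions, genes, flank_bp=flank_bp)
    assert panel.n_regions == N_PANEL_REGIONS
    return panel, whitelist


def _contigs(panel: Panel) -> list[tuple[str, int]]:
    ends: dict[str, int] = {}
    for r in panel.regions:
        ends[r.chrom] = max(ends.get(r.chrom, 0), r.end + 10_000)
    return sorted(ends.items())


# --------------------------------------------------------------------------
# configuration and truth containers
# --------------------------------------------------------------------------

#: default scenario mix, patterned on the reference diagnostic cohort
#: (6 hom / 16 compound-het / 3 het+CNV / 1 XL / 1 AD / ~5 single-allele of
#: 47 families, the rest with no causal configuration)
DEFAULT_SCENARIO_MIX = {
    "hom": 0.13,
    "compound_het": 0.34,
    "het_cnv": 0.06,
    "xl_male": 0.02,
    "ad_hotspot": 0.02,
    "single_allele": 0.11,
    "none": 0.32,
}

_EXPECTED_STATUS = {
    "hom": "solved", "compound_het": "solved", "het_cnv": "solved",
    "xl_male": "solved", "ad_hotspot": "solved",
    "single_allele": "partial", "none": "unsolved",
}


@dataclass
class SimConfig:
    """Knobs of the cohort generator; defaults emulate the study conditions."""

    n_families: int = 47
    n_samples_per_run: int = 8
    scenario_mix: dict = field(default_factory=lambda: dict(DEFAULT_SCENARIO_MIX))
    #: background variants per sample
    n_common_background: int = 12
    n_rare_background: int = 6
    common_maf_range: tuple = (0.01, 0.40)
    rare_maf_max: float = 0.005
    #: per-predictor probability of calling against its class
    predictor_confusion: float = 0.10
    #: probability a rare benign variant appears in the control exomes
    spv_presence_prob: float = 0.5
    #: probability a causal allele is a catalogued known mutation (rs + HGMD)
    known_allele_prob: float = 0.5
    #: probability a solved family's known allele was pre-identified by the
    #: genotyping microarray (prior allele)
    prior_allele_prob: float = 0.5
    #: coverage model: mean target depth, per-target lognormal spread (sigma
    #: of log), NB dispersion k on read counts, read length
    mean_depth: float = 300.0
    depth_sigma_log: float = 0.15
    nb_dispersion: float = 10_000.0
    read_length: int = 150
    #: spiked copy numbers (het deletion / het duplication)
    del_copy: int = 1
    dup_copy: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.scenario_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"scenario proportions must sum to 1, got {total}")
        unknown = set(self.scenario_mix) - set(_EXPECTED_STATUS)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")


@dataclass
class SyntheticTruth:
    """What was spiked, and what a perfect pipeline should conclude."""

    families: dict = field(default_factory=dict)
    cnv_events: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"families": self.families, "cnv_events": self.cnv_events},
                      fh, indent=1, sort_keys=True)


@dataclass
class SyntheticCohort:
    config: SimConfig
    panel: Panel
    whitelist: list
    families: list            # panel_io family-table row dicts
    variants_by_sample: dict  # sample -> list[AnnotatedVariant]
    runs: list                # list[CoverageMatrix]
    truth: SyntheticTruth

    @property
    def samples(self) -> list[str]:
        return [f["index_sample"] for f in self.families]

    def write(self, outdir) -> Path:
        """Emit every artefact in the dialects panel_io reads; deterministic."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_panel_bed(self.panel, outdir / "panel.bed")
        write_gene_table(self.panel.genes, outdir / "genes.tsv")
        write_family_table(self.families, outdir / "families.tsv")
        Config(deep_intronic_whitelist=self.whitelist,
               seed=self.config.seed).to_yaml(outdir / "config.yaml")
        for i, run in enumerate(self.runs, start=1):
            write_coverage_matrix(run, outdir / f"run{i:02d}.coverage.tsv")
        contigs = _contigs(self.panel)
        for sample in self.samples:
            variants = self.variants_by_sample.get(sample, [])
            recs = [(v.chrom, v.pos, v.rs_id, v.ref, v.alt, _gt(v.zygosity))
                    for v in variants]
            write_vcf(outdir / f"{sample}.vcf", recs, sample, contigs)
            write_annotation_table(variants, outdir / f"{sample}.annotations.tsv")
        self.truth.to_json(outdir / "truth.json")
        return outdir


def _gt(zygosity: str) -> str:
    return {"het": "0/1", "hom": "1/1", "hemi": "1"}[zygosity]


# --------------------------------------------------------------------------
# variant fabrication
# --------------------------------------------------------------------------

_BASES = "ACGT"

_CAUSAL_KINDS = ("missense", "nonsense", "frameshift", "canonical_splice")
_CAUSAL_KIND_P = (0.4, 0.2, 0.3, 0.1)


class _VariantFactory:
    """Fabricates annotated variants on the toy genome, unique per sample."""

    def __init__(self, panel: Panel, rng: np.random.Generator, confusion: float):
        self.panel = panel
        self.rng = rng
        self.confusion = confusion
        self._rs_counter = 10_000
        self._used: dict[str, set] = {}

    def _next_rs(self) -> str:
        self._rs_counter += self.rng.integers(1, 50)
        return f"rs{self._rs_counter}"

    def _position(self, sample: str, gene: str, kind: str) -> tuple[str, int, int]:
        """Pick (chrom, pos, exon) inside a random exon of ``gene``."""
        regions = [r for r in self.panel.regions_for_gene(gene)
                   if r.region_class == "coding_exon_flanked"]
        used = self._used.setdefault(sample, set())
        for _ in range(200):
            e = int(self.rng.integers(0, len(regions)))
            r = regions[e]
            if kind == "canonical_splice":
                # first intronic base after the coding end (still on-target)
                pos = r.end - self.panel.flank_bp + 1
            else:
                coding_len = len(r) - 2 * self.panel.flank_bp
                pos = r.start + self.panel.flank_bp + 1 + int(
                    self.rng.integers(0, coding_len))
            if (r.chrom, pos) not in used:
                used.add((r.chrom, pos))
                return r.chrom, pos, e + 1
        raise RuntimeError(f"could not place variant in {gene} for {sample}")

    def _alleles(self, kind: str) -> tuple[str, str]:
        ref = _BASES[int(self.rng.integers(0, 4))]
        if kind == "frameshift":
            if self.rng.random() < 0.5:
                return ref + _BASES[int(self.rng.integers(0, 4))], ref  # deletion
            return ref, ref + _BASES[int(self.rng.integers(0, 4))]      # insertion
        alt = _BASES[int(self.rng.integers(0, 4))]
        while alt == ref:
            alt = _BASES[int(self.rng.integers(0, 4))]
        return ref, alt

    def _vote(self, damaging: bool) -> bool:
        p = 1 - self.confusion if damaging else self.confusion
        return bool(self.rng.random() < p)

    def missense_profile(self, damaging: bool) -> PredictorProfile:
        rng = self.rng
        sift = (MissenseCall("D", round(float(rng.uniform(0, 0.04)), 3))
                if self._vote(damaging)
                else MissenseCall("T", round(float(rng.uniform(0.06, 0.9)), 3)))
        poly = (MissenseCall("Pr.D", round(float(rng.uniform(0.95, 1.0)), 3))
                if self._vote(damaging)
                else MissenseCall("B", round(float(rng.uniform(0.0, 0.4)), 3)))
        gvgd = (f"C{int(rng.choice([45, 55, 65]))}" if self._vote(damaging)
                else f"C{int(rng.choice([0, 15, 25]))}")
        mt = "D" if self._vote(damaging) else "P"
        return PredictorProfile(sift=sift, polyphen=poly, align_gvgd=gvgd,
                                mutation_taster=mt)

    def splice_profile(self, damaging: bool) -> PredictorProfile:
        rng = self.rng
        def entry() -> SpliceScores:
            wt = round(float(rng.uniform(60, 99)), 2)
            if self._vote(damaging):
                if rng.random() < 0.5:
                    return SpliceScores(wt=wt, site_lost=True)
                return SpliceScores(wt=wt, mut=round(wt * float(rng.uniform(0.5, 0.85)), 2))
            return SpliceScores(wt=wt, mut=round(wt * float(rng.uniform(0.95, 1.0)), 2))
        return PredictorProfile(hsf=entry(), bdgp=entry(), ast=entry(),
                                netgene2=entry(),
                                esefinder_motif_lost=self._vote(damaging))

    def _protein(self, kind: str, codon: int) -> Optional[str]:
        if kind == "missense":
            return f"p.Ala{codon}Val"
        if kind == "nonsense":
            return f"p.Arg{codon}*"
        if kind == "frameshift":
            return f"p.Leu{codon}Serfs*9"
        return None

    def causal(self, sample: str, gene: str, zygosity: str, known: bool,
               kind: Optional[str] = None, codon: Optional[int] = None,
               ) -> AnnotatedVariant:
        kind = kind or str(self.rng.choice(_CAUSAL_KINDS, p=_CAUSAL_KIND_P))
        chrom, pos, _ = self._position(sample, gene, kind)
        ref, alt = self._alleles(kind)
        codon = codon if codon is not None else int(self.rng.integers(20, 1200))
        maf = {}
        if self.rng.random() < 0.3:
            maf["ExAC"] = round(float(self.rng.uniform(1e-5, 1e-4)), 6)
        if kind == "missense":
            predictors = self.missense_profile(damaging=True)
        elif kind == "canonical_splice":
            predictors = self.splice_profile(damaging=True)
        else:
            predictors = PredictorProfile()
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=kind,
            sample=sample, zygosity=zygosity,
            rs_id=self._next_rs() if known else None,
            maf=maf, in_hgmd=known or None, in_lovd=None,
            spv_present=False, predictors=predictors,
            protein_change=self._protein(kind, codon))

    def common_background(self, sample: str, gene: str,
                          maf_range: tuple) -> AnnotatedVariant:
        kind = str(self.rng.choice(["synonymous", "missense"], p=[0.5, 0.5]))
        chrom, pos, _ = self._position(sample, gene, kind)
        ref, alt = self._alleles(kind)
        freq = round(float(self.rng.uniform(*maf_range)), 4)
        maf = {"1000G": freq, "ExAC": round(freq * float(self.rng.uniform(0.8, 1.2)), 4)}
        predictors = (self.missense_profile(damaging=False)
                      if kind == "missense" else PredictorProfile())
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=kind,
            sample=sample, zygosity="het" if self.rng.random() < 0.7 else "hom",
            rs_id=self._next_rs(), maf=maf, spv_present=bool(self.rng.random() < 0.8),
            predictors=predictors)

    def rare_background(self, sample: str, gene: str, maf_max: float,
                        spv_prob: float) -> AnnotatedVariant:
        kind = str(self.rng.choice(["missense", "synonymous"], p=[0.7, 0.3]))
        chrom, pos, _ = self._position(sample, gene, kind)
        ref, alt = self._alleles(kind)
        maf = {}
        if self.rng.random() < 0.5:
            maf["ExAC"] = round(float(self.rng.uniform(1e-5, maf_max)), 6)
        spv = bool(self.rng.random() < spv_prob)
        predictors = (self.missense_profile(damaging=False)
                      if kind == "missense" else PredictorProfile())
        return AnnotatedVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene, consequence=kind,
            sample=sample, zygosity="het", rs_id=None, maf=maf,
            spv_present=spv,
            spv_freq=round(float(self.rng.uniform(0.005, 0.05)), 4) if spv else None,
            predictors=predictors)


# --------------------------------------------------------------------------
# coverage simulation
# --------------------------------------------------------------------------

def _simulate_matrix(
    rng: np.random.Generator,
    panel: Panel,
    samples: Sequence[str],
    spikes: Sequence[tuple],  # (sample, target_labels, copy)
    mean_depth: float,
    depth_sigma_log: float,
    nb_dispersion: float,
    read_length: int,
) -> CoverageMatrix:
    labels = [r.label for r in panel.regions]
    lengths = np.array([len(r) for r in panel.regions], dtype=float)
    nt, ns = len(labels), len(samples)
    mu_t = mean_depth * (np.exp(rng.normal(0.0, depth_sigma_log, nt))
                         if depth_sigma_log > 0 else np.ones(nt))
    c_s = np.exp(rng.normal(0.0, 0.10, ns))
    reads_mean = (mu_t * lengths / read_length)[:, None] * c_s[None, :]
    idx = {lab: i for i, lab in enumerate(labels)}
    col = {s: j for j, s in enumerate(samples)}
    for sample, targets, copy in spikes:
        for t in targets:
            reads_mean[idx[t], col[sample]] *= copy / 2.0
    k = nb_dispersion
    p = k / (k + reads_mean)
    reads = rng.negative_binomial(k, p)
    depth = np.rint(reads * read_length / lengths[:, None]).astype(np.int64)
    return CoverageMatrix(pd.DataFrame(depth, index=labels, columns=list(samples)))


def simulate_cnv_run(
    events: Sequence[tuple],  # (sample, gene, first_exon, last_exon, copy)
    n_samples: int = 8,
    mean_depth: float = 300.0,
    nb_dispersion: float = 10_000.0,
    read_length: int = 150,
    seed: int = 0,
    panel: Optional[Panel] = None,
) -> tuple[CoverageMatrix, Panel, list[tuple]]:
    """One sequencing run with spiked CNV events at uniform target depth.

    Returns ``(matrix, panel, spikes)`` where each spike is
    ``(sample, target_labels, copy)``.
    """
    if panel is None:
        panel, _ = build_panel()
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    spikes = []
    for sample, gene, first, last, copy in events:
        targets = tuple(f"{gene}_ex{e}" for e in range(first, last + 1))
        for t in targets:
            panel.region(t)  # validate
        spikes.append((sample, targets, copy))
    matrix = _simulate_matrix(rng, panel, samples, spikes, mean_depth,
                              0.0, nb_dispersion, read_length)
    return matrix, panel, spikes


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _scenario_counts(mix: Mapping[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n families over the mix."""
    quotas = {s: n * p for s, p in mix.items()}
    counts = {s: int(q) for s, q in quotas.items()}
    short = n - sum(counts.values())
    order = sorted(quotas, key=lambda s: quotas[s] - counts[s], reverse=True)
    for s in order[:short]:
        counts[s] += 1
    return counts


def generate_cohort(config: Optional[SimConfig] = None) -> SyntheticCohort:
    """Generate a full synthetic cohort; identical seeds give identical bytes."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    panel, whitelist = build_panel()
    factory = _VariantFactory(panel, rng, config.predictor_confusion)

    ar_genes = sorted(g for g, info in panel.genes.items()
                      if info.is_ar and not info.is_xl)
    xl_genes = sorted(g for g, info in panel.genes.items() if info.is_xl)
    background_genes = sorted(g for g, info in panel.genes.items()
                              if not info.is_xl)
    cnv_capable = [g for g in ("USH2A", "EYS", "CEP290") if g in panel.genes]

    counts = _scenario_counts(config.scenario_mix, config.n_families)
    if sum(counts[s] for s in counts if s != "none") > len(ar_genes) + len(xl_genes):
        raise ValueError("more causal families than panel genes can host")
    scenarios = [s for s, c in sorted(counts.items()) for _ in range(c)]
    rng.shuffle(scenarios)

    families: list[dict] = []
    variants_by_sample: dict[str, list[AnnotatedVariant]] = {}
    truth = SyntheticTruth()
    spikes_by_run: dict[int, list[tuple]] = {}

    for i, scenario in enumerate(scenarios):
        family = f"FAM{i + 1:03d}"
        sample = f"S{i + 1:03d}"
        run_idx = i // config.n_samples_per_run
        sex = "M" if scenario == "xl_male" else ("M" if rng.random() < 0.5 else "F")
        variants: list[AnnotatedVariant] = []
        causal_keys: list[list] = []
        cnv_spans: list[dict] = []
        flags: list[str] = []
        gene = None
        prior = None

        if scenario in ("hom", "compound_het", "het_cnv", "single_allele"):
            gene = (str(rng.choice(cnv_capable)) if scenario == "het_cnv"
                    else str(rng.choice(ar_genes)))
        elif scenario == "xl_male":
            gene = str(rng.choice(xl_genes))
        elif scenario == "ad_hotspot":
            gene = "RP1"

        if scenario == "hom":
            known = bool(rng.random() < config.known_allele_prob)
            v = factory.causal(sample, gene, "hom", known)
            variants.append(v)
            causal_keys.append(list(v.key))
        elif scenario == "compound_het":
            for _ in range(2):
                known = bool(rng.random() < config.known_allele_prob)
                v = factory.causal(sample, gene, "het", known)
                variants.append(v)
                causal_keys.append(list(v.key))
        elif scenario == "het_cnv":
            known = bool(rng.random() < config.known_allele_prob)
            v = factory.causal(sample, gene, "het", known)
            variants.append(v)
            causal_keys.append(list(v.key))
            n_ex = sum(r.region_class == "coding_exon_flanked"
                       for r in panel.regions_for_gene(gene))
            first = int(rng.integers(1, n_ex - 2))
            last = first + int(rng.integers(0, 3))
            targets = tuple(f"{gene}_ex{e}" for e in range(first, last + 1))
            spikes_by_run.setdefault(run_idx, []).append(
                (sample, targets, config.del_copy))
            cnv_spans.append({"gene": gene, "first_exon": first, "last_exon": last,
                              "copy": config.del_copy, "type": "deletion"})
        elif scenario == "single_allele":
            v = factory.causal(sample, gene, "het",
                               bool(rng.random() < config.known_allele_prob))
            variants.append(v)
            causal_keys.append(list(v.key))
        elif scenario == "xl_male":
            v = factory.causal(sample, gene, "hemi",
                               bool(rng.random() < config.known_allele_prob),
                               kind=str(rng.choice(["missense", "nonsense"])))
            variants.append(v)
            causal_keys.append(list(v.key))
            flags.append("x_linked")
        elif scenario == "ad_hotspot":
            codon = int(rng.integers(RP1_AD_HOTSPOT[0], RP1_AD_HOTSPOT[1] + 1))
            v = factory.causal(sample, gene, "het", False, kind="frameshift",
                               codon=codon)
            variants.append(v)
            causal_keys.append(list(v.key))
            flags.append("autosomal_dominant")

        if scenario in ("hom", "compound_het", "het_cnv") and gene == "USH2A":
            flags.append("usher_followup")
        if scenario in ("hom", "compound_het", "het_cnv") and gene == "ABCA4":
            flags.append("cone_rod_dystrophy")

        # a previously microarray-identified allele, where one is catalogued
        known_causal = [v for v in variants if v.rs_id is not None]
        if (known_causal and scenario in ("hom", "compound_het", "het_cnv")
                and rng.random() < config.prior_allele_prob):
            prior = known_causal[0].key

        for _ in range(config.n_common_background):
            g = str(rng.choice(background_genes))
            variants.append(factory.common_background(sample, g,
                                                      config.common_maf_range))
        for _ in range(config.n_rare_background):
            g = str(rng.choice(background_genes))
            variants.append(factory.rare_background(sample, g, config.rare_maf_max,
                                                    config.spv_presence_prob))

        variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
        variants_by_sample[sample] = variants
        row = {"family": family, "index_sample": sample, "index_sex": sex,
               "declared_inheritance": "arRP" if rng.random() < 0.6 else "sporadic"}
        if prior is not None:
            row.update(prior_gene=gene, prior_chrom=prior[0], prior_pos=prior[1],
                       prior_ref=prior[2], prior_alt=prior[3])
        families.append(row)
        truth.families[family] = {
            "sample": sample,
            "scenario": scenario,
            "causal_gene": gene,
            "expected_status": _EXPECTED_STATUS[scenario],
            "causal_variants": causal_keys,
            "cnv": cnv_spans,
            "expected_flags": sorted(flags),
            "prior_allele": list(prior) if prior else None,
        }

    runs: list[CoverageMatrix] = []
    all_samples = [f["index_sample"] for f in families]
    for run_idx in range((len(all_samples) + config.n_samples_per_run - 1)
                         // config.n_samples_per_run):
        chunk = all_samples[run_idx * config.n_samples_per_run:
                            (run_idx + 1) * config.n_samples_per_run]
        spikes = spikes_by_run.get(run_idx, [])
        runs.append(_simulate_matrix(rng, panel, chunk, spikes,
                                     config.mean_depth, config.depth_sigma_log,
                                     config.nb_dispersion, config.read_length))
        for sample, targets, copy in spikes:
            truth.cnv_events.append({"run": run_idx + 1, "sample": sample,
                                     "targets": list(targets), "copy": copy})

    return SyntheticCohort(config=config, panel=panel, whitelist=whitelist,
                           families=families, variants_by_sample=variants_by_sample,
                           runs=runs, truth=truth)


# --------------------------------------------------------------------------
# validation set (redetection controls)
# --------------------------------------------------------------------------

@dataclass
class ValidationSpec:
    """24 control samples with pre-known heterozygous variants."""

    n_mutation: int = 17
    n_polymorphism: int = 7
    classes: Optional[list] = None

    def __post_init__(self) -> None:
        if self.classes is None:
            self.classes = (["mutation"] * self.n_mutation
                            + ["polymorphism"] * self.n_polymorphism)
        got = (self.classes.count("mutation"), self.classes.count("polymorphism"))
        if got != (self.n_mutation, self.n_polymorphism) or len(self.classes) != sum(got):
            raise ValueError(
                f"validation spec mismatch: declared "
                f"{(self.n_mutation, self.n_polymorphism)}, listed {got}")


def generate_validation_set(
    spec: Optional[ValidationSpec] = None, seed: int = 0,
) -> SyntheticCohort:
    """Samples each carrying one pre-known het variant to be redetected.

    Mutation-class variants are catalogued pathogenic alleles (rs + HGMD);
    polymorphism-class variants are common catalogued SNPs.  Every spiked
    variant is embedded in the emitted VCF and annotation table, so a
    faithful pipeline redetects all of them.
    """
    spec = spec or ValidationSpec()
    cfg = SimConfig(n_families=len(spec.classes), seed=seed,
                    scenario_mix={"none": 1.0})
    rng = np.random.default_rng(seed)
    panel, whitelist = build_panel()
    factory = _VariantFactory(panel, rng, cfg.predictor_confusion)
    ar_genes = sorted(g for g, info in panel.genes.items()
                      if info.is_ar and not info.is_xl)

    families: list[dict] = []
    variants_by_sample: dict[str, list[AnnotatedVariant]] = {}
    truth = SyntheticTruth()
    for i, cls in enumerate(spec.classes):
        family = f"VAL{i + 1:03d}"
        sample = f"V{i + 1:03d}"
        gene = str(rng.choice(ar_genes))
        if cls == "mutation":
            v = factory.causal(sample, gene, "het", known=True)
        elif cls == "polymorphism":
            v = factory.common_background(sample, gene, (0.02, 0.30))
        else:
            raise ValueError(f"unknown validation class {cls!r}")
        variants = [v]
        for _ in range(4):
            g = str(rng.choice(ar_genes))
            variants.append(factory.common_background(sample, g, (0.01, 0.40)))
        variants.sort(key=lambda v: (v.chrom, v.pos, v.alt))
        variants_by_sample[sample] = variants
        families.append({"family": family, "index_sample": sample,
                         "index_sex": "M" if rng.random() < 0.5 else "F",
                         "declared_inheritance": "arRP"})
        truth.families[family] = {
            "sample": sample, "scenario": f"validation_{cls}",
            "causal_gene": gene, "expected_status": "n/a",
            "causal_variants": [list(v.key)], "cnv": [],
            "expected_flags": [], "prior_allele": list(v.key),
            "class": cls,
        }
    return SyntheticCohort(config=cfg, panel=panel, whitelist=whitelist,
                           families=families, variants_by_sample=variants_by_sample,
                           runs=[], truth=truth)


# --------------------------------------------------------------------------
# per-base depth tracks for coverage QC
# --------------------------------------------------------------------------

def generate_depth_tracks(
    n_genes: int = 75,
    n_samples: int = 8,
    bases_per_gene: int = 120,
    frac_fully_covered: float = 0.735,
    mean_depth: float = 300.0,
    qc_threshold: int = 10,
    seed: int = 0,
):
    """Per-base depth table with a known fraction of fully covered genes.

    Fully covered genes draw every base at ``qc_threshold`` plus NB noise
    (never below threshold); the remainder get a short sample-independent
    dropout segment (mimicking GC-rich/repetitive capture failure) whose
    bases stay below threshold in every sample.  Returns
    ``(DepthTable, truth_pct)`` where ``truth_pct`` is the exact generated
    percentage of fully covered genes.
    """
    from .coverage_qc import DepthTable

    rng = np.random.default_rng(seed)
    gene_names = [g for g, _, _ in PANEL_GENES][:n_genes]
    if len(gene_names) < n_genes:
        gene_names += [f"GENE{i:03d}" for i in range(n_genes - len(gene_names))]
    n_full = int(round(frac_fully_covered * n_genes))
    full_genes = set(rng.choice(gene_names, size=n_full, replace=False))
    samples = [f"D{i + 1:02d}" for i in range(n_samples)]
    k = 150.0  # mild per-base overdispersion
    rows = []
    for gene in gene_names:
        dropout: set[int] = set()
        if gene not in full_genes:
            span = int(rng.integers(1, max(2, bases_per_gene // 10)))
            start = int(rng.integers(0, bases_per_gene - span))
            dropout = set(range(start, start + span))
        for sample in samples:
            mu = np.full(bases_per_gene, mean_depth - qc_threshold)
            depth = qc_threshold + rng.negative_binomial(k, k / (k + mu))
            for b in dropout:
                depth[b] = int(rng.integers(0, qc_threshold))
            rows.append(pd.DataFrame({
                "gene": gene, "pos": np.arange(1, bases_per_gene + 1),
                "sample": sample, "depth": depth.astype(np.int64)}))
    table = DepthTable(pd.concat(rows, ignore_index=True))
    return table, 100.0 * n_full / n_genes


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

#: statuses compatible with each truth scenario.  Background variants draw
#: predictor profiles stochastically, so ~5% of rare benign missense win two
#: damaging votes (the real screen saw the same: novel missense "predicted
#: pathogenic" later dismissed as population-specific).  Such a variant adds
#: a spurious single-allele gene, which can turn a truth-partial family into
#: uncertain_two_genes or a truth-none family into partial — but never into
#: solved, which is what sensitivity/specificity are scored on.
COMPATIBLE_STATUSES = {
    "hom": {"solved"}, "compound_het": {"solved"}, "het_cnv": {"solved"},
    "xl_male": {"solved"}, "ad_hotspot": {"solved"},
    "single_allele": {"partial", "uncertain_two_genes"},
    "none": {"unsolved", "partial", "uncertain_two_genes"},
}


def check_truth_consistency(resolutions: Mapping[str, object],
                            truth: "SyntheticTruth") -> list[str]:
    """Family-level agreement between pipeline output and generator truth.

    Returns a list of human-readable mismatches (empty = fully consistent).
    A solved-scenario family must be solved in the right gene with at least
    the expected reclassification flags; see ``COMPATIBLE_STATUSES`` for
    what background noise may legitimately do to the other scenarios.
    """
    problems: list[str] = []
    for family, t in truth.families.items():
        res = resolutions[family]
        allowed = COMPATIBLE_STATUSES[t["scenario"]]
        if res.status not in allowed:
            problems.append(f"{family} [{t['scenario']}]: status {res.status}, "
                            f"allowed {sorted(allowed)}")
            continue
        if t["expected_status"] == "solved" and t["causal_gene"] not in res.genes:
            problems.append(f"{family}: solved in {res.genes}, "
                            f"expected {t['causal_gene']}")
        if t["expected_status"] == "partial" and t["causal_gene"] not in res.genes:
            problems.append(f"{family}: partial in {res.genes}, "
                            f"expected {t['causal_gene']}")
        missing_flags = set(t["expected_flags"]) - set(res.flags)
        if t["expected_status"] == "solved" and missing_flags:
            problems.append(f"{family}: missing flags {sorted(missing_flags)}")
    return problems


def score_against_truth(resolutions: Mapping[str, object],
                        truth: SyntheticTruth) -> dict:
    """Compare pipeline resolutions with the generator's truth.

    sensitivity: fraction of truth-solvable families resolved as solved in
    the right gene.  specificity: fraction of truth-none families *not*
    called solved.  Both as percent, with a per-scenario confusion table.
    """
    missing = set(truth.families) - set(resolutions)
    extra = set(resolutions) - set(truth.families)
    if missing or extra:
        raise ValueError(f"family key mismatch: missing={sorted(missing)} "
                         f"extra={sorted(extra)}")
    confusion: dict[str, dict[str, int]] = {}
    n_solvable = n_detected = n_none = n_false = 0
    for family, t in truth.families.items():
        res = resolutions[family]
        confusion.setdefault(t["scenario"], {}).setdefault(res.status, 0)
        confusion[t["scenario"]][res.status] += 1
        if t["expected_status"] == "solved":
            n_solvable += 1
            if res.status == "solved" and t["causal_gene"] in res.genes:
                n_detected += 1
        elif t["scenario"] == "none":
            n_none += 1
            if res.status == "solved":
                n_false += 1
    return {
        "n_families": len(truth.families),
        "n_solvable": n_solvable,
        "n_detected": n_detected,
        "sensitivity_pct": 100.0 * n_detected / n_solvable if n_solvable else 100.0,
        "n_truth_none": n_none,
        "n_false_solved": n_false,
        "specificity_pct": 100.0 * (1 - n_false / n_none) if n_none else 100.0,
        "confusion": confusion,
    }
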