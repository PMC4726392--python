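# Methods

## Scope and data model

`panelrp` models the downstream half of a targeted-capture diagnostic
screen for autosomal recessive retinitis pigmentosa. Alignment and
SNV/indel calling are upstream and out of scope: the pipeline consumes
per-sample VCFs, a sidecar annotation TSV keyed by (chrom, pos, ref, alt),
a BED of capture targets with a gene/inheritance table, per-run
targets × samples coverage matrices, and a family table. Annotations
travel in a flat TSV rather than VCF INFO because the annotators such
pipelines sit behind (VEP, VariantStudio, …) emit incompatible INFO
dialects; a keyed table is dialect-free. A missing annotation is absent
(`None`), never zero — the frequency filter *passes* variants with no
recorded MAF, so absent ≠ 0 is load-bearing.

Coordinates follow the two native conventions: BED intervals are 0-based
half-open, VCF positions 1-based. A variant at the first base of an exon
(BED start s, VCF pos s+1) maps inside that exon's target under both.

## The prioritization cascade

Six criteria run in fixed order; each variant receives exactly one
terminal label plus the evidence trail of criteria that fired. Retained
candidates are `known_pathogenic`, `lof_pathogenic` and
`potentially_pathogenic`.

Decisions the published protocol leaves open, resolved here:

* **Known-mutation rule.** An rs identifier plus a record in *either*
  HGMD or LOVD suffices (the worked examples treat an rs + HGMD hit as
  known pathogenic). A variant with an rs id but no database record
  continues down the cascade; a variant without an rs id is a novel rare
  variant.
* **Damaging-vote mapping** (no per-tool definition is published):
  SIFT call `D`; PolyPhen-2 `Pos.D` or `Pr.D`; MutationTaster `D`;
  Align GVGD class ≥ C35 — C0–C25 are "less likely pathogenic" and do not
  vote. The Align GVGD floor is configurable (`agvgd_min_class`).
* **Splice votes.** A score tool votes when it reports loss of the
  natural site, creation of a new cryptic site (required so
  cryptic-acceptor cases count as damaging), or a relative score drop
  (wt − mut)/wt ≥ `splice_drop_fraction` (default 0.10; the protocol
  prints wt/mut scores but no cutoff). ESEfinder votes on enhancer-motif
  loss.
* **Population-control policy.** Default `any_presence`: any hit in the
  267 healthy-control exomes excludes a novel missense/splice variant.
  A `frequency` policy (exclude above `spv_freq_threshold`) is available
  because practice sometimes invokes "high frequency in controls" rather
  than bare presence.
* **Canonical vs non-canonical splice.** Intronic ±1/±2 is canonical
  (criterion 4); ±3 through the 20 bp flank is non-canonical and takes the
  consensus route.

Two known edge cases are kept honest rather than patched: one published
causative missense allele (USH2A p.Lys1821Arg) earns 0 consensus votes and
one reported potentially pathogenic allele (EYS p.Tyr2822Cys) earns 1;
the cascade reports those vote counts as computed, and causative status in
the shipped reference cohort comes from the cohort table itself, not from
re-running the predictors. Consensus and segregation remain separate
evidence; no override rule is guessed.

## CNV calling

For one run (default 8 samples), each sample's column is divided by its
median target depth (library-size correction; median is robust to the CNVs
themselves), then each target's value is divided by the median of the
run-mates' normalized values. Thresholds are strict: ratio < 0.7 ⇒
deletion, > 1.2 ⇒ duplication; exactly 0.7/1.2 is no call. Targets whose
run-mates' median *raw* depth is < 100× are masked (a sample-independent
eligibility mask, motivated by false-positive avoidance); a zero reference
median leaves the ratio undefined and the target ineligible. Adjacent
same-gene, same-direction calls merge with no gap tolerance. Fewer than 3
run-mates triggers a warning, not an error. Restricted mode analyzes only
(sample, gene) pairs where the sample carries exactly one pathogenic
heterozygous SNV — the second-allele hunt of the diagnostic workflow; an
unrestricted flag covers everything.

Heterozygous expectations driving the simulations (not the calling):
copy 1 ⇒ ratio ≈ 0.5, copy 3 ⇒ ≈ 1.5.

## Coverage QC

Per-base depth tables (gene, pos, sample, depth) rather than BAMs keep the
module testable without alignments. `pct_covered` is inclusive
(depth ≥ threshold, default 10). Quartiles use linear interpolation
between order statistics (numpy default) — a convention had to be fixed
for the 1.5×IQR outlier rule. Pooled mean depth and the per-base depth
range are reported side by side and labelled, since "mean coverage" mixes
per-sample and per-base views.

## Case resolution

A gene solves a family when its pathogenic alleles satisfy its
inheritance model: AR — homozygous, or two heterozygous alleles (SNVs
and/or CNV events, one dose each); XL — hemizygous allele in a male
index; AD — a single truncating allele inside a configured dominant
hotspot (default RP1 codons 500–1053; documented configuration, not
established biology). Without parental genotypes two heterozygous alleles
are accepted in trans with segregation `not_available`. One allele in one
recessive gene ⇒ `partial`; single alleles in ≥ 2 genes and no full
configuration ⇒ `uncertain_two_genes`; a homozygous allele plus a distinct
extra allele in the same gene resolves but carries a review note. If two
genes both reach a full AR configuration the family is solved in both with
a warning. Declared inheritance (arRP/sporadic) is advisory — XL and AD
findings override it, which is exactly the genetic-reclassification path.

Segregation: affected relatives must carry the full configuration;
unaffected relatives must not — except unaffected carriers of a dominant
allele in a penetrance-exempt gene (default: RP1 only, where incomplete
penetrance is documented). Reclassification rules are data
(`ReclassRule`), evaluated in order, several may fire: solved-in-USH2A ⇒
`usher_followup` (hearing follow-up applies to every USH2A family, so the
flag is not limited to the four historically re-diagnosed ones),
solved-in-ABCA4 ⇒ `cone_rod_dystrophy`, XL resolution ⇒ `x_linked`, AD
hotspot ⇒ `autosomal_dominant`.

The shipped reference cohort (`data/reference_cohort.tsv`) transcribes the
27 characterized families of the modeled screen. Labels in that fixture
derive from the table (published reference ⇒ known; truncating/canonical
splice ⇒ LOF; remaining novel missense ⇒ potentially pathogenic) because
the per-allele predictor scores are not part of the transcription. Index
sex is unpublished; the one X-linked family is set male (required by its
hemizygous resolution), all others unknown.

## Synthetic cohorts

The generator emulates the study conditions: 47 families by default, 8
samples per run, scenario mix patterned on the reference cohort
(hom 0.13, compound-het 0.34, het + CNV 0.06, XL-male 0.02, AD-hotspot
0.02, single-allele 0.11, none 0.32). The panel is structurally faithful —
75 genes, 1123 flanked coding-exon targets plus 4 whitelisted
deep-intronic targets = 1127 regions, ≈ 350 kb — on a toy genome; named
disease genes get approximately real exon counts, X-linked genes live on
chrX.

Causal variants draw damaging predictor profiles (SIFT near 0, PolyPhen
near 1, Align GVGD ≥ C45, MutationTaster D) with a 10% per-predictor
confusion probability so the two-vote consensus, not any single tool, is
exercised; half are catalogued known mutations (rs + HGMD). Background
variants per sample: 12 common (MAF 0.01–0.40, catalogued) and 6 rare
(benign profiles, half present in the control exomes). A consequence of
the 10% confusion: ~5% of rare benign missense variants that escape the
control screen still win two votes — the same "predicted pathogenic,
benign in controls" phenomenon diagnostic screens report. Such variants
can add a spurious single-allele gene, so truth scoring accepts
`uncertain_two_genes` for a truth-partial family and `partial`/
`uncertain_two_genes` for a truth-none family; they cannot fabricate a
*solved* family except by two hits in one gene (probability ≈ 10⁻⁴ per
family), so sensitivity and specificity are sharp.

**Coverage noise.** Read counts per target are negative binomial with
mean depth × length / read-length (150 bp reads) and dispersion
k = 10 000; reported depth is reads × read-length / length. This is
near-Poisson counting noise — depth CV ≈ 4% at 300× for a ~340 bp
target — on the grounds that per-target capture-efficiency effects are
target main effects that cancel in cross-sample ratios, and sample-level
library size cancels in normalization. Real capture data carry additional
sample × target interaction noise, so passing simulations bound what the
caller can do under idealized noise, not its false-positive rate on real
libraries (a stated limitation). Even so, the Poisson floor on the
shortest (~190 bp) targets yields P(null ratio > 1.2) ≈ 3 × 10⁻⁴, i.e. an
occasional single-target false duplication across tens of replicate runs —
consistent with the caller's stated tolerance of ≤ 1 false call per run.
Per-target mean depth is lognormal (σ_log = 0.15) in cohort mode and
uniform in the dedicated CNV-recovery simulation (reference depth 300×).

Problem sizes used by the test suite and acceptance script — chosen so a
laptop reruns everything in seconds: cohorts of 16–47 families, 24-sample
validation sets, 50 seeded 8-sample CNV replicate runs.

## Limitations

* Consequence assignment is consumed, not computed; transcript-level
  effects (and the cascade's dependence on their correctness) are out of
  scope.
* The CNV caller targets heterozygous single-gene events; homozygous
  deletions, mosaic events and breakpoint resolution are not modeled.
* Digenic inheritance is deliberately not inferred; two single-allele
  genes stay `uncertain_two_genes`.
* Synthetic predictor scores are class-conditional draws, not emulations
  of the actual tools; agreement structure between predictors is not
  modeled beyond the shared class.
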