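"""End-to-end composition: cohort directory in, family resolutions out.

Thin glue over the real modules, used by the command-line interface and by
round-trip analyses of generated cohorts.  A cohort directory is the
layout ``SyntheticCohort.write`` emits (and any real data marshalled the
same way): ``panel.bed`` + ``genes.tsv``, ``config.yaml``,
``families.tsv``, per-sample ``<sample>.vcf`` + ``<sample>.annotations.tsv``
and per-run ``runNN.coverage.tsv`` matrices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import case_resolution, cnv_caller, coverage_qc, panel_io, prioritization

__all__ = ["analyze_cohort_dir", "redetect_validation_dir", "single_het_genes"]


def single_het_genes(report: prioritization.CascadeReport, sample: str) -> list[str]:
    """Genes in which a sample carries exactly one pathogenic het small variant.

    This is the candidate table driving restricted CNV analysis: the CNV
    caller hunts the second allele only where one het pathogenic SNV
    already sits.
    """
    per_gene: dict[str, list] = {}
    for cv in report.candidates:
        if cv.variant.sample == sample and cv.variant.zygosity == "het":
            per_gene.setdefault(cv.variant.gene, []).append(cv)
    return sorted(g for g, cvs in per_gene.items() if len(cvs) == 1)


def _family_case(row: Mapping) -> case_resolution.FamilyCase:
    prior = None
    if row.get("prior_chrom") and not pd.isna(row.get("prior_chrom")):
        prior = (str(row["prior_chrom"]), int(row["prior_pos"]),
                 str(row["prior_ref"]), str(row["prior_alt"]))
    return case_resolution.FamilyCase(
        family_id=str(row["family"]),
        index_id=str(row["index_sample"]),
        index_sex=str(row.get("index_sex") or "U"),
        prior_allele=prior,
        declared_inheritance=str(row.get("declared_inheritance") or "arRP"),
    )


def analyze_cohort_dir(
    cohort_dir,
    config: Optional[panel_io.Config] = None,
    restrict_cnv: bool = True,
) -> dict:
    """Run cascade + CNV calling + case resolution over a cohort directory.

    Returns ``{"resolutions": {family: Resolution}, "reports": {sample:
    CascadeReport}, "cnv_calls": {sample: [CnvCall]}, "summary": dict}``.
    """
    cohort_dir = Path(cohort_dir)
    if config is None:
        cfg_path = cohort_dir / "config.yaml"
        config = panel_io.Config.from_yaml(cfg_path) if cfg_path.exists() else panel_io.Config()
    panel = panel_io.read_panel(cohort_dir / "panel.bed", cohort_dir / "genes.tsv", config)
    fam_df = panel_io.read_family_table(cohort_dir / "families.tsv")

    reports: dict[str, prioritization.CascadeReport] = {}
    for _, row in fam_df.iterrows():
        sample = str(row["index_sample"])
        variants, _ = panel_io.read_variants(
            cohort_dir / f"{sample}.vcf",
            cohort_dir / f"{sample}.annotations.tsv")
        reports[sample] = prioritization.run_cascade(variants, panel, config)

    # restricted CNV analysis per sequencing run
    cnv_by_sample: dict[str, list[cnv_caller.CnvCall]] = {}
    for run_path in sorted(cohort_dir.glob("run*.coverage.tsv")):
        matrix = panel_io.read_coverage_matrix(run_path)
        if restrict_cnv:
            case_table = {s: single_het_genes(reports[s], s)
                          for s in matrix.samples if s in reports}
            case_table = {s: genes for s, genes in case_table.items() if genes}
        else:
            case_table = None
        calls = cnv_caller.call_cnvs_for_run(
            matrix, panel, case_table,
            del_threshold=config.del_threshold,
            dup_threshold=config.dup_threshold,
            min_ref_coverage=config.min_ref_coverage,
            min_run_mates=config.min_run_mates)
        for sample, sample_calls in calls.items():
            cnv_by_sample.setdefault(sample, []).extend(sample_calls)

    resolutions: dict[str, case_resolution.Resolution] = {}
    for _, row in fam_df.iterrows():
        case = _family_case(row)
        report = reports[case.index_id]
        res = case_resolution.resolve_family(
            case, report.classified, cnv_by_sample.get(case.index_id, ()),
            panel.genes)
        resolutions[case.family_id] = case_resolution.apply_reclassification(res)

    summary = case_resolution.cohort_summary(list(resolutions.values()), len(fam_df))
    return {"resolutions": resolutions, "reports": reports,
            "cnv_calls": cnv_by_sample, "summary": summary}


def redetect_validation_dir(cohort_dir) -> dict:
    """Re-run the cascade over a validation cohort and score redetection.

    A mutation-class control counts as redetected when it reappears in the
    classified output as a candidate pathogenic allele; a polymorphism-class
    control when it reappears at all (its expected terminal label is the
    benign frequency bin).
    """
    import json

    cohort_dir = Path(cohort_dir)
    with open(cohort_dir / "truth.json") as fh:
        truth = json.load(fh)
    out = analyze_cohort_dir(cohort_dir)
    n_total = n_detected = 0
    detail = {}
    for family, t in truth["families"].items():
        sample = t["sample"]
        key = tuple(t["causal_variants"][0])
        key = (key[0], int(key[1]), key[2], key[3])
        labels = out["reports"][sample].labels
        present = key in labels
        if t.get("class") == "mutation":
            detected = present and labels[key].is_candidate
        else:
            detected = present
        n_total += 1
        n_detected += detected
        detail[family] = {"class": t.get("class"), "detected": bool(detected),
                          "label": labels[key].value if present else None}
    return {
        "n_controls": n_total,
        "n_redetected": n_detected,
        "sensitivity_pct": 100.0 * n_detected / n_total if n_total else 100.0,
        "detail": detail,
        "resolutions": out["resolutions"],
    }
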