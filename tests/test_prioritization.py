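"""The six-criterion cascade: worked predictor examples, a hand-applied
oracle fixture, and structural invariants."""

import pytest
from hypothesis import given, settings, strategies as st

from panelrp.panel_io import (
    AnnotatedVariant,
    AnnotationError,
    Config,
    MissenseCall,
    PredictorProfile,
    SpliceScores,
)
from panelrp import prioritization as pz


def mk(pos, consequence, chrom="chr6", gene="EYS", **kw):
    kw.setdefault("sample", "S01")
    return AnnotatedVariant(chrom=chrom, pos=pos, ref="A", alt="T", gene=gene,
                            consequence=consequence, **kw)


# --------------------------------------------------------------------------
# stages 1-5
# --------------------------------------------------------------------------

class TestRegionFilter:
    def test_exonic_retained_far_intronic_removed(self, tiny_panel, tiny_config):
        inside = mk(5030, "missense")                    # EYS_ex13 [5000,5340)
        beyond_flank = mk(4996, "noncanonical_splice")   # 25 bp before the exon
        kept, dropped = pz.filter_by_region([inside, beyond_flank], tiny_panel,
                                            tiny_config)
        assert kept == [inside]
        assert dropped[0].label.value == "out_of_region"

    def test_whitelisted_deep_intronic_retained(self, tiny_panel, tiny_config):
        di = mk(8026, "deep_intronic", chrom="chr12", gene="CEP290")
        off = mk(8027, "deep_intronic", chrom="chr12", gene="CEP290")
        kept, dropped = pz.filter_by_region([di, off], tiny_panel, tiny_config)
        assert kept == [di]          # exact whitelisted position only
        assert len(dropped) == 1

    def test_utr_inside_target_still_excluded(self, tiny_panel, tiny_config):
        utr = mk(5030, "utr")
        kept, dropped = pz.filter_by_region([utr], tiny_panel, tiny_config)
        assert kept == [] and dropped[0].label.value == "out_of_region"


class TestMafFilter:
    @pytest.mark.parametrize("maf,retained", [
        ({"ExAC": 0.00001}, True),              # PDE6A splice-variant frequency
        ({"1000G": 0.0016, "ExAC": 0.0003}, True),  # max 0.0016 <= 0.005
        ({}, True),                              # no recorded value passes
        ({"ExAC": 0.01}, False),
        ({"1000G": 0.005}, True),                # inclusive threshold
    ])
    def test_max_over_databases(self, maf, retained):
        v = mk(5030, "missense", maf=maf)
        kept, dropped = pz.filter_by_maf([v])
        assert (v in kept) is retained
        if not retained:
            assert dropped[0].label.value == "benign_frequency"


class TestKnownAndConsequence:
    def test_rs_plus_hgmd_is_known_pathogenic(self):
        v = mk(2276, "missense", gene="USH2A", rs_id="rs80338902", in_hgmd=True)
        label = pz.classify_known(v)
        assert label.value == "known_pathogenic"
        assert any("HGMD" in e for e in label.evidence)

    def test_no_rs_continues_as_novel(self):
        assert pz.classify_known(mk(100, "missense")) is None

    def test_rs_without_database_continues(self):
        v = mk(100, "missense", rs_id="rs1", in_hgmd=False, in_lovd=False)
        assert pz.classify_known(v) is None

    @pytest.mark.parametrize("consequence", ["nonsense", "frameshift",
                                             "canonical_splice"])
    def test_lof_consequences_pathogenic(self, consequence):
        assert pz.classify_by_consequence(mk(100, consequence)).value == "lof_pathogenic"

    def test_synonymous_continues(self):
        assert pz.classify_by_consequence(mk(100, "synonymous")) is None


class TestPopulationScreen:
    def test_absent_from_controls_forwarded(self):
        v = mk(100, "missense", spv_present=False)
        assert pz.screen_population_controls(v) is None

    def test_present_in_controls_benign(self):
        v = mk(100, "missense", spv_present=True)
        assert pz.screen_population_controls(v).value == "benign_population"

    def test_known_variant_not_screened(self):
        v = mk(100, "missense", rs_id="rs1", spv_present=True)
        assert pz.screen_population_controls(v) is None  # not novel

    def test_frequency_policy(self):
        cfg = Config(spv_policy="frequency", spv_freq_threshold=0.01)
        rare = mk(100, "missense", spv_present=True, spv_freq=0.004)
        common = mk(101, "missense", spv_present=True, spv_freq=0.02)
        assert pz.screen_population_controls(rare, cfg) is None
        assert pz.screen_population_controls(common, cfg).value == "benign_population"


# --------------------------------------------------------------------------
# stage 6: the published predictor rows as consensus worked examples
# --------------------------------------------------------------------------

def missense_profile(sift, poly, gvgd, mt):
    return PredictorProfile(
        sift=MissenseCall(*sift) if sift else None,
        polyphen=MissenseCall(*poly) if poly else None,
        align_gvgd=gvgd, mutation_taster=mt)


MISSENSE_ROWS = [
    # (id, sift, polyphen, gvgd, mt, expected_votes, flagged)
    ("CNGA1_Arg346Gln", ("D", 0.0), ("Pos.D", 0.852), "C35", "D", 4, True),
    ("RP2_Cys236Trp", ("D", 0.0), ("Pr.D", 0.997), "C65", "D", 4, True),
    ("USH2A_Cys3570Phe", ("D", 0.0), ("Pr.D", 0.996), "C65", "D", 4, True),
    ("USH2A_Leu3145Phe", ("D", 0.02), ("Pos.D", 0.598), "C15", "P", 2, True),
    ("USH2A_Lys1821Arg", ("T", 0.1), ("B", 0.096), "C25", "P", 0, False),
    ("USH2A_Gly1871Asp", ("D", 0.0), ("Pr.D", 0.995), "C65", "D", 4, True),
    # SIFT did not score this allele; only PolyPhen votes (C0 + MT "P" do not)
    ("EYS_Tyr2822Cys", None, ("Pr.D", 0.997), "C0", "P", 1, False),
]


class TestMissenseConsensus:
    @pytest.mark.parametrize("vid,sift,poly,gvgd,mt,votes,flagged", MISSENSE_ROWS,
                             ids=[r[0] for r in MISSENSE_ROWS])
    def test_published_rows(self, vid, sift, poly, gvgd, mt, votes, flagged):
        profile = missense_profile(sift, poly, gvgd, mt)
        got_flag, got_votes, voters = pz.consensus_missense(profile)
        assert got_votes == votes
        assert got_flag is flagged
        assert len(voters) == votes

    def test_no_predictions_is_an_error(self):
        with pytest.raises(AnnotationError, match="predictor"):
            pz.consensus_missense(PredictorProfile())

    def test_gvgd_class_mapping_configurable(self):
        profile = missense_profile(("T", 0.3), ("B", 0.1), "C25", "P")
        assert pz.consensus_missense(profile)[1] == 0
        assert pz.consensus_missense(profile, agvgd_min_class="C25")[1] == 1


SPLICE_ROWS = [
    # (id, hsf, bdgp, ast, netgene2, ese, min_votes_expected, flagged)
    ("PDE6A_c1620+1G>T",
     SpliceScores(95.1, site_lost=True), SpliceScores(0.99, site_lost=True),
     SpliceScores(86.85, 69.73), SpliceScores(0.82, site_lost=True), True, 5, True),
    ("PRCD_c74+1G>A",
     SpliceScores(79.8, site_lost=True), SpliceScores(0.45, site_lost=True),
     SpliceScores(67.08, 49.96), SpliceScores(0.7, site_lost=True), True, 5, True),
    # cryptic acceptor creation counts as a site-level change per predictor
    ("CNGB1_c2634+6G>A",
     SpliceScores(cryptic_site=True), SpliceScores(cryptic_site=True),
     None, SpliceScores(cryptic_site=True), True, 4, True),
]


class TestSpliceConsensus:
    @pytest.mark.parametrize("vid,hsf,bdgp,ast,ng2,ese,votes,flagged", SPLICE_ROWS,
                             ids=[r[0] for r in SPLICE_ROWS])
    def test_published_rows(self, vid, hsf, bdgp, ast, ng2, ese, votes, flagged):
        profile = PredictorProfile(hsf=hsf, bdgp=bdgp, ast=ast, netgene2=ng2,
                                   esefinder_motif_lost=ese)
        got_flag, got_votes, _ = pz.consensus_splice(profile)
        assert got_votes == votes and got_flag is flagged

    def test_unchanged_scores_not_flagged(self):
        profile = PredictorProfile(hsf=SpliceScores(90.0, 90.0),
                                   bdgp=SpliceScores(0.9, 0.9),
                                   esefinder_motif_lost=False)
        flagged, votes, _ = pz.consensus_splice(profile)
        assert votes == 0 and not flagged

    def test_drop_fraction_boundary(self):
        profile = PredictorProfile(hsf=SpliceScores(100.0, 90.0),
                                   bdgp=SpliceScores(100.0, 90.1))
        _, votes, voters = pz.consensus_splice(profile, drop_fraction=0.10)
        assert voters == ("HSF",)  # exactly 10% drop votes, 9.9% does not

    def test_nonpositive_wt_score_is_an_error(self):
        profile = PredictorProfile(hsf=SpliceScores(0.0, 0.0))
        with pytest.raises(AnnotationError, match="wild-type"):
            pz.consensus_splice(profile)


# --------------------------------------------------------------------------
# full cascade against a hand-applied oracle
# --------------------------------------------------------------------------

DAMAGING = missense_profile(("D", 0.0), ("Pr.D", 0.99), "C65", "D")


def oracle_fixture():
    """Eight variants spanning every label; expected labels were derived by
    applying the six rules by hand, in order, before implementation."""
    v1 = mk(5030, "missense", maf={"ExAC": 1e-05}, spv_present=False,
            predictors=DAMAGING)
    v2 = mk(999999, "intergenic", chrom="chr1", gene="USH2A")
    v3 = mk(1050, "missense", chrom="chr1", gene="USH2A", maf={"1000G": 0.01})
    v4 = mk(2050, "missense", chrom="chr1", gene="USH2A", rs_id="rs77",
            in_hgmd=True, maf={"ExAC": 1e-04})
    v5 = mk(6030, "nonsense")
    v6 = mk(2030, "missense", chrom="chr8", gene="RP1", spv_present=True)
    v7 = mk(1100, "synonymous", chrom="chr12", gene="CEP290")
    v8 = mk(3330, "noncanonical_splice", chrom="chr1", gene="USH2A",
            spv_present=False,
            predictors=PredictorProfile(hsf=SpliceScores(90.0, 70.0),
                                        bdgp=SpliceScores(0.90, 0.89),
                                        netgene2=SpliceScores(0.8, site_lost=True)))
    expected = {
        v1.key: "potentially_pathogenic",
        v2.key: "out_of_region",
        v3.key: "benign_frequency",
        v4.key: "known_pathogenic",
        v5.key: "lof_pathogenic",
        v6.key: "benign_population",
        v7.key: "uncertain",
        v8.key: "potentially_pathogenic",
    }
    return [v1, v2, v3, v4, v5, v6, v7, v8], expected


class TestRunCascade:
    def test_oracle_fixture_labels_and_stage_counts(self, tiny_panel, tiny_config):
        variants, expected = oracle_fixture()
        report = pz.run_cascade(variants, tiny_panel, tiny_config)
        assert {k: lbl.value for k, lbl in report.labels.items()} == expected
        by_stage = {s.stage: s for s in report.stages}
        assert (by_stage["region"].n_in, by_stage["region"].n_labeled) == (8, 1)
        assert (by_stage["maf"].n_in, by_stage["maf"].n_labeled) == (7, 1)
        assert (by_stage["known_db"].n_in, by_stage["known_db"].n_labeled) == (6, 1)
        assert (by_stage["consequence"].n_labeled) == 1
        assert (by_stage["population_controls"].n_labeled) == 1
        assert (by_stage["consensus"].n_in, by_stage["consensus"].n_labeled) == (3, 3)
        # candidates: v1 + v8 (consensus), v4 (known), v5 (LOF)
        assert len(report.candidates) == 4

    def test_empty_input(self, tiny_panel, tiny_config):
        report = pz.run_cascade([], tiny_panel, tiny_config)
        assert report.classified == []
        assert all(s.n_in == 0 for s in report.stages)

    def test_common_snp_never_reaches_consensus(self, tiny_panel, tiny_config):
        v = mk(5030, "synonymous", maf={"1000G": 0.2})
        report = pz.run_cascade([v], tiny_panel, tiny_config)
        assert report.labels[v.key].value == "benign_frequency"

    def test_region_and_maf_filters_commute(self, tiny_panel, tiny_config):
        variants, _ = oracle_fixture()
        a1, _ = pz.filter_by_region(variants, tiny_panel, tiny_config)
        a2, _ = pz.filter_by_maf(a1)
        b1, _ = pz.filter_by_maf(variants)
        b2, _ = pz.filter_by_region(b1, tiny_panel, tiny_config)
        assert {v.key for v in a2} == {v.key for v in b2}


# --------------------------------------------------------------------------
# property tests
# --------------------------------------------------------------------------

_consequences = st.sampled_from(["missense", "synonymous", "nonsense",
                                 "frameshift", "noncanonical_splice",
                                 "intergenic", "utr"])


@st.composite
def random_variant(draw, i):
    consequence = draw(_consequences)
    pos = draw(st.sampled_from([5030 + i, 6100, 9100, 4000, 12345]))
    maf = {}
    if draw(st.booleans()):
        maf["ExAC"] = draw(st.floats(0, 0.05, allow_nan=False))
    rs = f"rs{i}" if draw(st.booleans()) else None
    profile = missense_profile(
        ("D" if draw(st.booleans()) else "T", 0.1),
        ("Pr.D" if draw(st.booleans()) else "B", 0.5),
        draw(st.sampled_from(["C0", "C35", "C65"])),
        draw(st.sampled_from(["D", "P"])))
    if consequence == "noncanonical_splice":
        profile = PredictorProfile(
            hsf=SpliceScores(90.0, draw(st.floats(50, 90, allow_nan=False))),
            esefinder_motif_lost=draw(st.booleans()))
    return mk(pos, consequence, rs_id=rs, maf=maf,
              in_hgmd=draw(st.booleans()), spv_present=draw(st.booleans()),
              predictors=profile)


@st.composite
def variant_lists(draw):
    n = draw(st.integers(0, 12))
    return [draw(random_variant(i)) for i in range(n)]


class TestCascadeProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(variants=variant_lists())
    def test_exhaustive_and_monotone(self, tiny_panel, tiny_config, variants):
        """Every input variant is classified exactly once and each stage's
        forwarded set shrinks monotonically."""
        report = pz.run_cascade(variants, tiny_panel, tiny_config)
        assert len(report.classified) == len(variants)
        keys = sorted(cv.variant.key + (cv.variant.sample,)
                      for cv in report.classified)
        assert keys == sorted(v.key + (v.sample,) for v in variants)
        for s in report.stages:
            assert s.n_labeled + s.n_forward == s.n_in
            assert s.n_forward <= s.n_in
        assert all(lbl in pz.LABELS for lbl in
                   (cv.label.value for cv in report.classified))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(variants=variant_lists())
    def test_region_maf_commutation(self, tiny_panel, tiny_config, variants):
        a, _ = pz.filter_by_maf(pz.filter_by_region(variants, tiny_panel,
                                                    tiny_config)[0])
        b, _ = pz.filter_by_region(pz.filter_by_maf(variants)[0], tiny_panel,
                                   tiny_config)
        assert {id(v) for v in a} == {id(v) for v in b}
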