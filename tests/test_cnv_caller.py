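"""Coverage-ratio CNV calling: analytic examples, a brute-force oracle, and
scale-invariance / self-consistency properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panelrp import cnv_caller as cnv
from panelrp.panel_io import CoverageError, CoverageMatrix


TARGETS = ["USH2A_ex45", "USH2A_ex46", "USH2A_ex47", "USH2A_ex48", "USH2A_ex49",
           "EYS_ex1", "EYS_ex13", "EYS_ex14", "EYS_ex19",
           "CEP290_ex5", "CEP290_ex6", "RP1_ex4", "RP2_ex1"]


def matrix(data, samples=None, targets=None):
    targets = targets or TARGETS[: len(data)]
    samples = samples or [f"S{i + 1}" for i in range(len(data[0]))]
    return CoverageMatrix(pd.DataFrame(data, index=targets, columns=samples))


def flat_matrix(depth=300, n_samples=5, targets=TARGETS):
    return CoverageMatrix(pd.DataFrame(
        np.full((len(targets), n_samples), depth),
        index=targets, columns=[f"S{i + 1}" for i in range(n_samples)]))


class TestNormalize:
    def test_identical_samples_identical_columns(self):
        m = flat_matrix()
        norm = cnv.normalize(m)
        assert (norm.nunique(axis=1) == 1).all()

    def test_scale_invariance_of_normalization(self):
        m = flat_matrix()
        scaled = CoverageMatrix(m.depth.assign(S2=m.depth["S2"] * 3))
        assert np.allclose(cnv.normalize(m), cnv.normalize(scaled))

    def test_hand_computed_5x4(self):
        data = [[100, 200, 50, 400],
                [200, 400, 100, 800],
                [300, 600, 150, 1200],
                [400, 800, 200, 1600],
                [500, 1000, 250, 2000]]
        m = matrix(data)
        norm = cnv.normalize(m)
        # per-sample medians are row 3: 300, 600, 150, 1200
        expected = np.array(data) / np.array([300, 600, 150, 1200])
        assert np.allclose(norm.to_numpy(), expected)

    def test_all_zero_sample_rejected(self):
        m = matrix([[0, 300], [0, 300], [0, 300]])
        with pytest.raises(CoverageError, match="S1"):
            cnv.normalize(m)

    def test_single_sample_rejected(self):
        with pytest.raises(CoverageError, match="2 samples"):
            cnv.normalize(matrix([[300], [300]]))


class TestComputeRatios:
    def test_identical_samples_unit_ratios(self):
        track = cnv.compute_ratios(flat_matrix(), "S1")
        assert np.allclose(track.ratio, 1.0)
        assert track.eligible.all()

    def test_half_depth_gives_half_ratio(self):
        m = flat_matrix()
        depth = m.depth.copy()
        depth.loc["EYS_ex13", "S1"] = 150
        track = cnv.compute_ratios(CoverageMatrix(depth), "S1")
        assert track.ratio["EYS_ex13"] == pytest.approx(0.5)

    def test_low_reference_coverage_ineligible(self):
        m = flat_matrix()
        depth = m.depth.copy()
        depth.loc["EYS_ex13"] = 90  # all samples at 90x
        track = cnv.compute_ratios(CoverageMatrix(depth), "S1",
                                   min_ref_coverage=100)
        assert not track.eligible["EYS_ex13"]
        assert track.eligible.drop("EYS_ex13").all()

    def test_zero_reference_median_undefined(self):
        m = flat_matrix()
        depth = m.depth.copy()
        depth.loc["EYS_ex13"] = [300, 0, 0, 0, 0]
        track = cnv.compute_ratios(CoverageMatrix(depth), "S1")
        assert np.isnan(track.ratio["EYS_ex13"])
        assert not track.eligible["EYS_ex13"]

    def test_few_run_mates_warns(self):
        with pytest.warns(UserWarning, match="run-mate"):
            cnv.compute_ratios(flat_matrix(n_samples=3), "S1", min_run_mates=3)


class TestCallCnvs:
    def _track(self, tiny_panel, overrides, depth=300, n_samples=5):
        m = flat_matrix(depth, n_samples)
        d = m.depth.copy()
        for target, value in overrides.items():
            d.loc[target, "S1"] = value
        return cnv.compute_ratios(CoverageMatrix(d), "S1")

    def test_adjacent_deleted_exons_merge(self, tiny_panel):
        track = self._track(tiny_panel, {"EYS_ex13": 150, "EYS_ex14": 152})
        calls = cnv.call_cnvs(track, tiny_panel)
        assert len(calls) == 1
        c = calls[0]
        assert (c.gene, c.type, c.span, c.n_targets) == ("EYS", "deletion", "Ex13-14", 2)
        assert c.mean_ratio == pytest.approx(0.503, abs=0.01)

    def test_ratio_exactly_at_threshold_not_called(self, tiny_panel):
        track = self._track(tiny_panel, {"EYS_ex13": 210})  # ratio exactly 0.7
        assert cnv.call_cnvs(track, tiny_panel) == []
        track = self._track(tiny_panel, {"EYS_ex13": 209})
        assert len(cnv.call_cnvs(track, tiny_panel)) == 1

    def test_single_exon_duplication(self, tiny_panel):
        track = self._track(tiny_panel, {"CEP290_ex5": 450})
        calls = cnv.call_cnvs(track, tiny_panel)
        assert len(calls) == 1
        assert calls[0].type == "duplication" and calls[0].span == "Ex5"

    def test_five_consecutive_exons_one_call(self, tiny_panel):
        dels = {f"USH2A_ex{e}": 150 for e in range(45, 50)}
        calls = cnv.call_cnvs(self._track(tiny_panel, dels), tiny_panel)
        assert len(calls) == 1
        assert calls[0].span == "Ex45-49" and calls[0].n_targets == 5

    def test_mixed_direction_calls_do_not_merge(self, tiny_panel):
        track = self._track(tiny_panel, {"USH2A_ex45": 150, "USH2A_ex46": 450})
        calls = sorted(cnv.call_cnvs(track, tiny_panel), key=lambda c: c.span)
        assert [(c.type, c.span) for c in calls] == [
            ("deletion", "Ex45"), ("duplication", "Ex46")]

    def test_identical_samples_no_calls(self, tiny_panel):
        track = cnv.compute_ratios(flat_matrix(), "S1")
        assert cnv.call_cnvs(track, tiny_panel) == []


class TestRestriction:
    def test_candidate_gene_filtering(self, tiny_panel):
        m = flat_matrix()
        d = m.depth.copy()
        d.loc["USH2A_ex45", "S1"] = 150
        d.loc["EYS_ex13", "S1"] = 150
        mat = CoverageMatrix(d)
        restricted = cnv.call_cnvs_for_run(mat, tiny_panel, {"S1": ["USH2A"]})
        assert [c.gene for c in restricted["S1"]] == ["USH2A"]
        unrestricted = cnv.call_cnvs_for_run(mat, tiny_panel)
        assert {c.gene for c in unrestricted["S1"]} == {"USH2A", "EYS"}

    def test_sample_without_candidate_gene_skipped(self, tiny_panel):
        m = flat_matrix()
        out = cnv.call_cnvs_for_run(m, tiny_panel, {"S1": []})
        assert out == {}

    def test_restrict_to_candidates_postfilter(self, tiny_panel):
        call = cnv.CnvCall("S1", "EYS", ("EYS_ex13",), "deletion", 0.5)
        out = cnv.restrict_to_candidates({"S1": [call], "S2": [call]},
                                         {"S1": ["EYS"], "S2": ["USH2A"]})
        assert out == {"S1": [call]}


# --------------------------------------------------------------------------
# brute-force oracle (explicit loops, no shared code with the caller)
# --------------------------------------------------------------------------

def _median(values):
    vals = sorted(values)
    n = len(vals)
    return vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2


def brute_force_calls(depth: pd.DataFrame, panel, test_sample,
                      del_t=0.7, dup_t=1.2, min_ref=100):
    samples = list(depth.columns)
    others = [s for s in samples if s != test_sample]
    sample_median = {s: _median(depth[s].tolist()) for s in samples}
    calls = []
    for gene in panel.genes:
        run, run_type = [], None
        ratios = []
        for region in panel.regions_for_gene(gene):
            t = region.label
            if t not in depth.index:
                continue
            ref_norm = _median([depth.at[t, s] / sample_median[s] for s in others])
            ref_raw = _median([depth.at[t, s] for s in others])
            state = None
            if ref_norm > 0 and ref_raw >= min_ref:
                ratio = (depth.at[t, test_sample] / sample_median[test_sample]) / ref_norm
                if ratio < del_t:
                    state = "deletion"
                elif ratio > dup_t:
                    state = "duplication"
            else:
                ratio = None
            if state == run_type and state is not None:
                run.append((t, ratio))
            else:
                if run_type is not None:
                    calls.append((test_sample, gene, tuple(t for t, _ in run),
                                  run_type))
                run = [(t, ratio)] if state else []
                run_type = state
        if run_type is not None:
            calls.append((test_sample, gene, tuple(t for t, _ in run), run_type))
    return sorted(calls)


@st.composite
def small_matrices(draw):
    n_t = draw(st.integers(2, 10))
    n_s = draw(st.integers(2, 8))
    data = draw(st.lists(
        st.lists(st.integers(0, 600), min_size=n_s, max_size=n_s),
        min_size=n_t, max_size=n_t))
    # ensure every sample has a positive median
    for j in range(n_s):
        col = sorted(row[j] for row in data)
        if _median(col) <= 0:
            for row in data:
                row[j] += 150
    return data


class TestOracleEquivalence:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(data=small_matrices())
    def test_caller_matches_brute_force(self, tiny_panel, data):
        targets = TARGETS[: len(data)]
        m = matrix(data, targets=targets)
        got = []
        track = cnv.compute_ratios(m, "S1", min_run_mates=1)
        for c in cnv.call_cnvs(track, tiny_panel):
            got.append((c.sample, c.gene, c.targets, c.type))
        assert sorted(got) == brute_force_calls(m.depth, tiny_panel, "S1")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=small_matrices(), factor=st.integers(2, 9))
    def test_scale_invariance_of_calls(self, tiny_panel, data, factor):
        """Multiplying one sample's raw depths by a constant changes nothing."""
        targets = TARGETS[: len(data)]
        m = matrix(data, targets=targets)
        scaled = CoverageMatrix(m.depth.assign(S2=m.depth["S2"] * factor))
        def calls(mat):
            # absolute >=100x eligibility mask disabled: it is deliberately
            # not scale invariant (it gates on raw run-mate depth)
            track = cnv.compute_ratios(mat, "S1", min_ref_coverage=0,
                                       min_run_mates=1)
            return [(c.gene, c.targets, c.type) for c in
                    cnv.call_cnvs(track, tiny_panel)]
        assert calls(m) == calls(scaled)


class TestSimulationRecovery:
    def test_spiked_het_deletions_always_recovered(self, full_panel):
        """Copy-1 spikes at >=200x reference depth are called with
        sensitivity 1.0 over seeded replicates, with <=1 false call."""
        from panelrp import synthetic_data as sd
        panel, _ = full_panel
        events = [("S01", "EYS", 13, 14, 1), ("S02", "USH2A", 45, 49, 1)]
        cases = {"S01": ["EYS"], "S02": ["USH2A"]}
        expected = {("S01", "EYS", ("EYS_ex13", "EYS_ex14"), "deletion"),
                    ("S02", "USH2A", tuple(f"USH2A_ex{e}" for e in range(45, 50)),
                     "deletion")}
        for seed in range(10):
            m, _, _ = sd.simulate_cnv_run(events, mean_depth=200, seed=seed,
                                          panel=panel)
            calls = {(c.sample, c.gene, c.targets, c.type)
                     for cs in cnv.call_cnvs_for_run(m, panel, cases).values()
                     for c in cs}
            assert expected <= calls
            assert len(calls - expected) <= 1
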