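import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exomir.discovery_screen import (
    PairDesign,
    average_fold_change,
    call_directions,
    common_detected,
    consensus_overlap,
    filter_pair_detected,
    pair_fold_change,
    relative_expression,
    run_discovery,
)
from exomir.datasets import load_foldchange_table
from exomir.errors import CensoredInputError, ValidationError
from exomir.synthetic_data import SimulationConfig, simulate_profiling_pairs

from conftest import make_matrix


PAIR = PairDesign("p1", "case", "ctrl")


def pair_matrix(ct, assays, censored=None):
    return make_matrix(ct, assays, ["case", "ctrl"], censored=censored)


class TestDetectionFilter:
    def test_censored_in_both_excluded_one_retained(self):
        m = pair_matrix(
            [[np.nan, np.nan], [np.nan, 30.0], [25.0, 26.0]],
            ["both", "one", "none"],
        )
        assert filter_pair_detected(m, PAIR) == ["one", "none"]

    def test_fully_detected_all_retained_spikeins_excluded(self):
        m = pair_matrix(
            [[20.0, 20.0]] + [[25.0, 26.0]] * 5,
            ["UniSp3", "a", "b", "c", "d", "e"],
        )
        assert filter_pair_detected(m, PAIR) == ["a", "b", "c", "d", "e"]

    def test_common_is_intersection_in_matrix_order(self):
        pairs = [
            PairDesign("p1", "c1", "n1"),
            PairDesign("p2", "c2", "n2"),
            PairDesign("p3", "c3", "n3"),
        ]
        # detected sets {A,B,C}, {B,C,D}, {B,C}
        cen = {
            "A": [0, 0, 0, 0, 1, 1],
            "B": [0, 0, 0, 0, 0, 0],
            "C": [0, 0, 0, 0, 0, 0],
            "D": [1, 1, 0, 0, 0, 0],
        }
        m = make_matrix(
            [[30.0] * 6] * 4,
            list(cen),
            ["c1", "n1", "c2", "n2", "c3", "n3"],
            censored=[cen[a] for a in cen],
        )
        assert common_detected(m, pairs) == ["B", "C"]
        assert common_detected(m, pairs[:1]) == filter_pair_detected(m, pairs[0])

    def test_common_matches_bruteforce_on_simulation(self, sim_profiling):
        _, m, pairs, _ = sim_profiling
        got = common_detected(m, pairs)
        expected = []
        for a in m.target_assays:
            keep = True
            for p in pairs:
                if m.is_censored(a, p.case_sample) and m.is_censored(a, p.control_sample):
                    keep = False
            if keep:
                expected.append(a)
        assert got == expected


class TestFoldChange:
    def test_relative_expression_values(self):
        assert relative_expression(25.0, 25.0) == 1.0
        assert relative_expression(30.0, 25.0) == pytest.approx(2**-5)
        assert relative_expression(24.0, 25.0) == pytest.approx(2.0)
        with pytest.raises(CensoredInputError):
            relative_expression(float("nan"), 25.0)

    def test_pair_fold_change_hand_values(self):
        m = pair_matrix([[28.0, 30.0], [24.0, 24.0]], ["a", "ref"])
        rec = pair_fold_change(m, "a", PAIR, "ref")
        assert rec.fold_change == pytest.approx(4.0)  # ddCt = -2
        assert not rec.imputed

    def test_identical_columns_give_unity(self):
        m = pair_matrix([[28.0, 28.0], [24.0, 24.0]], ["a", "ref"])
        assert pair_fold_change(m, "a", PAIR, "ref").fold_change == pytest.approx(1.0)

    def test_censored_target_imputed_at_40(self):
        m = pair_matrix(
            [[np.nan, 30.0], [25.0, 25.0]], ["a", "ref"]
        )
        rec = pair_fold_change(m, "a", PAIR, "ref", impute_ct=40.0)
        assert rec.imputed
        assert rec.fold_change == pytest.approx(2.0 ** -(15 - 5))

    def test_censored_reference_is_hard_error(self):
        m = pair_matrix([[28.0, 30.0], [np.nan, 24.0]], ["a", "ref"])
        with pytest.raises(CensoredInputError, match="ref"):
            pair_fold_change(m, "a", PAIR, "ref")

    def test_reciprocity_under_pair_swap(self):
        m = pair_matrix([[27.3, 30.1], [24.2, 24.9]], ["a", "ref"])
        fwd = pair_fold_change(m, "a", PAIR, "ref").fold_change
        swapped = pair_fold_change(
            m, "a", PairDesign("p1", "ctrl", "case"), "ref"
        ).fold_change
        assert fwd * swapped == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        cts=st.lists(st.floats(15, 39), min_size=4, max_size=4),
    )
    def test_consistent_with_relative_expression(self, cts):
        """fold change = relExpr(case) / relExpr(control) to 1e-12."""
        m = pair_matrix([[cts[0], cts[1]], [cts[2], cts[3]]], ["a", "ref"])
        rec = pair_fold_change(m, "a", PAIR, "ref")
        ratio = relative_expression(cts[0], cts[2]) / relative_expression(cts[1], cts[3])
        assert rec.fold_change == pytest.approx(ratio, rel=1e-12)

    def test_average_fold_change(self):
        m = pair_matrix([[28.0, 30.0], [24.0, 24.0]], ["a", "ref"])
        recs = [
            dataclasses.replace(pair_fold_change(m, "a", PAIR, "ref"), fold_change=fc)
            for fc in (8.0, 4.0, 12.0)
        ]
        avg = average_fold_change(recs)
        assert avg.fold_change == pytest.approx(8.0)
        assert avg.pair_id == "average"
        assert average_fold_change(recs[:1]).fold_change == pytest.approx(8.0)

    def test_average_rejects_mixed_assays(self):
        m = pair_matrix([[28.0, 30.0], [29.0, 30.0], [24.0, 24.0]], ["a", "b", "ref"])
        recs = [
            pair_fold_change(m, "a", PAIR, "ref"),
            pair_fold_change(m, "b", PAIR, "ref"),
        ]
        with pytest.raises(ValidationError):
            average_fold_change(recs)


def _avg(assay, fc):
    from exomir.discovery_screen import FoldChangeRecord

    return FoldChangeRecord(assay, "average", "ref", 0.0, 0.0, fc)


class TestDirectionCalls:
    def test_thresholds(self):
        up, down = call_directions(
            [_avg("u", 2.0), _avg("n", 1.0), _avg("d", 0.346)],
            up_threshold=1.5,
            down_threshold=1 / 1.5,
        )
        assert up == ["u"]
        assert down == ["d"]

    def test_consensus_intersection(self):
        res = consensus_overlap(
            {
                "r1": (["a", "b"], ["x"]),
                "r2": (["b", "c"], ["y"]),
            }
        )
        assert res.consensus_up == ["b"]
        assert res.consensus_down == []

    def test_conflicting_direction_in_neither_list(self):
        res = consensus_overlap({"r1": (["a"], []), "r2": ([], ["a"])})
        assert res.consensus_up == [] and res.consensus_down == []


class TestPrintedAverages:
    """The shipped 19-row average fold-change table is internally consistent
    with the 1.5 / (1/1.5) direction thresholds under both normalizations."""

    def test_partition_reproduced_under_both_references(self):
        tab = load_foldchange_table()
        calls = {}
        for col in ("avg_fc_miR16", "avg_fc_miR93"):
            recs = [_avg(a, fc) for a, fc in zip(tab["assay_id"], tab[col])]
            calls[col] = call_directions(recs, 1.5, 1 / 1.5)
        cons = consensus_overlap(calls)
        assert len(cons.consensus_up) == 13 and len(cons.consensus_down) == 6
        assert set(cons.consensus_up) == set(tab[tab["direction"] == "up"]["assay_id"])
        assert set(cons.consensus_down) == set(tab[tab["direction"] == "down"]["assay_id"])


class TestPlantedRecovery:
    def test_zero_noise_zero_shift_gives_unit_fold_changes(self):
        cfg = SimulationConfig(
            seed=3,
            n_assays=30,
            sigma_ct=0.0,
            sigma_plate=0.0,
            sigma_spikein=0.0,
            biomarker_log2fc={},
            p_abundant=0.8,
            p_borderline=0.0,
        )
        m, pairs, truth = simulate_profiling_pairs(cfg)
        res = run_discovery(m, pairs, truth.references)
        for ref, avgs in res["averages"].items():
            for rec in avgs.values():
                assert rec.fold_change == pytest.approx(1.0, abs=1e-9)

    def test_zero_noise_consensus_recovers_planted_set_exactly(self):
        cfg = SimulationConfig(
            seed=3, sigma_ct=0.0, sigma_plate=0.0, sigma_spikein=0.0
        )
        m, pairs, truth = simulate_profiling_pairs(cfg)
        res = run_discovery(m, pairs, truth.references)
        cons = res["consensus"]
        assert set(cons.consensus_up) == set(truth.up_assays)
        assert set(cons.consensus_down) == set(truth.down_assays)
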