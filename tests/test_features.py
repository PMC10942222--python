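"""Feature extraction: hand-checked examples, oracle equivalence, invariances."""

import numpy as np
import pandas as pd
import pytest

from surgesture import (CaseTimeline, GestureEvent, extract_features,
                        feature_matrix, feature_names, shift_frequency,
                        worked_fixture)
from surgesture.features import (count_and_duration_features, de_features,
                                 interval_features)

from conftest import make_random_timeline
from oracles import oracle_features


def ev(label, hand, s, e, phase="MHT"):
    return GestureEvent(label=label, hand=hand, start_s=s, end_s=e, phase=phase)


def case_of(events, durations=None, vid="v", sid="s"):
    return CaseTimeline(vid, sid, tuple(events), durations or {"MHT": 120.0, "DGB": 60.0})


class TestCountsAndDurations:
    def test_three_hooks(self, tax):
        case = case_of([ev("hook", "unattributed", 10 * i, 10 * i + 5) for i in range(3)])
        vals = count_and_duration_features(case, tax)
        assert vals["count.hook"] == 3
        assert vals["dur.hook"] == pytest.approx(15.0)

    def test_hand_split_bookkeeping(self, tax):
        case = case_of([ev("grasp", "left", 0, 10), ev("grasp", "right", 2, 6)])
        vals = count_and_duration_features(case, tax)
        assert vals["count.grasp.L"] == 1 and vals["count.grasp.R"] == 1
        assert vals["dur.grasp.L"] == pytest.approx(10.0)
        assert vals["dur.grasp.R"] == pytest.approx(4.0)

    def test_empty_timeline_all_zero(self, tax):
        vals = count_and_duration_features(case_of([]), tax)
        assert len(vals) == 40
        assert all(v == 0 for v in vals.values())


class TestIntervals:
    def test_worked_gap_example(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 10),
                        ev("hook", "unattributed", 20, 30),
                        ev("hook", "unattributed", 50, 60)])
        vals = interval_features(case)
        assert vals["int.all.mean"] == pytest.approx(15.0)
        assert vals["int.all.max"] == pytest.approx(20.0)
        assert vals["int.all.min"] == pytest.approx(10.0)
        assert vals["int.all.sd"] == pytest.approx(7.071, abs=1e-3)

    def test_back_to_back_gaps_zero(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 10),
                        ev("hook", "unattributed", 10, 20),
                        ev("hook", "unattributed", 20, 30)])
        vals = interval_features(case)
        assert all(vals[f"int.all.{st}"] == 0 for st in ("mean", "max", "min", "sd"))

    def test_overlapping_hands_clamped_to_zero(self, tax):
        case = case_of([ev("grasp", "left", 0, 10), ev("push", "right", 5, 12)])
        assert interval_features(case)["int.all.mean"] == 0.0

    def test_degenerate_streams_still_full_vector(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 5)])
        assert len(extract_features(case, tax)) == 63

    def test_no_cross_phase_gap(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 10, "MHT"),
                        ev("hook", "unattributed", 50, 60, "DGB")])
        vals = interval_features(case)
        assert vals["int.all.mean"] == 0.0  # no within-phase gap exists


class TestShiftFrequency:
    def test_two_changes_over_two_minutes(self, tax):
        case = case_of(
            [ev("hook", "unattributed", 0, 5), ev("hook", "unattributed", 6, 10),
             ev("blunt_dissection", "unattributed", 11, 15),
             ev("hook", "unattributed", 16, 20)],
            durations={"MHT": 100.0, "DGB": 20.0})
        assert shift_frequency(case, "all") == pytest.approx(2 / 2.0)

    def test_constant_label_zero(self, tax):
        case = case_of([ev("hook", "unattributed", 5 * i, 5 * i + 3) for i in range(5)])
        assert shift_frequency(case, "all") == 0.0

    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_alternating_closed_form(self, tax, n):
        labels = ["hook", "blunt_dissection"]
        case = case_of([ev(labels[i % 2], "unattributed", 6 * i, 6 * i + 4)
                        for i in range(n)],
                       durations={"MHT": 120.0, "DGB": 60.0})
        assert shift_frequency(case, "all") == pytest.approx((n - 1) / 3.0)


class TestDEFeatures:
    def test_duration_ratio(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 90),
                        ev("grasp", "left", 0, 60)])
        assert de_features(case, tax)["de.dur_ratio"] == pytest.approx(1.5)

    def test_all_dissection_floor_rule(self, tax):
        case = case_of([ev("hook", "unattributed", 0, 30)])
        vals = de_features(case, tax)
        assert vals["de.count_E"] == 0
        assert vals["de.count_ratio"] == pytest.approx(1.0)  # 1 event / floor 1
        assert vals["de.dur_ratio"] == pytest.approx(30.0)   # 30 s / floor 1 s
        assert vals["de.shift"] == 0.0

    def test_class_change_rate(self, tax):
        seq = ["hook", "grasp", "hook", "grasp", "inefficient_grasp", "hook"]
        hands = ["unattributed", "left", "unattributed", "left", "left", "unattributed"]
        case = case_of([ev(l, h, 8 * i, 8 * i + 5) for i, (l, h) in enumerate(zip(seq, hands))],
                       durations={"MHT": 100.0, "DGB": 20.0})
        # D,E,D,E,E,D -> 4 class changes over 2 minutes
        assert de_features(case, tax)["de.shift"] == pytest.approx(2.0)

    def test_inefficient_variants_inherit_class(self, tax):
        case = case_of([ev("inefficient_hook", "unattributed", 0, 10),
                        ev("inefficient_grasp", "left", 12, 20)])
        vals = de_features(case, tax)
        assert vals["de.count_D"] == 1 and vals["de.count_E"] == 1


class TestFullVector:
    def test_cardinality_and_order(self, tax):
        names = feature_names(tax)
        assert len(names) == 63
        assert sum(n.startswith("count.") for n in names) == 20
        assert sum(n.startswith("dur.") for n in names) == 20
        assert sum(n.startswith("int.") for n in names) == 12
        assert sum(n.startswith("shift.") for n in names) == 3
        assert sum(n.startswith("de.") for n in names) == 7
        assert names[-1] == "manip_time"

    def test_empty_timeline_features(self, tax):
        case = CaseTimeline("v", "s", (), {"MHT": 60.0, "DGB": 60.0})
        vec = extract_features(case, tax)
        assert vec["manip_time"] == pytest.approx(2.0)
        assert all(v == 0 for k, v in vec.items() if k != "manip_time")

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_random_timelines(self, tax, seed):
        case = make_random_timeline(np.random.default_rng(seed), tax)
        got = extract_features(case, tax)
        want = oracle_features(case, tax)
        assert set(got) == set(want)
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-9), k

    @pytest.mark.parametrize("seed", range(5))
    def test_duration_doubling_scales_dur_features(self, tax, seed):
        case = make_random_timeline(np.random.default_rng(seed), tax, max_events=15)
        base = extract_features(case, tax)
        stretched = CaseTimeline(
            case.video_id, case.surgeon_id,
            tuple(GestureEvent(label=e.label, hand=e.hand, phase=e.phase,
                               start_s=2 * e.start_s, end_s=2 * e.end_s)
                  for e in case.events),
            {p: 2 * d for p, d in case.phase_durations.items()})
        got = extract_features(stretched, tax)
        for k in base:
            if k.startswith("dur.") or k in ("de.dur_D", "de.dur_E"):
                assert got[k] == pytest.approx(2 * base[k], abs=1e-6), k
            elif k.startswith("count.") or k in ("de.count_D", "de.count_E"):
                assert got[k] == base[k], k

    def test_time_shift_invariance(self, tax):
        case = make_random_timeline(np.random.default_rng(9), tax, max_events=10)
        base = extract_features(case, tax)
        shifted = CaseTimeline(
            case.video_id, case.surgeon_id,
            tuple(GestureEvent(label=e.label, hand=e.hand, phase=e.phase,
                               start_s=e.start_s + 1.0, end_s=e.end_s + 1.0)
                  for e in case.events),
            {p: d + 1.0 for p, d in case.phase_durations.items()})
        got = extract_features(shifted, tax)
        for k in base:
            if k.startswith(("count.", "dur.")):
                assert got[k] == pytest.approx(base[k], abs=1e-9), k


class TestWorkedFixtureGolden:
    def test_fixture_matrix_matches_golden(self, tax):
        """Shipped micro-cohort reproduces the oracle-computed golden table."""
        cases, _, _ = worked_fixture()
        got = feature_matrix(cases, tax).drop(columns="surgeon_id")
        from pathlib import Path
        golden = pd.read_csv(Path(__file__).parent / "data" /
                             "worked_fixture_features_golden.csv",
                             index_col="video_id")
        pd.testing.assert_frame_equal(got, golden, rtol=0, atol=1e-9)

    def test_fixture_covers_degenerate_branches(self, tax):
        cases, _, _ = worked_fixture()
        fm = feature_matrix(cases, tax)
        assert len(cases) == 12
        assert (fm["de.count_E"] == 0).any()          # all-dissection case
        assert (fm.drop(columns="surgeon_id").drop(columns="manip_time")
                .sum(axis=1) == 0).any()              # empty-events case
        assert (fm["count.grasp.L"] > 0).any() and (fm["count.grasp.R"] > 0).any()
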