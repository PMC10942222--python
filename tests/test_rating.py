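"""mGOALS aggregation, ICC/Kendall's W agreement, quantile grouping."""

import numpy as np
import pandas as pd
import pytest

from surgesture import (MGoalsRating, case_score, icc_absolute_agreement,
                        item_binarize, kendalls_w, quantile_grouping)
from surgesture.rating import MGOALS_ITEMS, RatingError

from oracles import oracle_icc21


def rating(vid, rater, *scores):
    return MGoalsRating(vid, rater, dict(zip(MGOALS_ITEMS, scores)))


class TestCaseScore:
    def test_mean_of_totals(self):
        total, per_item = case_score([rating("v", "r1", 5, 5, 5, 5),
                                      rating("v", "r2", 4, 4, 4, 4)])
        assert total == pytest.approx(18.0)
        assert per_item["efficiency"] == pytest.approx(4.5)

    def test_single_rater(self):
        total, _ = case_score([rating("v", "r1", 3, 4, 4, 4)])
        assert total == 15

    def test_three_raters(self):
        rs = [rating("v", "r1", 4, 4, 4, 4),     # 16
              rating("v", "r2", 5, 4, 5, 4),     # 18
              rating("v", "r3", 5, 5, 5, 5)]     # 20
        got, _ = case_score(rs)
        assert got == pytest.approx(np.mean([16, 18, 20]))

    @pytest.mark.parametrize("bad", [0, 6])
    def test_out_of_range_item_rejected(self, bad):
        with pytest.raises(RatingError, match=r"\[1, 5\]"):
            rating("v", "r", bad, 3, 3, 3)

    def test_item_set_enforced(self):
        with pytest.raises(RatingError, match="exactly"):
            MGoalsRating("v", "r", {"depth_perception": 3})


class TestICC:
    def test_perfect_agreement_is_one(self):
        col = np.array([10.0, 14.0, 17.0, 19.0, 12.0])
        icc, qualified = icc_absolute_agreement(np.vstack([col, col]))
        assert icc == pytest.approx(1.0)
        assert qualified

    def test_matches_anova_oracle_on_hand_matrix(self):
        m = np.array([[9.0, 14.0, 17.0, 20.0],
                      [11.0, 13.0, 18.0, 19.0]])
        icc, _ = icc_absolute_agreement(m)
        assert icc == pytest.approx(oracle_icc21(m), abs=1e-12)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        m = rng.normal(15, 3, size=(3, 10))
        icc, _ = icc_absolute_agreement(m)
        k, n = m.shape
        df = pd.DataFrame({
            "targets": np.tile(np.arange(n), k),
            "raters": np.repeat(np.arange(k), n),
            "scores": m.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        want = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert icc == pytest.approx(want, abs=1e-9)

    def test_independent_noise_drives_icc_to_zero(self):
        rng = np.random.default_rng(0)
        truth = rng.normal(15, 2, size=10_000)
        m = np.vstack([truth + rng.normal(0, 20, truth.size),
                       truth + rng.normal(0, 20, truth.size)])
        icc, qualified = icc_absolute_agreement(m)
        assert abs(icc) < 0.05
        assert not qualified

    def test_monotone_in_noise(self):
        rng = np.random.default_rng(1)
        truth = rng.normal(15, 2, size=2000)
        iccs = []
        for sd in (0.0, 1.0, 3.0, 9.0):
            noisy = np.vstack([truth + rng.normal(0, sd, truth.size),
                               truth + rng.normal(0, sd, truth.size)])
            iccs.append(icc_absolute_agreement(noisy)[0])
        assert iccs == sorted(iccs, reverse=True)

    def test_constant_matrix_degenerate(self):
        with pytest.raises(RatingError, match="degenerate"):
            icc_absolute_agreement(np.full((2, 5), 3.0))


class TestKendallsW:
    def test_identical_rankings_is_one(self):
        ranks = np.array([[1.0, 2, 3, 4, 5]] * 3)
        assert kendalls_w(ranks) == pytest.approx(1.0)

    def test_reversed_rankings_is_zero(self):
        m = np.array([[1.0, 2, 3], [3.0, 2, 1]])
        assert kendalls_w(m) == pytest.approx(0.0)

    def test_random_rankings_near_zero(self):
        # E[W] ~ 1/k under independent rankings: many raters push W toward 0
        rng = np.random.default_rng(2)
        m = np.vstack([rng.permutation(200) for _ in range(20)]).astype(float)
        assert kendalls_w(m) < 0.1

    def test_monotone_in_noise(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(0, 1, 800)
        ws = []
        for sd in (0.0, 0.5, 2.0, 8.0):
            m = np.vstack([truth + rng.normal(0, sd, truth.size) for _ in range(2)])
            ws.append(kendalls_w(m))
        assert ws == sorted(ws, reverse=True)

    def test_needs_two_items(self):
        with pytest.raises(RatingError):
            kendalls_w(np.array([[1.0], [1.0]]))


class TestQuantileGrouping:
    def test_eight_value_oracle(self):
        scores = {f"s{i}": v for i, v in enumerate([10, 12, 14, 16, 18, 20, 20, 20])}
        g = quantile_grouping(scores)
        vals = np.array(list(scores.values()), float)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        assert g.q1_cut == pytest.approx(q1) and g.q3_cut == pytest.approx(q3)
        for sid, v in scores.items():
            want = "bottom" if v < q1 else ("top" if v > q3 else "medium")
            assert g.group[sid] == want

    def test_uniform_split_proportions(self):
        rng = np.random.default_rng(5)
        scores = {f"s{i}": float(v) for i, v in enumerate(rng.uniform(0, 1, 100))}
        g = quantile_grouping(scores)
        counts = pd.Series(g.group).value_counts()
        assert abs(counts["bottom"] - 25) <= 5
        assert abs(counts["top"] - 25) <= 5
        assert abs(counts["medium"] - 50) <= 10

    def test_binary_partition_exhaustive(self):
        scores = {f"s{i}": float(i) for i in range(10)}
        g = quantile_grouping(scores)
        n_inc = sum(v == "incompetent" for v in g.binary.values())
        n_comp = sum(v == "competent" for v in g.binary.values())
        assert n_inc + n_comp == 10
        assert set(g.binary) == set(scores)

    def test_boundary_score_is_medium(self):
        scores = {"a": 10.0, "b": 12.0, "c": 12.0, "d": 12.0, "e": 14.0}
        g = quantile_grouping(scores)
        assert g.q1_cut == 12.0
        assert g.group["b"] == "medium"

    def test_monotone_in_score(self):
        scores = {f"s{i}": float(i) for i in range(12)}
        g = quantile_grouping(scores)
        rank = {"bottom": 0, "medium": 1, "top": 2}
        bumped = dict(scores)
        bumped["s1"] = 20.0
        g2 = quantile_grouping(bumped)
        assert rank[g2.group["s1"]] >= rank[g.group["s1"]]

    def test_study_cuts_give_49_26_split(self):
        """Scores drawn around the study's printed quartiles (15.5 / 18.71)
        reproduce a 49/26-style competent/incompetent split of 75 videos."""
        rng = np.random.default_rng(8)
        low = rng.uniform(9, 15.49, 26)
        high = rng.uniform(15.51, 20, 49)
        scores = {f"s{i}": float(v) for i, v in enumerate(np.concatenate([low, high]))}
        cuts = (15.5, 18.71)
        binary = {s: ("incompetent" if v < cuts[0] else "competent")
                  for s, v in scores.items()}
        assert sum(b == "incompetent" for b in binary.values()) == 26
        assert sum(b == "competent" for b in binary.values()) == 49


class TestItemBinarize:
    def test_lowest_quarter_flagged(self):
        s = pd.Series(np.arange(1.0, 9.0), index=[f"v{i}" for i in range(8)])
        labels = item_binarize(s, q=0.25)
        assert labels.sum() == 2
        assert labels["v0"] == 1 and labels["v1"] == 1

    def test_all_fives_degenerate(self):
        s = pd.Series(5.0, index=[f"v{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            labels = item_binarize(s)
        assert labels.sum() == 0

    def test_invariant_to_monotone_rescaling(self):
        rng = np.random.default_rng(6)
        s = pd.Series(rng.uniform(1, 5, 20), index=[f"v{i}" for i in range(20)])
        base = item_binarize(s)
        squashed = item_binarize(np.exp(s / 2))
        pd.testing.assert_series_equal(base, squashed)
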