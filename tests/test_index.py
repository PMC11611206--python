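"""Index construction and scoring arithmetic."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mish.ensemble import EnsembleSummary
from mish.errors import DataError
from mish.index import (IndexEntry, MishDefinition, assign_signs,
                        build_indicator_index, build_overall_index, score,
                        select_top_enzymes, sweep_k)
from mish.profile import FeatureTable


def _summary(rows, n_runs=25):
    """rows: {ec: (presence_count, average_gain, rho)}"""
    t = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["presence_count", "average_gain", "spearman_rho"])
    return EnsembleSummary(table=t, n_runs=n_runs)


def _features(values, columns, scaled=True):
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      columns=columns,
                      index=[f"S{i}" for i in range(len(values))])
    params = {c: (0.0, 1.0) for c in columns} if scaled else None
    return FeatureTable(data=df, scaled=scaled, scaling_params=params)


class TestSelectTopEnzymes:
    def test_presence_filter_excludes_unstable(self):
        s = _summary({"A": (25, 0.1, 0.5), "B": (12, 0.9, 0.5),
                      "C": (20, 0.2, 0.5)})
        top = select_top_enzymes(s, presence_min=13, k=3)
        assert "B" not in top.index
        assert list(top.index) == ["C", "A"]

    def test_tie_break_higher_presence_then_lexicographic(self):
        s = _summary({"B": (20, 0.5, 0), "A": (20, 0.5, 0),
                      "C": (25, 0.5, 0)})
        top = select_top_enzymes(s, presence_min=13, k=3)
        assert list(top.index) == ["C", "A", "B"]

    def test_k_larger_than_survivors_warns(self):
        s = _summary({"A": (25, 0.1, 0)})
        with pytest.warns(UserWarning, match="only 1"):
            top = select_top_enzymes(s, presence_min=13, k=5)
        assert len(top) == 1

    def test_infeasible_presence_min_rejected(self):
        s = _summary({"A": (25, 0.1, 0)})
        with pytest.raises(DataError):
            select_top_enzymes(s, presence_min=26, k=1)


class TestAssignSigns:
    def test_anti_ranked_feature_negative(self):
        feats = _features([[0.9], [0.5], [0.1]], ["A"])
        rating = pd.Series([10.0, 50.0, 90.0], index=feats.data.index)
        assert assign_signs(feats, rating, ["A"]) == {"A": -1}

    def test_co_ranked_feature_positive(self):
        feats = _features([[0.1], [0.5], [0.9]], ["A"])
        rating = pd.Series([10.0, 50.0, 90.0], index=feats.data.index)
        assert assign_signs(feats, rating, ["A"]) == {"A": +1}

    def test_constant_feature_defaults_positive_with_warning(self):
        feats = _features([[0.5], [0.5], [0.5]], ["A"])
        rating = pd.Series([10.0, 50.0, 90.0], index=feats.data.index)
        with pytest.warns(UserWarning, match="undefined"):
            assert assign_signs(feats, rating, ["A"]) == {"A": +1}


class TestScore:
    def test_single_ec_hand_value(self):
        d = MishDefinition("SOM", [IndexEntry("A", 2.7, +1)])
        feats = _features([[0.4]], ["A"])
        assert score(d, feats).iloc[0] == pytest.approx(40.0)

    def test_two_ec_weighted_mean(self):
        d = MishDefinition("SOM", [IndexEntry("A", 1.0, +1),
                                   IndexEntry("B", 3.0, +1)])
        feats = _features([[1.0, 0.0]], ["A", "B"])
        assert score(d, feats).iloc[0] == pytest.approx(25.0)

    def test_all_ones_gives_100(self):
        d = MishDefinition("SOM", [IndexEntry("A", 0.2, +1),
                                   IndexEntry("B", 5.0, +1)])
        feats = _features([[1.0, 1.0]], ["A", "B"])
        assert score(d, feats).iloc[0] == pytest.approx(100.0)

    def test_missing_ec_imputed_zero_post_inversion(self):
        d = MishDefinition("SOM", [IndexEntry("A", 1.0, +1),
                                   IndexEntry("GONE", 1.0, -1)])
        feats = _features([[0.5]], ["A"])
        with pytest.warns(UserWarning, match="GONE"):
            s = score(d, feats)
        # missing EC scores as 0, then inverted to 1: (0.5 + 1)/2 * 100
        assert s.iloc[0] == pytest.approx(75.0)

    def test_unscaled_table_rejected(self):
        d = MishDefinition("SOM", [IndexEntry("A", 1.0, +1)])
        feats = _features([[0.4]], ["A"], scaled=False)
        with pytest.raises(DataError):
            score(d, feats)


@st.composite
def _random_case(draw):
    k = draw(st.integers(1, 6))
    n = draw(st.integers(1, 8))
    ecs = [f"E{i}" for i in range(k)]
    weights = [draw(st.floats(0.01, 10)) for _ in range(k)]
    signs = [draw(st.sampled_from([+1, -1])) for _ in range(k)]
    vals = [[draw(st.floats(0, 1)) for _ in range(k)] for _ in range(n)]
    return ecs, weights, signs, vals


class TestScoreProperties:
    @given(_random_case())
    @settings(max_examples=150, deadline=None)
    def test_matches_loop_oracle_and_bounds(self, case):
        ecs, weights, signs, vals = case
        d = MishDefinition("x", [IndexEntry(e, w, s)
                                 for e, w, s in zip(ecs, weights, signs)])
        feats = _features(vals, ecs)
        got = score(d, feats)
        for i, row in enumerate(vals):
            num = sum(w * (v if s == 1 else 1 - v)
                      for w, s, v in zip(weights, signs, row))
            expected = 100 * num / sum(weights)
            assert got.iloc[i] == pytest.approx(expected, abs=1e-9)
            assert -1e-9 <= got.iloc[i] <= 100 + 1e-9

    @given(_random_case())
    @settings(max_examples=100, deadline=None)
    def test_inversion_symmetry(self, case):
        """Replacing x by 1-x and flipping the sign leaves scores unchanged."""
        ecs, weights, signs, vals = case
        d1 = MishDefinition("x", [IndexEntry(e, w, s)
                                  for e, w, s in zip(ecs, weights, signs)])
        flipped = [[1 - v for v in row] for row in vals]
        d2 = MishDefinition("x", [IndexEntry(e, w, -s)
                                  for e, w, s in zip(ecs, weights, signs)])
        s1 = score(d1, _features(vals, ecs))
        s2 = score(d2, _features(flipped, ecs))
        assert np.allclose(s1, s2, atol=1e-9)

    @given(_random_case(), st.floats(0.01, 100))
    @settings(max_examples=100, deadline=None)
    def test_weight_scale_invariance(self, case, factor):
        ecs, weights, signs, vals = case
        d1 = MishDefinition("x", [IndexEntry(e, w, s)
                                  for e, w, s in zip(ecs, weights, signs)])
        d2 = MishDefinition("x", [IndexEntry(e, w * factor, s)
                                  for e, w, s in zip(ecs, weights, signs)])
        feats = _features(vals, ecs)
        assert np.allclose(score(d1, feats), score(d2, feats), atol=1e-8)

    @given(_random_case())
    @settings(max_examples=100, deadline=None)
    def test_monotonicity_in_feature_value(self, case):
        ecs, weights, signs, vals = case
        d = MishDefinition("x", [IndexEntry(e, w, s)
                                 for e, w, s in zip(ecs, weights, signs)])
        base = score(d, _features(vals, ecs))
        bumped = [list(row) for row in vals]
        for row in bumped:
            row[0] = min(1.0, row[0] + 0.25)
        new = score(d, _features(bumped, ecs))
        if signs[0] == +1:
            assert (new >= base - 1e-9).all()
        else:
            assert (new <= base + 1e-9).all()


class TestBuildIndex:
    def test_planted_signal_definition(self, small_filtered):
        """On synthetic data the definition recovers planted ECs and signs."""
        feats, rated, truth = small_filtered
        rating = rated.ratings.iloc[:, 0]
        planted = truth.all_signal_ecs()
        # fake a perfect ensemble summary: planted ECs always present
        rows = {}
        for i, ec in enumerate(feats.feature_ids):
            if ec in planted:
                rows[ec] = (25, 0.5 - 0.001 * i, np.nan)
            else:
                rows[ec] = (5, 0.001, np.nan)
        summary = _summary(rows)
        d = build_indicator_index(summary, feats, rating, presence_min=13,
                                  k=len(planted))
        assert {e.ec for e in d.entries} == set(planted)
        for e in d.entries:
            assert e.sign == planted[e.ec]

    def test_rebuild_is_deterministic(self, small_filtered):
        feats, rated, truth = small_filtered
        rating = rated.ratings.iloc[:, 0]
        rows = {ec: (20, 0.1 + 0.01 * i, np.nan)
                for i, ec in enumerate(feats.feature_ids)}
        summary = _summary(rows)
        d1 = build_indicator_index(summary, feats, rating, k=5)
        d2 = build_indicator_index(summary, feats, rating, k=5)
        assert d1.to_frame().equals(d2.to_frame())

    def test_stability_guarantee(self, small_filtered):
        """No EC below the presence threshold ever enters a definition."""
        feats, rated, truth = small_filtered
        rating = rated.ratings.iloc[:, 0]
        rows = {ec: ((25 if i % 2 else 3), 1.0, np.nan)
                for i, ec in enumerate(feats.feature_ids)}
        summary = _summary(rows)
        d = build_indicator_index(summary, feats, rating, presence_min=13,
                                  k=100)
        for e in d.entries:
            assert summary.table.loc[e.ec, "presence_count"] >= 13

    def test_json_round_trip(self, tmp_path):
        d = MishDefinition("SOM", [IndexEntry("A", 1.5, -1),
                                   IndexEntry("B", 0.5, +1)],
                           scaling_params={"A": (0, 2), "B": (1, 3)},
                           provenance={"n_runs": 25})
        p = tmp_path / "def.json"
        d.to_json(p)
        back = MishDefinition.from_json(p)
        assert back.to_frame().equals(d.to_frame())
        assert back.scaling_params == {"A": (0.0, 2.0), "B": (1.0, 3.0)}


class TestSweepK:
    def _setup(self, small_filtered):
        feats, rated, truth = small_filtered
        rating = rated.ratings.iloc[:, 0]
        planted = truth.all_signal_ecs()
        rows = {}
        for i, ec in enumerate(feats.feature_ids):
            gain = 0.5 - 0.001 * i if ec in planted else 0.002
            rows[ec] = (25, gain, np.nan)
        return _summary(rows), feats, rating, planted

    def test_parsimony_rule_picks_smallest_plateau_k(self, small_filtered):
        summary, feats, rating, planted = self._setup(small_filtered)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sweep_k(summary, feats, rating, k_grid=(8, 16, 24),
                          presence_min=13)
        assert res.chosen_k in res.grid
        plateau = max(res.adj_r2)
        assert res.adj_r2[res.grid.index(res.chosen_k)] >= plateau - 0.005

    def test_singleton_grid(self, small_filtered):
        summary, feats, rating, _ = self._setup(small_filtered)
        res = sweep_k(summary, feats, rating, k_grid=(6,), presence_min=13)
        assert res.chosen_k == 6 and len(res.grid) == 1

    def test_identical_r2_prefers_smaller_k(self):
        """Adding zero-weight-tier enzymes that change nothing keeps k small."""
        # two ECs carry all signal; grid (2, 4) must choose 2 when R2 ties
        ecs = ["A", "B", "C", "D"]
        rng = np.random.default_rng(0)
        n = 40
        base = rng.random(n)
        vals = np.column_stack([base, 1 - base,
                                np.full(n, 0.25), np.full(n, 0.75)])
        feats = _features(vals, ecs)
        rating = pd.Series(100 * base, index=feats.data.index, name="SOM")
        rows = {"A": (25, 0.5, np.nan), "B": (25, 0.4, np.nan),
                "C": (25, 0.0001, np.nan), "D": (25, 0.0001, np.nan)}
        summary = _summary(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sweep_k(summary, feats, rating, k_grid=(2, 4),
                          presence_min=13, tolerance=0.01)
        assert res.chosen_k == 2


class TestOverallIndex:
    def test_max_gain_rule_for_shared_ec(self):
        d1 = MishDefinition("SOM", [IndexEntry("A", 0.02, +1)])
        d2 = MishDefinition("ACE", [IndexEntry("A", 0.05, -1)])
        with pytest.warns(UserWarning, match="conflicting"):
            overall = build_overall_index([d1, d2], k_per_indicator=50)
        assert overall.k == 1
        assert overall.entries[0].weight == pytest.approx(0.05)
        assert overall.entries[0].sign == -1  # from the max-gain indicator

    def test_disjoint_union_keeps_weights(self):
        d1 = MishDefinition("SOM", [IndexEntry("A", 0.1, +1),
                                    IndexEntry("B", 0.2, +1)])
        d2 = MishDefinition("ACE", [IndexEntry("C", 0.3, -1),
                                    IndexEntry("D", 0.4, +1),
                                    IndexEntry("E", 0.5, +1)])
        overall = build_overall_index([d1, d2], k_per_indicator=50)
        assert overall.k == 5
        weights = {e.ec: e.weight for e in overall.entries}
        assert weights == {"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4, "E": 0.5}

    def test_k_per_indicator_truncates(self):
        d1 = MishDefinition("SOM", [IndexEntry("A", 0.9, +1),
                                    IndexEntry("B", 0.2, +1)])
        overall = build_overall_index([d1], k_per_indicator=1)
        assert [e.ec for e in overall.entries] == ["A"]
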