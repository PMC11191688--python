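"""Importance scorers, consensus ranking, and Kneedle knee detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietsel import (
    Comparison,
    ImportanceVector,
    SelectionConfig,
    consensus_rank,
    elastic_net_scores,
    kneedle_cutoff,
    plsda_vip,
    rf_gini,
    select_variables,
)
from dietsel.errors import ConfigurationError, PreconditionError

from conftest import chord_distance_argmax


def _xy(seed: int, n_per_class: int = 8, p: int = 40, planted: int | None = None, d: float = 3.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.standard_normal((2 * n_per_class, p)),
        columns=[f"v{i:02d}" for i in range(p)],
    )
    y = np.r_[np.zeros(n_per_class), np.ones(n_per_class)].astype(int)
    if planted is not None:
        X.iloc[:, planted] += d * y
    return X, y


class TestElasticNet:
    def test_null_data_mostly_zero(self):
        zero_fracs = []
        for seed in range(10):
            X, y = _xy(seed)
            iv = elastic_net_scores(X, y, seed=seed)
            zero_fracs.append(float((iv.scores == 0).mean()))
        assert np.median(zero_fracs) >= 0.5

    def test_planted_variable_tops_ranking(self):
        hits = 0
        for seed in range(15):
            X, y = _xy(seed, planted=3)
            iv = elastic_net_scores(X, y, seed=seed)
            hits += iv.scores.idxmax() == "v03"
        assert hits / 15 >= 0.8

    def test_grouping_keeps_duplicated_signal(self):
        """Elastic net (unlike lasso) keeps both copies of a duplicated
        informative column nonzero together."""
        X, y = _xy(0, planted=3)
        X["v03_copy"] = X["v03"] + 1e-6 * np.random.default_rng(1).standard_normal(len(X))
        iv = elastic_net_scores(X, y, alpha_mix=0.5, seed=0)
        assert iv.scores["v03"] + iv.scores["v03_copy"] > 0

    def test_binary_scores_switch(self):
        X, y = _xy(0, planted=3)
        iv = elastic_net_scores(X, y, seed=0, binary_scores=True)
        assert set(np.unique(iv.scores)) <= {0.0, 1.0}

    def test_single_class_rejected(self):
        X, _ = _xy(0)
        with pytest.raises(ConfigurationError):
            elastic_net_scores(X, np.zeros(len(X), dtype=int), seed=0)


class TestPlsdaVip:
    def test_vip_squared_mean_is_one(self):
        for seed in range(10):
            X, y = _xy(seed, p=30)
            vip = plsda_vip(X, y, n_components=2).scores
            assert float((vip**2).mean()) == pytest.approx(1.0, abs=1e-8)

    def test_informative_variable_attains_max_vip(self):
        hits = 0
        for seed in range(20):
            X, y = _xy(seed, planted=5)
            vip = plsda_vip(X, y).scores
            hits += vip.idxmax() == "v05"
        assert hits / 20 >= 0.9

    def test_permuted_labels_kill_the_signal(self):
        """After scaling (as the pipeline does), a permuted-label fit leaves
        the formerly planted variable at a chance-level VIP rank."""
        drops = 0
        for seed in range(20):
            X, y = _xy(seed, planted=5)
            X = (X - X.mean()) / X.std(ddof=1)
            rng = np.random.default_rng(1000 + seed)
            vip_perm = plsda_vip(X, rng.permutation(y)).scores
            rank = vip_perm.rank(ascending=False)["v05"]
            drops += rank > 5
        assert drops / 20 >= 0.7

    def test_invalid_components_rejected(self):
        X, y = _xy(0)
        with pytest.raises(ConfigurationError):
            plsda_vip(X, y, n_components=0)


class TestRfGini:
    def test_scores_nonnegative_and_informative(self):
        X, y = _xy(0, planted=2)
        iv = rf_gini(X, y, n_trees=200, seed=0)
        assert (iv.scores >= 0).all()
        assert iv.scores.sum() > 0

    def test_planted_variable_top_scored(self):
        hits = 0
        for seed in range(10):
            X, y = _xy(seed, planted=2)
            iv = rf_gini(X, y, n_trees=300, seed=seed)
            hits += iv.scores.idxmax() == "v02"
        assert hits / 10 >= 0.8

    def test_seeded_determinism(self):
        X, y = _xy(3, planted=1)
        a = rf_gini(X, y, n_trees=200, seed=9).scores
        b = rf_gini(X, y, n_trees=200, seed=9).scores
        pd.testing.assert_series_equal(a, b)

    def test_too_few_trees_rejected(self):
        X, y = _xy(0)
        with pytest.raises(ConfigurationError):
            rf_gini(X, y, n_trees=50)


def _iv(method, mapping):
    return ImportanceVector(method=method, scores=pd.Series(mapping, dtype=float))


class TestConsensusRank:
    def test_single_scoring_method(self):
        ranking = consensus_rank([
            _iv("elastic_net", {"A": 2.0, "B": 0.0}),
            _iv("plsda_vip", {"A": 0.0, "B": 0.0}),
            _iv("rf_gini", {"A": 0.0, "B": 0.0}),
        ])
        tbl = ranking.table
        assert tbl.loc["A", "total_score"] == 1.0
        assert tbl.loc["B", "total_score"] == 0.0
        assert tbl.loc["A", "rank"] == 1

    def test_unanimous_top_variable_scores_three(self):
        vecs = [
            _iv(m, {"A": 5.0, "B": 1.0, "C": 0.0})
            for m in ("elastic_net", "plsda_vip", "rf_gini")
        ]
        tbl = consensus_rank(vecs).table
        assert tbl.loc["A", "total_score"] == pytest.approx(3.0)
        assert tbl.loc["A", "rank"] == 1
        assert tbl["total_score"].between(0, 3).all()

    def test_tie_broken_by_methods_count_then_id(self):
        vecs = [
            _iv("elastic_net", {"A": 1.0, "B": 0.0, "C": 1.0}),
            _iv("plsda_vip", {"A": 0.0, "B": 1.0, "C": 0.0}),
            _iv("rf_gini", {"A": 1.0, "B": 1.0, "C": 1.0}),
        ]
        tbl = consensus_rank(vecs).table
        # A and B: total 2; A scored by 2 methods, B by 2 -> lexicographic
        assert list(tbl.index[:2]) == ["A", "B"]

    def test_mismatched_universe_rejected(self):
        from dietsel.errors import AlignmentError

        with pytest.raises(AlignmentError):
            consensus_rank([
                _iv("elastic_net", {"A": 1.0}),
                _iv("plsda_vip", {"B": 1.0}),
                _iv("rf_gini", {"A": 1.0}),
            ])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        scores=st.lists(
            st.tuples(
                st.floats(0, 10, allow_nan=False),
                st.floats(0, 10, allow_nan=False),
                st.floats(0, 10, allow_nan=False),
            ),
            min_size=4,
            max_size=12,
        ),
        scale_=st.floats(0.1, 50),
        offset=st.floats(0, 5),
        which=st.integers(0, 2),
    )
    def test_affine_rescaling_invariance(self, scores, scale_, offset, which):
        """Ranking is unchanged by a positive affine transform of any one
        method's raw scores (min-max normalization property)."""
        names = [f"x{i:02d}" for i in range(len(scores))]
        methods = ["elastic_net", "plsda_vip", "rf_gini"]
        vecs = [
            _iv(m, dict(zip(names, [s[j] for s in scores])))
            for j, m in enumerate(methods)
        ]
        base = consensus_rank(vecs).table
        rescaled = [
            _iv(
                m,
                dict(zip(names, [
                    s[j] * scale_ + offset if j == which else s[j] for s in scores
                ])),
            )
            for j, m in enumerate(methods)
        ]
        # an affine offset can turn zero raw scores positive, changing the
        # methods_count tie-break; compare total scores and order by total
        other = consensus_rank(rescaled).table
        assert np.allclose(
            base["total_score"].sort_index(), other["total_score"].sort_index(), atol=1e-9
        )


class TestKneedle:
    def test_linear_curve_has_no_knee(self):
        with pytest.warns(UserWarning):
            k = kneedle_cutoff(np.linspace(3.0, 0.0, 30))
        assert k == 30

    def test_two_regime_curves_over_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            head = np.sort(rng.uniform(0.8, 1.0, 10))[::-1]
            tail = np.sort(rng.uniform(0.0, 0.1, 80))[::-1]
            k = kneedle_cutoff(np.r_[head, tail])
            hits += abs(k - 10) <= 2
        assert hits >= 95

    def test_agrees_with_chord_distance_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(200 + seed)
            head = np.sort(rng.uniform(0.7, 1.0, rng.integers(5, 15)))[::-1]
            tail = np.sort(rng.uniform(0.0, 0.15, rng.integers(30, 80)))[::-1]
            curve = np.r_[head, tail]
            k = kneedle_cutoff(curve)
            oracle = chord_distance_argmax(curve)
            assert abs((k - 1) - oracle) <= 1

    def test_preconditions(self):
        with pytest.raises(PreconditionError):
            kneedle_cutoff([1.0, 2.0, 3.0])
        with pytest.raises(PreconditionError):
            kneedle_cutoff([1.0, 2.0])

    def test_constant_curve_falls_back(self):
        with pytest.warns(UserWarning):
            assert kneedle_cutoff([1.0, 1.0, 1.0, 1.0]) == 4


class TestSelectVariables:
    def test_recovery_of_planted_discriminators(self, planted_table, planted_config,
                                                tenebrio_vs_control):
        from dietsel import ground_truth, preprocess

        proc, _ = preprocess(planted_table)
        res = select_variables(proc, tenebrio_vs_control, SelectionConfig(seed=0))
        truth = {e.variable for e in ground_truth(planted_config)}
        assert len(set(res.selected) & truth) >= 6
        assert res.knee_index == len(res.selected)
        assert res.knee_index <= len(res.ranking.variables)

    def test_deterministic_given_seed(self, planted_table, tenebrio_vs_control):
        from dietsel import preprocess

        proc, _ = preprocess(planted_table)
        a = select_variables(proc, tenebrio_vs_control, SelectionConfig(seed=4))
        b = select_variables(proc, tenebrio_vs_control, SelectionConfig(seed=4))
        assert a.selected == b.selected
        pd.testing.assert_frame_equal(a.ranking.table, b.ranking.table)

    def test_audit_trail_complete(self, planted_table, tenebrio_vs_control):
        from dietsel import preprocess

        proc, _ = preprocess(planted_table)
        res = select_variables(proc, tenebrio_vs_control, SelectionConfig(seed=0))
        assert set(res.raw_scores) == {"elastic_net", "plsda_vip", "rf_gini"}
        frame = res.to_frame()
        assert frame["selected"].sum() == res.knee_index
        # a variable with zero total score never outranks a positive one
        zeros = frame[frame["total_score"] == 0]
        if len(zeros):
            assert zeros["rank"].min() > frame[frame["total_score"] > 0]["rank"].max()
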