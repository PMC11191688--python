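"""Venn set algebra, fold-change matrices and Spearman correlation maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietsel import (
    Comparison,
    SampleTable,
    StudyConfig,
    correlation_heatmap,
    foldchange_heatmap,
    generate_study,
    spearman,
    venn,
)
from dietsel.consensus import ConsensusRanking, SelectionResult
from dietsel.errors import AlignmentError, DataError, DegenerateSampleError
from dietsel.integration import VennResult, star_for_p

from conftest import spearman_bruteforce


def _selection(selected, universe, label="A_vs_B") -> SelectionResult:
    tbl = pd.DataFrame(
        {"total_score": np.linspace(1, 0, len(universe))},
        index=pd.Index(universe, name="variable"),
    )
    return SelectionResult(
        comparison=Comparison(*label.split("_vs_")),
        ranking=ConsensusRanking(table=tbl),
        knee_index=len(selected),
        selected=list(selected),
    )


class TestVenn:
    def test_basic_set_algebra(self):
        u = ["a", "b", "c", "d"]
        v = venn(_selection(["a", "b"], u), _selection(["b", "c"], u, "C_vs_D"))
        assert v.intersection == {"b"}
        assert v.counts["union"] == 3

    def test_identical_selections(self):
        u = ["a", "b", "c"]
        v = venn(_selection(["a", "b"], u), _selection(["a", "b"], u, "C_vs_D"))
        assert v.intersection == frozenset({"a", "b"})

    def test_study_arithmetic_27_19_11(self):
        """Inclusion-exclusion on the healthy-scenario counts: 27 and 19
        selected with 11 common gives a 35-variable union."""
        u = [f"v{i:02d}" for i in range(60)]
        a = u[:27]                 # 27 selected in comparison 1
        b = u[16:35]               # 19 selected, overlapping a in 11
        v = venn(_selection(a, u), _selection(b, u, "C_vs_D"))
        assert v.counts == {"A": 27, "B": 19, "intersection": 11, "union": 35}

    def test_disjoint_universes_rejected(self):
        with pytest.raises(AlignmentError):
            venn(_selection(["a"], ["a", "b"]), _selection(["x"], ["x", "y"], "C_vs_D"))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        a=st.frozensets(st.integers(0, 40), max_size=30),
        b=st.frozensets(st.integers(0, 40), max_size=30),
    )
    def test_inclusion_exclusion_property(self, a, b):
        v = VennResult(set_a=frozenset(map(str, a)), set_b=frozenset(map(str, b)))
        c = v.counts
        assert c["union"] == c["A"] + c["B"] - c["intersection"]


class TestSpearman:
    def test_perfect_antitone(self):
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rho, _ = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert spearman(x, y)[0] == pytest.approx(spearman(np.exp(x), y)[0], abs=1e-12)

    def test_matches_midrank_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(5, 25)
            x = rng.integers(0, 6, n).astype(float)  # heavy ties
            y = rng.standard_normal(n)
            if np.ptp(x) == 0:
                continue
            rho, p = spearman(x, y)
            rho_ref, p_ref = spearman_bruteforce(x, y)
            assert rho == pytest.approx(rho_ref, abs=1e-12)
            assert p == pytest.approx(p_ref, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            spearman([1, 2, 3], [1, 2, 3])
        with pytest.raises(DegenerateSampleError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestStars:
    @pytest.mark.parametrize(
        "p,star", [(0.2, ""), (0.04, "*"), (0.009, "**"), (0.0005, "***")]
    )
    def test_levels(self, p, star):
        assert star_for_p(p) == star


class TestFoldchangeHeatmap:
    def test_equal_means_zero_log2fc(self, tiny_table):
        tiny_table.data["metabolic_01"] = [2.0, 3.0, 4.0, 5.0] * 2
        fch = foldchange_heatmap(
            tiny_table, ["metabolic_01"], [Comparison("Tenebrio", "Control")]
        )
        assert fch["log2fc"].iloc[0] == pytest.approx(0.0)
        assert fch["flag"].iloc[0] == ""

    def test_planted_direction_concordant_across_comparisons(self):
        from dietsel.synthetic import plant_effects

        cfg = plant_effects(
            StudyConfig(master_seed=2), ["inflammatory_02"],
            ("Tenebrio", "Buffalo"), d=2.0,
        )
        t = generate_study(cfg)
        fch = foldchange_heatmap(
            t, ["inflammatory_02"],
            [Comparison("Tenebrio", "Control"), Comparison("Buffalo", "Control")],
        )
        assert (fch["log2fc"] > 0).all()

    def test_cell_matches_standalone_fold_change(self, tiny_table):
        from dietsel import fold_change

        fch = foldchange_heatmap(
            tiny_table, ["inflammatory_01"], [Comparison("Tenebrio", "Control")]
        )
        rec = fold_change(tiny_table, "inflammatory_01", "Tenebrio", "Control")
        assert fch["fc"].iloc[0] == rec.fc

    def test_empty_common_set_warns(self, tiny_table):
        with pytest.warns(UserWarning):
            fch = foldchange_heatmap(tiny_table, [], [Comparison("Tenebrio", "Control")])
        assert fch.empty

    def test_flags_taken_from_screen(self, tiny_table):
        from dietsel import pairwise_screen

        cmp_ = Comparison("Tenebrio", "Control")
        screen = pairwise_screen(tiny_table, [cmp_])
        fch = foldchange_heatmap(tiny_table, ["tasr_expression_01"], [cmp_], screen=screen)
        expected = screen.loc[screen["variable"] == "tasr_expression_01", "flag"].iloc[0]
        assert fch["flag"].iloc[0] == expected


class TestCorrelationHeatmap:
    def test_matrix_dimensions(self, null_table):
        corr = correlation_heatmap(null_table, ["Control", "Tenebrio", "Buffalo"])
        assert corr.rho.shape == (31, 58)
        assert corr.p.shape == corr.rho.shape
        assert corr.stars.shape == corr.rho.shape

    def test_planted_shared_factor_is_matrix_maximum(self):
        hits = 0
        for seed in range(20):
            t = generate_study(StudyConfig(master_seed=300 + seed))
            rng = np.random.default_rng(seed)
            latent = rng.standard_normal(len(t.data))
            data = t.data.copy()
            data["tasr_expression_01"] = np.exp(0.5 * (latent + 0.3 * rng.standard_normal(len(latent))))
            data["inflammatory_01"] = latent + 0.3 * rng.standard_normal(len(latent))
            t2 = SampleTable(data=data, groups=t.groups, annotations=t.annotations)
            corr = correlation_heatmap(t2, ["Control", "Tenebrio", "Buffalo"])
            r, c = np.unravel_index(np.argmax(np.abs(corr.rho.to_numpy())), corr.rho.shape)
            hits += (corr.rho.index[r], corr.rho.columns[c]) == (
                "tasr_expression_01", "inflammatory_01",
            )
        assert hits / 20 >= 0.9

    def test_null_star_rate_near_nominal(self):
        """Independent data: raw '*' rate approximates 5% over simulations."""
        star_hits, cells = 0, 0
        for seed in range(30):
            t = generate_study(
                StudyConfig(
                    blocks={"tasr_expression": 4, "inflammatory": 8},
                    block_correlation=0.0,
                    master_seed=500 + seed,
                )
            )
            corr = correlation_heatmap(t, ["Control", "Tenebrio", "Buffalo"])
            star_hits += (corr.p.to_numpy() < 0.05).sum()
            cells += corr.p.size
        rate = star_hits / cells
        se = np.sqrt(0.05 * 0.95 / cells)
        assert abs(rate - 0.05) < 5 * se  # wide band: cells within a sim correlate

    def test_stars_consistent_with_p(self, null_table):
        corr = correlation_heatmap(null_table, ["Control", "LPS", "TenebrioLPS"])
        assert (corr.stars == corr.p.map(star_for_p)).all().all()
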