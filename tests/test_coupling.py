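import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eldercare_coupling import (
    classify,
    composite_score,
    compute_weights,
    coordination_degree,
    coupling_degree,
    coupling_table,
    d_matrix,
    load_reference_coupling,
    period_mean,
    standardize_year,
)
from eldercare_coupling.coupling import classify_series
from eldercare_coupling.pipeline import matches_printed

from conftest import make_panel, make_specs
from oracles import bf_pipeline_d


class TestCouplingDegree:
    def test_equal_scores_maximize(self):
        assert coupling_degree(0.5, 0.5) == pytest.approx(1.0)

    def test_zero_factor_gives_zero(self):
        assert coupling_degree(0.8, 0.0) == 0.0
        assert coupling_degree(0.0, 0.0) == 0.0

    def test_hand_value(self):
        assert coupling_degree(0.9, 0.1) == pytest.approx(0.6)

    def test_symmetry_and_bound(self, rng):
        t = rng.uniform(0, 1, size=(100, 2))
        c12 = coupling_degree(t[:, 0], t[:, 1])
        c21 = coupling_degree(t[:, 1], t[:, 0])
        np.testing.assert_allclose(c12, c21)
        assert (c12 <= 1.0).all()

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            coupling_degree(-0.1, 0.5)


class TestCoordinationDegree:
    def test_equal_scores_collapse_to_score(self):
        assert coordination_degree(0.64, 0.64) == pytest.approx(0.64)
        assert coordination_degree(0.0, 0.0) == 0.0

    def test_hand_value(self):
        assert coordination_degree(0.9, 0.1) == pytest.approx(0.252)

    def test_alpha_beta_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            coordination_degree(0.5, 0.5, alpha=0.5, beta=0.6)

    def test_sqrt_variant(self):
        d = coordination_degree(0.64, 0.64, sqrt_variant=True)
        assert d == pytest.approx(0.8)

    def test_monotone_in_demand_score(self):
        grid = np.linspace(0.05, 1.0, 20)
        d = coordination_degree(np.full_like(grid, 0.3), grid)
        assert (np.diff(d) > 0).all()

    def test_bounded_by_max_score(self, rng):
        t1, t2 = rng.uniform(0, 1, 200), rng.uniform(0, 1, 200)
        d = coordination_degree(t1, t2)
        assert (d <= np.maximum(t1, t2) + 1e-12).all()


class TestClassify:
    @pytest.mark.parametrize(
        "d,level,category",
        [
            (0.8632, "Good balance", "excellent"),   # published Jiangsu average
            (0.1216, "Serious imbalance", "poor"),   # published Tibet average
            (0.4, "Close to imbalance", "medium"),   # half-open boundary
            (0.6, "Primary balance", "excellent"),
            (0.0, "Extreme imbalance", "poor"),
            (1.0, "Excellent balance", "excellent"), # top bin closed
        ],
    )
    def test_known_levels(self, d, level, category):
        assert classify(d) == (level, category)

    def test_out_of_range_rejected(self):
        for bad in (-0.01, 1.01, float("nan")):
            with pytest.raises(ValueError):
                classify(bad)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0.0, 1.0, allow_nan=False))
    def test_partition_of_unit_interval(self, d):
        """Every D gets exactly one level, and category follows the 0.4/0.6 cuts."""
        level, category = classify(d)
        if d < 0.4:
            assert category == "poor"
        elif d < 0.6:
            assert category == "medium"
        else:
            assert category == "excellent"


class TestCompositeScore:
    def make_std_w(self, weights, row):
        from eldercare_coupling.entropy import WeightVector
        from eldercare_coupling.standardize import StandardizedMatrix

        ids = [f"I{j}" for j in range(len(weights))]
        mat = pd.DataFrame([row], index=["R0"], columns=ids)
        std = StandardizedMatrix(2010, "supply", mat, [])
        w = WeightVector(2010, "supply", pd.Series(weights, index=ids),
                         pd.Series(0.5, index=ids), pd.Series(0.5, index=ids), mat)
        return std, w

    @pytest.mark.parametrize(
        "weights,row,expected",
        [((1.0, 0.0), (0.3, 0.9), 0.3),
         ((0.5, 0.5), (0.2, 0.8), 0.5),
         ((0.25, 0.75), (0.4, 0.8), 0.7)],
    )
    def test_hand_dot_products(self, weights, row, expected):
        std, w = self.make_std_w(weights, row)
        assert composite_score(std, w, "R0") == pytest.approx(expected)

    def test_mismatched_year_rejected(self):
        std, w = self.make_std_w((1.0,), (0.5,))
        w.year = 2011
        with pytest.raises(ValueError, match="match"):
            composite_score(std, w, "R0")


class TestPeriodMean:
    def test_published_row_means(self):
        ref = load_reference_coupling("observed").set_index("region")
        years = [c for c in ref.columns if isinstance(c, int)]
        assert round(period_mean(ref.loc["Beijing", years]), 4) == 0.6142
        assert round(period_mean(ref.loc["Jiangsu", years]), 4) == 0.8632
        assert matches_printed(period_mean(ref.loc["Heilongjiang", years]), 0.4280)

    def test_constant_series(self):
        assert period_mean([0.5] * 10) == 0.5

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            period_mean([])


class TestPipeline:
    def test_matches_brute_force_on_random_panels(self, rng):
        """Pipeline D equals the literal loop transcription on 5x2x2 panels."""
        specs = make_specs(2, 2)
        for _ in range(25):
            values = {
                (f"R{i}", 2010, s.id): float(rng.uniform(1, 100))
                for i in range(5) for s in specs
            }
            panel = make_panel(values, specs)
            table = coupling_table(panel)
            supply = [[values[(f"R{i}", 2010, "X1")], values[(f"R{i}", 2010, "X2")]]
                      for i in range(5)]
            demand = [[values[(f"R{i}", 2010, "Y1")], values[(f"R{i}", 2010, "Y2")]]
                      for i in range(5)]
            expected = bf_pipeline_d(supply, demand)
            np.testing.assert_allclose(table["D"].to_numpy(), expected, atol=1e-12)

    def test_d_matrix_layout(self, tiny_panel):
        table = coupling_table(tiny_panel)
        wide = d_matrix(table)
        assert list(wide.columns) == ["region", 2010, 2011, "average"]
        np.testing.assert_allclose(
            wide["average"], wide[[2010, 2011]].mean(axis=1))

    def test_classify_series_matches_scalar(self, tiny_panel):
        table = coupling_table(tiny_panel)
        frame = classify_series(table["D"])
        for d, lvl in zip(table["D"], frame["level"]):
            assert classify(d)[0] == lvl
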