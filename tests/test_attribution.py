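import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grassnpp import attribution
from grassnpp.attribution import (
    DEGRADED_CLASSES,
    RESTORED_CLASSES,
    aggregate,
    classify,
    human_npp,
    slope,
    slope_triple,
)
from grassnpp.io_config import GridSpec


class TestHumanNpp:
    def test_reported_regional_means(self):
        """Residual of the reported potential and actual regional means."""
        assert human_npp(704.1, 163.8) == pytest.approx(540.3, abs=1e-9)

    def test_identical_inputs_give_zero(self):
        assert human_npp(5.0, 5.0) == 0.0

    def test_algebraic_closure_on_grids(self, rng):
        np_, na = rng.uniform(0, 500, (2, 6, 6))
        nh = human_npp(np_, na)
        np.testing.assert_allclose(np_ - nh, na, rtol=1e-12)

    def test_mask_union_propagates(self):
        np_ = np.array([1.0, np.nan])
        na = np.array([np.nan, 1.0])
        assert np.isnan(human_npp(np_, na)).all()


class TestSlope:
    def test_constant_series_is_flat(self):
        assert slope(np.full(16, 7.0)) == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        i = np.arange(1, 17)
        assert slope(2.0 * i + 3.0) == pytest.approx(2.0, rel=1e-12)

    def test_matches_independent_least_squares_oracle(self, rng):
        series = rng.normal(50, 20, (1000, 16))
        ours = slope(series, axis=1)
        years = np.arange(1, 17)
        oracle = np.polyfit(years, series.T, 1)[0]
        np.testing.assert_allclose(ours, oracle, rtol=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            slope(np.array([1.0]))

    def test_masked_series_gives_masked_slope(self):
        s = np.full(16, 3.0)
        s[4] = np.nan
        assert np.isnan(slope(s))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5, 5), st.floats(-100, 100))
    def test_affine_series_slope_is_exact(self, b, a):
        y = a + b * np.arange(1, 17)
        assert slope(y) == pytest.approx(b, abs=1e-9 * max(1.0, abs(b)))


class TestClassify:
    @pytest.mark.parametrize(
        "sa, sp, expected",
        [
            (1.0, -0.5, 1),   # restoration, climate down -> human-driven
            (1.0, 2.0, 2),    # climate up more than actual -> climate-driven
            (2.0, 1.0, 3),    # both contribute -> climate-human
            (-1.0, 0.5, 4),   # degradation despite climate gain -> human
            (-1.0, -2.0, 5),  # climate fell harder than actual -> climate
            (-1.0, -0.5, 6),  # both fell -> climate-human
        ],
    )
    def test_residual_consistent_semantics(self, sa, sp, expected):
        assert classify(sa, sp)[()] == expected

    def test_zero_actual_slope_unclassified(self):
        assert classify(0.0, 1.0, epsilon=1e-6)[()] == 0

    def test_table_literal_matches_published_triples(self):
        # condition 1 of the published table: Sa>0, Sp<0, Sh>0
        assert classify(1.0, -1.0, 1.0, mode="table_literal")[()] == 1
        # the same pixel is unreachable under Sh = Sp - Sa
        assert classify(1.0, -1.0, -2.0, mode="table_literal")[()] == 0
        assert classify(-1.0, -0.5, -0.5, mode="table_literal")[()] == 6

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            classify(1.0, 1.0, mode="nope")

    def test_partition_no_pixel_in_two_classes(self, rng):
        sa = rng.normal(0, 1, 5000)
        sp = rng.normal(0, 1, 5000)
        cls = classify(sa, sp)
        assert set(np.unique(cls)) <= {0, 1, 2, 3, 4, 5, 6}
        # with epsilon=0 and continuous slopes every pixel is classified
        assert (cls > 0).all()
        # restoration/degradation split follows the sign of Sa
        assert np.isin(cls[sa > 0], RESTORED_CLASSES).all()
        assert np.isin(cls[sa < 0], DEGRADED_CLASSES).all()


class TestSlopeTriple:
    def test_linearity_identity(self, sim_run):
        tri = slope_triple(sim_run["actual"].annual, sim_run["np_annual"])
        scale = np.abs(tri.s_a) + np.abs(tri.s_p) + 1e-12
        assert np.all(np.abs(tri.s_h - (tri.s_p - tri.s_a)) <= 1e-9 * scale)


class TestAggregate:
    spec = GridSpec(2, 2, pixel_size=1000.0)

    def test_single_class_takes_whole_group(self):
        cmap = np.full((2, 2), 5, dtype=np.int8)
        na = np.full((2, 2), 100.0)
        df = aggregate(cmap, na, self.spec).set_index("class")
        assert df.loc[5, "area_pct_of_group"] == 100.0
        assert df.loc[5, "pixel_count"] == 4

    def test_gigagram_unit_conversion(self):
        """One 1 km^2 pixel at 100 g C m^-2 a^-1 holds 0.1 Gg C a^-1."""
        cmap = np.array([[1, 0], [0, 0]], dtype=np.int8)
        na = np.full((2, 2), 100.0)
        df = aggregate(cmap, na, self.spec).set_index("class")
        assert df.loc[1, "npp_total_GgC"] == pytest.approx(0.1)

    def test_group_fractions_sum_to_hundred(self, rng):
        cmap = rng.integers(0, 7, (30, 30)).astype(np.int8)
        na = rng.uniform(0, 300, (30, 30))
        df = aggregate(cmap, na, GridSpec(30, 30))
        restored = df[df["class"].isin(RESTORED_CLASSES)]["area_pct_of_group"].sum()
        degraded = df[df["class"].isin(DEGRADED_CLASSES)]["area_pct_of_group"].sum()
        assert restored == pytest.approx(100.0, abs=1e-9)
        assert degraded == pytest.approx(100.0, abs=1e-9)

    def test_class_totals_sum_to_classified_total(self, rng):
        cmap = rng.integers(0, 7, (20, 20)).astype(np.int8)
        na = rng.uniform(0, 300, (20, 20))
        df = aggregate(cmap, na, GridSpec(20, 20))
        expected = na[cmap > 0].sum() * 1e6 / 1e9
        assert df["npp_total_GgC"].sum() == pytest.approx(expected, rel=1e-12)


def test_attribute_residual_identity_bit_exact(sim_run):
    res = attribution.attribute(
        sim_run["actual"].annual, sim_run["np_annual"], sim_run["params"].grid
    )
    diff = sim_run["np_annual"] - sim_run["actual"].annual - res.nh
    assert np.all(diff == 0.0)
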