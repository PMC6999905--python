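import numpy as np
import pytest
from scipy import stats

from nof1serial.correlation import ZeroVarianceError
from nof1serial.serial_tests import (
    ObservationSeries,
    PairedDifferenceSeries,
    p_value_and_ci,
    paired_serial_level,
    paired_serial_rate,
    screen_change,
    two_sample_serial_level,
    two_sample_serial_rate,
    usual_paired_level,
    usual_paired_rate,
    usual_two_sample_level,
    usual_two_sample_rate,
)


class TestPairedLevel:
    def test_patient_18_one_sided(self, patient_18):
        res = paired_serial_level(patient_18.array("diff"), direction="greater")
        assert res.p_one_sided == pytest.approx(0.02, abs=0.01)

    def test_worked_example_difference_row(self, patient_1390):
        res = paired_serial_level(patient_1390.array("diff"))
        assert round(res.t, 2) == patient_1390.references["level_paired_t"]
        assert round(res.df, 2) == patient_1390.references["level_paired_df"]
        assert round(float(np.sqrt(res.s2)), 1) == patient_1390.references["level_paired_s"]
        assert round(res.r_used, 2) == patient_1390.references["level_paired_r"]

    def test_minimum_m(self):
        with pytest.raises(ValueError, match="m >= 4"):
            paired_serial_level([1.0, 2.0, 3.0])

    def test_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            paired_serial_level([2.0, 2.0, 2.0, 2.0])


class TestTwoSampleLevel:
    def test_worked_example(self, patient_1390):
        res = two_sample_serial_level(patient_1390.array("pre"), patient_1390.array("post"))
        assert round(res.t, 2) == patient_1390.references["level_two_sample_t"]
        assert round(res.df, 2) == patient_1390.references["level_two_sample_df"]
        assert round(float(np.sqrt(res.s2)), 1) == patient_1390.references["level_two_sample_s"]
        assert round(res.r_used, 2) == patient_1390.references["level_two_sample_r"]

    def test_size_rules(self):
        with pytest.raises(ValueError, match="at least 3"):
            two_sample_serial_level([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(ValueError, match=">= 7"):
            two_sample_serial_level([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])


class TestPairedRate:
    def test_worked_example_scale_and_r(self, patient_1390):
        res = paired_serial_rate(patient_1390.array("diff"))
        assert round(res.t, 2) == patient_1390.references["rate_paired_t"]
        assert round(float(np.sqrt(res.s2)), 1) == patient_1390.references["rate_paired_s"]
        assert round(res.r_used, 2) == patient_1390.references["rate_paired_r"]

    def test_minimum_m(self):
        with pytest.raises(ValueError, match="m >= 5"):
            paired_serial_rate([1.0, 2.0, 1.0, 2.0])

    def test_perfectly_linear_degenerate(self):
        with pytest.raises(ZeroVarianceError):
            paired_serial_rate([1.0, 2.0, 3.0, 4.0, 5.0])


class TestTwoSampleRate:
    def test_worked_example_scale_and_r(self, patient_1390):
        res = two_sample_serial_rate(patient_1390.array("pre"), patient_1390.array("post"))
        assert round(float(np.sqrt(res.s2)), 1) == patient_1390.references["rate_two_sample_s"]
        assert round(res.r_used, 2) == patient_1390.references["rate_two_sample_r"]

    def test_size_rules(self):
        with pytest.raises(ValueError, match="at least 4"):
            two_sample_serial_rate([1.0, 2.0, 4.0], [1.0, 5.0, 3.0, 4.0, 2.0, 6.0])
        with pytest.raises(ValueError, match=">= 9"):
            two_sample_serial_rate([1.0, 5.0, 2.0, 4.0], [4.0, 1.0, 6.0, 3.0])


class TestUsualAnalogues:
    def test_patient_9_footnote_p(self, fibro_patient):
        res = usual_paired_level(fibro_patient.array("diff"), direction="greater")
        assert res.p_one_sided == pytest.approx(
            fibro_patient.references["usual_p_one_sided"], abs=0.01
        )

    def test_patient_17_p(self):
        res = usual_paired_level([-0.08, 0.86, 1.07, 1.15], direction="greater")
        assert res.p_one_sided == pytest.approx(0.04, abs=0.01)

    def test_symmetric_data_two_sided_p_one(self):
        res = usual_paired_level([-1.0, 1.0, -2.0, 2.0])
        assert res.t == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_scipy_one_sample(self, rng):
        y = rng.normal(0.5, 1.0, size=9)
        res = usual_paired_level(y)
        t_ref, p_ref = stats.ttest_1samp(y, 0.0)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-10)

    def test_matches_scipy_two_sample(self, rng):
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        res = usual_two_sample_level(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b)
        assert res.t == pytest.approx(t_ref, rel=1e-12)
        assert res.p_two_sided == pytest.approx(p_ref, rel=1e-10)

    def test_matches_scipy_slope(self, rng):
        y = rng.normal(0, 1, 10) + 0.3 * np.arange(10)
        res = usual_paired_rate(y)
        fit = stats.linregress(np.arange(1, 11), y)
        assert res.estimate == pytest.approx(fit.slope, rel=1e-12)
        assert res.p_two_sided == pytest.approx(fit.pvalue, rel=1e-10)


class TestRhoZeroReduction:
    """With the correlation overridden to zero every serial test must equal
    its usual analogue exactly."""

    def test_paired_level(self, rng):
        y = rng.normal(0, 1, 7)
        s = paired_serial_level(y, rho=0.0)
        u = usual_paired_level(y)
        for attr in ("t", "df", "p_one_sided", "p_two_sided", "ci_lower", "ci_upper"):
            assert getattr(s, attr) == pytest.approx(getattr(u, attr), abs=1e-12)

    def test_paired_rate(self, rng):
        y = rng.normal(0, 1, 8)
        s = paired_serial_rate(y, rho=0.0)
        u = usual_paired_rate(y)
        for attr in ("t", "df", "p_one_sided", "p_two_sided", "ci_lower", "ci_upper"):
            assert getattr(s, attr) == pytest.approx(getattr(u, attr), abs=1e-12)

    def test_two_sample_level(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 5)
        s = two_sample_serial_level(a, b, rho=0.0)
        u = usual_two_sample_level(a, b)
        for attr in ("t", "df", "p_one_sided", "p_two_sided", "ci_lower", "ci_upper"):
            assert getattr(s, attr) == pytest.approx(getattr(u, attr), abs=1e-12)

    def test_two_sample_rate(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(0, 1, 5)
        s = two_sample_serial_rate(a, b, rho=0.0)
        u = usual_two_sample_rate(a, b)
        for attr in ("t", "df", "p_one_sided", "p_two_sided", "ci_lower", "ci_upper"):
            assert getattr(s, attr) == pytest.approx(getattr(u, attr), abs=1e-12)


class TestInvariances:
    def test_shift_leaves_rate_unchanged(self, rng):
        y = rng.normal(0, 1, 8)
        base = paired_serial_rate(y)
        shifted = paired_serial_rate(y + 100.0)
        assert shifted.t == pytest.approx(base.t, rel=1e-9)
        assert shifted.df == pytest.approx(base.df, rel=1e-9)

    def test_shift_moves_level_estimate_only(self, rng):
        y = rng.normal(0, 1, 8)
        base = paired_serial_level(y)
        shifted = paired_serial_level(y + 3.0)
        assert shifted.estimate == pytest.approx(base.estimate + 3.0, rel=1e-9)
        assert shifted.s2 == pytest.approx(base.s2, rel=1e-9)

    def test_scale_equivariance(self, rng):
        y = rng.normal(0.4, 1, 8)
        k = 2.5
        base = paired_serial_level(y)
        scaled = paired_serial_level(k * y)
        assert scaled.t == pytest.approx(base.t, rel=1e-10)
        assert scaled.df == pytest.approx(base.df, rel=1e-10)
        assert scaled.p_two_sided == pytest.approx(base.p_two_sided, rel=1e-9)
        assert scaled.estimate == pytest.approx(k * base.estimate, rel=1e-10)
        assert scaled.ci_upper == pytest.approx(k * base.ci_upper, rel=1e-9)

    def test_arm_swap_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 7), rng.normal(0.8, 1, 6)
        fwd = two_sample_serial_level(a, b)
        rev = two_sample_serial_level(b, a)
        assert rev.t == pytest.approx(-fwd.t, rel=1e-10)
        assert rev.estimate == pytest.approx(-fwd.estimate, rel=1e-10)
        assert rev.df == pytest.approx(fwd.df, rel=1e-10)
        assert rev.p_two_sided == pytest.approx(fwd.p_two_sided, rel=1e-9)

    def test_positive_r_tempers_inference(self, patient_1390):
        # positive estimated correlation: fewer effective observations and a
        # larger standard error than the usual analogue
        pre, post = patient_1390.array("pre"), patient_1390.array("post")
        serial = two_sample_serial_level(pre, post)
        usual = usual_two_sample_level(pre, post)
        assert serial.r_used > 0
        assert serial.df < usual.df
        assert serial.se > usual.se


class TestPValueAndCi:
    def test_t_zero_two_sided(self):
        _, p_two, _ = p_value_and_ci(0.0, 3.7, "greater", 0.95, 0.0, 1.0)
        assert p_two == pytest.approx(1.0)

    def test_known_quantile(self):
        # 90% CI at 3 df uses the 95th percentile of t
        _, _, (lo, hi) = p_value_and_ci(0.0, 3.0, "greater", 0.90, 0.0, 1.0)
        assert hi == pytest.approx(2.3534, abs=5e-5)
        assert lo == pytest.approx(-2.3534, abs=5e-5)

    def test_directions_complementary(self):
        pg, _, _ = p_value_and_ci(1.3, 5.2, "greater", 0.95, 1.0, 0.5)
        pl, _, _ = p_value_and_ci(1.3, 5.2, "less", 0.95, 1.0, 0.5)
        assert pg + pl == pytest.approx(1.0)

    def test_df_error(self):
        with pytest.raises(ValueError):
            p_value_and_ci(1.0, 0.0, "greater", 0.95, 1.0, 1.0)


class TestScreenChange:
    def test_no_change_for_worked_example(self, patient_1390):
        out = screen_change(patient_1390.array("pre"), patient_1390.array("post"))
        assert not out["changed"]

    def test_detects_strong_level_shift(self, rng):
        a = rng.normal(0, 0.2, 8)
        b = rng.normal(10, 0.2, 8)
        out = screen_change(a, b)
        assert out["level_change"]
        assert out["changed"]

    def test_paired_route(self, rng):
        a = rng.normal(5, 0.3, 8)
        b = rng.normal(0, 0.3, 8)
        out = screen_change(a, b, paired=True)
        assert out["changed"]


def test_series_types_validate():
    with pytest.raises(ValueError):
        ObservationSeries(np.array([1.0, np.nan, 2.0]))
    with pytest.raises(ValueError):
        PairedDifferenceSeries.from_arms(
            ObservationSeries(np.arange(4.0)), ObservationSeries(np.arange(5.0))
        )


def test_result_to_dict_roundtrip(patient_1390):
    res = paired_serial_level(patient_1390.array("diff"))
    d = res.to_dict()
    assert d["design"] == "paired_level"
    assert d["df"] == pytest.approx(res.df)
    assert d["kernels"][0]["m"] == 8
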