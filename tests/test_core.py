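"""Assay arithmetic: percent remaining, calibration lines, elemental ratios."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radkin import (
    DPPH_CALIBRATION,
    GLV_CALIBRATION,
    CalibrationCurve,
    ElementalComposition,
    KineticTrace,
    Radical,
    SampleSpec,
    SOParams,
    Source,
    absorbance_to_concentration,
    concentration_to_absorbance,
    elemental_ratios,
    fit_calibration,
    percent_remaining,
    read_calibration,
    read_trace,
    so_model,
    trace_to_percent,
    write_calibration,
    write_trace,
)
from radkin.core import (
    DegenerateDesignError,
    InvalidCalibrationError,
    InvalidReferenceError,
    ValidationError,
)


class TestPercentRemaining:
    @pytest.mark.parametrize(
        "a_t,a_0,expected",
        [
            (1.1219, 1.1219, 100.0),  # identity at the DPPH assay A0
            (1.1720, 1.1720, 100.0),
            (0.0, 1.1720, 0.0),  # fully quenched
            (0.5610, 1.1219, 100.0 * 0.5610 / 1.1219),  # ~50.0045%
        ],
    )
    def test_values(self, a_t, a_0, expected):
        assert percent_remaining(a_t, a_0) == pytest.approx(expected, abs=1e-9)

    def test_values_above_100_are_not_clamped(self):
        assert percent_remaining(1.2, 1.0) == pytest.approx(120.0)

    @pytest.mark.parametrize("a_0", [0.0, -1.0, float("nan"), float("inf")])
    def test_bad_reference(self, a_0):
        with pytest.raises(InvalidReferenceError):
            percent_remaining(0.5, a_0)

    def test_nonfinite_absorbance(self):
        with pytest.raises(ValidationError):
            percent_remaining(float("nan"), 1.0)

    @given(
        a=st.floats(0.0, 10.0),
        c=st.floats(0.0, 5.0),
        a0=st.floats(0.1, 5.0),
    )
    def test_linearity_in_a_t(self, a, c, a0):
        lhs = percent_remaining(c * a, a0)
        rhs = c * percent_remaining(a, a0)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-9)


class TestTraceToPercent:
    def test_constant_trace_is_100(self):
        tr = KineticTrace(
            times=np.arange(5.0), absorbance=np.full(5, 1.1219), radical=Radical.DPPH
        )
        out = trace_to_percent(tr)
        assert out.shape == (5, 2)
        assert np.allclose(out[:, 1], 100.0)

    def test_halved_trace_is_50(self):
        tr = KineticTrace(
            times=np.arange(4.0),
            absorbance=np.full(4, 1.1720 / 2),
            radical=Radical.GLV,
        )
        assert np.allclose(trace_to_percent(tr)[:, 1], 50.0)

    def test_so_trace_starts_at_100(self, grid):
        p = SOParams(k=0.001, ar0=1.0, aah0=1.5)
        tr = KineticTrace(
            times=grid, absorbance=so_model(grid, p), radical=Radical.DPPH,
            a0_reference=1.0,
        )
        assert trace_to_percent(tr)[0, 1] == pytest.approx(100.0)


class TestCalibration:
    def test_intercept_maps_to_zero(self):
        assert absorbance_to_concentration(0.0315, DPPH_CALIBRATION) == pytest.approx(
            0.0, abs=1e-12
        )
        assert absorbance_to_concentration(0.0471, GLV_CALIBRATION) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_unit_concentration(self):
        # 8.7200 = 8.6885 * 1 + 0.0315 by construction
        assert absorbance_to_concentration(8.7200, DPPH_CALIBRATION) == pytest.approx(
            1.0, rel=1e-12
        )

    @given(
        slope=st.floats(0.1, 50.0),
        intercept=st.floats(-1.0, 1.0),
        x=st.floats(-10.0, 10.0),
    )
    def test_roundtrip_identity(self, slope, intercept, x):
        cal = CalibrationCurve(Radical.DPPH, slope, intercept)
        y = concentration_to_absorbance(x, cal)
        assert absorbance_to_concentration(y, cal) == pytest.approx(x, abs=1e-12, rel=1e-12)

    @pytest.mark.parametrize(
        "slope,intercept,radical",
        [(8.6885, 0.0315, Radical.DPPH), (18.465, 0.0471, Radical.GLV)],
    )
    def test_exact_line_recovery(self, slope, intercept, radical):
        x = np.linspace(0.01, 0.12, 8)
        pts = [(xi, slope * xi + intercept) for xi in x]
        cal = fit_calibration(pts, radical)
        assert cal.slope == pytest.approx(slope, abs=1e-9)
        assert cal.intercept == pytest.approx(intercept, abs=1e-9)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_matches_polyfit_oracle(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.01, 0.12, 20)
        y = 8.6885 * x + 0.0315 + rng.normal(0, 0.01, x.size)
        cal = fit_calibration(list(zip(x, y)), Radical.DPPH)
        slope_oracle, intercept_oracle = np.polyfit(x, y, 1)
        assert cal.slope == pytest.approx(slope_oracle, rel=1e-10)
        assert cal.intercept == pytest.approx(intercept_oracle, rel=1e-8)
        assert abs(cal.slope - 8.6885) < 0.2

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_calibration([(0.1, 1.0), (0.1, 1.1), (0.1, 0.9)], Radical.DPPH)

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_calibration([(0.1, 1.0), (0.2, 2.0)], Radical.DPPH)

    def test_negative_slope_rejected(self):
        with pytest.raises(InvalidCalibrationError):
            CalibrationCurve(Radical.DPPH, -1.0, 0.0)


class TestElementalRatios:
    FLOWER = ElementalComposition(pct_c=43.75, pct_h=6.32, pct_n=3.37)
    FRUIT = ElementalComposition(pct_c=49.27, pct_h=6.95, pct_n=1.19)

    def test_flower_mass_ratios(self):
        r = elemental_ratios(self.FLOWER)
        assert r.h_over_c_mass == pytest.approx(6.32 / 43.75, rel=1e-12)
        assert r.n_over_c_mass == pytest.approx(3.37 / 43.75, rel=1e-12)

    def test_fruit_mass_ratios(self):
        r = elemental_ratios(self.FRUIT)
        assert r.n_over_c_mass == pytest.approx(1.19 / 49.27, rel=1e-12)

    def test_molar_basis_unit_case(self):
        r = elemental_ratios(ElementalComposition(12.011, 1.008, 0.0))
        assert r.h_over_c_molar == pytest.approx(1.0, rel=1e-12)
        assert r.n_over_c_molar == 0.0

    def test_flower_vs_fruit_qualitative_pattern(self):
        """Flowers are nitrogen-richer per carbon; H/C is nearly identical."""
        rf = elemental_ratios(self.FLOWER)
        ro = elemental_ratios(self.FRUIT)
        assert rf.n_over_c_mass > ro.n_over_c_mass
        assert abs(rf.h_over_c_mass - ro.h_over_c_mass) < 0.01

    def test_zero_carbon_rejected(self):
        with pytest.raises(ValidationError):
            elemental_ratios(ElementalComposition(0.0, 1.0, 1.0))


class TestKineticTrace:
    def test_defaults_filled_per_radical(self):
        tr = KineticTrace(np.arange(3.0), np.ones(3), Radical.GLV)
        assert tr.a0_reference == 1.1720
        assert tr.wavelength == 428.0

    @pytest.mark.parametrize(
        "times,absorbance",
        [
            (np.arange(2.0), np.ones(2)),  # too short
            (np.array([0.0, 1.0, 1.0]), np.ones(3)),  # non-increasing
            (np.array([-1.0, 0.0, 1.0]), np.ones(3)),  # negative time
            (np.arange(3.0), np.array([1.0, np.nan, 1.0])),  # non-finite
            (np.arange(3.0), np.ones(4)),  # length mismatch
        ],
    )
    def test_invalid_traces_rejected(self, times, absorbance):
        with pytest.raises(ValidationError):
            KineticTrace(times, absorbance, Radical.DPPH)

    def test_wavelength_radical_consistency(self):
        with pytest.raises(ValidationError):
            KineticTrace(np.arange(3.0), np.ones(3), Radical.DPPH, wavelength=428.0)


class TestSampleSpec:
    def test_volumes_derived_from_level(self):
        spec = SampleSpec(Source.FLOWER, 1.5)
        assert spec.infusion_volume_ml == 1.5
        assert spec.water_volume_ml == 8.5
        assert spec.radical_solution_ml == 3.0

    @pytest.mark.parametrize(
        "source,level,radical,expected",
        [
            (Source.FLOWER, 1.0, Radical.DPPH, "KDPPH1.0"),
            (Source.FRUIT, 2.5, Radical.GLV, "OGL2.5"),
        ],
    )
    def test_acronyms(self, source, level, radical, expected):
        assert SampleSpec(source, level).acronym(radical) == expected

    def test_invalid_level(self):
        with pytest.raises(ValidationError):
            SampleSpec(Source.FLOWER, 3.0)


class TestIO:
    def test_trace_roundtrip(self, tmp_path, noiseless_so_trace):
        path = write_trace(noiseless_so_trace, tmp_path / "t.csv")
        back = read_trace(path)
        assert np.allclose(back.times, noiseless_so_trace.times)
        assert np.allclose(back.absorbance, noiseless_so_trace.absorbance)
        assert back.radical == noiseless_so_trace.radical
        assert back.a0_reference == noiseless_so_trace.a0_reference

    def test_missing_sidecar(self, tmp_path):
        p = tmp_path / "x.csv"
        p.write_text("time_s,absorbance\n0,1\n1,0.9\n2,0.8\n")
        with pytest.raises(ValidationError):
            read_trace(p)

    def test_calibration_roundtrip(self, tmp_path):
        path = write_calibration(DPPH_CALIBRATION, tmp_path / "cal.json")
        back = read_calibration(path)
        assert back == DPPH_CALIBRATION
        assert json.loads(path.read_text())["slope"] == 8.6885
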