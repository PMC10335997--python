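"""Q10dB and QERB tuning metrics against closed-form fixtures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpoaewave.interference import PropagationOptions, RatioFunction
from dpoaewave.synthetic import APICAL_BM, SiteProfile, generate_frequency_response
from dpoaewave.tuning import (
    TuningUndefinedError,
    average_tuning,
    nonlinear_gain,
    q10,
    qerb,
    ratio_function_tuning,
)


def db_to_amp(db):
    return 10.0 ** (np.asarray(db) / 20.0)


class TestQ10:
    def test_piecewise_linear_triangle(self):
        """0 dB at 9 kHz falling to -10 dB at 8 and 10 kHz gives Q10 = 4.5."""
        freqs = np.array([8000.0, 9000.0, 10000.0])
        amps = db_to_amp([-10.0, 0.0, -10.0])
        res = q10(freqs, amps, log_axis=False)
        assert res.q10 == pytest.approx(9.0 / 2.0, rel=1e-9)
        assert res.bw10 == pytest.approx(2000.0, rel=1e-9)

    def test_parabola_in_db(self):
        """-10*((f-9)/1)^2 dB crosses -10 dB at 8 and 10 kHz: Q10 = 4.5."""
        freqs = np.linspace(7000.0, 11000.0, 801)
        amps = db_to_amp(-10.0 * ((freqs - 9000.0) / 1000.0) ** 2)
        res = q10(freqs, amps, log_axis=False)
        assert res.q10 == pytest.approx(4.5, rel=1e-4)

    def test_monotone_curve_flagged_undefined(self):
        freqs = np.linspace(1000.0, 2000.0, 11)
        res = q10(freqs, freqs.copy())
        assert not res.q10_defined
        assert math.isnan(res.q10)

    def test_shallow_flank_flagged_undefined(self):
        freqs = np.array([8000.0, 9000.0, 10000.0])
        amps = db_to_amp([-5.0, 0.0, -10.0])
        res = q10(freqs, amps)
        assert not res.q10_defined

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3), st.booleans())
    def test_amplitude_scale_and_axis_unit_invariance(self, scale, khz):
        freqs = np.linspace(7000.0, 11000.0, 401)
        amps = db_to_amp(-10.0 * ((freqs - 9000.0) / 1000.0) ** 2)
        base = q10(freqs, amps).q10
        f2 = freqs / 1000.0 if khz else freqs
        assert q10(f2, amps * scale).q10 == pytest.approx(base, rel=1e-9)

    def test_log_translation_invariance(self):
        """A fixed shape translated in log-frequency keeps its Q10."""
        nu = np.linspace(-1.0, 1.0, 801)
        amps = db_to_amp(-30.0 * nu**2)
        q_a = q10(1000.0 * 2.0**nu, amps).q10
        q_b = q10(7350.0 * 2.0**nu, amps).q10
        assert q_b == pytest.approx(q_a, rel=1e-9)


class TestQERB:
    def test_rectangle(self):
        """A flat-top band from 8 to 10 kHz has ERB = 2 kHz."""
        freqs = np.arange(7000.0, 11000.0, 10.0)
        amps = np.where((freqs >= 8000.0) & (freqs <= 10000.0), 1.0, 0.0)
        res = qerb(freqs, amps)
        assert res.erb == pytest.approx(2000.0, rel=0.01)

    def test_gaussian_closed_form(self):
        """Squared normalised Gaussian integrates to sigma*sqrt(pi)."""
        sigma = 1000.0
        freqs = np.arange(4000.0, 14000.0, 10.0)
        amps = np.exp(-((freqs - 9000.0) ** 2) / (2 * sigma**2))
        res = qerb(freqs, amps)
        assert res.erb == pytest.approx(sigma * math.sqrt(math.pi), rel=0.005)
        assert res.q_erb == pytest.approx(9000.0 / (sigma * math.sqrt(math.pi)), rel=0.005)

    def test_scale_invariance(self):
        freqs = np.arange(4000.0, 14000.0, 10.0)
        amps = np.exp(-((freqs - 9000.0) ** 2) / (2 * 1000.0**2))
        a = qerb(freqs, amps)
        b = qerb(freqs, amps * 37.2)
        assert b.q_erb == pytest.approx(a.q_erb, rel=1e-12)

    def test_truncation_warning(self):
        freqs = np.linspace(8500.0, 9500.0, 101)
        amps = np.exp(-((freqs - 9000.0) ** 2) / (2 * 1000.0**2))
        with pytest.warns(RuntimeWarning, match="truncation"):
            res = qerb(freqs, amps)
        assert res.erb_truncated

    def test_narrower_curves_sharper(self):
        """Nested Gaussians: smaller sigma gives strictly larger Q10 and QERB."""
        freqs = np.arange(2000.0, 16000.0, 10.0)
        prev_q10, prev_qerb = 0.0, 0.0
        for sigma in (2000.0, 1000.0, 500.0):
            amps = np.exp(-((freqs - 9000.0) ** 2) / (2 * sigma**2))
            r10 = q10(freqs, amps)
            rerb = qerb(freqs, amps)
            assert r10.q10 > prev_q10 and rerb.q_erb > prev_qerb
            prev_q10, prev_qerb = r10.q10, rerb.q_erb


class TestRatioFunctionTuning:
    @staticmethod
    def _make_rf(ratios, amps, f2=9000.0):
        ratios = np.asarray(ratios, dtype=float)
        f1 = f2 / ratios
        return RatioFunction(
            f2=f2, level1=50.0, level2=50.0, ratios=ratios, f1=f1,
            f_dp=2 * f1 - f2, dpoae=np.asarray(amps, dtype=complex),
            options=PropagationOptions(),
        )

    def test_analyzed_versus_dp_frequency(self):
        """A peak at ratio 1.295 sits at f_dp = 2*9000/1.295 - 9000 = 4.90 kHz."""
        ratios = np.arange(1.02, 1.87, 0.025)
        f_dp = 2 * 9000.0 / ratios - 9000.0
        peak_fdp = 2 * 9000.0 / 1.295 - 9000.0
        amps = np.exp(-((f_dp - peak_fdp) ** 2) / (2 * 800.0**2))
        res = ratio_function_tuning(self._make_rf(ratios, amps))
        assert res.f_max == pytest.approx(4900.0, abs=30.0)
        assert res.optimal_ratio == pytest.approx(1.295, abs=0.013)

    def test_symmetric_bandpass_centered(self):
        ratios = np.arange(1.02, 1.87, 0.025)
        f_dp = 2 * 9000.0 / ratios - 9000.0
        amps = np.exp(-((f_dp - 6000.0) ** 2) / (2 * 700.0**2))
        res = ratio_function_tuning(self._make_rf(ratios, amps), log_axis=False)
        # f_max is quantised to the f_dp grid (~310 Hz spacing near 6 kHz)
        assert res.f_max == pytest.approx(6000.0, abs=160.0)

    def test_tie_broken_to_smallest_ratio(self):
        ratios = np.array([1.1, 1.2, 1.3, 1.4])
        amps = np.array([0.5, 1.0, 1.0, 0.2])
        res = ratio_function_tuning(self._make_rf(ratios, amps))
        assert res.optimal_ratio == pytest.approx(1.1 + 0.1)


class TestNonlinearGain:
    def test_linear_response_has_zero_gain(self):
        fr = generate_frequency_response(SiteProfile(gain_max=0.0))
        assert nonlinear_gain(fr) == pytest.approx(0.0, abs=1e-9)

    def test_default_apical_gain(self):
        fr = generate_frequency_response(APICAL_BM)
        assert nonlinear_gain(fr) == pytest.approx(41.1, abs=1.0)

    def test_missing_levels_rejected(self):
        fr = generate_frequency_response(APICAL_BM, levels=np.array([40.0, 60.0]))
        with pytest.raises(ValueError):
            nonlinear_gain(fr)


class TestAverageTuning:
    def test_mean_of_two(self):
        freqs = np.linspace(7000.0, 11000.0, 401)
        a = q10(freqs, db_to_amp(-10 * ((freqs - 9000) / 1000.0) ** 2))
        b = q10(freqs, db_to_amp(-10 * ((freqs - 9000) / 1500.0) ** 2))
        avg = average_tuning([a, b])
        assert avg.q10 == pytest.approx((a.q10 + b.q10) / 2)

    def test_identity_for_single_input(self):
        freqs = np.linspace(7000.0, 11000.0, 401)
        a = q10(freqs, db_to_amp(-10 * ((freqs - 9000) / 1000.0) ** 2))
        assert average_tuning([a]).q10 == pytest.approx(a.q10)

    def test_undefined_member_rejected(self):
        freqs = np.linspace(1000.0, 2000.0, 11)
        bad = q10(freqs, freqs.copy())
        with pytest.raises(TuningUndefinedError):
            average_tuning([bad])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_tuning([])
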