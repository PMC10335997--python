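"""Propagation, vector summation and the model's interference phenomenology."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dpoaewave.interference import (
    PropagationOptions,
    default_ratio_grid,
    local_dp_ratio_function,
    phase_spread,
    propagate_to_stapes,
    ratio_function,
    sum_dpoae,
)
from dpoaewave.placemap import PlaceMap, spatial_response
from dpoaewave.spectral import round_frequency
from dpoaewave.synthetic import APICAL_BM, FrequencyResponse, model_reference_grid
from dpoaewave.synthetic import generate_frequency_response
from dpoaewave.transducer import LocalDPField, local_dp


def flat_reference(mag=1.0, phase=0.0):
    """Reference response that is constant over frequency and level, so the
    slow-wave weight is exactly `mag` and the propagation phase `phase`."""
    freqs = np.arange(100.0, 90001.0, 100.0)
    levels = np.array([40.0, 50.0])
    return FrequencyResponse(
        site=APICAL_BM,
        freqs=freqs,
        levels=levels,
        magnitude=np.full((2, freqs.size), mag),
        phase=np.full((2, freqs.size), phase),
        includes_middle_ear=False,
    )


def make_dps(positions, values, f_dp=5000.0):
    return LocalDPField(
        positions=np.asarray(positions, dtype=float),
        f_dp=f_dp,
        dp_generated=np.asarray(values, dtype=complex),
    )


class TestPropagateToStapes:
    def test_unit_weight_zero_phase_is_identity(self):
        dps = make_dps([3.0, 4.0], [1 + 2j, -0.5j])
        out = propagate_to_stapes(dps, flat_reference(1.0, 0.0), PlaceMap())
        assert np.allclose(out.dp_stapes, dps.dp_generated)

    def test_fast_wave_is_identity(self):
        dps = make_dps([3.0, 4.0], [1 + 2j, -0.5j])
        out = propagate_to_stapes(
            dps, flat_reference(0.123, -0.4), PlaceMap(), PropagationOptions(mode="fast_wave")
        )
        assert np.allclose(out.dp_stapes, dps.dp_generated)

    def test_magnitude_and_phase_weighting(self):
        dps = make_dps([4.0], [2.0 + 0j])
        out = propagate_to_stapes(dps, flat_reference(0.5, -0.25), PlaceMap())
        assert abs(out.dp_stapes[0]) == pytest.approx(1.0, rel=1e-12)
        assert np.angle(out.dp_stapes[0]) / (2 * np.pi) == pytest.approx(-0.25, abs=1e-12)

    def test_velocity_weighting_scales_by_angular_frequency(self):
        dps = make_dps([4.0], [1.0 + 0j], f_dp=5000.0)
        disp = propagate_to_stapes(dps, flat_reference(0.5, 0.0), PlaceMap())
        vel = propagate_to_stapes(
            dps, flat_reference(0.5, 0.0), PlaceMap(), PropagationOptions(weighting="velocity")
        )
        assert abs(vel.dp_stapes[0]) == pytest.approx(
            abs(disp.dp_stapes[0]) * 2 * np.pi * 5000.0, rel=1e-12
        )


class TestSumDpoae:
    def test_antiphase_components_cancel(self):
        dps = make_dps([3.0, 4.0], [1.0, -1.0])
        dps = propagate_to_stapes(dps, flat_reference(), PlaceMap())
        assert abs(sum_dpoae(dps)) < 1e-14

    def test_in_phase_components_add(self):
        n, m = 7, 0.3
        dps = make_dps(np.linspace(3, 4, n), np.full(n, m) * np.exp(0.25j))
        dps = propagate_to_stapes(dps, flat_reference(), PlaceMap())
        assert abs(sum_dpoae(dps)) == pytest.approx(n * m, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.complex_numbers(max_magnitude=10, allow_nan=False), min_size=1, max_size=20))
    def test_zero_phase_control_bounds_coherent_sum(self, values):
        dps = make_dps(np.arange(len(values), dtype=float) * 0.1 + 1.0, values)
        dps = propagate_to_stapes(dps, flat_reference(), PlaceMap())
        coherent = abs(sum_dpoae(dps))
        zero_phase = abs(sum_dpoae(dps, PropagationOptions(zero_phase_control=True)))
        assert zero_phase >= coherent - 1e-9

    def test_empty_rejected(self):
        dps = make_dps([], [])
        with pytest.raises(ValueError):
            sum_dpoae(dps)


class TestPhaseSpread:
    def test_single_location_zero(self):
        dps = make_dps([4.0], [1.0 + 0j])
        dps = propagate_to_stapes(dps, flat_reference(), PlaceMap())
        assert phase_spread(dps) == 0.0

    def test_two_locations_hand_value(self):
        """In-region phases of -0.2 and -0.9 cycles spread over 0.7 cycles."""
        phases = np.array([-0.2, -0.9])
        dps = LocalDPField(
            positions=np.array([3.9, 4.0]),
            f_dp=5000.0,
            dp_generated=np.array([1.0, 1.0], dtype=complex),
            dp_stapes=np.exp(2j * np.pi * phases),
            stapes_phase=phases,
        )
        assert phase_spread(dps) == pytest.approx(0.7, abs=1e-9)

    def test_region_restricted_to_10db_of_max(self):
        """Locations more than 10 dB below the peak |DP| are excluded."""
        mags = np.array([1e-3, 1.0, 0.9, 1e-3])
        phases = np.array([10.0, -0.1, -0.3, -20.0])
        dps = LocalDPField(
            positions=np.array([3.7, 3.8, 3.9, 4.0]),
            f_dp=5000.0,
            dp_generated=mags.astype(complex),
            dp_stapes=mags * np.exp(2j * np.pi * phases),
            stapes_phase=phases,
        )
        assert phase_spread(dps) == pytest.approx(0.2, abs=1e-9)

    def test_all_zero_rejected(self):
        dps = LocalDPField(
            positions=np.array([3.9, 4.0]),
            f_dp=5000.0,
            dp_generated=np.zeros(2, dtype=complex),
            dp_stapes=np.zeros(2, dtype=complex),
        )
        with pytest.raises(ValueError):
            phase_spread(dps)


class TestRatioGrid:
    def test_default_grid_has_35_points(self):
        g = default_ratio_grid()
        assert g.size == 35
        assert g[0] == pytest.approx(1.02)
        assert g[-1] == pytest.approx(1.87)
        assert np.allclose(np.diff(g), 0.025)

    def test_invalid_ratios_rejected(self):
        fr = generate_frequency_response(APICAL_BM, include_middle_ear=False)
        with pytest.raises(ValueError, match="ratios"):
            ratio_function(fr, PlaceMap(), 9000.0, ratios=np.array([0.9, 1.2]))


class TestLocalDPRatioFunction:
    @pytest.fixture(scope="class")
    def curve(self):
        fr = generate_frequency_response(
            APICAL_BM, model_reference_grid(APICAL_BM), include_middle_ear=False
        )
        ratios = np.array([1.05, 1.095, 1.2, 1.3])
        r, amps = local_dp_ratio_function(fr, PlaceMap(), 9000.0, ratios, level=50.0)
        return r, amps, fr

    def test_monotone_growth_toward_small_ratios(self, curve):
        """Local intracochlear DPs keep growing as f1 approaches f2, unlike
        the emission, which is shaped by interference."""
        ratios, amps, _ = curve
        assert amps[0] > amps[-1]
        assert np.all(amps > 0) and np.all(np.isfinite(amps))

    def test_consistent_with_local_dp_at_f2_peak(self, curve):
        ratios, amps, fr = curve
        pm = PlaceMap()
        pos = pm.position_grid()
        f1 = round_frequency(9000.0 / 1.2)
        fl1 = spatial_response(fr, pm, f1, 50.0, pos)
        fl2 = spatial_response(fr, pm, 9000.0, 50.0, pos)
        dps = local_dp(fl1, fl2, pm)
        i_peak = int(np.argmax(fl2.magnitude))
        assert amps[2] == pytest.approx(abs(dps.dp_generated[i_peak]), rel=1e-9)

    def test_dp_generation_peaks_at_or_basal_to_f2_place(self, curve):
        _, _, fr = curve
        pm = PlaceMap()
        pos = pm.position_grid()
        f1 = round_frequency(9000.0 / 1.095)
        fl1 = spatial_response(fr, pm, f1, 50.0, pos)
        fl2 = spatial_response(fr, pm, 9000.0, 50.0, pos)
        dps = local_dp(fl1, fl2, pm)
        x_dp = pos[int(np.argmax(np.abs(dps.dp_generated)))]
        x_f2 = pos[int(np.argmax(fl2.magnitude))]
        x_f1 = pos[int(np.argmax(fl1.magnitude))]
        assert x_dp <= x_f2 + 1e-9          # basal to or at the f2 peak place
        assert x_dp <= x_f1                 # within the f1-f2 overlap region
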