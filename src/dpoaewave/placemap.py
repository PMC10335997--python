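"""Frequency-to-place mapping and scaling-symmetry spatial extrapolation.

The mouse cochlear map is log-linear: the distance from the base, expressed
as a percentage of the total basilar-membrane length, is

    position(%) = a - b * log10(f / 1 kHz)

with a = 156.5 % and b = 82.5 %/decade by default, over a 5.13 mm
partition.  Under cochlear scaling symmetry a location's response depends on
stimulus frequency only through f/CF, so the frequency response measured at
one reference site (CF ``cf_ref``) can stand in for the spatial profile of
a traveling wave: the displacement at position ``x`` for a tone at ``f``
equals the reference response evaluated at the equivalent frequency
``f' = f * cf_ref / CF(x)``.  Magnitudes are interpolated in dB and
unwrapped phases in cycles, both linearly against log2 frequency, with
straight-line extrapolation from the two nearest grid points beyond the
measured span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import FrequencyResponse

__all__ = ["PlaceMap", "SpatialField", "spatial_response"]


@dataclass(frozen=True)
class PlaceMap:
    """Invertible map between cochlear position (mm from base) and CF (Hz)."""

    length_mm: float = 5.13
    coef_a: float = 156.5
    coef_b: float = 82.5

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.coef_b <= 0:
            raise ValueError("coef_b must be positive for a monotone map")

    @property
    def cf_base(self) -> float:
        return self.cf_at(0.0)

    @property
    def cf_apex(self) -> float:
        return self.cf_at(self.length_mm)

    def cf_at(self, x_mm):
        """Characteristic frequency (Hz) at position ``x_mm`` from the base."""
        x = np.asarray(x_mm, dtype=float)
        if np.any(x < -1e-12) or np.any(x > self.length_mm + 1e-12):
            raise ValueError(f"position outside [0, {self.length_mm}] mm")
        percent = 100.0 * x / self.length_mm
        f_khz = 10.0 ** ((self.coef_a - percent) / self.coef_b)
        out = 1000.0 * f_khz
        return float(out) if np.isscalar(x_mm) else out

    def place_of(self, f_hz):
        """Position (mm from base) whose CF equals ``f_hz``."""
        f = np.asarray(f_hz, dtype=float)
        lo, hi = self.cf_apex, self.cf_base
        if np.any(f < lo * (1 - 1e-12)) or np.any(f > hi * (1 + 1e-12)):
            raise ValueError(f"frequency outside map range [{lo:.1f}, {hi:.1f}] Hz")
        percent = self.coef_a - self.coef_b * np.log10(f / 1000.0)
        out = np.clip(percent / 100.0 * self.length_mm, 0.0, self.length_mm)
        return float(out) if np.isscalar(f_hz) else out

    def position_grid(self, step_mm: float = 0.01) -> np.ndarray:
        """Inclusive position grid from base to apex (514 points by default)."""
        n = int(round(self.length_mm / step_mm)) + 1
        return np.linspace(0.0, self.length_mm, n)


@dataclass(frozen=True)
class SpatialField:
    """Complex displacement of one tone along the cochlea.

    ``displacement`` holds magnitude (nm RMS) * exp(2j*pi*phase_cycles) per
    position; magnitudes and phases are also exposed separately.
    """

    stim_freq: float
    stim_level: float
    positions: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "magnitude", np.asarray(self.magnitude, dtype=float))
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly ascending")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitudes must be non-negative")

    @property
    def displacement(self) -> np.ndarray:
        return self.magnitude * np.exp(2j * np.pi * self.phase)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos_mm": self.positions,
                "mag_nm_rms": self.magnitude,
                "phase_cycles": self.phase,
            }
        )


def _interp_extrap(x: np.ndarray, xp: np.ndarray, yp: np.ndarray) -> np.ndarray:
    """Linear interpolation with straight-line extrapolation at both ends."""
    y = np.interp(x, xp, yp)
    below = x < xp[0]
    if np.any(below):
        slope = (yp[1] - yp[0]) / (xp[1] - xp[0])
        y[below] = yp[0] + slope * (x[below] - xp[0])
    above = x > xp[-1]
    if np.any(above):
        slope = (yp[-1] - yp[-2]) / (xp[-1] - xp[-2])
        y[above] = yp[-1] + slope * (x[above] - xp[-1])
    return y


def spatial_response(
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    f: float,
    level: float,
    positions: np.ndarray | None = None,
) -> SpatialField:
    """Spatial traveling-wave profile of a tone via scaling symmetry.

    Parameters
    ----------
    fr_ref : FrequencyResponse
        Reference single-site response with the middle-ear delay removed
        (its phases must reflect traveling-wave propagation only).
    place_map : PlaceMap
        Frequency-to-place map.
    f : float
        Stimulus frequency (Hz).
    level : float
        Stimulus level (dB SPL); must be on or bracketed by the reference
        level grid.
    positions : array, optional
        Position grid (mm from base); defaults to the 0.01 mm grid.

    Returns
    -------
    SpatialField
        At each position ``x`` the response equals the reference response at
        the equivalent frequency ``f' = f * cf_ref / CF(x)``.
    """
    if fr_ref.includes_middle_ear:
        raise ValueError(
            "reference response still contains the middle-ear delay; remove it "
            "first so phases reflect traveling-wave propagation only"
        )
    if f <= 0:
        raise ValueError("stimulus frequency must be positive")
    if positions is None:
        positions = place_map.position_grid()
    cf = place_map.cf_at(positions)
    f_equiv = f * fr_ref.site.cf_ref / cf

    mag_ref, ph_ref = fr_ref.at_level(level)
    log_f = np.log2(fr_ref.freqs)
    mag_db = _interp_extrap(np.log2(f_equiv), log_f, 20.0 * np.log10(mag_ref))
    phase = _interp_extrap(np.log2(f_equiv), log_f, ph_ref)
    return SpatialField(
        stim_freq=f,
        stim_level=level,
        positions=positions,
        magnitude=10.0 ** (mag_db / 20.0),
        phase=phase,
    )
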