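"""Measurement-convention utilities: steady-state component extraction,
noise floors, DP phase referencing, frequency rounding, middle-ear delay
removal.

Conventions follow common otoacoustic-emission practice: stimulus
frequencies are rounded to the nearest 10 Hz so an analysis window of a
multiple of 100 ms contains an integer number of cycles; component
magnitudes are RMS; phases are in cycles, wrapped to (-0.5, 0.5] before any
unwrapping; the 2f1-f2 response phase is referenced to 2*phi1ec - phi2ec of
the ear-canal stimulus tones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .synthetic import FrequencyResponse

__all__ = [
    "SpectrumRecord",
    "extract_component",
    "noise_floor",
    "reference_dp_phase",
    "wrap_phase",
    "round_frequency",
    "remove_middle_ear_delay",
    "DP_NOISE_BAND",
    "STIMULUS_NOISE_BAND",
]

#: Offset band (Hz) of neighbouring bins used for DP noise floors.
DP_NOISE_BAND = (20.0, 120.0)
#: Offset band (Hz) used for noise floors at the stimulus frequencies.
STIMULUS_NOISE_BAND = (220.0, 320.0)


@dataclass(frozen=True)
class SpectrumRecord:
    """Uniformly binned spectrum: RMS magnitudes and phases (cycles)."""

    freqs: np.ndarray
    magnitudes: np.ndarray
    phases: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "freqs", np.asarray(self.freqs, dtype=float))
        object.__setattr__(self, "magnitudes", np.asarray(self.magnitudes, dtype=float))
        object.__setattr__(self, "phases", np.asarray(self.phases, dtype=float))
        df = np.diff(self.freqs)
        if np.any(df <= 0):
            raise ValueError("frequency bins must be ascending")
        if df.size and not np.allclose(df, df[0]):
            raise ValueError("frequency bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def extract_component(waveform: np.ndarray, fs: float, f: float) -> complex:
    """Complex RMS amplitude of the ``f`` component of a steady-state window.

    The window must contain an integer number of cycles of ``f``.  A
    waveform ``sqrt(2)*cos(2*pi*f*t)`` yields magnitude 1 (RMS) and phase 0;
    the phase (in cycles) is ``angle/2/pi`` of the returned complex value.
    """
    y = np.asarray(waveform, dtype=float)
    n = y.size
    cycles = f * n / fs
    if abs(cycles - round(cycles)) > 1e-6:
        raise ValueError(
            f"analysis window of {n/fs:g} s does not contain an integer number "
            f"of cycles of {f:g} Hz"
        )
    t = np.arange(n) / fs
    c = y @ np.exp(-2j * np.pi * f * t) * (2.0 / n)
    return complex(c / math.sqrt(2.0))


def noise_floor(
    spec: SpectrumRecord, f: float, band: tuple[float, float] = DP_NOISE_BAND
) -> float:
    """Noise floor at ``f``: mean + 3 sample SDs of nearby bin magnitudes.

    ``band = (lo, hi)`` selects bins whose offset |freq - f| lies within
    [lo, hi] on either side; the component bin itself is excluded (lo must
    exceed half a bin width).
    """
    lo, hi = band
    if lo <= spec.bin_width / 2:
        raise ValueError("band must exclude the component bin itself")
    off = np.abs(spec.freqs - f)
    sel = (off >= lo) & (off <= hi)
    mags = spec.magnitudes[sel]
    if mags.size < 2:
        raise ValueError("fewer than 2 neighbour bins in the noise band")
    return float(mags.mean() + 3.0 * mags.std(ddof=1))


def wrap_phase(phi):
    """Wrap phase (cycles) into (-0.5, 0.5]."""
    out = -(np.mod(-np.asarray(phi, dtype=float) + 0.5, 1.0) - 0.5)
    return float(out) if np.isscalar(phi) else out


def reference_dp_phase(phi_dp, phi1ec, phi2ec):
    """Reference a 2f1-f2 response phase to the ear-canal stimulus phases.

    Subtracts ``2*phi1ec - phi2ec`` (all in cycles) and wraps the result to
    (-0.5, 0.5].  Unwrapping across a sweep, if desired, is done afterwards
    in order of increasing DP frequency.
    """
    return wrap_phase(np.asarray(phi_dp) - (2.0 * np.asarray(phi1ec) - np.asarray(phi2ec)))


def round_frequency(f: float) -> float:
    """Round a stimulus frequency to the nearest 10 Hz (ties round up)."""
    if f <= 0:
        raise ValueError("frequency must be positive")
    return 10.0 * math.floor(f / 10.0 + 0.5)


def remove_middle_ear_delay(fr: FrequencyResponse, tau: float | None = None) -> FrequencyResponse:
    """Remove a pure middle-ear delay from a frequency response's phases.

    ``phase(f) += f * tau`` (the delay appears as a lag ``-f*tau``), the
    magnitudes are untouched and the ``includes_middle_ear`` flag is
    cleared.  ``tau`` defaults to the profile's ``middle_ear_delay``.
    """
    if not fr.includes_middle_ear:
        raise ValueError("middle-ear delay already removed from this response")
    if tau is None:
        tau = fr.site.middle_ear_delay
    phase = fr.phase + fr.freqs[None, :] * tau
    return replace(fr, phase=phase, includes_middle_ear=False)
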