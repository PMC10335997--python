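"""Local 2f1-f2 distortion-product generation by the OHC transducer.

At each cochlear location the displacements driven by the two stimulus
tones are fed, as sinusoids, into a first-order Boltzmann function

    y(x) = 1 / (1 + exp(a1 * (x1 - x)))

approximating the saturating relationship between stereociliary bundle
position ``x`` (nm) and normalised mechanotransduction current ``y``
(bounded in (0, 1)).  The output is low-pass filtered — the OHC membrane's
electrical filtering, a single pole with corner frequency a fixed number of
octaves below the local CF — and the complex component at ``f_dp = 2*f1 -
f2`` of the filtered output is the locally generated DP.

Simulation is time-domain: stimulus frequencies are rounded to multiples of
10 Hz so a 100 ms window holds an integer number of cycles of every
component, and the DP component is extracted by projection onto
``exp(-2j*pi*f_dp*t)``.  Amplitudes are *peak* (sinusoid amplitude) in this
module; displacement fields store RMS magnitudes and are converted
(x sqrt(2)) when a drive is built from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .placemap import PlaceMap, SpatialField

__all__ = [
    "BoltzmannParams",
    "LowPassParams",
    "TwoToneDrive",
    "LocalDPField",
    "boltzmann",
    "lowpass_transfer",
    "simulate_two_tone_dp",
    "local_dp",
    "DEFAULT_FS",
    "DEFAULT_DURATION",
]

#: Default sampling rate (Hz) for time-domain simulation.
DEFAULT_FS = 400e3
#: Default steady-state window (s); integer cycles for any multiple of 10 Hz.
DEFAULT_DURATION = 0.1


@dataclass(frozen=True)
class BoltzmannParams:
    """First-order Boltzmann transducer parameters.

    ``a1`` (nm^-1) sets the slope, ``x1`` (nm) the bundle position of
    maximum slope; the resting position is ``operating_point`` (nm).
    """

    a1: float = 0.28
    x1: float = 2.6
    operating_point: float = 0.0

    def __post_init__(self) -> None:
        if self.a1 <= 0:
            raise ValueError("a1 must be positive")


@dataclass(frozen=True)
class LowPassParams:
    """Single-pole membrane low-pass filter, corner below the local CF."""

    octaves_below_cf: float = 2.36
    enabled: bool = True

    def corner(self, cf) -> np.ndarray:
        return np.asarray(cf, dtype=float) * 2.0 ** (-self.octaves_below_cf)


@dataclass(frozen=True)
class TwoToneDrive:
    """Local sinusoidal drive: peak amplitudes (nm) and phases (cycles)."""

    f1: float
    f2: float
    amp1: float
    amp2: float
    phase1: float = 0.0
    phase2: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f2 > self.f1 > 0):
            raise ValueError("require f2 > f1 > 0")
        if self.f_dp <= 0:
            raise ValueError("2*f1 - f2 must be positive")

    @property
    def f_dp(self) -> float:
        return 2.0 * self.f1 - self.f2


@dataclass(frozen=True)
class LocalDPField:
    """Per-location 2f1-f2 components along the cochlea.

    ``dp_generated`` is the complex locally generated DP (normalised
    transducer units, peak convention); ``dp_stapes`` is filled in by the
    propagation step and is None until then.
    """

    positions: np.ndarray
    f_dp: float
    dp_generated: np.ndarray
    dp_stapes: np.ndarray | None = None
    #: unwrapped stapes-bound phase (cycles), kept alongside the complex
    #: values so spatial phase spreads are not limited to (-0.5, 0.5] jumps
    stapes_phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "dp_generated", np.asarray(self.dp_generated, dtype=complex))
        if self.dp_stapes is not None:
            object.__setattr__(self, "dp_stapes", np.asarray(self.dp_stapes, dtype=complex))
        if self.stapes_phase is not None:
            object.__setattr__(self, "stapes_phase", np.asarray(self.stapes_phase, dtype=float))
        if self.positions.shape != self.dp_generated.shape:
            raise ValueError("positions and dp_generated must have equal shape")

    def __len__(self) -> int:
        return self.positions.size


def boltzmann(x, p: BoltzmannParams = BoltzmannParams()):
    """Normalised transducer current for bundle position ``x`` (nm)."""
    x = np.asarray(x, dtype=float)
    out = 1.0 / (1.0 + np.exp(p.a1 * (p.x1 - x)))
    return float(out) if out.ndim == 0 else out


def lowpass_transfer(f, cf, lp: LowPassParams = LowPassParams()):
    """Complex transfer of the membrane low-pass filter at frequency ``f``.

    ``H(f) = 1 / (1 + i f/fc)`` with ``fc = cf * 2**(-octaves_below_cf)``;
    identity when the filter is disabled.
    """
    f = np.asarray(f, dtype=float)
    cf = np.asarray(cf, dtype=float)
    if not lp.enabled:
        return np.ones(np.broadcast_shapes(f.shape, cf.shape), dtype=complex) if f.ndim or cf.ndim else 1.0 + 0j
    out = 1.0 / (1.0 + 1j * f / lp.corner(cf))
    return complex(out) if out.ndim == 0 else out


def _check_window(freqs, fs: float, duration: float) -> None:
    n_cycles = np.asarray(freqs, dtype=float) * duration
    if np.any(np.abs(n_cycles - np.round(n_cycles)) > 1e-6):
        raise ValueError(
            "stimulus frequencies must give an integer number of cycles in the "
            f"{duration:g} s analysis window (round them to multiples of "
            f"{1/duration:g} Hz)"
        )
    if fs < 20.0 * np.max(freqs):
        raise ValueError("sampling rate too low; require fs >= 20 * f2")


def _dp_batch(
    amp1: np.ndarray,
    phase1: np.ndarray,
    amp2: np.ndarray,
    phase2: np.ndarray,
    f1: float,
    f2: float,
    p: BoltzmannParams,
    fs: float,
    duration: float,
    chunk: int = 96,
) -> np.ndarray:
    """Complex DP (peak convention) for batches of drives at shared f1, f2."""
    _check_window([f1, f2, 2 * f1 - f2], fs, duration)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    c1, s1 = np.cos(2 * np.pi * f1 * t), np.sin(2 * np.pi * f1 * t)
    c2, s2 = np.cos(2 * np.pi * f2 * t), np.sin(2 * np.pi * f2 * t)
    f_dp = 2.0 * f1 - f2
    probe = np.exp(-2j * np.pi * f_dp * t)

    amp1, phase1, amp2, phase2 = np.broadcast_arrays(
        np.asarray(amp1, float), np.asarray(phase1, float),
        np.asarray(amp2, float), np.asarray(phase2, float),
    )
    m = amp1.size
    out = np.empty(m, dtype=complex)
    a1c = (amp1 * np.cos(2 * np.pi * phase1)).ravel()
    a1s = (amp1 * np.sin(2 * np.pi * phase1)).ravel()
    a2c = (amp2 * np.cos(2 * np.pi * phase2)).ravel()
    a2s = (amp2 * np.sin(2 * np.pi * phase2)).ravel()
    for i in range(0, m, chunk):
        j = slice(i, min(i + chunk, m))
        x = (
            np.outer(a1c[j], c1) - np.outer(a1s[j], s1)
            + np.outer(a2c[j], c2) - np.outer(a2s[j], s2)
            + p.operating_point
        )
        y = 1.0 / (1.0 + np.exp(p.a1 * (p.x1 - x)))
        out[j] = y @ probe * (2.0 / n)
    return out.reshape(amp1.shape)


def simulate_two_tone_dp(
    drive: TwoToneDrive,
    p: BoltzmannParams = BoltzmannParams(),
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
) -> complex:
    """Complex 2f1-f2 component of the Boltzmann output for one drive.

    Returns the complex peak amplitude ``C`` such that the DP component of
    the output is ``Re(C * exp(2j*pi*f_dp*t))``; the phase in cycles is
    ``angle(C)/2/pi``.  In the small-signal regime |C| approaches the cubic
    Taylor prediction ``|y'''(0)| * A1^2 * A2 / 8`` and the phase equals
    ``2*phase1 - phase2 + 0.5`` cycles (the cubic coefficient is negative at
    the default operating point).
    """
    return complex(
        _dp_batch(
            np.atleast_1d(drive.amp1),
            np.atleast_1d(drive.phase1),
            np.atleast_1d(drive.amp2),
            np.atleast_1d(drive.phase2),
            drive.f1,
            drive.f2,
            p,
            fs,
            duration,
        )[0]
    )


def local_dp(
    field1: SpatialField,
    field2: SpatialField,
    place_map: PlaceMap,
    p: BoltzmannParams = BoltzmannParams(),
    lp: LowPassParams = LowPassParams(),
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    neglect_rel: float = 1e-10,
) -> LocalDPField:
    """Locally generated 2f1-f2 DP at every position of two spatial fields.

    ``field1``/``field2`` are the displacement profiles of the f1 and f2
    tones on a shared position grid (magnitudes nm RMS).  At each position
    the RMS magnitudes are converted to peak amplitudes, driven through the
    Boltzmann function, and the extracted DP component is multiplied by the
    membrane low-pass transfer at the local CF.

    Locations whose intermodulation drive ``A1^2 * A2`` falls below
    ``neglect_rel`` times its maximum (-200 dB for the default) are assigned
    a zero DP without simulation; their contribution is far below numerical
    precision of the vector sum.
    """
    if field1.positions.shape != field2.positions.shape or not np.allclose(
        field1.positions, field2.positions
    ):
        raise ValueError("f1 and f2 fields must share the position grid")
    f1, f2 = field1.stim_freq, field2.stim_freq
    if not f2 > f1:
        raise ValueError("field2 must carry the higher-frequency tone")
    sqrt2 = np.sqrt(2.0)
    a1, a2 = field1.magnitude * sqrt2, field2.magnitude * sqrt2
    weight = a1 * a1 * a2
    keep = weight >= weight.max() * neglect_rel
    dp_raw = np.zeros(a1.size, dtype=complex)
    dp_raw[keep] = _dp_batch(
        a1[keep],
        field1.phase[keep],
        a2[keep],
        field2.phase[keep],
        f1,
        f2,
        p,
        fs,
        duration,
    )
    f_dp = 2.0 * f1 - f2
    cf = place_map.cf_at(field1.positions)
    h = lowpass_transfer(f_dp, cf, lp)
    return LocalDPField(positions=field1.positions, f_dp=f_dp, dp_generated=dp_raw * h)
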