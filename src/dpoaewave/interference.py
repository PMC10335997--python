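"""Wave-interference model of DPOAE generation.

The 2f1-f2 emission measured in the ear canal is modelled as the vector sum
of distortion-product wavelets generated along the whole cochlea.  For each
``f2/f1`` ratio the spatial displacement profiles of the two tones are
obtained from a single-site reference response by scaling symmetry, driven
through the saturating transducer at every location, and the resulting
local DPs are propagated back to the stapes before summation.

Reverse propagation modes:

* ``slow_wave`` (default) — each DP rides a reverse traveling wave coupled
  to the basilar membrane: its magnitude is weighted by the local BM
  displacement that a low-level (40 dB SPL) tone at the DP frequency would
  drive, and its phase is shifted by the local phase of a forward-traveling
  wave at the DP frequency (a lag).
* ``fast_wave`` — DPs reach the stapes nearly instantaneously through the
  cochlear fluids: the locally generated DPs are summed unchanged.

A ``zero_phase_control`` discards all phase variation before summation
(summing magnitudes), which destroys the bandpass shape of the ratio
function and confirms that the tuning arises from interference.

The :class:`WaveInterferenceModel` / :class:`WaveInterferenceResults` pair
wraps the functional layer: the model is built from a reference frequency
response, ``fit`` sweeps ratio and level, and the results object carries the
ratio functions, their tuning metrics and a ``summary()`` table.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import spectral, transducer, tuning
from .placemap import PlaceMap, SpatialField, spatial_response
from .synthetic import (
    FrequencyResponse,
    SiteProfile,
    generate_frequency_response,
    model_reference_grid,
)
from .transducer import BoltzmannParams, LocalDPField, LowPassParams

__all__ = [
    "PropagationOptions",
    "RatioFunction",
    "default_ratio_grid",
    "propagate_to_stapes",
    "sum_dpoae",
    "ratio_function",
    "ratio_functions_multi",
    "phase_spread",
    "local_dp_ratio_function",
    "WaveInterferenceModel",
    "WaveInterferenceResults",
]


@dataclass(frozen=True)
class PropagationOptions:
    """How locally generated DPs are carried to the stapes and summed."""

    mode: str = "slow_wave"
    weighting: str = "displacement"
    weight_level: float = 40.0
    zero_phase_control: bool = False
    apical_limit_mm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"slow_wave", "fast_wave"}:
            raise ValueError(f"unknown propagation mode {self.mode!r}")
        if self.weighting not in {"displacement", "velocity"}:
            raise ValueError(f"unknown weighting {self.weighting!r}")

    def label(self) -> str:
        parts = [self.mode]
        if self.weighting != "displacement":
            parts.append(self.weighting)
        if self.zero_phase_control:
            parts.append("zero_phase")
        return "+".join(parts)


def default_ratio_grid() -> np.ndarray:
    """f2/f1 ratios 1.02-1.87 in 0.025 steps (35 points)."""
    return np.round(np.arange(1.02, 1.87 + 1e-9, 0.025), 10)


@dataclass(frozen=True)
class RatioFunction:
    """Complex DPOAE amplitude vs f2/f1 ratio at fixed f2 and level.

    ``dpoae`` is in arbitrary units (normalised transducer output times nm
    weighting); ``phase_spread`` holds, per ratio, the spatial spread of
    stapes-bound DP phase over the dominant generation region (cycles).
    """

    f2: float
    level1: float
    level2: float
    ratios: np.ndarray
    f1: np.ndarray
    f_dp: np.ndarray
    dpoae: np.ndarray
    options: PropagationOptions
    phase_spread: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("ratios", "f1", "f_dp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(self, "dpoae", np.asarray(self.dpoae, dtype=complex))
        if np.any(self.ratios < 1.0) or np.any(self.ratios >= 2.0):
            raise ValueError("ratios must lie in [1.0, 2.0)")
        if np.any(np.diff(self.ratios) <= 0):
            raise ValueError("ratios must be ascending")
        if not np.allclose(self.f_dp, 2.0 * self.f1 - self.f2):
            raise ValueError("f_dp grid inconsistent with f1 and f2")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.dpoae)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.dpoae) / (2 * np.pi)

    def db_re_max(self) -> np.ndarray:
        a = self.amplitude
        return 20.0 * np.log10(a / a.max())

    def is_bandpass(self, edge_drop_db: float = 10.0) -> bool:
        """True when the maximum is interior and both grid ends sit at least
        ``edge_drop_db`` below it."""
        db = self.db_re_max()
        i = int(np.argmax(db))
        return 0 < i < db.size - 1 and db[0] <= -edge_drop_db and db[-1] <= -edge_drop_db

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ratio": self.ratios,
                "f1_hz": self.f1,
                "fdp_hz": self.f_dp,
                "dpoae_mag": self.amplitude,
                "dpoae_db_re_max": self.db_re_max(),
                "dpoae_phase_cycles": self.phase,
            }
        )
        if self.phase_spread is not None:
            df["phase_spread_cycles"] = self.phase_spread
        return df


def propagate_to_stapes(
    dps: LocalDPField,
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    opt: PropagationOptions = PropagationOptions(),
) -> LocalDPField:
    """Fill in ``dp_stapes`` from ``dp_generated`` for one DP field.

    In slow-wave mode each local DP is multiplied by the complex value of a
    forward-traveling BM wave at the DP frequency, evaluated from the
    low-level reference response: magnitude ``W(x)`` (optionally times
    ``2*pi*f_dp`` for velocity weighting) and phase ``phi_fw(x)`` applied as
    the reverse-propagation lag.  In fast-wave mode the DPs are unchanged.
    """
    gen_phase = np.unwrap(np.angle(dps.dp_generated)) / (2 * np.pi)
    if opt.mode == "fast_wave":
        return replace(dps, dp_stapes=dps.dp_generated.copy(), stapes_phase=gen_phase)
    wave = spatial_response(fr_ref, place_map, dps.f_dp, opt.weight_level, dps.positions)
    w = wave.magnitude
    if opt.weighting == "velocity":
        w = w * (2.0 * np.pi * dps.f_dp)
    return replace(
        dps,
        dp_stapes=dps.dp_generated * w * np.exp(2j * np.pi * wave.phase),
        stapes_phase=gen_phase + wave.phase,
    )


def sum_dpoae(dps: LocalDPField, opt: PropagationOptions = PropagationOptions()) -> complex:
    """Vector sum of stapes-bound DPs over all locations.

    With ``zero_phase_control`` the magnitudes are summed instead (phases
    zeroed first), which by the triangle inequality bounds the coherent sum.
    """
    if len(dps) == 0:
        raise ValueError("no local DPs to sum")
    if dps.dp_stapes is None:
        raise ValueError("dp_stapes not populated; run propagate_to_stapes first")
    if opt.zero_phase_control:
        return complex(np.sum(np.abs(dps.dp_stapes)))
    return complex(np.sum(dps.dp_stapes))


def phase_spread(dps: LocalDPField, within_db: float = 10.0) -> float:
    """Spatial phase spread (cycles) of stapes-bound DPs over the dominant
    generation region.

    The region is the contiguous run of positions around the location of
    maximum |dp_generated| whose magnitudes lie within ``within_db`` of the
    maximum; the spread is max - min of the unwrapped ``dp_stapes`` phase
    over that region (the ``stapes_phase`` record when present, else the
    phase unwrapped along position).
    """
    if dps.dp_stapes is None:
        raise ValueError("dp_stapes not populated; run propagate_to_stapes first")
    mag = np.abs(dps.dp_generated)
    if mag.max() == 0:
        raise ValueError("all local DP magnitudes are zero")
    i_peak = int(np.argmax(mag))
    with np.errstate(divide="ignore"):
        rel_db = 20.0 * np.log10(mag / mag[i_peak])
    ok = rel_db >= -within_db
    lo = i_peak
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < ok.size - 1 and ok[hi + 1]:
        hi += 1
    if dps.stapes_phase is not None:
        ph = dps.stapes_phase[lo : hi + 1]
    else:
        ph = np.unwrap(np.angle(dps.dp_stapes[lo : hi + 1])) / (2 * np.pi)
    return float(np.max(ph) - np.min(ph))


def _fields_for_ratio(
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    f2: float,
    ratio: float,
    level1: float,
    level2: float,
    positions: np.ndarray,
) -> tuple[SpatialField, SpatialField]:
    f1 = spectral.round_frequency(f2 / ratio)
    field1 = spatial_response(fr_ref, place_map, f1, level1, positions)
    field2 = spatial_response(fr_ref, place_map, f2, level2, positions)
    return field1, field2


def _sweep_positions(
    place_map: PlaceMap, f2: float, opt_list: Sequence[PropagationOptions]
) -> np.ndarray:
    """Position grid, truncated by the tightest apical generation limit."""
    positions = place_map.position_grid()
    limits = [o.apical_limit_mm for o in opt_list if o.apical_limit_mm is not None]
    if limits:
        x_max = place_map.place_of(f2) + min(limits)
        positions = positions[positions <= x_max + 1e-12]
    return positions


def ratio_functions_multi(
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    f2: float,
    ratios: np.ndarray | None,
    level1: float,
    level2: float | None,
    p: BoltzmannParams,
    lp: LowPassParams,
    opt_list: Sequence[PropagationOptions],
    fs: float | None = None,
    duration: float = transducer.DEFAULT_DURATION,
) -> list[RatioFunction]:
    """Ratio functions for several propagation variants in one sweep.

    The expensive per-location transducer simulation depends only on the
    stimulus fields, so all propagation variants (slow/fast wave, velocity
    weighting, zero-phase control) share it.  All variants must share any
    ``apical_limit_mm``.
    """
    if level2 is None:
        level2 = level1
    ratios = default_ratio_grid() if ratios is None else np.asarray(ratios, dtype=float)
    if np.any(ratios < 1.0) or np.any(ratios >= 2.0):
        raise ValueError("ratios must lie in [1.0, 2.0)")
    f2 = spectral.round_frequency(f2)
    if fs is None:
        # smallest 100 kHz multiple satisfying the anti-aliasing margin
        fs = 1e5 * math.ceil(20.0 * f2 / 1e5)
    limits = {o.apical_limit_mm for o in opt_list}
    if len(limits) > 1:
        raise ValueError("all propagation variants must share apical_limit_mm")
    positions = _sweep_positions(place_map, f2, opt_list)

    n_r = ratios.size
    results = [
        {
            "dpoae": np.empty(n_r, dtype=complex),
            "spread": np.full(n_r, np.nan),
        }
        for _ in opt_list
    ]
    f1_grid = np.empty(n_r)
    for k, ratio in enumerate(ratios):
        field1, field2 = _fields_for_ratio(fr_ref, place_map, f2, ratio, level1, level2, positions)
        f1_grid[k] = field1.stim_freq
        dps = transducer.local_dp(field1, field2, place_map, p, lp, fs=fs, duration=duration)
        for res, opt in zip(results, opt_list):
            prop = propagate_to_stapes(dps, fr_ref, place_map, opt)
            res["dpoae"][k] = sum_dpoae(prop, opt)
            res["spread"][k] = phase_spread(prop)
    return [
        RatioFunction(
            f2=f2,
            level1=level1,
            level2=level2,
            ratios=ratios,
            f1=f1_grid,
            f_dp=2.0 * f1_grid - f2,
            dpoae=res["dpoae"],
            options=opt,
            phase_spread=res["spread"],
        )
        for res, opt in zip(results, opt_list)
    ]


def ratio_function(
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    f2: float,
    ratios: np.ndarray | None = None,
    level1: float = 50.0,
    level2: float | None = None,
    p: BoltzmannParams = BoltzmannParams(),
    lp: LowPassParams = LowPassParams(),
    opt: PropagationOptions = PropagationOptions(),
    fs: float | None = None,
    duration: float = transducer.DEFAULT_DURATION,
) -> RatioFunction:
    """DPOAE amplitude vs f2/f1 ratio for one level pair and one variant."""
    return ratio_functions_multi(
        fr_ref, place_map, f2, ratios, level1, level2, p, lp, [opt], fs, duration
    )[0]


def local_dp_ratio_function(
    fr_ref: FrequencyResponse,
    place_map: PlaceMap,
    f2: float,
    ratios: np.ndarray | None = None,
    level: float = 50.0,
    p: BoltzmannParams = BoltzmannParams(),
    lp: LowPassParams = LowPassParams(),
    fs: float | None = None,
    duration: float = transducer.DEFAULT_DURATION,
) -> tuple[np.ndarray, np.ndarray]:
    """|dp_generated| at the f2 peak place, per ratio.

    Returns ``(ratios, amplitudes)``.  Unlike the emission, this local
    quantity grows monotonically as f1 approaches f2 (the two excitation
    patterns overlap more), so comparing it with the bandpass ratio function
    isolates the effect of interference.
    """
    ratios = default_ratio_grid() if ratios is None else np.asarray(ratios, dtype=float)
    f2 = spectral.round_frequency(f2)
    if fs is None:
        fs = 1e5 * math.ceil(20.0 * f2 / 1e5)
    positions = place_map.position_grid()
    amps = np.empty(ratios.size)
    for k, ratio in enumerate(ratios):
        field1, field2 = _fields_for_ratio(fr_ref, place_map, f2, ratio, level, level, positions)
        dps = transducer.local_dp(field1, field2, place_map, p, lp, fs=fs, duration=duration)
        i_peak = int(np.argmax(field2.magnitude))
        amps[k] = np.abs(dps.dp_generated[i_peak])
    return ratios, amps


# ---------------------------------------------------------------------------
# Model / Results facade
# ---------------------------------------------------------------------------


class WaveInterferenceModel:
    """Wave-interference DPOAE model built from a reference frequency response.

    Parameters
    ----------
    fr_ref : FrequencyResponse
        Single-site reference response.  If it still includes the
        middle-ear delay it is removed automatically (the model requires
        phases reflecting traveling-wave propagation only).
    place_map : PlaceMap, optional
        Cochlear frequency-to-place map (mouse defaults).
    boltzmann, lowpass : BoltzmannParams, LowPassParams, optional
        Transducer parameters.
    propagation : PropagationOptions, optional
        Default propagation variant for :meth:`fit`.

    Examples
    --------
    >>> model = WaveInterferenceModel.from_profile()
    >>> res = model.fit(f2=9000, levels=(40, 50, 60, 70))
    >>> print(res.summary())          # doctest: +SKIP
    """

    def __init__(
        self,
        fr_ref: FrequencyResponse,
        place_map: PlaceMap | None = None,
        boltzmann: BoltzmannParams | None = None,
        lowpass: LowPassParams | None = None,
        propagation: PropagationOptions | None = None,
    ) -> None:
        if fr_ref.includes_middle_ear:
            fr_ref = spectral.remove_middle_ear_delay(fr_ref)
        self.fr_ref = fr_ref
        self.place_map = place_map or PlaceMap()
        self.boltzmann = boltzmann or BoltzmannParams()
        self.lowpass = lowpass or LowPassParams()
        self.propagation = propagation or PropagationOptions()

    @classmethod
    def from_profile(
        cls,
        profile: SiteProfile | None = None,
        freqs: np.ndarray | None = None,
        levels: np.ndarray | None = None,
        **kwargs,
    ) -> "WaveInterferenceModel":
        """Build the model from a synthetic site profile (apical default).

        The reference response is generated on the dense
        :func:`~dpoaewave.synthetic.model_reference_grid` unless ``freqs``
        is given.
        """
        profile = profile or SiteProfile()
        if freqs is None:
            freqs = model_reference_grid(profile)
        fr = generate_frequency_response(profile, freqs, levels, include_middle_ear=False)
        return cls(fr, **kwargs)

    def fit(
        self,
        f2: float = 9000.0,
        levels: Sequence[float] = (40.0, 50.0, 60.0, 70.0),
        ratios: np.ndarray | None = None,
        level2: float | None = None,
        variants: Sequence[PropagationOptions] | None = None,
        fs: float | None = None,
        duration: float = transducer.DEFAULT_DURATION,
    ) -> "WaveInterferenceResults":
        """Sweep f2/f1 ratio (and stimulus level) and quantify the tuning.

        ``level2`` fixes the f2-tone level while ``levels`` sweeps the
        f1-tone level (the unequal-level paradigm); by default both tones
        share each level.  ``variants`` adds propagation variants evaluated
        from the same transducer simulations.
        """
        opt_list = [self.propagation] + list(variants or [])
        rfs: dict[str, dict[float, RatioFunction]] = {o.label(): {} for o in opt_list}
        for level in levels:
            out = ratio_functions_multi(
                self.fr_ref,
                self.place_map,
                f2,
                ratios,
                level,
                level2,
                self.boltzmann,
                self.lowpass,
                opt_list,
                fs,
                duration,
            )
            for opt, rf in zip(opt_list, out):
                rfs[opt.label()][float(level)] = rf
        return WaveInterferenceResults(self, rfs, primary=opt_list[0].label())


class WaveInterferenceResults:
    """Results of a ratio/level sweep of the wave-interference model."""

    def __init__(
        self,
        model: WaveInterferenceModel,
        ratio_functions: dict[str, dict[float, RatioFunction]],
        primary: str,
    ) -> None:
        self.model = model
        self._rfs = ratio_functions
        self.primary = primary
        self._tuning: dict[str, dict[float, tuning.TuningResult]] = {
            label: {lv: tuning.ratio_function_tuning(rf) for lv, rf in by_level.items()}
            for label, by_level in ratio_functions.items()
        }

    @property
    def variants(self) -> list[str]:
        return list(self._rfs)

    @property
    def levels(self) -> list[float]:
        return sorted(self._rfs[self.primary])

    def ratio_function(self, level: float, variant: str | None = None) -> RatioFunction:
        return self._rfs[variant or self.primary][float(level)]

    def tuning(self, level: float, variant: str | None = None) -> tuning.TuningResult:
        return self._tuning[variant or self.primary][float(level)]

    def optimal_ratios(self, variant: str | None = None) -> dict[float, float]:
        return {
            lv: t.optimal_ratio for lv, t in sorted(self._tuning[variant or self.primary].items())
        }

    def q10_by_level(self, variant: str | None = None) -> dict[float, float]:
        return {lv: t.q10 for lv, t in sorted(self._tuning[variant or self.primary].items())}

    def input_q10_by_level(self) -> dict[float, float]:
        """Q10dB of the single-tone reference response at each fitted level."""
        out: dict[float, float] = {}
        fr = self.model.fr_ref
        for lv in self.levels:
            mag, _ = fr.at_level(lv)
            out[lv] = tuning.q10(fr.freqs, mag).q10
        return out

    def phase_spread_at(self, level: float, ratio: float, variant: str | None = None) -> float:
        rf = self.ratio_function(level, variant)
        k = int(np.argmin(np.abs(rf.ratios - ratio)))
        return float(rf.phase_spread[k])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, by_level in self._rfs.items():
            for lv, rf in sorted(by_level.items()):
                df = rf.to_frame()
                df.insert(0, "variant", label)
                df.insert(1, "level_db_spl", lv)
                rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def summary(self) -> str:
        """Human-readable per-level tuning table, per variant."""
        buf = io.StringIO()
        m = self.model
        buf.write("Wave-interference DPOAE model\n")
        buf.write("=" * 64 + "\n")
        f2 = next(iter(self._rfs[self.primary].values())).f2
        buf.write(
            f"f2 = {f2:.0f} Hz   CF_ref = {m.fr_ref.site.cf_ref:.0f} Hz   "
            f"Boltzmann a1={m.boltzmann.a1} nm^-1, x1={m.boltzmann.x1} nm\n"
        )
        lp = m.lowpass
        buf.write(
            f"low-pass: {'corner ' + format(lp.octaves_below_cf, 'g') + ' oct below CF' if lp.enabled else 'disabled'}\n"
        )
        for label in self.variants:
            buf.write(f"\n[{label}]\n")
            buf.write(
                f"{'level':>6} {'opt ratio':>10} {'f_max/Hz':>10} {'BW10/Hz':>10} "
                f"{'Q10dB':>8} {'QERB':>8}\n"
            )
            for lv in sorted(self._rfs[label]):
                t = self._tuning[label][lv]
                buf.write(
                    f"{lv:>6.0f} {t.optimal_ratio:>10.3f} {t.f_max:>10.0f} "
                    f"{t.bw10:>10.0f} {t.q10:>8.2f} {t.q_erb:>8.2f}\n"
                )
        return buf.getvalue()

    def plot_ratio_functions(self, variant: str | None = None, ax=None):
        """Plot |DPOAE| (dB re max across levels) vs f2/f1 ratio per level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = variant or self.primary
        ref = max(rf.amplitude.max() for rf in self._rfs[label].values())
        for lv, rf in sorted(self._rfs[label].items()):
            ax.plot(rf.ratios, 20 * np.log10(rf.amplitude / ref), label=f"{lv:.0f} dB SPL")
        ax.set_xlabel("$f_2/f_1$ ratio")
        ax.set_ylabel("DPOAE (dB re max)")
        ax.set_title(label)
        ax.legend(frameon=False, fontsize="small")
        return ax
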