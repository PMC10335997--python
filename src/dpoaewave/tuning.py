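"""Tuning-sharpness metrics for cochlear frequency responses and DPOAE ratio functions.

Two standard metrics are provided:

* ``Q10dB`` — the frequency of the response peak divided by the bandwidth
  measured 10 dB below the peak.  Larger values mean sharper tuning.
* ``QERB`` — the peak frequency divided by the equivalent rectangular
  bandwidth (ERB) of the squared, max-normalised amplitude curve.

Both are computed from a sampled amplitude-versus-frequency curve; ratio
functions (DPOAE amplitude vs ``f2/f1``) are analysed with respect to the
distortion-product frequency ``f_dp = 2*f1 - f2`` rather than the ratio
itself, so that the resulting Q values are comparable to single-tone tuning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "TuningResult",
    "TuningUndefinedError",
    "q10",
    "qerb",
    "quantify_tuning",
    "ratio_function_tuning",
    "nonlinear_gain",
    "average_tuning",
]


class TuningUndefinedError(ValueError):
    """Raised when a tuning metric cannot be computed from a curve."""


@dataclass(frozen=True)
class TuningResult:
    """Tuning metrics for a single amplitude curve.

    Attributes
    ----------
    f_max : float
        Frequency (Hz) of the maximum response.
    bw10 : float
        Bandwidth (Hz) 10 dB below the peak; NaN when undefined.
    q10 : float
        ``f_max / bw10``; NaN when undefined.
    erb : float
        Equivalent rectangular bandwidth (Hz); NaN when not computed.
    q_erb : float
        ``f_max / erb``; NaN when not computed.
    optimal_ratio : float
        For ratio functions, the ``f2/f1`` ratio maximising the amplitude
        (smallest ratio wins ties); NaN otherwise.
    erb_truncated : bool
        True when the curve does not decay at the grid edges, biasing the
        ERB integral low.
    """

    f_max: float
    bw10: float = math.nan
    q10: float = math.nan
    erb: float = math.nan
    q_erb: float = math.nan
    optimal_ratio: float = math.nan
    erb_truncated: bool = False

    @property
    def q10_defined(self) -> bool:
        return math.isfinite(self.q10)

    @property
    def q_erb_defined(self) -> bool:
        return math.isfinite(self.q_erb)


def _as_curve(freqs: Sequence[float], amps: Sequence[float]):
    f = np.asarray(freqs, dtype=float)
    a = np.asarray(amps, dtype=float)
    if f.ndim != 1 or a.shape != f.shape:
        raise ValueError("freqs and amps must be 1-D arrays of equal length")
    if f.size < 3:
        raise ValueError("need at least 3 points to quantify tuning")
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequencies must be strictly ascending")
    if np.any(a < 0):
        raise ValueError("amplitudes must be non-negative")
    return f, a


def _cross_10db(x: np.ndarray, db: np.ndarray, i_peak: int, side: int) -> float:
    """Locate the -10 dB crossing by linear interpolation along axis ``x``.

    ``side`` is -1 (below peak) or +1 (above peak).  Returns the crossing
    coordinate in the units of ``x`` or NaN when the curve never reaches
    10 dB below the peak on that side.
    """
    target = db[i_peak] - 10.0
    idx = range(i_peak - 1, -1, -1) if side < 0 else range(i_peak + 1, len(db))
    prev = i_peak
    for i in idx:
        if db[i] <= target:
            # interpolate between prev (above target) and i (at/below)
            frac = (db[prev] - target) / (db[prev] - db[i])
            return x[prev] + frac * (x[i] - x[prev])
        prev = i
    return math.nan


def q10(freqs: Sequence[float], amps: Sequence[float], *, log_axis: bool = True) -> TuningResult:
    """Q10dB of an amplitude curve.

    The peak frequency is divided by the bandwidth 10 dB below the peak.
    Crossings are located by linear interpolation of dB amplitude against
    log2 frequency (``log_axis=True``, the default) or linear frequency.
    When either flank never drops 10 dB below the peak the result is
    flagged undefined (``q10`` is NaN) rather than extrapolated.
    """
    f, a = _as_curve(freqs, amps)
    if np.all(a == 0):
        raise TuningUndefinedError("all-zero amplitude curve")
    i_peak = int(np.argmax(a))
    f_max = float(f[i_peak])
    if i_peak == 0 or i_peak == len(f) - 1:
        return TuningResult(f_max=f_max)  # monotone curve: undefined
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.where(a > 0, a, np.finfo(float).tiny))
    x = np.log2(f) if log_axis else f
    lo = _cross_10db(x, db, i_peak, -1)
    hi = _cross_10db(x, db, i_peak, +1)
    if math.isnan(lo) or math.isnan(hi):
        return TuningResult(f_max=f_max)
    if log_axis:
        lo, hi = 2.0 ** lo, 2.0 ** hi
    bw = hi - lo
    return TuningResult(f_max=f_max, bw10=bw, q10=f_max / bw)


def qerb(freqs: Sequence[float], amps: Sequence[float]) -> TuningResult:
    """QERB of an amplitude curve.

    Amplitudes (linear units) are normalised to their maximum and squared so
    that they are proportional to power; the ERB is the trapezoidal area
    under that curve over linear frequency, and QERB = f_max / ERB.
    A warning is issued when the curve has not decayed at the grid edges
    (ERB then underestimates the true bandwidth).
    """
    f, a = _as_curve(freqs, amps)
    a_max = a.max()
    if a_max == 0:
        raise TuningUndefinedError("all-zero amplitude curve")
    i_peak = int(np.argmax(a))
    p = (a / a_max) ** 2
    truncated = bool(p[0] > 0.1 or p[-1] > 0.1)
    if truncated:
        warnings.warn(
            "amplitude curve has not decayed at the grid edges; "
            "ERB is biased low by truncation",
            RuntimeWarning,
            stacklevel=2,
        )
    erb = float(np.trapezoid(p, f))
    f_max = float(f[i_peak])
    return TuningResult(f_max=f_max, erb=erb, q_erb=f_max / erb, erb_truncated=truncated)


def quantify_tuning(
    freqs: Sequence[float], amps: Sequence[float], *, log_axis: bool = True
) -> TuningResult:
    """Compute both Q10dB and QERB for one curve."""
    r10 = q10(freqs, amps, log_axis=log_axis)
    rerb = qerb(freqs, amps)
    return replace(r10, erb=rerb.erb, q_erb=rerb.q_erb, erb_truncated=rerb.erb_truncated)


def ratio_function_tuning(rf, *, log_axis: bool = True) -> TuningResult:
    """Tuning of a DPOAE ratio function, analysed vs the DP frequency.

    The amplitude curve |DPOAE| is re-indexed by ``f_dp`` (ascending) before
    Q10dB/QERB are computed, matching how emission tuning is compared with
    single-tone vibratory tuning.  The returned result also carries the
    optimal ``f2/f1`` ratio — the ratio maximising |DPOAE|, with ties broken
    toward the smallest ratio.
    """
    ratios = np.asarray(rf.ratios, dtype=float)
    f_dp = np.asarray(rf.f_dp, dtype=float)
    amps = np.abs(np.asarray(rf.dpoae))
    order = np.argsort(f_dp)
    res = quantify_tuning(f_dp[order], amps[order], log_axis=log_axis)
    # smallest ratio wins ties
    best = amps.max()
    optimal = float(ratios[np.isclose(amps, best)].min())
    return replace(res, optimal_ratio=optimal)


def nonlinear_gain(fr) -> float:
    """Nonlinear cochlear gain (dB) of a frequency response.

    The difference between stimulus-pressure-normalised CF magnitudes at 30
    and 90 dB SPL: a linear response yields 0 dB, a compressive one a
    positive gain.
    """
    levels = np.asarray(fr.levels, dtype=float)
    for need in (30.0, 90.0):
        if not np.any(np.isclose(levels, need)):
            raise ValueError(f"frequency response must contain the {need:g} dB SPL level")
    cf = fr.site.cf_ref

    def norm_db(level: float) -> float:
        mag, _ = fr.at_level(level)
        # interpolate magnitude in dB vs log2 frequency at the site CF
        mdb = 20.0 * np.log10(mag)
        val = float(np.interp(np.log2(cf), np.log2(fr.freqs), mdb))
        return val - level

    return norm_db(30.0) - norm_db(90.0)


def average_tuning(results: Sequence[TuningResult]) -> TuningResult:
    """Arithmetic mean of tuning metrics across repeated measurements."""
    if len(results) == 0:
        raise ValueError("no tuning results to average")
    for r in results:
        if not r.q10_defined and not r.q_erb_defined:
            raise TuningUndefinedError("cannot average undefined tuning results")

    def mean(attr: str) -> float:
        vals = [getattr(r, attr) for r in results]
        return float(np.mean(vals))

    return TuningResult(
        f_max=mean("f_max"),
        bw10=mean("bw10"),
        q10=mean("q10"),
        erb=mean("erb"),
        q_erb=mean("q_erb"),
        optimal_ratio=mean("optimal_ratio"),
    )
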