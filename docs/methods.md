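# Methods

This note documents the model, the synthetic-data generator that drives it,
the numerical conventions, and the design choices made where the design was
genuinely open. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## The wave-interference model

The 2f1−f2 emission is modelled as the coherent sum of distortion-product
(DP) wavelets generated along the cochlear partition:

1. The spatial displacement profiles of the f1 and f2 tones are obtained
   from a single-site reference frequency response by cochlear scaling
   symmetry: the response at position x to a tone at f equals the reference
   response at the equivalent frequency f′ = f·CF_ref/CF(x), with CF(x)
   from the log-linear mouse map, position(%) = 156.5 − 82.5·log10(f/kHz)
   over 5.13 mm. Magnitude is interpolated in dB and unwrapped phase in
   cycles, both linearly against log2 f, with straight-line extrapolation
   from the two nearest grid points beyond the reference span. Before any
   spatial use the reference phases must contain traveling-wave delay only,
   so the pure middle-ear delay (36 μs by default) is removed first; the
   code enforces this with a flag.
2. At each of 514 positions (0–5.13 mm in 0.01 mm steps) the two local
   displacements drive a first-order Boltzmann function
   y(x) = 1/(1 + e^{a1(x1−x)}), a1 = 0.28 nm⁻¹, x1 = 2.6 nm, resting
   position 0 (so y(0) ≈ 0.326). Stored RMS magnitudes are converted to
   peak amplitudes (×√2) before the nonlinearity. The simulation is
   time-domain: stimulus frequencies are rounded to the nearest 10 Hz so a
   100 ms window holds an integer number of cycles of f1, f2 and
   f_dp = 2f1−f2; the sampling rate is the smallest multiple of 100 kHz
   with fs ≥ 20·f2 (400 kHz for the single-drive default). The complex DP
   is the projection of the transducer output onto e^{−2πi·f_dp·t}, in the
   peak-amplitude convention, for which the small-signal closed form is
   |y‴(0)|·A1²A2/8 with phase 2φ1 − φ2 + ½ cycle (the cubic coefficient is
   negative at the default operating point). Locations whose
   intermodulation drive A1²A2 falls 200 dB below the maximum are assigned
   zero DP without simulation.
3. The DP is multiplied by the membrane low-pass transfer
   H(f) = 1/(1 + i·f/fc), a single pole with corner fc = CF·2^(−2.36)
   (the filter order is a modelling choice; only the corner is
   constrained), giving DP_generated(x).
4. Reverse propagation (slow-wave mode) weights each DP by the BM
   displacement a 40 dB SPL tone at f_dp would drive locally and shifts its
   phase by the local phase of a forward-traveling wave at f_dp (a lag,
   added). Velocity weighting multiplies the weight by 2π·f_dp. Fast-wave
   mode sums DP_generated directly. The zero-phase control sums magnitudes.
5. The complex sum over positions, swept over the f2/f1 grid
   (1.02–1.87 in 0.025 steps, 35 points) and stimulus level, yields ratio
   functions, which are quantified against the DP frequency with Q10dB and
   QERB.

`WaveInterferenceModel.fit()` evaluates all requested propagation variants
from one set of transducer simulations, since those depend only on the
stimulus fields.

## Tuning metrics

* **Q10dB** — peak frequency divided by the bandwidth 10 dB below the
  peak. Crossings are located by linear interpolation of dB amplitude
  against log2 frequency (a config switch selects linear frequency; the
  axis convention is not standardised in the literature). Curves whose
  flanks never reach −10 dB, or whose maximum sits on the grid edge, are
  flagged undefined rather than extrapolated. With non-monotone flanks the
  first crossing walking outward from the peak is used.
* **QERB** — amplitudes are normalised to their maximum, squared
  (∝ power), and integrated over linear frequency by the trapezoid rule on
  the native grid; QERB = f_max/ERB. Curves that have not decayed at the
  grid edges trigger a truncation warning and a flag.
* Ratio functions are re-indexed by f_dp = 2f1 − f2 (ascending) before
  quantification; the optimal ratio is the grid ratio maximising |DPOAE|,
  ties broken toward the smallest ratio.
* Noise floors follow the measurement convention mean + 3 sample SDs of
  neighbouring-bin magnitudes (±20–120 Hz for DPs, ±220–320 Hz at the
  stimulus frequencies); the sample (n−1) SD is used, the population/sample
  choice being unstated in common practice.
* The spatial phase spread of stapes-bound DPs is measured over the
  contiguous run of positions within 10 dB of the |DP_generated| maximum —
  the same criterion as the tuning bandwidth; an explicitly tracked
  unwrapped phase (generated-DP phase unwrapped along position plus the
  continuous reverse-wave lag) avoids half-cycle ambiguities.

## The synthetic generator

The generator stands in for averaged mouse basilar-membrane (BM)
single-tone responses; its defaults are the study conditions, calibrated
once against published summary statistics and not revisited:

* CF gain (stimulus-normalised CF response at 30 minus 90 dB SPL):
  41.1 dB apical, 40.5 dB middle turn.
* Q10dB falling by a factor of ~2 from 40 to 75 dB SPL (generator: 2.07),
  with Q10dB(40) ≈ 4.0.
* Middle-turn (CF 20 kHz, sharpness multiplier 1.65) Q10dB ≥ 1.5× apical
  at matched levels.
* Downward peak shift ≤ 0.15 + 0.05 octaves from the lowest to the highest
  level; 1.24 nm RMS at CF for a 30 dB SPL tone.
* Traveling-wave lag of 1.5 cycles at CF at low level (configurable; the
  literature rarely tabulates this number), accumulating monotonically and
  saturating about half an octave above CF; near-CF slope ~5 cycles/octave
  at low level, relaxing by about half at the highest levels; tail phase
  essentially level-independent below CF/2.

**Magnitude model.** In dB, the sum of a level-independent passive skirt
growing 1 dB/dB with level and an active gain window G(L)·W(ν) in
ν = log2(f/CF), with G(L) = gain_max·clip((90−L)/60, 0, 1). The passive
skirt is quadratic (16 dB/oct² below its peak, 120 above), peaks
`peak_shift_octaves` below CF, and saturates smoothly at −28 dB on the low
side — BM tails flatten toward a plateau rather than falling without
bound. The active window is a generalised exponential
exp(−½|ν/σ|^p) with σ = 0.38/0.11 oct and p = 0.8/2.2 below/above CF,
tapered off 1.3 octaves below CF so the far tail grows exactly linearly
with level. The heavy (p < 1) basal skirt matters: the model's mid-ratio
DPOAE peak is fed by the f1 wave's basal flank at the f2 place, and a
thin-skirted (Gaussian) window starves it, leaving the ratio functions
monotone instead of bandpass.

**Phase model.** φ(ν) = −phase_cycles_at_cf · L((ν−c)/w)/L(−c/w) with L
the logistic function, inflection c = 0.2 oct above CF, and width
w = 0.15·(1 + 0.9·(1 − G(L)/gain_max)) oct. Pinning the sigmoid value at
ν = 0 keeps the lag at CF level-independent, while the width carries the
level dependence of the near-CF slope. Two features were found to be
load-bearing for the interference mechanism and are worth stating
explicitly:

* The lag must keep accumulating slightly *past* the peak (inflection
  above CF). If the phase saturates right at CF, the apical flank of the
  generation region sums coherently and the destructive interference at
  small f2/f1 ratios — the entire source of the bandpass shape — is
  capped.
* The reference grid must be dense (CF/90 ≈ 0.01 octave;
  `model_reference_grid`). On the coarse 0.5-kHz measurement grid the
  piecewise-linear interpolation kinks floor the attainable cancellation
  (the 40 dB SPL low-ratio edge rises from −16 dB to −4 dB re peak).
  Generator defaults keep the 0.5-kHz measured convention; only the model
  constructor densifies.

The generator is deterministic; an optional helper adds a seeded
Rayleigh-type noise floor for robustness experiments.

## What the synthetic stand-in does and does not show

With these inputs the model reproduces the qualitative physics: bandpass
ratio functions at every level 40–70 dB SPL in both slow- and fast-wave
modes, a monotone zero-phase control, fast-wave tuning broader than
slow-wave, level-dependent optimal ratios (1.12–1.17 at f2 = 9 kHz,
~4% below the published modelled range 1.17–1.22), DPOAE decline setting
in once the spatial phase spread of stapes-bound DPs exceeds ~0.5 cycles,
and smaller optima for middle-turn inputs with the 0.32 mm apical
generation limit (mean 1.095 over 50–70 dB SPL).

It does *not* reproduce the published relation between model and input
tuning sharpness: with real averaged BM data the modelled ratio-function
Q10dB falls ~15% below the input single-tone Q10dB (and direct summation
~21% below), whereas the parametric stand-in yields model tuning somewhat
*sharper* than its input (≈ −25%, and ≈ +4% for fast wave). That
percentage is controlled by flank mass between −10 and −30 dB re peak —
the tip-versus-tail structure of real tuning curves — which the smooth
two-component parametric form cannot supply while simultaneously holding
the printed calibration statistics; window variants with an explicit
tip+tail shelf moved the percentage positive but destroyed the fast-wave
bandwidth definition and injected deep interference notches. Passing
tests on the synthetic inputs therefore validate the mechanism and the
pipeline, not this particular quantitative comparison with real data.

Other acknowledged simplifications, shared with the modelling approach the
package implements: no mutual suppression between the two tones
(single-tone responses are used as inputs), no reflection-source
component, no middle-ear or ear-canal acoustics beyond a pure delay, and
no OHC biophysics beyond the static Boltzmann nonlinearity plus membrane
low-pass.

## Numerical choices and degenerate inputs

* Frequencies are rounded to 10 Hz before simulation; non-commensurate
  frequencies or fs < 20·f2 raise errors.
* Level lookups accept exact grid levels or linear interpolation (dB
  magnitude, cycles phase) between bracketing levels.
* Undefined bandwidths propagate as NaN with a `q10_defined` flag; they
  are never clamped. `average_tuning` refuses undefined members.
* Phase wrap interval (−0.5, 0.5]; sweep unwrapping in order of
  increasing f_dp.
* Response tables round-trip bit-identically (`%.17g` on write,
  `float_precision="round_trip"` on read); duplicated (freq, level) rows
  and non-rectangular grids are rejected.
* Problem sizes: the shipped analyses use 35 ratios × 5 levels × 514
  positions for the apical sweeps and 35 × 3 × ~285 for the middle turn
  (the grid is truncated 0.32 mm apical to the f2 place), with a 100 ms
  window at 200–400 kHz sampling; the full reproduction runs in under a
  minute on one CPU.
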