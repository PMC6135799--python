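# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `mecopto`, in the spirit of a package-level
methods appendix. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic sessions

### Trajectory

Open-field foraging is modeled as a mean-reverting (Ornstein–Uhlenbeck)
velocity process with reflecting walls:

- box 75 × 75 cm, tracking clock 30 Hz;
- velocity time constant `tau_s = 2 s`; per-component stationary SD is
  set so that the 2-D speed (Rayleigh) has the requested mean, default
  15 cm/s;
- head direction = instantaneous movement heading + wrapped Gaussian
  noise (SD 10°), standing in for the two-diode estimate of a real rig.

Real animals are not OU processes: they pause, groom, and over-sample
walls and corners. The simulated occupancy is more uniform, and speeds
are more symmetric, than real data. Consequently the calibration results
below demonstrate correctness of the *statistics*, not robustness to
every behavioral pathology. No published speed distribution was
available to fit, so the defaults are chosen to look like a
well-habituated mouse rather than to reproduce a particular animal.

### Cell models

All units are inhomogeneous Poisson processes with intensity
λ(x, y, hd, v):

- **grid**: thresholded sum of three plane-wave cosines at 60°
  separations (wave number 4π/(√3·spacing)), normalized to [0, 1],
  background clipped at a threshold (default 0.3 of the normalized
  field) and rescaled, times `peak_rate`. The cosine construction is
  chosen over Gaussian bumps because its node positions and spacing are
  analytic, which the oracle tests exploit. Defaults: spacing 40 cm,
  peak 10–25 Hz.
- **hd**: von Mises `exp(κ(cos(θ−μ)−1))` normalized to peak 1. The
  session-level HD score of such a cell converges to the Bessel ratio
  I₁(κ)/I₀(κ), which is used as a closed-form oracle.
- **speed**: `max(0, intercept + slope·v)`.
- **conjunctive**: product of the grid and HD factors.
- **untuned / interneuron**: constant rate (interneurons simply default
  to high rate and a symmetric waveform summary, `peak_valley = 1.1`).

Spikes are drawn by exact thinning against the maximum intensity along
the path, with the intensity linearly interpolated between tracking
frames, so trains are exact samples from the stated model up to the
30 Hz resolution of the rate series.

### Light-response kernel

The per-pulse multiplicative gain is

- excitation: gain `1 + exc_gain` on a rectangular bump whose **onset**
  is at `exc_latency` (support `[latency, latency + width]`, width
  default 2 ms), jittered per trial by a Gaussian of SD `exc_jitter`;
- inhibition: drop to `1 − inh_depth` at `inh_onset` with linear
  recovery to 1 over `inh_recovery`. The 50 %-of-baseline crossing of
  this kernel is analytic: `inh_onset + (0.5 − (1−depth))/depth ·
  recovery` for depth ≥ 0.5 (e.g. 20 ms for full suppression at 10 ms
  with 20 ms recovery), which anchors the inhibition-window recovery
  test.

Placing the bump's *onset* (rather than its center) at `exc_latency`
makes the generator consistent with the latency estimator, which is
defined by the half-peak *rise* of the PSTH. Note the first-spike jitter
estimator measures `sqrt(exc_jitter² + width²/12)` plus baseline
contamination, not `exc_jitter` itself; the recovery experiment
therefore uses a 1 ms bump and a 2 Hz baseline, where the estimator bias
(≈ 0.08 ms at jitter 0.5 ms) is far below the stated 0.3 ms tolerance.

A variant generator (`apply_opto_with_displacement`) evaluates the rate
function at a per-pulse Gaussian-displaced position for candidates
inside the inhibition window: the cell keeps its firing statistics but
fires at the wrong place, which is the mechanism used to emulate
transiently degraded grid accuracy.

### LFP

Phase-continuous oscillation with instantaneous frequency
`f0 + freq_slope·v(t)` and amplitude `amp0 + amp_slope·v(t)`, plus white
noise and, optionally, a damped 3 ms transient at each pulse onset
emulating population-spike artifacts. Noise is drawn before artifacts so
that `artifact_amp = 0` reproduces the stim-free signal bit for bit
under the same seed.

Beware frequency aliasing in experiments: an 8 Hz theta with an 8 Hz
pulse train makes every peri-stimulus window sample a fixed oscillation
phase. Tests that need phase coverage use theta frequencies away from
the stimulation frequency.

## Analysis parameters

| Quantity | Value | Notes |
| --- | --- | --- |
| rate-map bins | 3 × 3 cm (1.5 cm for autocorrelation) | |
| smoothing kernel | fixed 5 × 5 matrix, center 0.16, sum 1 | applied as NaN-aware normalized convolution |
| rate-map NaN rules | bin center > 2.5 cm from every tracked point, or occupancy < 150 ms | |
| field extraction | local maxima > 2 Hz, contour at 0.3 × peak, simultaneous re-growth | see below |
| grid spacing | mean nearest-neighbor centroid distance | all-pairs distance grows with field count and is not a lattice estimate |
| gridness annulus | inner: first 1-bin ring with mean correlation < 0.2; outer: 1.25 × mean distance of the ≤ 6 nearest peaks | rotations by bilinear resampling |
| HD curve | 1° bins, score = resultant of the binned curve | zero-occupancy bins excluded |
| speed score | 33 ms rate bins, Gaussian smoothing with ±2 SD = 250 ms; Kalman speed | Kalman: constant velocity, meas. σ = 1 cm, accel. σ = 10 cm/s² |
| shuffle null | rigid shift U[20, 580] s (U[20, dur−20] for short sessions), wrapped; 1000 shuffles by default | label needs > 95th pct in ≥ 2 of 3 sessions |
| PSTH | ±40 ms, 1 ms bins (0.1 ms for latency), `Mean_pre` normalizer | edge-crossing trials dropped |
| interneuron gate | rate ≥ 5 Hz and peak–valley ≤ 1.3; opposite quadrant = principal; mixed quadrants excluded | |
| burst index | (max of 1 ms autocorrelogram in 0–10 ms − mean in 40–50 ms) / max of the two | defined here explicitly; small positive bias for Poisson trains because a maximum is compared with a mean — the test oracle simulates this null exactly |
| downsampling control | Pre spikes drawn without replacement to the exact test count, mean of 50 draws | small samples inflate resultant lengths; matching removes the bias |
| Morlet wavelet | center-frequency/bandwidth ratio 7; 0.1 Hz grid in 6–10 Hz, parabolic peak interpolation | |
| theta–speed inference | OLS slopes; two-session comparison via interaction term with Newey–West (HAC, 2 s lags) errors | naive OLS p-values are badly anti-conservative on autocorrelated theta series |

## Design decisions on genuinely open points

- **Field extraction.** Contours are grown from *local maxima* of the
  smoothed map in decreasing order; a bare "highest remaining bin" rule
  would seed spurious fields on the shoulders just outside an extracted
  0.3-contour. Where fields meet, contested bins are assigned by
  simultaneous breadth-first growth (first-reached wins, ties to the
  higher-peak field). Field boundaries for reporting are marching-squares
  level sets; membership is by bin.
- **Reference map.** Field boundaries for windowed metrics are detected
  on the bin-wise average of the three session maps (NaN in a minority of
  sessions ignored), which suppresses single-session occupancy noise.
- **Smoothing at NaN borders** renormalizes the kernel over valid
  neighbors. The alternative (zero-filling) would bleed rate mass into
  masked regions and break the constant-map invariance.
- **Inhibition-null direction.** The population threshold for inhibition
  is the 5 % extreme-decrease tail of the per-cell pre-light
  minimum-window distribution (a value below 1), mirroring the 95 %
  tail of maxima used for excitation; both classifiers then flag ≈ 5 %
  of null cells by construction. Because each cell's pre-light minimum
  shares data with its own normalizer `Mean_pre`, exact 5 % calibration
  additionally requires across-cell rate heterogeneity; the calibration
  suite therefore uses a lognormal rate population (median 2 Hz,
  σ_log = 1), which is also the realistic condition for cortical
  populations.
- **Direct vs synaptic excitation** is deliberately not distinguished;
  only a single excited flag is produced.
- **PSTH minimum-finding** smooths with a 3-bin moving average before
  locating the rate minimum so single-bin noise cannot place it;
  exposed as a parameter.
- **Speed filter.** No immobility cutoff is applied by default; the
  speed score accepts an optional `speed_filter_cm_s`.
- **Wavelet slope attenuation.** The Morlet estimator smooths the
  instantaneous frequency over ≈ 0.14 s at 8 Hz, attenuating the
  recovered speed–frequency slope by roughly 10 % for a 2 s-correlated
  speed process. The recovery test's tolerance accommodates this known
  estimator property; the regression is left unadjusted on purpose
  (deconvolving the regressor would be a different estimator).

## Problem sizes used by the test and acceptance suites

Sessions are 600 s (statistical suites) or 120–300 s (unit tests) at
30 Hz tracking; calibration uses 200 cells × 3 sessions × 200 shuffles;
parameter-recovery and dissociation experiments use 8 Hz stimulation
(4 800 trials per 600 s session) and populations of 20 cells. These
sizes keep every statistical check comfortably powered at desk scale;
the defaults in the library itself (e.g. 1000 shuffles) correspond to
full-scale use.

## Known limitations

- Spike waveforms are represented only by summary statistics; no
  waveform synthesis or clustering.
- No Neuralynx/NWB ingestion; the documented CSV/JSON (+ HDF5 LFP)
  bundle is the only interchange format.
- Group-level inferential statistics (ANOVAs, post-hoc families) are out
  of scope; the package stops at per-cell metrics and the slope
  interaction test.
- The trajectory generator does not model immobility bouts, wall
  following, or lighting artifacts in tracking.
- Theta estimates are computed on the raw (artifact-bearing) signal by
  default; `lfp_analysis.blank_around_pulses` exists only as a
  sensitivity-analysis helper, not as an artifact-removal method.
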