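# Methods

This note records the models implemented in `csibreath`, the parameter
choices that matter, and what the synthetic studies do and do not show.

## Signal model

The simulator realises the standard two-component reflection model for
a breathing person near a WiFi link. Per receive chain `j` and
subcarrier of wavelength λ:

    H_j(t) = exp(−j ψ(t)) · [ Hs_j + A_j m(t) exp(−j 2π d_j(t) / λ) + n_j(t) ]

* `Hs_j` — static component (line of sight plus fixed reflectors),
  complex constant per chain.
* `d_j(t) = b_j + g_j · d(t)` — dynamic path length: a per-chain
  resting length `b_j` plus the chest displacement `d(t)` scaled by a
  per-chain geometry factor `g_j`. The two receive antennas sit roughly
  half a metre apart, so the chest's motion projects differently onto
  the two reflection paths; without this difference the two-link ratio
  would carry no breathing signal at all (the shared part cancels).
* `ψ(t)` — random phase common to all chains of one device (carrier
  frequency offset and packet detection delay), modelled as a random
  walk. It multiplies the whole channel estimate, which is what makes
  the two-link ratio cancel it *exactly*; the additive complex Gaussian
  noise `n_j` is placed inside the bracket so the rotation leaves its
  distribution unchanged and the cancellation stays algebraic.
* `m(t)` — motion-burst amplitude multiplier (1 in quiet breathing).

Chest displacement `d(t)` is periodic with period `60 / rate_bpm`:
a half-cosine inhale ramp, a peak pause (inhale→exhale), a half-cosine
exhale ramp, and a longer trough pause (exhale→inhale). Half-cosine
ramps are C¹ at the pause boundaries, so the simulated trajectory has
no artificial corners that could alias as transitions. Ground truth
transition times are the pause midpoints, two per cycle.

Sampling timestamps are a uniform grid plus Gaussian jitter, sorted and
kept strictly increasing. Motion bursts additionally superimpose an
independent random-walk displacement inside the burst window.

### Default scene (the simulated study conditions)

| parameter | default | why |
| --- | --- | --- |
| sampling | 20 Hz nominal, 5 ms jitter SD | commodity CSI streaming rates |
| chest amplitude | 8 mm peak-to-peak | quiet adult chest-wall excursion |
| pauses | 0.5 s trough / 0.3 s peak | exhale→inhale pause slightly longer |
| λ | 57.9 mm | 5.18 GHz mid-channel; configurable |
| `Hs` | (1.0+0.3j, 0.8−0.2j) | static power ≫ dynamic, as in real rooms |
| `A` | (0.30, 0.24) | dynamic-to-static ratio ≈ −11 dB |
| `g` | (1.0, 0.45) | antenna separation vs ~1 m chest distance |
| `b` | (3.000, 3.117) m | resting paths; difference sets ratio phase offset |
| noise SD | 0.005/component | ≈46 dB CSI SNR on a strong link |
| ψ step SD | 0.05 rad/sample | raw phase drifts by radians per record |

With these values the one-way I/Q arc of the ratio per half-breath is
≈0.17 (|Q| ≈ 1.4), and raw-phase breathing extraction fails while the
ratio survives — the phenomenon the method exists for.

## Preprocessing

Real and imaginary parts of each chain are treated as two outputs of a
single Gaussian process (shared RBF length scale, constant scale,
white-noise term). Hyperparameters are fitted by maximising the
marginal likelihood on a contiguous window (≤192 samples, taken from
the middle of the record) with three fixed length-scale restarts; the
posterior mean at the uniform grid times is the interpolant, evaluated
blockwise (12 s blocks with a 4ℓ pad) so long records stay O(seconds).
One hyperparameter fit serves both chains of a record: independent
fits can land on different length scales and smooth the chains
asymmetrically, which distorts their ratio.

The length-scale prior is bounded to [0.05 s, 0.4 s] by default. The
lower bound avoids degenerate noise-tracking; the upper bound keeps the
interpolator from flattening breathing ramps and — critically — motion
bursts, which must survive into the dispersion statistic to be
detected. Both bounds are configurable.

The ratio is taken on the full interpolated CSI by default; a flag
(`ratio_on_dynamic`) ratios the static-removed series instead. Static
estimation offers a calibration-prefix mean (default, first 10 s) and a
centred moving average; which window real deployments should use
depends on whether a human-free calibration period exists. Samples
whose denominator magnitude falls below `1e−3 ×` median are marked
invalid and skipped downstream.

## Motion filtering

The dispersion of a window of W ratio samples is the (W−1)-normalised
sum of squared deviations from the window mean, averaged over
subcarriers and summed over admitted pairs of distinct links. Windows
with `D > 0.001` (the reference threshold, configurable) are flagged;
flagged samples are dropped, not repaired, and fitting proceeds per
contiguous clean segment.

The window is 0.15 s with a 0.05 s stride by default. The window length
trades drift sensitivity against noise: quiet breathing drifts the
ratio continuously, and over windows much longer than ~0.2 s that
drift alone exceeds the 0.001 threshold at realistic trajectory scales,
which would flag quiet breathing itself. At 0.15 s the quiet-breathing
dispersion stays a few 10⁻⁴ under the threshold at all supported rates
while gross motion exceeds it by an order of magnitude.

Flagged regions separated by clean gaps shorter than 1 s are merged
(`mask_close_gap_s`): gross motion episodes contain sub-second lulls
(direction reversals of the moving limb) during which windowed
dispersion dips, but the contamination has not ended. At defaults this
yields ≥90% coverage of simulated 2 s bursts with ≤2% false flags on
quiet samples.

## Trajectory fitting

Per clean segment, ordinary least squares of the real and imaginary
channels onto `p` Gaussian bumps with centres at fractional positions
`d/(p+1)` of the segment window (making the fit invariant to time
translation) and common width `s`. A ridge term of 1e−8 stabilises the
normal equations, and the segment mean is removed before the fit and
restored after — the bumps then only represent motion around the large
static offset. The complex fit separates exactly into the two real
fits because the objective is a sum of squared moduli.

Auto hyperparameters: bump spacing `min(expected_period/4, 0.5 s)` —
about four bumps per breath at the expected rate, but never sparser
than one bump per 0.5 s so faster-than-expected breathing (up to
~30 breaths/min) is not smoothed away; `s` equals the spacing.

## Breath extraction

Turning angles are the four-quadrant angle between incoming and
outgoing displacement vectors of the fitted trajectory at each interior
grid point, in [0, π]. The displacement vectors span a configurable
lag (default 0.8 s) rather than one grid step: during the transition
pause the trajectory is nearly stationary, so adjacent-sample
displacements are noise and the reversal is invisible at one-step
granularity; vectors spanning roughly the pause make the reversal angle
sharp (near π) while mid-ramp curvature stays far below threshold.

Transitions are local maxima of the angle series above `2π/3`, thinned
to a minimum separation of 0.8 s (shorter than any half-breath at
≤37 breaths/min). Each transition time is then refined by a
mirror-correlation estimate of the local centre of symmetry: the
trajectory around a transition, projected onto its local principal
direction, is a deceleration ramp, a pause, and the mirrored
acceleration ramp; maximising `Σ_u x(c+u)·x(c−u)` over candidate
centres `c` uses the high-velocity ramps to localise the pause centre,
which the angle peak alone fixes only to within the pause duration.
The refinement is plain post-processing of the fitted trajectory and
can be disabled (`refine_transitions`).

The waveform `S` starts at zero and accumulates the per-step chord
length of the fitted trajectory with a direction flag that starts at +1
and negates after each transition (the step *into* a transition still
moves in the old direction). The global sign is an arbitrary
convention — inhale versus exhale is not observable from arc length —
so scoring against a reference tries both signs and keeps the better.

The breathing rate is `60 / median(cycle intervals)` when at least
three full-cycle intervals (same-direction transition gaps) exist; the
median shrugs off a single missed or spurious turn. With fewer
intervals the rate falls back to counting half-cycles over the
transition span. Partial half-cycles at the record edges are excluded.
Rates of multiple clean segments combine with duration weights.

## Scoring

* **ACC** — per-breath terms `(t_ref − |t_ref − t_det|)/t_ref` after
  greedy nearest-time matching of breath anchors with a gate of
  0.5 × median reference interval; unmatched reference breaths score 0.
  The headline number is the global mean; per-minute bin means are
  reported alongside.
* **MAE** — mean absolute difference after min–max normalisation of
  both signals to [0, 1], the reference linearly resampled onto the
  extracted grid. Constant signals are rejected (normalisation
  undefined).
* **AER** — absolute difference of the two rates in breaths/min.

## What the synthetic studies show — and what they do not

The simulator emulates the features the pipeline is built to handle:
non-uniform sampling, a dominant static component, device-common phase
noise, per-antenna geometry, asymmetric transition pauses, and gross
motion bursts. It does not emulate multipath beyond one dynamic path,
Fresnel-zone blind spots, multiple people, posture drift, hardware
quantisation, or the irregular cycle-to-cycle variability of real
breathing (every simulated cycle has the same period). Passing the
synthetic studies therefore demonstrates the internal consistency and
noise robustness of the chain, not field performance; on real hardware
the absolute scores will depend on scene geometry in ways the
orientation and distance presets only sketch.

## Numerical details and degenerate inputs

* GP: `alpha = 1e−10` jitter on the kernel diagonal; outputs normalised
  per channel; prediction blocks padded by max(4ℓ, 0.25 s).
* Zero-length displacements carry turning angle 0 (logged as no turn).
* Arc length integrates chord lengths on a refined grid (factor 4),
  through the basis form for fitted trajectories and a cubic spline
  (linear below 4 points) otherwise.
* Segments with fewer clean samples than basis functions are skipped
  with a warning; a record with no fittable segment is a pipeline
  error, not a silent zero.
* Ratio grids must agree to 1e−9 s; ratio of a link with itself is an
  error outside explicitly flagged test use.

## Known limitations

* The turning-angle threshold `2π/3` and dispersion threshold `0.001`
  are fixed reference values; the dispersion threshold in particular is
  scale-dependent (the ratio is not normalised) and the window default
  was chosen to make the printed value meaningful at realistic
  trajectory scales.
* Breathing rates above ~30 breaths/min need a smaller basis spacing,
  angle lag and minimum separation than the defaults.
* The rate estimator assumes breathing is quasi-stationary over the
  record; a genuinely varying rate yields the median cycle, not a
  time-resolved rate curve.
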