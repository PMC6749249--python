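# Methods

`mosdetect` detects *moments of stress* (MOS) in wrist-worn wearable
recordings of galvanic skin response (GSR, microsiemens) and skin
temperature (ST, °C), geolocates them, and maps spatial clusters of
stress with the local Getis-Ord Gi* statistic. This note documents the
model, the defaults and why they are what they are, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Physiological model

An acute stressor triggers a skin-conductance response (SCR): after a
latency of roughly 1–5 s the conductance rises from a local minimum
(onset) to a peak over a rising time of 1–5 s, then recovers
asymptotically, reaching 50 % of the peak excursion after a
half-recovery time of roughly 1–10 s. The phasic SCR rides on a slowly
varying tonic skin-conductance level (SCL). Sympathetic activation also
constricts peripheral vessels, so wrist skin temperature (normally
32–35 °C) begins to *decrease* a few seconds (nominally 3 s) after the
conductance rise. The detector looks for this temporally shifted
coincidence: a conductance rise of the right shape accompanied by a
delayed temperature drop.

## Preprocessing chain

1. **Imputation.** Missing samples (sensor dropouts, values outside the
   physical 0.01–100 μS range) are replaced by the mean of the nearest
   valid previous and next value. Runs longer than `max_gap` (default 1)
   raise a data-quality error unless linear interpolation is explicitly
   enabled: neighbour-mean imputation is only justified for isolated
   dropouts.
2. **GSR filtering.** A first-order Butterworth low-pass at 5 Hz removes
   sensor noise; a first-order Butterworth high-pass at 0.05 Hz then
   splits the signal into phasic (SCR) and tonic (SCL = filtered −
   phasic) components, so the decomposition identity holds exactly.
3. **ST filtering.** A second-order 1 Hz low-pass and a second-order
   0.1 Hz high-pass produce a band-limited temperature trace, retained
   as an optional input to the temperature rule alongside the raw trace.
4. **Downsampling to 1 Hz.** Each integer-second window takes the mean
   of its samples; edge windows with partial coverage are filled by a
   cubic spline through the complete-window means.
5. **Geolocation join.** Each second is assigned the nearest-in-time GPS
   fix within 5 s, else null coordinates (lab sessions have no GPS).

**Nyquist clamping.** A 5 Hz cut-off cannot be realised on a 4 Hz
stream (Nyquist 2 Hz). Any cut-off at or above Nyquist is clamped to
0.99 × Nyquist with a warning, so the stage degrades to a gentle
anti-noise filter on 4 Hz recordings while acting at its nominal
frequency on faster ones.

**Zero-phase filtering.** Filtering is forward–backward by default:
it doubles the attenuation but does not shift response onsets, on which
the 3 s GSR→ST delay rule depends. A causal mode (`zero_phase=False`,
CLI `--no-zero-phase`) exists for streaming use; it introduces a
fraction-of-a-second onset lag.

Note that digital Butterworth filters (bilinear transform) attenuate
*more* than the analog magnitude response `|H(f)|² = 1/(1+(f/fc)^{2n})`
near Nyquist (reaching zero at Nyquist itself); the analytic formula is
a good approximation only well below Nyquist, which is how the tests
use it.

## Detection rules

On the 1 Hz table, every maximal run of strictly positive first
differences of the phasic GSR is a *candidate*: onset = run start
(local minimum), peak = run end (local maximum), rise run n = peak −
onset in seconds. Five rules score each candidate on the ternary scale
{0, 0.5, 1} (not / partially / fully satisfied):

| rule | feature | 1 | 0.5 | 0 |
|------|---------|---|-----|---|
| R1 | GSR increase run n | 2 ≤ n ≤ 5 | 5 < n ≤ 8 | otherwise |
| R2 | ST decrease (≥ 3 s run of negative diffs) starting s after onset | s = 3 | 2 ≤ s ≤ 6 | otherwise |
| R3 | rising time t_peak − t_onset | 1–5 s | 5–15 s | > 15 s |
| R4 | response slope arctan(Δg/Δt) | ≥ 10° | ≥ 8° | < 8° |
| R5 | gap to previous accepted MOS | > 10 s | — | ≤ 10 s |

The total score is TS = Σ scₙ·wₙ with Σwₙ = 100, so TS ∈ [0, 100] and
TS = 100 iff every rule is fully satisfied (given positive weights). A
candidate is accepted as a MOS when TS ≥ CS (critical score, default
75) **and** it is outside the 10 s refractory window (R5 = 1). Treating
R5 as a hard constraint rather than a weighted vote is deliberate: a
second detection within the average duration of a single stress
response would be double-counting the same response, and the hard form
guarantees two useful invariants — consecutive detections are always
separated by more than 10 s, and the number of detections is monotone
non-increasing in CS (eligibility no longer depends on detection
history). The boundary is strict: a gap of exactly 10 s still blocks.

The slope threshold "10°" is only meaningful for fixed axis units; here
Δg is in μS and Δt in s, so 10° corresponds to 0.176 μS/s.

### Which signal feeds which rule

The run structure (R1, R3, candidate boundaries) is evaluated on the
**phasic** component: the tonic drift would otherwise fuse long
stretches of slow upward wander into single runs and destroy the
run-length feature entirely in quiet recordings. The R4 amplitude,
however, is read from the **noise-filtered conductance** at the
candidate's onset and peak: SCR amplitude is defined as peak
conductance minus the pre-stimulus level, and the 0.05 Hz zero-phase
high-pass attenuates a canonical 1 μS / 4 s rise to about 0.6 μS —
enough to push a clearly full-score response (14°) down to the 8.5°
band edge. The temperature rule runs on the **raw 1 Hz ST**: the
0.1–1 Hz band both attenuates the slow (≈ 5 s) drop ramp and passes
most of the sensor noise, making the derivative-sign test
noise-dominated. All three choices are switches on `detect_mos`
(`gsr_column`, `amplitude_column`, `st_column`).

### Default weights

The original calibration's weights were never published; the shipped
defaults are a package choice:

    w = (25, 20, 10, 30, 15)   for R1..R5, CS = 75.

The governing constraint is w1 + w2 + w3 + w5 < CS: R1, R2, R3 and R5
are all satisfiable by zero-amplitude noise (any 2 s wiggle passes R1
and R3 for free, and flat-plus-noise temperature gives a ≥ 3 s negative
run somewhere in the 2–6 s window about a third of the time), so if
those four rules alone can reach the critical score the detector fires
on noise throughout a recording. Making the slope rule — the only
amplitude-bearing rule — necessary (its weight exceeding 25) removes
that failure mode while leaving the GSR-increase and ST-decrease rules
the heaviest contextual contributors. `calibrate_weights` (random
search over the weight simplex × a CS grid, maximising TP − λ·FP
against ground truth, deterministic given a seed) is the supported path
to study-specific weights.

## Synthetic sessions

The generator emulates the calibration protocol: sessions of 1500 s
framed by 300 s stimulus-free rest phases, ten identical stressors at
random times at least 60 s apart (sampled uniformly over the feasible
schedules by the exact construction: sorted uniforms on the slack
interval plus mandatory gaps — no rejection loop needed), canonical
SCR shape (latency 3 s, linear rise of 1 μS over 4 s, exponential decay
with rate ln 2 / half-recovery so the 50 %-recovery definition holds
exactly), an ST drop of 0.3 °C over 5 s starting 3 s after each rise
onset with a slow linear return, tonic baseline 2 μS with 0.01 μS/min
drift, and i.i.d. Gaussian sensor noise (0.01 μS, 0.02 °C per 4 Hz
sample). Optional knobs: per-event shape jitter over the
physiological ranges, geometric habituation of amplitudes, and a
designated stress-zone time window that confines stimuli and emits the
corresponding track polygon for spatial tests. GPS tracks are straight
constant-speed walks (1.4 m/s) with one fix per second.

The SCR amplitude scale is not a literature value — published studies
do not report a canonical amplitude for this protocol — so 1 μS was
fixed once as a typical clearly-visible response; it is configuration,
not a claim.

What the generator does **not** model: motion and pressure artifacts,
electrode drying, thermoregulatory and ambient-temperature ST trends,
GPS error, overlapping responses, or inter-individual differences.
Passing recovery tests on this data therefore shows the pipeline is
correct and well-calibrated *for clean, well-separated canonical
responses*; it does not predict field accuracy, where artifact pressure
and individual variation dominate.

## Spatial hotspot analysis

Geolocated detections and measurement seconds are binned into half-open
square cells (default 50 m) in a local equirectangular tangent plane
centred on the data centroid — at sub-10 km track extents the
projection error is centimetres, and the half-open convention counts
boundary points exactly once. Each cell carries the MOS ratio
x_j = detections / seconds of exposure, which standardises for unequal
dwell times. With self-inclusive binary distance-band weights w_ij
(default band 2 × cell size),

    Gi* = (Σ_j w_ij x_j − W_i x̄) / ( S · sqrt[(n S1_i − W_i²)/(n−1)] ),

with W_i = Σ_j w_ij, S1_i = Σ_j w_ij², x̄ the mean and S the population
standard deviation of x over all n cells. The statistic is already a
z-score; cells are classed hot / cold / not-significant by the
two-sided normal approximation at α (default 0.05). No multiple-testing
correction is applied by default (matching common practice for these
maps); degenerate inputs are explicit errors (constant field, singleton
grid) or warnings (a band so large that every cell neighbours every
other, where the variance term vanishes and z is set to 0).

## Numerical and design notes

- All timestamps are UTC epoch seconds end to end; there is no
  local-time arithmetic anywhere.
- Score-band edges follow the table above literally; ties at edges not
  fixed by it resolve to the higher score.
- Insufficient ST coverage for R2 (candidate too close to the end of
  the recording) scores 0 with a warning rather than erroring.
- Evaluation matches detections to stimuli greedily one-to-one within a
  ±10 s window; accuracy = TP/(TP+FP+FN), defined as 1 when all three
  are zero.
- Problem sizes in the test suite (sessions of 400–1500 s, 100-session
  property sweeps, grids ≤ 50 cells) were chosen to exercise every code
  path at interactive runtimes; all results are deterministic given the
  seeds baked into the tests.

## Known limitations

- The detector is binary (stress / no stress); response magnitude is
  reported only through TS.
- The rule thresholds are tailored to 1 Hz, wrist-worn, low-noise
  recordings; they are not global constants, and transfer to other
  sensors or sites requires recalibration.
- The equirectangular projection is inappropriate for tracks spanning
  hundreds of kilometres; swap in a proper projected CRS upstream if
  needed.
- Without GPS, spatial operations are disabled (null coordinates), not
  emulated.
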