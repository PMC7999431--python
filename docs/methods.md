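# Methods

## Signal model and sampling

The patch reads a resistive pressure sensor through a voltage divider and
transmits one 8-bit sample per 160 ms Bluetooth access, so the analysis
stream is uniformly sampled at 6.25 Hz with a Nyquist frequency of
3.125 Hz. All thresholds in the classifier therefore apply to
*discrete-time* quantities: in particular the derivative amplitude is the
maximum absolute central finite difference of the sampled stream, which for
fast waveform transitions is substantially smaller than the continuous-time
slope. This is deliberate — the phone only ever sees the sampled stream.

The resting divider voltage is not a measured quantity; the package uses
1.65 V, half the 3.3 V analog rail, which is where a divider sits when the
load matches the sensor resistance (the maximum-sensitivity operating
point). It is configurable per behavior in the simulator block.

## Feature extractors

* **Amplitude** — `max |V - median(V)|` over the window. The median
  baseline is robust to impulsive waveforms; the choice of peak deviation
  (rather than peak-to-peak or RMS) makes a ±0.55 V flapping swing report
  ~0.55 V, inside the 0.4–0.6 V range characteristic of flapping. The
  measure is invariant to baseline shifts and sign flips about the
  baseline.
* **Frequency** — periodogram argmax over non-DC bins when the peak power
  exceeds 4× the median non-DC power; otherwise the zero-crossing rate of
  the mean-removed signal divided by twice the window duration.
  The prominence gate keeps narrowband signals on the accurate spectral
  path while noise-like windows fall back to the zero-crossing estimate,
  which for band-limited noise sits near the band's RMS frequency and
  stays below the 1 Hz split. Quasi-constant windows report 0 Hz. Windows
  must span ≥ 2 s so the resolution (1/duration) is at worst 0.5 Hz around
  the 1 Hz decision boundary.
* **Derivative** — `np.gradient`: exact central differences with one-sided
  differences at the two stream endpoints, optionally after a moving
  average (`smooth_len`; default 1 = off). The sliding-window pipeline
  differentiates the whole stream once and cuts windows out of the
  derivative trace, so window edges see true central differences; the
  stream's own two endpoint samples are excluded from window maxima
  because one-sided differences double the apparent slope of a steep
  segment.
* **Cycle endings** — a Schmitt-trigger walk over the derivative with a
  hysteresis band (default 0.1 V/s, just above the ~0.08 V/s chatter of a
  one-LSB step per sample at 8 bits/3.3 V). Counts transitions of one
  chosen direction; the counts of the two directions can differ by at most
  one on any trace. Positive-to-negative endings are the per-cycle marker
  used for roll counting. Both directions are exposed because either
  convention may be preferred when aligning against video.

## Classifier

STOP is decided first, from amplitude alone (< 0.1 V), before any spectral
evaluation — a flat signal has no meaningful frequency. The remaining
windows are placed in the 2×2×2 space of strict high/low comparisons
against the splits (1 Hz, 0.5 V, 3 V/s): three cells are the rolling /
flapping / sliding signatures, every other cell is MOVING, and a feature
exactly equal to a split is ERROR. Equality-as-ERROR makes threshold
misconfiguration visible instead of silently tie-breaking; the splits live
in the run configuration precisely so they can be re-tuned when ERROR
appears. The dV/dt split is interpreted in V/s, consistent with volts and
seconds everywhere else.

Windowing default is 5 s windows hopped by 1 s: at least two full periods
of the slowest signature (0.625 Hz flapping) while keeping segmentation
latency near the few-second bout durations typical of this animal. Each
window's label is assigned to the window center; runs of identical labels
merge into maximal segments whose boundaries sit half a hop beyond the
outermost member centers, so segment durations sum exactly to the covered
timeline. Windows straddling a behavior change mix two signatures and
typically classify MOVING; segment boundaries are therefore accurate to
about one window length.

## Synthetic behavior waveforms

The generator's defaults are calibrated so that the *sampled* feature
triple of each behavior sits strictly inside its signature at zero noise,
with margins of several noise standard deviations at the default noise
levels:

* **stop** — constant baseline, Gaussian noise sd 0.01 V. Window amplitude
  ≈ 2.5 sd ≈ 0.03 V, far below the 0.1 V bound.
* **rolling** — 1.25 Hz two-harmonic waveform
  `A·(0.880·sin(2πft) − 0.508·sin(4πft))`, A = 0.52 V. A pure sinusoid
  cannot represent rolling: f > 1 Hz and A > 0.5 V force a peak slope
  2πfA > π > 3 V/s. The second harmonic flattens the sampled extrema so
  the 6.25 Hz central-difference derivative peaks at exactly 2.5 V/s
  (margin 0.5 V/s ≈ 5.7 noise sd below the split at 0.02 V noise) while
  the fundamental stays the dominant spectral line (3× the harmonic's
  power) — and both lines lie above 1 Hz, so the frequency test is robust
  either way.
* **flapping** — 0.625 Hz carrier (82% of the amplitude) plus one
  impulsive biphasic kick per cycle that swings the signal from −A to +A
  across two sample intervals, giving a sampled derivative of
  A/0.16 s = 3.44 V/s at A = 0.55 V. This reflects the physical picture of
  a violent flap: a fast strain transient riding on a slow stroke. The
  kick carries ~5% of the spectral power, so the dominant frequency stays
  at 0.625 Hz. Note 3.44 V/s is the *ceiling* for any waveform confined to
  ±0.55 V at this sample rate — the > 3 V/s flapping signature is only
  reachable at all because the kick uses the full amplitude in a single
  two-sample swing.
* **sliding** — a random-phase multisine: four tones at 0.30, 0.45, 0.62
  and 0.85 Hz with amplitudes 0.4/0.34/0.29/0.23 × A (A = 0.28 V), phases
  drawn from the seed, plus 0.015 V noise. This is a finite spectral
  representation of band-limited noise — no single dominant periodicity,
  window amplitude confined to roughly 0.15–0.45 V — chosen over filtered
  white noise because a genuinely random envelope occasionally dips a
  window's amplitude below the 0.1 V STOP bound, which would make even the
  noiseless signature non-deterministic.

Carrier periods are integer multiples of the sample interval (0.8 s = 5
samples; 1.6 s = 10 samples) so the sampled waveforms are phase-stable and
their discrete derivatives exactly reproducible; in multi-bout sessions
each bout's phase restarts at the bout's first sample for the same reason.
Traces are clipped to the [0, 3.3] V rail, and can optionally be passed
through the 8-bit ADC model to emulate the quantized stream (the calibrated
margins comfortably absorb the ±½ LSB ≈ 6.5 mV rounding).

What the generator does *not* emulate: bout-to-bout variability of
amplitude and tempo, waveform drift within a bout, sensor hysteresis and
creep, strap-tension changes, and transmission dropouts. Passing the
round-trip tests therefore shows the pipeline is correct and well-margined
under the modeled signatures, not that field recordings of real seals will
classify at the same accuracy.

## Hardware models

* **Peukert lifetime** `t = C/I^k` is evaluated with C in mAh and I in mA,
  reproducing the device estimate 7.74 ± 2.4 h for 350 mAh at 25 mA with
  k ∈ [1.1, 1.3]. As printed the law is dimensionally inconsistent (hours
  emerge only with these mixed units); the package keeps the convention
  rather than re-normalizing, and `lifetime_range` reports the midpoint
  and half-range over the coefficient interval.
* **RSSI decay** is fitted as `RSSI(d) = r0·exp(d/λ)` with r0 < 0 — the
  magnitude grows by e every λ meters — via linear regression of ln|RSSI|
  on distance. This is the only simple form consistent with a finite level
  at d = 0 and a 1/e characteristic distance; for the nominal link
  (r0 = −31.1 dBm, λ = 6.4 m) the level at one decay constant is
  −84.5 dBm. Replicate distances are legitimate inputs and weight the
  regression naturally. A fit is refused when RSSI is non-negative, fewer
  than 3 distinct distances exist, or the magnitude does not grow with
  distance.
* **ADC** rounding is half-up to the nearest code (common MCU behavior),
  giving a deterministic round-trip error ≤ ½ LSB; the reference is the
  regulated 3.3 V rail, not the 3.7 V cell.

## Problem sizes and numerical choices

Synthetic validation uses 30 s traces (187 samples, 26 windows each):
long enough for stable per-window statistics while keeping the full suite
in seconds. Noisy label-recovery statistics use 20 traces per behavior at
0.02 V noise; RSSI bias checks use 200 replicates of a 30-point table
(5 replicates × 6 distances, 2 dB noise). Uniform sampling is enforced at
the I/O boundary to 1 ns; trace CSVs store times to 9 decimals and voltages
to 6, so write→read round trips preserve both the waveform and the
uniformity invariant. The nominal sample interval of a parsed file is the
most common successive difference (first seen wins ties), so a single bad
row is reported by row number instead of silently shifting the nominal
rate. All randomness flows through explicit integer seeds; there is no
global RNG state anywhere in the package.

## Known limitations

* Defaults are calibrated for the 6.25 Hz device rate; generating the
  rolling or flapping waveforms at other sample rates (or re-sampling
  them) changes the discrete derivative and can leave the signature.
* The frequency analyzer reports the raw periodogram argmax; near-equal
  split of power between two lines (possible for heavily distorted
  waveforms) can flip the reported bin between windows.
* Segment boundaries are only window-accurate (± one window length), and
  sub-window bouts shorter than ~2 windows may be absorbed or labeled
  MOVING.
* The classifier is purely per-window; no temporal smoothing (HMM or
  run-length priors) is applied, by design.
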