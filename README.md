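# sealpatch

Signal analysis for a flipper-mounted pressure-sensor "smart patch" used to
monitor captive harbor seals (*Phoca vitulina*). The patch streams the
voltage at a resistive-sensor divider node over Bluetooth at one 8-bit
sample every 160 ms; the stream encodes flipper strain, and four behaviors —
**stop**, **rolling**, **flapping**, **sliding** — leave distinct signatures
in its amplitude, dominant frequency and time derivative.

The package is for researchers and engineers working with this class of
animal-borne tag: it simulates labeled sensor streams, extracts the window
features, classifies behavior with a threshold decision algorithm, counts
rolling cycles from derivative sign transitions, and models the supporting
electronics.

## The model

Each sliding window (default 5 s, hop 1 s) of the 6.25 Hz stream is reduced
to a feature triple

* amplitude `A = max |V - median(V)|` (V),
* dominant frequency `f` (Hz): periodogram argmax over non-DC bins, with a
  zero-crossing fallback when no clear spectral line exists,
* derivative amplitude `D = max |dV/dt|` (V/s), from central finite
  differences on the stream,

and mapped to a behavior by fixed thresholds:

| behavior | frequency | amplitude | dV/dt |
|----------|-----------|-----------|-------|
| stop     | —         | < 0.1 V   | —     |
| rolling  | > 1 Hz    | > 0.5 V   | < 3 V/s |
| flapping | < 1 Hz    | > 0.5 V   | > 3 V/s |
| sliding  | < 1 Hz    | < 0.5 V   | < 3 V/s |

Any other combination is `MOVING`; a feature landing exactly on a split is
`ERROR` (the cue to re-tune thresholds in the config rather than tie-break
silently). Positive-to-negative transitions of dV/dt mark the end of each
rolling cycle, so rolling segments also report a roll count.

The hardware models are closed forms: the sensing divider
`V_out = V_in * R_L / (R_L + R_S)` and its inverse; an n-bit ADC
quantize/dequantize pair (round-half-up, round-trip error ≤ ½ LSB);
Peukert's battery law `t = C / I^k`; the per-component power budget
`P = I * V_DD`; and a least-squares fit of the Bluetooth link's RSSI decay
`RSSI(d) = r0 * exp(d / λ)`.

## Worked example

Simulate a session of all four behaviors (15 s each), classify it, and
query the device models:

```sh
$ printf 'label,duration_s\nstop,15\nrolling,15\nflapping,15\nsliding,15\n' > script.csv
$ sealpatch simulate --script script.csv --seed 42 --out session.csv --truth-out truth.csv
$ sealpatch classify session.csv --out segments.csv
stop.count=1 stop.duration_s=10.56 stop.rolls=0
rolling.count=1 rolling.duration_s=14.40 rolling.rolls=16
flapping.count=1 flapping.duration_s=16.32 flapping.rolls=0
sliding.count=1 sliding.duration_s=10.56 sliding.rolls=0
moving.count=2 moving.duration_s=3.84 moving.rolls=0
```

All four bouts are recovered in order; the two short `MOVING` segments are
windows straddling bout changes, and the 14.4 s rolling segment contains 16
detected roll cycles (one per 0.8 s period of the default rolling
waveform, within edge trimming). The segments CSV carries each segment's
aggregate features:

```
label,t_start_s,t_end_s,frequency_hz,amplitude_v,dvdt_amp
STOP,1.920000,12.480000,1.458028,0.019034,0.075680
ROLLING,13.440000,27.840000,1.209677,0.534574,2.563960
FLAPPING,30.720000,47.040000,0.628558,0.565284,3.488804
SLIDING,47.040000,57.600000,0.403226,0.333979,0.898663
...
```

The device models print the battery-lifetime band for the patch's 350 mAh
cell at its 25 mA draw (Peukert coefficient 1.1–1.3) and the power budget
at the 3.3 V rail:

```sh
$ sealpatch battery --capacity 350 --current 25 --kmin 1.1 --kmax 1.3
lifetime_mean_h=7.74
lifetime_half_range_h=2.41
$ sealpatch power
mcu.power_mw=23.1
bluetooth.power_mw=59.4
temp_sensor.power_mw=0.0
pressure_sensor.power_mw=0.0
total_current_ma=25.0
```

That is, the patch runs 7.74 ± 2.4 h on a charge, and the 25 mA total draw
is dominated by the Bluetooth module (18 mA) and MCU (7 mA); the resistive
sensors draw effectively nothing.

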