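# Methods

This note records the model, the parameter choices, and the numerical
decisions behind `pcgfusion`, together with what the synthetic
validation does and does not demonstrate.

## Signal model and processing chain

The pipeline assumes two simultaneously recorded channels on a common
clock: a chest phonocardiogram (PCG) and a photoplethysmogram (PPG).
All times are seconds internally; canonical processing rates are
1 kHz (PCG) and 100 Hz (PPG), so the sample-count parameters below have
fixed physical meaning (the 20-sample entropy window spans 20 ms; the
10-sample peak spread spans 100 ms). Inputs at other rates are
resampled on load (polyphase, mean-padded edges).

### PCG segmentation

1. **Band-pass 20–200 Hz**, 4th-order Butterworth applied zero-phase
   (forward–backward), mean removed first. S1/S2 energy lies in this
   band; the upper edge is configurable to 400 Hz for microphones with
   wider response. Zero-phase filtering is essential because the gate
   edges below are read as onset times.
2. **Adaptive amplitude thresholding**: division by the maximum
   absolute value, then samples below `floor_frac = 0.05` of that
   maximum are zeroed. This suppresses the noise floor between sounds
   (the main source of false gate openings) and guarantees the
   entropy's |x| ≤ 1 domain.
3. **Third-order Shannon-entropy envelope**,
   SE = −(1/N)·Σ |x³|·ln|x³| over a centered N = 20 sample window with
   0·ln 0 := 0. Edge windows are truncated and renormalised so the
   envelope has the trace's length. The natural logarithm is used; the
   base only rescales SE, but the fixed gate offset (below) is defined
   on this scale.
4. **Smoothing**: a rectangular (moving-mean) kernel of 50 ms, forced
   to odd length and applied twice, giving a symmetric zero-phase
   triangular response. 50 ms is shorter than an S1/S2 burst but long
   enough to merge intra-sound spikes.
5. **Gate**: GL = 1 where SE exceeds its whole-record mean plus
   0.01. A single global mean (not a running mean) is used; with
   offset 0 the gate is invariant to envelope scaling.
6. **Boundaries**: rising edge → start, next zero sample → end; a
   segment open at the record end closes at the last sample. Segments
   closer than 20 ms are merged, then durations outside 30–250 ms are
   discarded (physiological S1/S2 duration bounds).

Two opposing timing biases nearly cancel at the gate's rising edge: the
noise floor delays the first visible burst samples, while the symmetric
smoothing advances the envelope's rise. On noiseless synthetic bursts
the detected start-points sit within about ±4 ms of the true onsets,
well inside the ±10 ms evaluation tolerance.

### PPG delineation

1. **Band-pass 0.5–5 Hz**, 2nd-order Butterworth zero-phase — the
   cardiac band up to the 220 bpm ceiling; the gentle order preserves
   pulse morphology.
2. **Moving-average smoothing** (centered, truncated edges), with the
   order chosen as the smallest n whose smoothed output has at most 10
   zero crossings per second of record, capped at 0.25 s of samples.
   The search is a deterministic linear scan.
3. **Peak detection.** Candidates are local maxima of the smoothed
   entropy envelope above 20% of its global maximum and at least one
   220-bpm period apart. Before the envelope is computed the trace is
   scaled to e^(−1/3) ≈ 0.717: the transform −y·ln y (y = |x|³) is
   monotone in |x| only up to that amplitude and returns to zero at
   |x| = 1, so an unscaled ±1-normalised pulse would produce an
   envelope *dip* exactly at its peak and candidates drifting onto the
   pulse flanks. Each candidate is refined to the waveform argmax
   within ±10 samples, with parabolic three-point interpolation for
   sub-sample timing; refined maxima with non-positive amplitude
   (troughs of the zero-mean trace) are rejected, and peaks violating
   the 60/220 s refractory spacing keep the larger amplitude.
   The refinement runs on the band-passed, smoothed trace. Reading the
   time off the raw waveform instead (supported via the
   `refine_trace` argument) removes the filter's systematic ~8 ms late
   shift of the asymmetric pulse peak but replaces it with ~10 ms of
   noise-driven argmax jitter on the flat pulse top, which is the worse
   trade; the systematic shift is absorbed by the labeling windows.
4. **Onsets**: per peak, the waveform minimum between the previous peak
   and the peak.

### S1/S2 identification

A detected start-point Tsp is labeled against a systolic-peak time
Tpeak as S1 when Tpeak − 500 ms ≤ Tsp < Tpeak − 20 ms and as S2 when
|Tsp − Tpeak| ≤ 20 ms (the shared boundary belongs to S2, whose window
is closed on both sides; a 1 ns guard absorbs float round-off at the
edges). The windows are disjoint by construction. One cycle is created
per peak; a start-point eligible for several peaks goes to a peak
giving the S2 label if any, else the earliest eligible peak, and when
several candidates land in one window the largest envelope peak keeps
the label while the rest become `other`. Unmatched start-points are
kept as `other` rather than dropped, preserving false-positive
accounting for evaluation.

Heart rate is 60 over the mean inter-peak interval; the predicted
per-recording sound count is round(2·bpm·duration/60) — 138 at 69 bpm
over 60 s.

## Synthetic data

The generator emulates exactly the timing structure the identification
rule relies on. Per cycle: an S1 burst at the cycle onset; an S2 burst
one systolic interval later, drawn from N(300, 20²) ms and clipped so
S1 stays strictly inside its window; a PPG pulse whose analytic maximum
lands at the S2 onset plus a uniform jitter. The jitter bound defaults
to ±10 ms — the physiological S2-to-peak dispersion is a bound of
±20 ms, not a distribution filling it, and a uniform fill of the
extreme bound would be unrealistic; the bound is configurable up to
±20 ms, at which the labeling windows are exactly saturated.

Bursts are Gaussian-windowed sinusoids (S1: 70 Hz carrier, 100 ms;
S2: 110 Hz, 80 ms, amplitude 0.8 relative to S1), supported on
[onset, onset + duration] with the Gaussian's 3σ tails at the support
edges. The PPG pulse is a gamma-like template (τ/τr)²·e^(2(1−τ/τr))
with rise τr = 150 ms, decaying to ~5% of peak 450 ms after the
maximum. Per-beat periods are 60/N(HR, 2²) bpm; cohorts draw subject
HRs from N(68.3, 3.2²) bpm truncated to [50, 100]. White Gaussian
noise is added per channel at a requested SNR defined on mean-square
power. One root seed feeds independent per-subject and per-channel
sub-streams, so recordings are bit-reproducible regardless of
generation order.

**What the generator does not emulate**: murmurs, S3/S4, respiratory
amplitude modulation, motion and contact artifacts, baseline wander,
dicrotic notches, or sensor-specific transfer functions. Passing tests
on this data demonstrate the timing logic and noise robustness of the
chain, not clinical performance on real recordings.

## Problem sizes used in validation

The automated checks run the full pipeline on a 20-subject cohort of
60 s recordings at 20 dB SNR (~2 700 truth events), pooled event-level
accuracy at ±10 ms tolerance; single-recording checks use 30–60 s
records across SNR ∈ {30, 20, 10, 0} dB. The whole suite completes in
well under a minute.

## Known limitations

- **The fusion count can never exceed the envelope count.** The
  identification rule labels boundaries the envelope segmentation
  already found; it filters, it does not recover. On this generator's
  white-noise model the envelope segmentation never over-detects (the
  duration rules and noise floor remove noise blips), so the
  envelope-only count is already exact at every tested SNR and the
  PPG-confirmed count cannot be closer to truth than it — the
  corresponding comparison in the acceptance suite documents this
  honestly as a failing expectation. On real devices, where envelope
  segmentation both over- and under-detects, the PPG reference is what
  rejects spurious sounds; recovering *missed* sounds would require a
  PPG-guided re-search of the envelope below the global gate threshold,
  which is outside the present classifier's contract.
- At 0 dB SNR the PPG delineation degrades faster than the PCG
  segmentation, so labeling accuracy (72% pooled) falls well below the
  20 dB figure even though detection sensitivity stays high.
- The ±20 ms S2 window is specific to chest-site PPG; other sensor
  sites (finger, wrist) add pulse-transit delay and would need a
  re-tuned window.
- `select_smoothing_order` reads the "10 zero crossings" criterion as a
  per-second budget; the moving-average formula is read as a sliding
  (not prefix) mean. Both readings are configurable assumptions.
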