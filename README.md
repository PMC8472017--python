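# pcgfusion

Automatic heart-sound analysis from a phonocardiogram (PCG) recorded
simultaneously with a photoplethysmogram (PPG). The package segments
heart sounds from the PCG with a Shannon-entropy envelope, delineates
the PPG systolic peaks, and labels each detected sound as **S1** or
**S2** purely from its timing relative to the PPG peak — no ECG
reference and no machine-learned model. It is aimed at wearable
auscultation settings (chest-worn microphone + optical pulse sensor)
where both channels are acquired by one device.

## Method

**PCG segmentation.** The PCG (1 kHz) is band-passed (zero-phase
Butterworth, 20–200 Hz), normalised with a noise floor, and transformed
with a third-order Shannon-entropy envelope over a sliding window of
N = 20 samples:

```
SE(i) = -(1/N) · Σ |x(j)³| · ln|x(j)³|        (j in the window at i)
```

which emphasises mid-amplitude bursts while flattening spikes and
low-level noise. After zero-phase rectangular smoothing, a gate signal
marks where the envelope exceeds its global mean plus a small offset:

```
GL(i) = 1   if  SE(i) > SE_avg + 0.01,   else 0
```

Rising/falling gate edges give each sound's start and end point, with
physiological duration limits (30–250 ms) and gap merging (20 ms).

**PPG delineation.** The PPG (100 Hz) is band-passed to 0.5–5 Hz
(consistent with a 220 bpm ceiling), smoothed with a moving average
whose order is selected by a zero-crossing criterion (≤ 10 crossings
per second), and searched for systolic peaks via the same entropy
envelope; each peak is refined to the waveform argmax within ±10
samples. Pulse onsets are the pre-peak minima.

**S1/S2 identification.** Blood needs under ~500 ms to reach the
periphery after the onset of systole, and S2 (semilunar-valve closure)
coincides with the PPG systolic peak to within ±20 ms at the chest.
Each sound start-point `Tsp` is therefore labeled against its cycle's
peak time `Tpeak`:

```
S1   if  Tpeak - 500 ms ≤ Tsp < Tpeak - 20 ms
S2   if  Tpeak -  20 ms ≤ Tsp ≤ Tpeak + 20 ms
```

Start-points matching no peak's windows are kept as `other`. Heart rate
comes from the mean inter-peak interval, and the predicted sound count
per recording is `round(2 · bpm · duration / 60)`.

Because no public dataset accompanies this problem setting, the package
ships a synthetic generator (`pcgfusion.synth`) producing paired 60 s
recordings — Gaussian-windowed S1/S2 bursts, an asymmetric PPG pulse
whose peak lands near the S2 onset, beat-to-beat heart-rate
variability, and white noise at a chosen SNR — with exact ground-truth
event times for every stage.

## Worked example

```python
from pcgfusion import (SynthConfig, generate_recording, identify_s1_s2,
                       heart_rate_from_peaks, predicted_sound_count,
                       match_detections)
from pcgfusion.ppg_delineation import delineate_ppg

rec = generate_recording(SynthConfig(seed=42, snr_db=20.0))
labeled, cycles = identify_s1_s2(rec.pcg, rec.ppg)
print("cycles:", len(cycles))
print("S1:", sum(s.label == "S1" for s in labeled),
      "S2:", sum(s.label == "S2" for s in labeled))

_, peaks, _ = delineate_ppg(rec.ppg)
hr = heart_rate_from_peaks(peaks)
print(f"heart rate {hr:.1f} bpm -> predicted {predicted_sound_count(hr, 60)} sounds")

rep = match_detections(labeled, rec.truth_s1, rec.truth_s2, tol_s=0.010)
print(f"sensitivity {rep.sensitivity:.3f}, label accuracy {rep.label_accuracy:.3f}")
```

On this 60 s recording (69 bpm subject, 20 dB SNR) the pipeline finds
69 cycles and labels 69 S1 and 69 S2 sounds; the estimated heart rate
is 69.2 bpm, predicting 138 sounds; every true sound is matched within
±10 ms (sensitivity 1.000, label accuracy 1.000, mean timing error
1.6 ms).

The same pipeline is available from the shell:

```
pcgfusion simulate --subjects 1 --seed 5 --snr-db 20 --out-dir data/
pcgfusion analyze  --pcg data/subj01.wav --ppg data/subj01_ppg.csv \
                   --out data/annotations.csv --summary data/summary.json
pcgfusion evaluate --annotations data/annotations.csv \
                   --truth data/subj01_truth.csv --report data/report.json
```

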