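"""PPG waveform delineation: systolic peaks and pulse onsets.

The photoplethysmogram is band-passed to the cardiac band (0.5-5 Hz,
consistent with a maximum heart rate of 220 bpm), smoothed with a
moving average whose order is chosen from a zero-crossing criterion,
and peak-normalised. Candidate systolic peaks are then located on the
smoothed Shannon-entropy envelope of the trace and refined to the local
maximum of the waveform itself inside a window of +-``spread`` samples
around each candidate (with parabolic sub-sample interpolation of the
refined maximum). Pulse onsets are the pre-peak minima.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .config import PpgParams
from .pcg_segmentation import ParameterError, shannon_envelope, smooth_envelope, windowed_mean
from .signal_io import SignalTrace

#: Minimum spacing of systolic peaks: one period at the 220 bpm ceiling.
MIN_PEAK_PERIOD_S = 60.0 / 220.0

#: The entropy term -y*ln(y), y = |x|^3, increases with |x| only up to
#: |x| = e^(-1/3) and falls back to zero at |x| = 1. Scaling the trace to
#: this value before the envelope keeps the transform monotone in
#: amplitude, so envelope humps stay aligned with waveform extrema
#: instead of dipping at them.
ENTROPY_MONOTONE_SCALE = float(np.exp(-1.0 / 3.0))

PeakKind = Literal["systolic_peak", "pulse_onset"]


@dataclass(frozen=True)
class PeakEvent:
    """A delineated PPG event (systolic peak or pulse onset)."""

    time_s: float
    amplitude: float
    kind: PeakKind = "systolic_peak"


def bandpass_ppg(
    trace: SignalTrace, low: float = 0.5, high: float = 5.0, order: int = 2
) -> SignalTrace:
    """Zero-phase Butterworth band-pass of the PPG; removes DC drift."""
    if trace.fs <= 2 * high:
        raise ParameterError(
            f"fs = {trace.fs} Hz too low for a band-pass up to {high} Hz"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    return replace(trace, samples=sosfiltfilt(sos, trace.samples - np.mean(trace.samples)))


def moving_average(trace: SignalTrace, n: int) -> SignalTrace:
    """Centered n-point moving mean (edges truncated and renormalised)."""
    if not (1 <= n <= len(trace)):
        raise ParameterError(f"moving-average order {n} outside [1, {len(trace)}]")
    return replace(trace, samples=windowed_mean(trace.samples, n))


def _zero_crossings(x: np.ndarray) -> int:
    return int(np.count_nonzero(x[:-1] * x[1:] < 0.0))


def select_smoothing_order(
    trace: SignalTrace,
    target_crossings: float = 10.0,
    cap_s: float = 0.25,
) -> int:
    """Smallest moving-average order meeting a zero-crossing budget.

    Returns the smallest ``n >= 1`` such that the n-smoothed trace has at
    most ``target_crossings`` zero crossings per second of record, capped
    at ``cap_s`` worth of samples. The input should already be band-passed
    (zero-mean), otherwise crossings are meaningless. Deterministic.
    """
    cap = max(1, int(round(cap_s * trace.fs)))
    budget = target_crossings * trace.duration_s
    for n in range(1, cap + 1):
        if _zero_crossings(windowed_mean(trace.samples, n)) <= budget:
            return n
    return cap


def _parabolic_offset(y_prev: float, y0: float, y_next: float) -> float:
    """Sub-sample offset of a quadratic through three equidistant points."""
    denom = y_prev - 2.0 * y0 + y_next
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (y_prev - y_next) / denom
    return float(np.clip(delta, -0.5, 0.5))


def detect_systolic_peaks(
    trace: SignalTrace,
    spread: int = 10,
    params: PpgParams | None = None,
    refine_trace: SignalTrace | None = None,
) -> list[PeakEvent]:
    """Detect systolic peaks on a preprocessed (band-passed, smoothed,
    peak-normalised) PPG trace.

    Candidates are local maxima of the smoothed Shannon-entropy envelope
    (computed on a copy scaled into the transform's monotone regime)
    above ``candidate_rel_threshold`` of its global maximum; each is
    refined to the argmax of the waveform within +-``spread`` samples,
    with parabolic interpolation for sub-sample timing. Refined peaks
    with non-positive amplitude (troughs of a zero-mean trace) are
    dropped, and peaks closer than one 220-bpm period keep the larger
    amplitude.

    ``refine_trace`` (same time grid) optionally supplies the waveform
    the final argmax is taken on — typically the raw smoothed PPG, whose
    pulse maxima are not displaced by the band-pass filter. Candidate
    vetting still happens on the zero-mean ``trace``.
    """
    params = params or PpgParams()
    x = trace.samples
    if len(x) < 3 or float(np.max(np.abs(x))) == 0.0:
        return []

    scaled = x / float(np.max(np.abs(x))) * ENTROPY_MONOTONE_SCALE
    env = shannon_envelope(replace(trace, samples=scaled), params.entropy_window_n)
    smooth_n_s = min(params.env_smooth_s, 0.9 * trace.duration_s / 2)
    env = smooth_envelope(env, max(smooth_n_s, 1.5 / trace.fs))
    ev = env.values
    if float(ev.max()) <= 0.0:
        return []

    min_dist = max(1, int(round(MIN_PEAK_PERIOD_S * trace.fs)))
    candidates, _ = find_peaks(
        ev, height=params.candidate_rel_threshold * float(ev.max()), distance=min_dist
    )

    xr = refine_trace.samples if refine_trace is not None else x
    refined: list[tuple[float, float]] = []
    for c in candidates:
        lo = max(0, c - spread)
        hi = min(len(x), c + spread + 1)
        i = lo + int(np.argmax(x[lo:hi]))
        if float(x[i]) <= 0.0:
            continue
        if xr is not x:
            lo = max(0, i - spread)
            hi = min(len(xr), i + spread + 1)
            i = lo + int(np.argmax(xr[lo:hi]))
        amp = float(xr[i])
        delta = 0.0
        if 0 < i < len(xr) - 1:
            delta = _parabolic_offset(float(xr[i - 1]), float(xr[i]), float(xr[i + 1]))
        refined.append((trace.t0 + (i + delta) / trace.fs, amp))

    # enforce the refractory spacing, keeping the larger amplitude
    refined.sort()
    kept: list[tuple[float, float]] = []
    for t, amp in refined:
        if kept and t - kept[-1][0] < MIN_PEAK_PERIOD_S:
            if amp > kept[-1][1]:
                kept[-1] = (t, amp)
        else:
            kept.append((t, amp))
    return [PeakEvent(time_s=t, amplitude=a, kind="systolic_peak") for t, a in kept]


def detect_pulse_onsets(trace: SignalTrace, peaks: list[PeakEvent]) -> list[PeakEvent]:
    """Pulse onset = minimum of the trace between consecutive peaks.

    For each systolic peak the onset is the argmin of the waveform on the
    interval from the previous peak (exclusive; trace start for the first
    peak) up to the peak, giving exactly one onset per peak and the
    interleaving onset_k-1 < peak_k-1 < onset_k < peak_k.
    """
    out: list[PeakEvent] = []
    prev_idx = 0
    for p in peaks:
        p_idx = int(round((p.time_s - trace.t0) * trace.fs))
        p_idx = min(max(p_idx, 0), len(trace) - 1)
        lo = min(prev_idx + 1, p_idx) if out else prev_idx
        hi = max(p_idx, lo + 1)
        i = lo + int(np.argmin(trace.samples[lo:hi]))
        out.append(
            PeakEvent(
                time_s=trace.t0 + i / trace.fs,
                amplitude=float(trace.samples[i]),
                kind="pulse_onset",
            )
        )
        prev_idx = p_idx
    return out


def delineate_ppg(
    trace: SignalTrace, params: PpgParams | None = None
) -> tuple[SignalTrace, list[PeakEvent], list[PeakEvent]]:
    """Full PPG chain: band-pass, order-selected smoothing, normalisation,
    peak and onset detection. Returns (processed trace, peaks, onsets)."""
    from .signal_io import resample

    params = params or PpgParams()
    if abs(trace.fs - params.fs_hz) > 1e-6:
        trace = resample(trace, params.fs_hz)
    filtered = bandpass_ppg(trace, params.band_low_hz, params.band_high_hz, params.filter_order)
    n = select_smoothing_order(filtered, params.target_crossings, params.smooth_cap_s)
    smoothed = moving_average(filtered, n)
    peak = float(np.max(np.abs(smoothed.samples)))
    if peak > 0:
        smoothed = replace(smoothed, samples=smoothed.samples / peak)
    peaks = detect_systolic_peaks(smoothed, params.peak_spread_samples, params)
    onsets = detect_pulse_onsets(smoothed, peaks)
    return smoothed, peaks, onsets
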