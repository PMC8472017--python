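"""PCG heart-sound segmentation via a Shannon-entropy envelope.

The chain turns a raw phonocardiogram into a list of heart-sound
boundaries:

1.  zero-phase Butterworth band-pass (baseline and high-frequency
    rejection; S1/S2 energy sits in roughly 20-200 Hz),
2.  adaptive amplitude thresholding: max-abs normalisation plus a noise
    floor that zeroes sub-threshold samples,
3.  third-order Shannon entropy over a short moving window,
        SE = -(1/N) * sum |x^3| * ln|x^3|,
    which emphasises mid-amplitude bursts while flattening both spikes
    and low-level noise,
4.  zero-phase rectangular (moving-mean) smoothing,
5.  a gate signal: GL = 1 where SE exceeds its global mean plus a small
    offset (0.01 on the natural-log entropy scale),
6.  boundary extraction from the gate's rising/falling edges with
    physiological duration limits and gap merging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .config import PcgParams
from .signal_io import InputError, SignalTrace


class ParameterError(ValueError):
    """A processing parameter is inconsistent with the data."""


@dataclass(frozen=True)
class EnvelopeTrace:
    """Nonnegative entropy envelope aligned sample-for-sample to a trace."""

    values: np.ndarray
    fs: float
    window_n: int
    t0: float = 0.0
    source_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GateSignal:
    """Binary gate marking where the envelope exceeds its threshold."""

    values: np.ndarray
    fs: float
    threshold: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise InputError("gate values must be binary")
        object.__setattr__(self, "values", v.astype(np.int8))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SoundBoundary:
    """Start/end of one detected heart sound (seconds, absolute time)."""

    start_s: float
    end_s: float
    peak_env: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise InputError("boundary requires start_s < end_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# --------------------------------------------------------------------------
# Stage implementations

def windowed_mean(x: np.ndarray, n: int) -> np.ndarray:
    """Centered n-point moving mean with truncated, renormalised edges.

    The window at position ``i`` spans indices ``i - n//2 .. i + (n-1)//2``
    clipped to the array; the sum is divided by the actual window length,
    so a constant input is returned unchanged.
    """
    if n <= 1:
        return np.asarray(x, dtype=float).copy()
    x = np.asarray(x, dtype=float)
    kernel = np.ones(n)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones(x.size), kernel, mode="same")
    return num / den


def bandpass_pcg(trace: SignalTrace, low: float, high: float, order: int = 4) -> SignalTrace:
    """Zero-phase Butterworth band-pass; output length equals input length."""
    nyq = trace.fs / 2.0
    if not (0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    # removing the mean first keeps the DC step from exciting edge transients
    return replace(trace, samples=sosfiltfilt(sos, trace.samples - np.mean(trace.samples)))


def adaptive_threshold(trace: SignalTrace, floor_frac: float = 0.05) -> SignalTrace:
    """Max-abs normalisation plus a noise floor.

    The trace is divided by its maximum absolute value and samples with
    magnitude below ``floor_frac`` (of that maximum) are zeroed. The
    output therefore lies in [-1, 1], the domain on which the entropy
    terms of the envelope are nonnegative. An all-zero trace is returned
    unchanged.
    """
    x = trace.samples
    peak = float(np.max(np.abs(x)))
    if peak == 0.0:
        return trace
    y = x / peak
    y[np.abs(y) < floor_frac] = 0.0
    return replace(trace, samples=y)


def shannon_envelope(trace: SignalTrace, window_n: int = 20) -> EnvelopeTrace:
    """Third-order Shannon-entropy envelope.

    For each sample, SE = -(1/N) * sum over a centered length-N window of
    |x^3| * ln|x^3|, with 0*ln(0) := 0 and edge windows truncated (the
    sum is divided by the actual window length). Requires |x| <= 1, which
    keeps every term nonnegative (maximal at |x|^3 = 1/e).
    """
    if window_n < 1:
        raise ParameterError("window_n must be >= 1")
    x = trace.samples
    if np.max(np.abs(x)) > 1.0 + 1e-9:
        raise InputError("shannon_envelope requires samples normalised to [-1, 1]")
    y = np.abs(x) ** 3
    term = np.zeros_like(y)
    nz = y > 0.0
    term[nz] = -y[nz] * np.log(y[nz])
    values = windowed_mean(term, window_n)
    return EnvelopeTrace(
        values=values, fs=trace.fs, window_n=window_n, t0=trace.t0,
        source_label=trace.label,
    )


def smooth_envelope(env: EnvelopeTrace, window_s: float) -> EnvelopeTrace:
    """Zero-phase rectangular smoothing (moving mean applied twice).

    The kernel length is ``round(window_s * fs)`` forced odd so the
    response is symmetric: a symmetric unimodal peak keeps its argmax.
    The forward+backward application gives an effective triangular
    response of the same centre.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    n = int(round(window_s * env.fs))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    if n > len(env):
        raise ParameterError(
            f"smoothing window of {n} samples exceeds trace length {len(env)}"
        )
    values = windowed_mean(windowed_mean(env.values, n), n)
    return replace(env, values=values)


def gate_envelope(env: EnvelopeTrace, offset: float = 0.01) -> GateSignal:
    """Threshold the envelope at its global mean plus ``offset``.

    GL(i) = 1 where SE(i) > mean(SE) + offset, else 0. The mean is taken
    over the whole record, so the gate is invariant to a uniform scaling
    of the envelope when offset = 0.
    """
    if len(env) == 0:
        raise InputError("empty envelope")
    threshold = float(np.mean(env.values)) + offset
    values = (env.values > threshold).astype(np.int8)
    return GateSignal(values=values, fs=env.fs, threshold=threshold, t0=env.t0)


def extract_boundaries(
    gate: GateSignal,
    min_dur_s: float = 0.030,
    max_dur_s: float = 0.250,
    merge_gap_s: float = 0.020,
    envelope: EnvelopeTrace | None = None,
) -> list[SoundBoundary]:
    """Turn gate edges into sound boundaries.

    A rising edge opens a segment and the next falling edge (the first
    zero sample) closes it; a segment still open at the end of the trace
    is closed at the last sample. Segments separated by a gap shorter
    than ``merge_gap_s`` are merged, then segments with durations outside
    [min_dur_s, max_dur_s] are discarded. ``envelope`` (when given, on
    the same grid) supplies each boundary's peak envelope value.
    """
    v = gate.values
    padded = np.concatenate(([0], v, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)            # index of first 1
    ends = np.flatnonzero(d == -1)             # index of first 0 after the run
    ends = np.minimum(ends, len(v) - 1)        # open at trace end -> last sample
    segments = [(int(s), int(e)) for s, e in zip(starts, ends) if e > s]

    merged: list[list[int]] = []
    gap_n = merge_gap_s * gate.fs
    for s, e in segments:
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out: list[SoundBoundary] = []
    for s, e in merged:
        dur = (e - s) / gate.fs
        if dur < min_dur_s or dur > max_dur_s:
            continue
        peak = float(np.max(envelope.values[s : e + 1])) if envelope is not None else float("nan")
        out.append(
            SoundBoundary(
                start_s=gate.t0 + s / gate.fs,
                end_s=gate.t0 + e / gate.fs,
                peak_env=peak,
            )
        )
    return out


def segment_pcg(trace: SignalTrace, params: PcgParams | None = None) -> list[SoundBoundary]:
    """Full envelope segmentation of a PCG trace at the canonical rate."""
    from .signal_io import resample  # local import keeps module deps one-way

    params = params or PcgParams()
    if abs(trace.fs - params.fs_hz) > 1e-6:
        trace = resample(trace, params.fs_hz)
    filtered = bandpass_pcg(trace, params.band_low_hz, params.band_high_hz, params.filter_order)
    gated_in = adaptive_threshold(filtered, params.floor_frac)
    env = shannon_envelope(gated_in, params.entropy_window_n)
    env = smooth_envelope(env, params.smooth_window_s)
    gate = gate_envelope(env, params.gate_offset)
    return extract_boundaries(
        gate, params.min_dur_s, params.max_dur_s, params.merge_gap_s, envelope=env
    )
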