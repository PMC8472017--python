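"""Signal containers, file I/O, resampling and two-channel alignment.

The pipeline works on two simultaneously recorded channels: a
phonocardiogram (PCG, WAV audio, canonically 1 kHz) and a
photoplethysmogram (PPG, two-column CSV, canonically 100 Hz). Everything
downstream runs on :class:`SignalTrace`, a plain uniformly-sampled
waveform with a start time, so the ms-scale timing logic never has to
touch sample indices across channels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly


class InputError(ValueError):
    """A file or argument violated an input contract."""


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled real-valued waveform.

    Sample ``i`` occurs at time ``t0 + i / fs`` seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise InputError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise InputError("samples must be finite")
        if not (self.fs > 0):
            raise InputError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    @property
    def end_s(self) -> float:
        """Time just past the last sample (t0 + n/fs)."""
        return self.t0 + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class SynchronizedPair:
    """A PCG and a PPG trace cropped to an identical time interval."""

    pcg: SignalTrace
    ppg: SignalTrace

    @property
    def duration_s(self) -> float:
        return min(self.pcg.duration_s, self.ppg.duration_s)


# --------------------------------------------------------------------------
# Readers

_INT_FULL_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_pcg_wav(path: str | Path) -> SignalTrace:
    """Read a PCG recording from a WAV file.

    Amplitudes are rescaled to [-1, 1] by the format's full-scale value
    (integer PCM divided by 2**(bits-1); float data taken as-is). Stereo
    files fall back to channel 0 with a warning.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except (ValueError, EOFError, FileNotFoundError) as exc:
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no audio")
    if data.ndim == 2:
        warnings.warn(
            f"{path.name}: {data.shape[1]}-channel audio; using channel 0",
            stacklevel=2,
        )
        data = data[:, 0]
    if data.dtype in _INT_FULL_SCALE:
        samples = data.astype(float) / _INT_FULL_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return SignalTrace(samples=samples, fs=float(fs), t0=0.0, label="PCG")


def write_pcg_wav(trace: SignalTrace, path: str | Path) -> None:
    """Write a trace as 16-bit PCM WAV (amplitudes clipped to [-1, 1])."""
    x = np.clip(trace.samples, -1.0, 1.0)
    data = np.round(x * 32767.0).astype(np.int16)
    wavfile.write(Path(path), int(round(trace.fs)), data)


def read_ppg_csv(path: str | Path) -> SignalTrace:
    """Read a PPG waveform from a ``time_s,amplitude`` CSV.

    The sampling rate is inferred as 1/median(dt); spacing deviating from
    the median by more than 1% is rejected as non-uniform.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise InputError(f"cannot read PPG CSV {path}: {exc}") from exc
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise InputError(f"{path}: need at least 2 samples")
    try:
        t = df["time_s"].astype(float).to_numpy()
        a = df["amplitude"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: non-numeric cells") from exc
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InputError(f"{path}: time_s must be strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.01 * med:
        raise InputError(f"{path}: sampling is non-uniform beyond 1% tolerance")
    return SignalTrace(samples=a, fs=1.0 / med, t0=float(t[0]), label="PPG")


def write_ppg_csv(trace: SignalTrace, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": np.round(trace.times(), 6), "amplitude": trace.samples}
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Resampling / alignment

def resample(trace: SignalTrace, target_fs: float) -> SignalTrace:
    """Band-limited (polyphase) resampling to ``target_fs``.

    Identity when the rate already matches; duration is preserved to
    within one output sample.
    """
    if not (target_fs > 0):
        raise InputError("target_fs must be positive")
    if math.isclose(target_fs, trace.fs, rel_tol=1e-9):
        return trace
    frac = Fraction(target_fs / trace.fs).limit_denominator(10_000)
    # mean-padding keeps DC exactly flat at the edges instead of letting
    # it decay toward zero padding
    out = resample_poly(trace.samples, frac.numerator, frac.denominator, padtype="mean")
    n_expected = int(round(len(trace) * target_fs / trace.fs))
    out = out[: max(n_expected, 1)]
    return replace(trace, samples=out, fs=float(target_fs))


def align(pcg: SignalTrace, ppg: SignalTrace) -> SynchronizedPair:
    """Crop both channels to their common time interval (no resampling)."""
    start = max(pcg.t0, ppg.t0)
    end = min(pcg.end_s, ppg.end_s)
    if end - start <= 0:
        raise InputError("traces do not overlap in time")

    def crop(tr: SignalTrace) -> SignalTrace:
        i0 = int(np.ceil((start - tr.t0) * tr.fs - 1e-9))
        i1 = int(np.floor((end - tr.t0) * tr.fs + 1e-9))  # exclusive
        i0, i1 = max(i0, 0), min(i1, len(tr))
        return replace(tr, samples=tr.samples[i0:i1], t0=tr.t0 + i0 / tr.fs)

    return SynchronizedPair(pcg=crop(pcg), ppg=crop(ppg))


# --------------------------------------------------------------------------
# Annotations

ANNOTATION_COLUMNS = ("time_s", "event", "source")


def write_annotations(sounds: Sequence, peaks: Sequence, path: str | Path) -> None:
    """Write labeled heart sounds and PPG events as a sorted CSV.

    ``sounds`` are objects with ``start_s``/``label`` (source ``pcg``);
    ``peaks`` have ``time_s``/``kind`` (source ``ppg``, events
    ``ppg_peak`` / ``ppg_onset``). Timestamps carry 3 decimals (1 ms).
    """
    rows: list[tuple[float, str, str]] = []
    for s in sounds:
        rows.append((float(s.start_s), str(s.label), "pcg"))
    for p in peaks:
        event = "ppg_peak" if p.kind == "systolic_peak" else "ppg_onset"
        rows.append((float(p.time_s), event, "ppg"))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(",".join(ANNOTATION_COLUMNS) + "\n")
        for t, event, source in rows:
            fh.write(f"{t:.3f},{event},{source}\n")


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read an annotation CSV back into a DataFrame (sorted by time)."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing annotation columns {sorted(missing)}")
    return df.sort_values(["time_s", "event"], kind="stable").reset_index(drop=True)
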