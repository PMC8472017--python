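"""Scoring of pipeline output against ground truth or a reference device.

Provides event-level detection matching (sensitivity, PPV, timing error,
label accuracy), Pearson cross-correlation maximised over lag,
Bland-Altman agreement statistics, the Wilcoxon paired signed-rank test,
and the envelope-only ("envelogram") sound count used as the PCG-only
baseline against the PPG-referenced fusion count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .config import PcgParams
from .pcg_segmentation import segment_pcg
from .signal_io import InputError, SignalTrace


@dataclass(frozen=True)
class DetectionReport:
    """Event-level detection scores against ground truth."""

    tp: int
    fp: int
    fn: int
    mean_abs_timing_err_s: float
    n_correct_label: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def label_accuracy(self) -> float:
        """Fraction of matched events carrying the correct S1/S2 label."""
        return self.n_correct_label / self.tp if self.tp else float("nan")

    @property
    def accuracy(self) -> float:
        """Correctly labeled matched events over all truth events."""
        n_truth = self.tp + self.fn
        return self.n_correct_label / n_truth if n_truth else float("nan")


@dataclass(frozen=True)
class BlandAltmanStats:
    """Bias and 1.96-SD limits of agreement between paired measurements."""

    bias: float
    loa_low: float
    loa_high: float


def match_detections(
    detected: Sequence,
    truth_s1: Sequence[float],
    truth_s2: Sequence[float],
    tol_s: float = 0.010,
) -> DetectionReport:
    """Greedy one-to-one matching of detections to truth events.

    ``detected`` are LabeledSound-like objects (``start_s``, ``label``);
    every detected start-point counts as a detection regardless of label.
    Both streams are walked in time order; a pair within ``tol_s`` is a
    match (TP), an unmatched detection an FP, an unmatched truth event an
    FN. Label accuracy is scored over matched pairs.
    """
    truth = sorted(
        [(float(t), "S1") for t in truth_s1] + [(float(t), "S2") for t in truth_s2]
    )
    det = sorted(detected, key=lambda d: d.start_s)

    tp = fp = fn = correct = 0
    errs: list[float] = []
    i = j = 0
    while i < len(det) and j < len(truth):
        dt = det[i].start_s - truth[j][0]
        if abs(dt) <= tol_s:
            tp += 1
            errs.append(abs(dt))
            if det[i].label == truth[j][1]:
                correct += 1
            i += 1
            j += 1
        elif dt < 0:
            fp += 1
            i += 1
        else:
            fn += 1
            j += 1
    fp += len(det) - i
    fn += len(truth) - j
    return DetectionReport(
        tp=tp,
        fp=fp,
        fn=fn,
        mean_abs_timing_err_s=float(np.mean(errs)) if errs else float("nan"),
        n_correct_label=correct,
    )


def max_cross_correlation(
    a: SignalTrace, b: SignalTrace, max_lag_s: float = 0.1
) -> tuple[float, float]:
    """Pearson correlation maximised over integer lags in +-max_lag_s.

    Returns (coefficient, lag_s); a positive lag means ``b`` is delayed
    relative to ``a``. Constant traces have no defined correlation.
    """
    if abs(a.fs - b.fs) > 1e-9:
        raise InputError("traces must share a sampling rate")
    xa, xb = a.samples, b.samples
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise InputError("correlation undefined for a constant trace")
    max_lag = int(round(max_lag_s * a.fs))
    n = min(len(xa), len(xb))
    if n - max_lag < 2:
        raise InputError("traces too short for the requested maximum lag")
    best_r, best_lag = -np.inf, 0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            u, v = xa[: n - lag], xb[lag:n]
        else:
            u, v = xa[-lag:n], xb[: n + lag]
        su, sv = np.std(u), np.std(v)
        if su == 0 or sv == 0:
            continue
        r = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
        if r > best_r:
            best_r, best_lag = r, lag
    return best_r, best_lag / a.fs


def bland_altman(a: Sequence[float], b: Sequence[float]) -> BlandAltmanStats:
    """Bland-Altman agreement: bias = mean(a - b), LoA = bias +- 1.96 SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise InputError("bland_altman needs two equal-length lists (n >= 2)")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanStats(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired samples.

    Zero differences are discarded; at least 5 informative pairs are
    required for the test to be meaningful.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("paired samples must have equal length")
    d = a - b
    d = d[d != 0.0]
    if d.size < 5:
        raise InputError("need >= 5 non-zero paired differences")
    return float(stats.wilcoxon(d, alternative="two-sided").pvalue)


def count_sounds_envelogram(pcg: SignalTrace, params: PcgParams | None = None) -> int:
    """PCG-only baseline: number of sounds found by envelope segmentation
    alone, with no PPG reference."""
    return len(segment_pcg(pcg, params))
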