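"""PPG-referenced identification of S1 and S2 heart sounds.

Physiological premise: blood takes less than ~500 ms to reach the
periphery after the onset of systole (S1), while the second heart sound
S2 — semilunar-valve closure at the systolic pressure peak — occurs
within +-20 ms of the PPG systolic peak measured at the chest. A
detected heart-sound start-point ``t_sp`` is therefore labeled against
the systolic-peak time ``t_peak`` of its cardiac cycle:

    S1  if  t_peak - 500 ms <= t_sp <  t_peak - 20 ms
    S2  if  t_peak -  20 ms <= t_sp <= t_peak + 20 ms

and ``other`` when no peak's windows contain it. The two windows are
disjoint by construction, so at most one label can fire per peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Optional

import numpy as np

from .config import FusionParams, PipelineConfig
from .pcg_segmentation import SoundBoundary, segment_pcg
from .ppg_delineation import PeakEvent, delineate_ppg
from .signal_io import InputError, SignalTrace

Label = Literal["S1", "S2", "other"]


@dataclass(frozen=True)
class LabeledSound:
    """A heart-sound start-point with its S1/S2/other label.

    ``anchor_peak_s`` is the PPG systolic-peak time the label was taken
    against (None for ``other``), ``cycle_index`` the cycle it belongs to.
    """

    start_s: float
    label: Label
    cycle_index: Optional[int] = None
    anchor_peak_s: Optional[float] = None
    peak_env: float = float("nan")


@dataclass(frozen=True)
class CardiacCycle:
    """One PPG-peak-anchored cardiac cycle with its S1 and S2 (if found)."""

    peak_s: float
    s1: Optional[LabeledSound] = None
    s2: Optional[LabeledSound] = None


def classify_start_point(
    t_sp: float, t_peak: float, params: FusionParams | None = None
) -> Label:
    """Label one start-point against one systolic peak.

    The S2 window is closed on both sides, so the shared boundary at
    ``t_peak - 20 ms`` belongs to S2; the S1 window is closed at
    ``t_peak - 500 ms`` and open at its late edge.
    """
    params = params or FusionParams()
    w = params.s2_window_s
    eps = 1e-9                                # absorb float round-off at the edges
    lead = t_peak - t_sp                      # positive when the sound precedes the peak
    if -w - eps <= lead <= w + eps:
        return "S2"
    if w + eps < lead <= params.s1_max_lead_s + eps:
        return "S1"
    return "other"


def pair_cycles(
    peaks: list[PeakEvent],
    boundaries: list[SoundBoundary],
    params: FusionParams | None = None,
) -> tuple[list[LabeledSound], list[CardiacCycle]]:
    """Assign each sound start-point to a cardiac cycle and label it.

    One cycle per systolic peak. A start-point eligible for several
    peaks' windows goes to a peak giving the S2 label if any (the +-20 ms
    window is the more specific claim), otherwise to the earliest
    eligible peak. Within a cycle, when several candidates land in the
    same window the one with the largest envelope peak keeps the label
    and the rest become ``other``.
    """
    params = params or FusionParams()
    peak_times = [p.time_s for p in peaks]
    # cycle slot -> list of (boundary index, label) candidates
    s1_cand: dict[int, list[int]] = {}
    s2_cand: dict[int, list[int]] = {}
    assignment: list[tuple[Label, Optional[int]]] = []

    for bi, b in enumerate(boundaries):
        hits: list[tuple[int, Label]] = []
        for k, tp in enumerate(peak_times):
            if tp - b.start_s > params.s1_max_lead_s + 1e-12:
                break  # peaks sorted: every later peak is even further ahead
            lab = classify_start_point(b.start_s, tp, params)
            if lab != "other":
                hits.append((k, lab))
        if not hits:
            assignment.append(("other", None))
            continue
        s2_hits = [h for h in hits if h[1] == "S2"]
        k, lab = s2_hits[0] if s2_hits else hits[0]
        assignment.append((lab, k))
        (s1_cand if lab == "S1" else s2_cand).setdefault(k, []).append(bi)

    def _winner(cands: list[int]) -> int:
        envs = [boundaries[i].peak_env for i in cands]
        if all(math.isnan(e) for e in envs):
            return cands[0]
        return cands[int(np.nanargmax(envs))]

    winners: dict[tuple[int, str], int] = {}
    for k, cands in s1_cand.items():
        winners[(k, "S1")] = _winner(cands)
    for k, cands in s2_cand.items():
        winners[(k, "S2")] = _winner(cands)

    labeled: list[LabeledSound] = []
    for bi, b in enumerate(boundaries):
        lab, k = assignment[bi]
        if lab != "other" and winners.get((k, lab)) != bi:
            lab, k = "other", None             # lost the within-cycle tie-break
        labeled.append(
            LabeledSound(
                start_s=b.start_s,
                label=lab,
                cycle_index=k,
                anchor_peak_s=peak_times[k] if k is not None else None,
                peak_env=b.peak_env,
            )
        )

    cycles: list[CardiacCycle] = []
    for k, tp in enumerate(peak_times):
        s1 = next((s for s in labeled if s.cycle_index == k and s.label == "S1"), None)
        s2 = next((s for s in labeled if s.cycle_index == k and s.label == "S2"), None)
        cycles.append(CardiacCycle(peak_s=tp, s1=s1, s2=s2))
    return labeled, cycles


def identify_s1_s2(
    pcg: SignalTrace,
    ppg: SignalTrace,
    config: PipelineConfig | None = None,
) -> tuple[list[LabeledSound], list[CardiacCycle]]:
    """End-to-end pipeline: segment the PCG, delineate the PPG, and label
    every detected heart-sound start-point as S1/S2/other."""
    config = config or PipelineConfig()
    boundaries = segment_pcg(pcg, config.pcg)
    _, peaks, _ = delineate_ppg(ppg, config.ppg)
    return pair_cycles(peaks, boundaries, config.fusion)


def heart_rate_from_peaks(peaks: list[PeakEvent]) -> float:
    """Mean heart rate (bpm) from inter-peak intervals: 60 / mean(dt)."""
    if len(peaks) < 2:
        raise InputError("need at least 2 systolic peaks to estimate heart rate")
    times = np.array([p.time_s for p in peaks])
    return 60.0 / float(np.mean(np.diff(times)))


def predicted_sound_count(bpm: float, duration_s: float) -> int:
    """Predicted number of S1+S2 sounds: two per cycle, rounded.

    At 69 bpm over 60 s this is 138, the per-subject prediction used when
    auditing detected counts against the heart rate.
    """
    if bpm <= 0 or duration_s <= 0:
        raise InputError("bpm and duration_s must be positive")
    return int(math.floor(2.0 * bpm * duration_s / 60.0 + 0.5))
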