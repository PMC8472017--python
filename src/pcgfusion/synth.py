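"""Synthetic paired PCG+PPG recordings with ground-truth timing.

The generator emulates the timing structure the fusion rule relies on:
per cycle, an S1 burst at the cycle onset, an S2 burst one systolic
interval (~300 ms) later, and a PPG pulse whose systolic peak lands
within a small jitter of the S2 onset — so that, by construction, every
cycle satisfies the S1 window (20-500 ms before the peak) and the S2
window (+-20 ms around the peak). Heart sounds are Gaussian-windowed
sinusoids (Morlet-like bursts); the PPG pulse is an asymmetric
gamma-shaped template (fast rise ~0.15 s, slow decay ~0.45 s). White
Gaussian noise can be added per channel at a prescribed SNR.

Identical seeds give bit-identical recordings; cohorts derive
independent per-subject streams from one root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import PCG_FS_HZ, PPG_FS_HZ
from .signal_io import InputError, SignalTrace

#: Cohort-level heart-rate distribution (bpm): subjects' resting rates.
COHORT_HR_MEAN_BPM = 68.3
COHORT_HR_SD_BPM = 3.2


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters for one paired recording.

    Timing invariants enforced at construction: the S2-to-peak jitter
    bound stays within the 20 ms S2 window, and the systolic interval
    (plus jitter) keeps S1 inside its (20, 500] ms pre-peak window.
    """

    duration_s: float = 60.0
    hr_bpm: float = 69.0
    hr_sd_bpm: float = 2.0          # beat-to-beat standard deviation
    systole_s: float = 0.300        # mean S1 -> S2 onset interval
    systole_sd_s: float = 0.020
    s2_peak_jitter_s: float = 0.010  # |S2 onset - PPG peak| bound (<= 0.020)
    s1_freq_hz: float = 70.0
    s2_freq_hz: float = 110.0
    s1_dur_s: float = 0.100
    s2_dur_s: float = 0.080
    s1_amp: float = 1.0
    s2_amp: float = 0.8
    ppg_rise_s: float = 0.15
    ppg_decay_s: float = 0.45
    snr_db: float | None = None
    seed: int = 0
    fs_pcg: float = PCG_FS_HZ
    fs_ppg: float = PPG_FS_HZ

    def __post_init__(self) -> None:
        for name in ("duration_s", "systole_s", "s1_dur_s", "s2_dur_s",
                     "ppg_rise_s", "ppg_decay_s"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.hr_bpm <= 0:
            raise InputError("hr_bpm must be positive")
        if not (0 <= self.s2_peak_jitter_s <= 0.020):
            raise InputError("s2_peak_jitter_s must lie in [0, 0.020]")
        if not (0.020 < self.systole_s <= 0.500):
            raise InputError("systole_s must lie in (0.020, 0.500]")


@dataclass(frozen=True)
class SyntheticRecording:
    """Paired traces plus the ground truth that produced them."""

    pcg: SignalTrace
    ppg: SignalTrace
    truth_s1: np.ndarray
    truth_s2: np.ndarray
    truth_peaks: np.ndarray
    config: SynthConfig

    def __post_init__(self) -> None:
        for name in ("truth_s1", "truth_s2", "truth_peaks"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_cycles(self) -> int:
        return self.truth_peaks.size


def _render_bursts(
    n: int, fs: float, onsets: np.ndarray, dur: float, freq: float, amp: float
) -> np.ndarray:
    """Sum of Gaussian-windowed sinusoids with support [onset, onset+dur].

    The Gaussian is centered at onset + dur/2 with sigma = dur/6, so the
    envelope at the nominal onset is at its 3-sigma tail (~1% of peak).
    """
    out = np.zeros(n)
    sigma = dur / 6.0
    for t_on in onsets:
        i0 = max(0, int(np.floor(t_on * fs)))
        i1 = min(n, int(np.ceil((t_on + dur) * fs)) + 1)
        if i1 <= i0:
            continue
        tt = np.arange(i0, i1) / fs
        center = t_on + dur / 2.0
        out[i0:i1] += (
            amp
            * np.exp(-((tt - center) ** 2) / (2.0 * sigma**2))
            * np.sin(2.0 * np.pi * freq * (tt - t_on))
        )
    return out


def _ppg_pulse_template(tau: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Gamma-like pulse, unit peak exactly at tau = rise.

    Shape h(tau) = (tau/rise)^k * exp(k (1 - tau/rise)) with k chosen so
    the pulse decays to ~5% of peak ``decay`` seconds after the peak.
    """
    k = 2.0
    h = np.zeros_like(tau)
    pos = tau > 0
    r = tau[pos] / rise
    h[pos] = r**k * np.exp(k * (1.0 - r))
    return h


def generate_recording(config: SynthConfig | None = None) -> SyntheticRecording:
    """Generate one paired PCG+PPG recording with ground truth."""
    config = config or SynthConfig()
    ss = np.random.SeedSequence(config.seed)
    timing_ss, pcg_noise_ss, ppg_noise_ss = ss.spawn(3)
    rng = np.random.default_rng(timing_ss)

    # --- cycle timing -----------------------------------------------------
    onsets: list[float] = []
    t = 0.0
    while True:
        hr = float(np.clip(rng.normal(config.hr_bpm, config.hr_sd_bpm), 30.0, 220.0))
        period = 60.0 / hr
        if t + period > config.duration_s + 1e-9:
            break
        onsets.append(t)
        t += period
    if not onsets:
        raise InputError("duration_s too short for a single cardiac cycle")
    truth_s1 = np.asarray(onsets)

    j = config.s2_peak_jitter_s
    # keep S1 strictly inside (20, 500] ms before the peak even after jitter
    systole = np.clip(
        rng.normal(config.systole_s, config.systole_sd_s, truth_s1.size),
        0.030 + j,
        0.490 - j,
    )
    truth_s2 = truth_s1 + systole
    jitter = rng.uniform(-j, j, truth_s1.size) if j > 0 else np.zeros(truth_s1.size)
    truth_peaks = truth_s2 + jitter

    # --- PCG channel ------------------------------------------------------
    n_pcg = int(round(config.duration_s * config.fs_pcg))
    pcg = _render_bursts(n_pcg, config.fs_pcg, truth_s1, config.s1_dur_s,
                         config.s1_freq_hz, config.s1_amp)
    pcg += _render_bursts(n_pcg, config.fs_pcg, truth_s2, config.s2_dur_s,
                          config.s2_freq_hz, config.s2_amp)

    # --- PPG channel ------------------------------------------------------
    n_ppg = int(round(config.duration_s * config.fs_ppg))
    tt = np.arange(n_ppg) / config.fs_ppg
    ppg = np.zeros(n_ppg)
    for pk in truth_peaks:
        start = pk - config.ppg_rise_s
        span = config.ppg_rise_s + 2.0 * config.ppg_decay_s
        i0 = max(0, int(np.floor(start * config.fs_ppg)))
        i1 = min(n_ppg, int(np.ceil((start + span) * config.fs_ppg)) + 1)
        if i1 <= i0:
            continue
        ppg[i0:i1] += _ppg_pulse_template(
            tt[i0:i1] - start, config.ppg_rise_s, config.ppg_decay_s
        )
    peak_abs = np.max(np.abs(ppg))
    if peak_abs > 0:
        ppg = ppg / peak_abs

    rec = SyntheticRecording(
        pcg=SignalTrace(samples=pcg, fs=config.fs_pcg, t0=0.0, label="PCG"),
        ppg=SignalTrace(samples=ppg, fs=config.fs_ppg, t0=0.0, label="PPG"),
        truth_s1=truth_s1,
        truth_s2=truth_s2,
        truth_peaks=truth_peaks,
        config=config,
    )
    if config.snr_db is not None:
        rec = add_noise(
            rec,
            config.snr_db,
            seed=(pcg_noise_ss, ppg_noise_ss),
        )
    return rec


def add_noise(
    rec: SyntheticRecording, snr_db: float, seed=0
) -> SyntheticRecording:
    """Add white Gaussian noise per channel at the requested SNR (dB).

    Noise power is scaled so 10*log10(signal power / noise power) equals
    ``snr_db`` on each channel, with signal power the mean square of the
    clean channel. Ground truth is untouched.
    """
    if not np.isfinite(snr_db):
        raise InputError("snr_db must be finite")
    if isinstance(seed, tuple):
        pcg_rng, ppg_rng = (np.random.default_rng(s) for s in seed)
    else:
        pcg_ss, ppg_ss = np.random.SeedSequence(seed).spawn(2)
        pcg_rng, ppg_rng = np.random.default_rng(pcg_ss), np.random.default_rng(ppg_ss)

    def noisy(trace: SignalTrace, rng: np.random.Generator) -> SignalTrace:
        power = float(np.mean(trace.samples**2))
        if power == 0.0:
            raise InputError("cannot set an SNR on a zero-power signal")
        sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
        return dataclasses.replace(
            trace, samples=trace.samples + rng.normal(0.0, sigma, len(trace))
        )

    return dataclasses.replace(
        rec, pcg=noisy(rec.pcg, pcg_rng), ppg=noisy(rec.ppg, ppg_rng)
    )


def generate_cohort(
    n_subjects: int,
    base_config: SynthConfig | None = None,
    seed: int = 0,
    hr_mean_bpm: float = COHORT_HR_MEAN_BPM,
    hr_sd_bpm: float = COHORT_HR_SD_BPM,
) -> list[SyntheticRecording]:
    """Generate a cohort with per-subject resting heart rates.

    Subject mean HRs are drawn from N(hr_mean, hr_sd^2) bpm truncated to
    [50, 100] by rejection; each subject gets an independent sub-seed, so
    the cohort is reproducible given the root seed regardless of order.
    """
    if n_subjects < 1:
        raise InputError("n_subjects must be >= 1")
    base = base_config or SynthConfig()
    out: list[SyntheticRecording] = []
    for child in np.random.SeedSequence(seed).spawn(n_subjects):
        rng = np.random.default_rng(child)
        while True:
            hr = float(rng.normal(hr_mean_bpm, hr_sd_bpm))
            if 50.0 <= hr <= 100.0:
                break
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(base, hr_bpm=hr, seed=sub_seed)
        out.append(generate_recording(cfg))
    return out
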