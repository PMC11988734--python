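"""Seeded synthetic Holter ECG with known rhythm ground truth.

The simulator emulates the phenomenology that separates paroxysmal atrial
fibrillation from sinus rhythm on a single- or two-lead ambulatory ECG:

* sinus rhythm — near-regular RR intervals (Normal, small SD) with a
  visible P wave before every QRS;
* AF episodes — irregular RR intervals (Gamma, coefficient of variation
  ~0.25), absent P waves, and a low-amplitude fibrillatory (f) wave
  oscillation near the isoelectric line;
* ambulatory noise — EMG bursts, baseline wander, and spike artifacts.

Beats are sums of Gaussian P-Q-R-S-T waves placed on the RR lattice; this
is a deliberate simplification (amplitude patterns are what the beat-stack
image transform consumes, not waveform physiology).  Every record carries
exact ground truth: one QRS index per simulated beat and the configured AF
episode intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

from .ecg_io import ECGRecord

__all__ = ["SyntheticConfig", "synth_record", "synth_cohort"]

# Gaussian wave layout relative to the R peak: (offset_s, width_s).
WAVE_SHAPES = {
    "P": (-0.16, 0.025),
    "Q": (-0.025, 0.010),
    "R": (0.0, 0.012),
    "S": (0.030, 0.010),
    "T": (0.22, 0.060),
}

DEFAULT_AMPLITUDES_UV = {"P": 100.0, "Q": -80.0, "R": 1000.0, "S": -150.0, "T": 250.0}


@dataclass
class SyntheticConfig:
    """Simulation parameters; amplitudes in microvolts, times in seconds."""

    fs: float = 200.0
    duration_s: float = 60.0
    leads: list[str] = field(default_factory=lambda: ["I", "II"])
    sinus_rr_mean_s: float = 0.8
    sinus_rr_sd_s: float = 0.03
    af_rr_mean_s: float = 0.6
    af_rr_cv: float = 0.25
    wave_amplitudes_uv: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES_UV))
    lead2_scale: float = 0.7
    lead2_extra_noise_uv: float = 15.0
    lead2_t_flip: bool = False
    fwave_amp_uv: float = 60.0
    fwave_freq_hz: float = 6.0
    emg_burst_rate_per_min: float = 1.5
    emg_amp_uv: float = 80.0
    baseline_wander_amp_uv: float = 100.0
    baseline_wander_freq_range_hz: tuple[float, float] = (0.2, 0.4)
    spike_rate_per_min: float = 0.5
    spike_amp_uv: float = 1200.0
    af_episodes_s: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        for rr in (self.sinus_rr_mean_s, self.af_rr_mean_s):
            if not (0 < rr < self.duration_s):
                raise ValueError("RR means must lie in (0, duration)")
        if self.af_rr_cv <= self.sinus_rr_sd_s / self.sinus_rr_mean_s:
            raise ValueError("AF RR must be more irregular than sinus (af_rr_cv too low)")
        if any(abs(v) < 0 for v in self.wave_amplitudes_uv.values()):  # pragma: no cover
            raise ValueError("amplitudes must be finite")
        for start, end in self.af_episodes_s:
            if not (0 <= start < end <= self.duration_s):
                raise ValueError(f"AF episode ({start}, {end}) outside record duration")

    def noise_free(self) -> "SyntheticConfig":
        """Copy with all noise generators switched off."""
        return replace(
            self,
            emg_amp_uv=0.0,
            baseline_wander_amp_uv=0.0,
            spike_amp_uv=0.0,
            spike_rate_per_min=0.0,
            emg_burst_rate_per_min=0.0,
            lead2_extra_noise_uv=0.0,
        )


def _in_episode(t: float, episodes: Sequence[tuple[float, float]]) -> bool:
    return any(start <= t < end for start, end in episodes)


def _beat_lattice(cfg: SyntheticConfig, rng: np.random.Generator):
    """Simulate beat times; returns (times_s, is_af flags)."""
    k = 1.0 / cfg.af_rr_cv**2  # Gamma shape for the AF RR process
    theta = cfg.af_rr_mean_s / k
    times, flags = [], []
    t = 0.3 + 0.2 * rng.random()
    while t < cfg.duration_s:
        af = _in_episode(t, cfg.af_episodes_s)
        times.append(t)
        flags.append(af)
        if af:
            rr = rng.gamma(k, theta)
        else:
            rr = rng.normal(cfg.sinus_rr_mean_s, cfg.sinus_rr_sd_s)
        t += max(rr, 0.25 * cfg.sinus_rr_mean_s)
    return np.asarray(times), np.asarray(flags, dtype=bool)


def _add_gaussian(sig: np.ndarray, fs: float, center_s: float, width_s: float, amp: float):
    if amp == 0.0:
        return
    half = 4.0 * width_s
    lo = max(0, int((center_s - half) * fs))
    hi = min(sig.size, int((center_s + half) * fs) + 1)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    sig[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / width_s) ** 2)


def _clean_lead(cfg, beat_times, beat_af, amps, fs, n) -> np.ndarray:
    sig = np.zeros(n)
    for t_r, af in zip(beat_times, beat_af):
        for wave, (off, width) in WAVE_SHAPES.items():
            amp = amps[wave]
            if wave == "P" and af:
                amp = 0.0  # no organized atrial depolarization during AF
            _add_gaussian(sig, fs, t_r + off, width, amp)
    return sig


def _fwave(cfg, rng, n) -> np.ndarray:
    """Fibrillatory oscillation with drifting frequency, nonzero only in episodes."""
    if cfg.fwave_amp_uv == 0.0 or not cfg.af_episodes_s:
        return np.zeros(n)
    t = np.arange(n) / cfg.fs
    f_inst = cfg.fwave_freq_hz * (
        1.0
        + 0.12 * np.sin(2 * np.pi * 0.11 * t + 2 * np.pi * rng.random())
        + 0.05 * rng.standard_normal(n).cumsum() / np.sqrt(np.arange(1, n + 1))
    )
    phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fs + 2 * np.pi * rng.random()
    wave = cfg.fwave_amp_uv * np.sin(phase)
    mask = np.zeros(n)
    for start, end in cfg.af_episodes_s:
        mask[int(start * cfg.fs) : int(end * cfg.fs)] = 1.0
    return wave * mask


def _noise(cfg, rng, n) -> np.ndarray:
    t = np.arange(n) / cfg.fs
    sig = np.zeros(n)
    if cfg.baseline_wander_amp_uv > 0:
        f_bw = rng.uniform(*cfg.baseline_wander_freq_range_hz)
        sig += cfg.baseline_wander_amp_uv * np.sin(
            2 * np.pi * f_bw * t + 2 * np.pi * rng.random()
        )
    n_bursts = rng.poisson(cfg.emg_burst_rate_per_min * cfg.duration_s / 60.0)
    for _ in range(n_bursts):
        dur = rng.uniform(0.5, 2.0)
        start = rng.uniform(0, max(cfg.duration_s - dur, 0.0))
        lo, hi = int(start * cfg.fs), min(int((start + dur) * cfg.fs), n)
        if hi > lo and cfg.emg_amp_uv > 0:
            env = np.hanning(hi - lo)
            sig[lo:hi] += cfg.emg_amp_uv * env * rng.standard_normal(hi - lo)
    n_spikes = rng.poisson(cfg.spike_rate_per_min * cfg.duration_s / 60.0)
    for _ in range(n_spikes):
        idx = rng.integers(1, n - 1)
        sig[idx - 1 : idx + 2] += cfg.spike_amp_uv * np.array([0.4, 1.0, 0.4]) * rng.choice(
            [-1.0, 1.0]
        )
    return sig


def synth_record(config: SyntheticConfig, record_id: str = "synthetic") -> ECGRecord:
    """Simulate one ECG record with exact beat and episode ground truth.

    The per-beat rhythm flag (was this beat generated by the AF RR process?)
    is stored in ``record.meta["beat_is_af"]`` for test introspection.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    beat_times, beat_af = _beat_lattice(cfg, rng)

    leads = []
    for li, lead in enumerate(cfg.leads):
        amps = dict(cfg.wave_amplitudes_uv)
        scale = 1.0 if li == 0 else cfg.lead2_scale
        for k in amps:
            amps[k] *= scale
        if li > 0 and cfg.lead2_t_flip:
            amps["T"] *= -1.0
        sig = _clean_lead(cfg, beat_times, beat_af, amps, cfg.fs, n)
        sig += scale * _fwave(cfg, rng, n)
        sig += _noise(cfg, rng, n)
        if li > 0 and cfg.lead2_extra_noise_uv > 0:
            sig += cfg.lead2_extra_noise_uv * rng.standard_normal(n)
        leads.append(sig)

    qrs = np.round(beat_times * cfg.fs).astype(np.int64)
    keep = qrs < n
    qrs, beat_af = qrs[keep], beat_af[keep]
    episodes = [
        (int(round(s * cfg.fs)), int(round(e * cfg.fs))) for s, e in cfg.af_episodes_s
    ]
    return ECGRecord(
        record_id=record_id,
        leads=list(cfg.leads),
        signal=np.stack(leads),
        fs=cfg.fs,
        qrs_idx=qrs,
        af_episodes=episodes,
        meta={"config": asdict(cfg), "beat_is_af": beat_af.tolist()},
    )


def _derive_seed(master_seed: int, index: int) -> int:
    # Counter scheme: reproducible under parallel generation, < 2**31.
    return (1_000_003 * int(master_seed) + 7_919 * int(index) + 1) % (2**31)


def _random_episodes(duration_s: float, rng: np.random.Generator):
    """Two AF episodes (~45-55% coverage) leaving sinus stretches between."""
    T = duration_s
    s1 = rng.uniform(0.10, 0.20) * T
    e1 = s1 + rng.uniform(0.25, 0.35) * T
    s2 = e1 + rng.uniform(0.10, 0.20) * T
    e2 = min(s2 + rng.uniform(0.15, 0.25) * T, 0.95 * T)
    return [(s1, e1), (s2, e2)]


def synth_cohort(
    n_records: int,
    config: SyntheticConfig | None = None,
    seed: int = 0,
    af_fraction: float = 0.5,
) -> list[ECGRecord]:
    """Simulate a cohort of records with distinct ids and derived seeds.

    ``af_fraction`` of the records (rounded) contain AF episodes — either
    the template's explicit ``af_episodes_s`` or two randomly placed
    episodes covering roughly half of the record; the rest are AF-free.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    template = config or SyntheticConfig(duration_s=600.0)
    template.validate()
    n_af = int(round(n_records * af_fraction))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_records)
    is_af_record = np.zeros(n_records, dtype=bool)
    is_af_record[order[:n_af]] = True

    records = []
    for i in range(n_records):
        rec_seed = _derive_seed(seed, i)
        rec_rng = np.random.default_rng(rec_seed + 2**20)
        if is_af_record[i]:
            episodes = template.af_episodes_s or _random_episodes(
                template.duration_s, rec_rng
            )
        else:
            episodes = []
        cfg = replace(template, af_episodes_s=episodes, seed=rec_seed)
        records.append(synth_record(cfg, record_id=f"rec_{i:03d}"))
    return records
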