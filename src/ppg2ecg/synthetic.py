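"""Seeded generator of paired ECG/PPG records with ground-truth peak annotations.

The generator emulates the structure the reconstruction pipeline assumes:
quasi-periodic beats, a PPG that lags the ECG by a record-constant pulse
arrival time (PAT), and a PPG waveform derived deterministically from the
same beat times as the ECG so that the PPG→ECG mapping is learnable by
construction.

Each ECG beat is a sum of five Gaussian bumps (P, Q, R, S, T); each PPG
beat is a sum of two Gaussian bumps (systolic and diastolic wave).  Beat
centres are placed on a jittered RR grid, then snapped to integer sample
indices so that every true systolic-peak index equals its R-peak index
plus ``round(pat_s * fs)`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import Record
from .preprocess import PeakAnnotations

__all__ = [
    "WaveComponent",
    "SyntheticConfig",
    "SyntheticRecord",
    "generate",
    "make_cohort",
    "noise_sd_from_snr",
]


@dataclass(frozen=True)
class WaveComponent:
    """One Gaussian bump: ``amp * exp(-(t - center)^2 / (2 width^2))``.

    ``center`` is the offset in seconds from the beat's R time (ECG) or
    from the beat's systolic time (PPG); ``width`` is the Gaussian sigma.
    """

    amp: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"wave width must be > 0, got {self.width}")


# Lead-II-like morphology in mV, offsets relative to the R peak.
DEFAULT_ECG_WAVES: tuple[WaveComponent, ...] = (
    WaveComponent(0.15, -0.20, 0.025),   # P
    WaveComponent(-0.15, -0.030, 0.010),  # Q
    WaveComponent(1.20, 0.0, 0.012),     # R
    WaveComponent(-0.25, 0.030, 0.010),  # S
    WaveComponent(0.35, 0.25, 0.045),    # T
)

# Systolic + diastolic wave, offsets relative to the systolic peak.
DEFAULT_PPG_WAVES: tuple[WaveComponent, ...] = (
    WaveComponent(1.00, 0.0, 0.09),      # systolic
    WaveComponent(0.35, 0.32, 0.11),     # diastolic
)


@dataclass(frozen=True)
class SyntheticConfig:
    fs: float = 125.0
    duration_s: float = 300.0
    heart_rate_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.02
    pat_s: float = 0.2
    ecg_wave_params: tuple[WaveComponent, ...] = DEFAULT_ECG_WAVES
    ppg_wave_params: tuple[WaveComponent, ...] = DEFAULT_PPG_WAVES
    ecg_noise_sd: float = 0.0
    ppg_noise_sd: float = 0.0
    ppg_scale: float = 100.0
    ppg_offset: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0 or self.heart_rate_bpm <= 0:
            raise ValueError("fs, duration_s and heart_rate_bpm must be positive")
        if self.pat_s < 0:
            raise ValueError("pat_s must be >= 0")
        if self.rr_jitter_sd_s < 0 or self.ecg_noise_sd < 0 or self.ppg_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class SyntheticRecord:
    record: Record
    truth: PeakAnnotations
    config: SyntheticConfig


def _beat_sample_indices(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """R-peak and systolic-peak sample indices on a jittered RR grid."""
    mean_rr = 60.0 / cfg.heart_rate_bpm
    n_samples = int(round(cfg.duration_s * cfg.fs))
    pat_samples = int(round(cfg.pat_s * cfg.fs))
    # start half a beat in so the first beat's P wave fits in the record
    t = 0.5 * mean_rr
    r_times = []
    while t < cfg.duration_s:
        r_times.append(t)
        rr = mean_rr + (rng.normal(0.0, cfg.rr_jitter_sd_s) if cfg.rr_jitter_sd_s > 0 else 0.0)
        t += max(rr, 0.3)  # floor: 200 bpm, keeps beats ordered
    # round half-up so an exact 1-s grid stays uniform
    r_idx = np.floor(np.asarray(r_times) * cfg.fs + 0.5).astype(np.int64)
    # keep beats whose R and systolic peaks are safely inside the record
    keep = (r_idx >= int(round(0.3 * cfg.fs))) & \
           (r_idx + pat_samples < n_samples - int(round(0.1 * cfg.fs)))
    r_idx = r_idx[keep]
    s_idx = r_idx + pat_samples
    return r_idx, s_idx


def _render(n_samples: int, fs: float, centers_idx: np.ndarray,
            waves: tuple[WaveComponent, ...]) -> np.ndarray:
    """Sum of Gaussian bumps at centers (sample indices), vectorized per beat."""
    t = np.arange(n_samples) / fs
    out = np.zeros(n_samples)
    for c in centers_idx:
        tc = c / fs
        for w in waves:
            # only render a local window (±6 sigma) for speed
            lo = max(0, int((tc + w.center - 6 * w.width) * fs))
            hi = min(n_samples, int((tc + w.center + 6 * w.width) * fs) + 1)
            if hi <= lo:
                continue
            out[lo:hi] += w.amp * np.exp(-0.5 * ((t[lo:hi] - tc - w.center) / w.width) ** 2)
    return out


def generate(config: SyntheticConfig) -> SyntheticRecord:
    """Generate one paired ECG/PPG record with exact peak ground truth.

    Identical seed yields bitwise-identical output.  Every true systolic
    peak index equals its R-peak index + round(pat_s * fs) by construction.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    r_idx, s_idx = _beat_sample_indices(cfg, rng)
    if len(r_idx) == 0:
        raise ValueError("configuration produced no beats inside the record")

    ecg = _render(n_samples, cfg.fs, r_idx, cfg.ecg_wave_params)
    ppg = _render(n_samples, cfg.fs, s_idx, cfg.ppg_wave_params)
    # PPG on an arbitrary positive scale, as raw acquisitions are
    ppg = ppg * cfg.ppg_scale + cfg.ppg_offset

    if cfg.ecg_noise_sd > 0:
        ecg = ecg + rng.normal(0.0, cfg.ecg_noise_sd, n_samples)
    if cfg.ppg_noise_sd > 0:
        ppg = ppg + rng.normal(0.0, cfg.ppg_noise_sd * cfg.ppg_scale, n_samples)

    record = Record(record_id=f"synthetic-{cfg.seed}", fs=cfg.fs, ecg=ecg, ppg=ppg)
    truth = PeakAnnotations(r_peaks=r_idx, systolic_peaks=s_idx)
    return SyntheticRecord(record=record, truth=truth, config=cfg)


def noise_sd_from_snr(signal: np.ndarray, snr_db: float) -> float:
    """Additive-noise sigma giving the requested SNR against the AC signal power."""
    ac = np.asarray(signal, dtype=float)
    ac = ac - ac.mean()
    rms = float(np.sqrt(np.mean(ac**2)))
    return rms / (10.0 ** (snr_db / 20.0))


def make_cohort(
    n_records: int,
    base: SyntheticConfig | None = None,
    variation: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[SyntheticRecord]:
    """Generate a cohort of subjects with per-record parameters drawn from ranges.

    ``variation`` maps SyntheticConfig field names (heart_rate_bpm, pat_s,
    rr_jitter_sd_s, ...) to (low, high) ranges sampled uniformly with a
    per-record sub-seed; degenerate ranges (low == high) are allowed and
    pin the parameter while noise still differs across records.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    base = base if base is not None else SyntheticConfig()
    variation = variation if variation is not None else {
        "heart_rate_bpm": (55.0, 95.0),
        "pat_s": (0.15, 0.30),
    }
    for key, (lo, hi) in variation.items():
        if not hasattr(base, key):
            raise ValueError(f"unknown SyntheticConfig field in variation: {key!r}")
        if hi < lo:
            raise ValueError(f"empty range for {key!r}: ({lo}, {hi})")
    master = np.random.default_rng(seed)
    out = []
    for k in range(n_records):
        draws = {key: float(master.uniform(lo, hi)) for key, (lo, hi) in variation.items()}
        sub_seed = int(master.integers(0, 2**31 - 1))
        cfg = replace(base, seed=sub_seed, **draws)
        rec = generate(cfg)
        rec = SyntheticRecord(
            record=Record(record_id=f"synthetic-{seed}-{k:03d}", fs=rec.record.fs,
                          ecg=rec.record.ecg, ppg=rec.record.ppg),
            truth=rec.truth,
            config=cfg,
        )
        out.append(rec)
    return out
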