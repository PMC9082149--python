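"""End-to-end run configuration and orchestration.

One record = one subject = one model: the pipeline trains a fresh
subject-specific reconstructor per record and never shares parameters
across subjects.  Stages: band-pass filter -> peak detection ->
Alignment I -> PPG normalization -> split/segment -> BiLSTM training ->
reconstruction -> stitching -> Alignment II -> metrics.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .signal_io import Record
from .preprocess import (FilterSpec, PeakAnnotations, AlignedPair, ECG_FILTER,
                         PPG_FILTER, bandpass, detect_r_peaks,
                         detect_systolic_peaks, align_pair)
from .split_segment import SplitSpec, SegmentSet, split, stitch
from .reconstructor import ReconstructorConfig, BiLSTMRegressor, build, train, reconstruct
from .metrics import EvalReport, evaluate, summarize

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_cohort"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration for a full pipeline run."""

    ecg_filter: FilterSpec = ECG_FILTER
    ppg_filter: FilterSpec = PPG_FILTER
    anchor_beat: int = 3
    split: SplitSpec = field(default_factory=SplitSpec)
    model: ReconstructorConfig = field(default_factory=ReconstructorConfig)
    align_window_ms: float = 80.0
    stitched_band_radius_s: float = 1.0
    seed: int = 0

    _SECTIONS = {
        "filter": {"ecg", "ppg", "order", "stopband_atten_db"},
        "align": {"anchor_beat", "window_ms"},
        "split": {"train_s", "val_s", "gap_s", "test_s", "segment_s"},
        "model": {"hidden_units", "l1", "l2", "learning_rate", "batch_size",
                  "max_epochs", "early_stop_patience", "seed", "loss"},
        "eval": {"align_window_ms", "stitched_band_radius_s"},
        "seed": None,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        """Build from a nested dict (e.g. parsed YAML); unknown keys are rejected."""
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        for section, allowed in cls._SECTIONS.items():
            if allowed is None or section not in raw:
                continue
            bad = set(raw[section]) - allowed
            if bad:
                raise ValueError(f"unknown key(s) in [{section}]: {sorted(bad)}")

        f = raw.get("filter", {})
        order = f.get("order", 4)
        atten = f.get("stopband_atten_db", 40.0)
        ecg_band = f.get("ecg", {}).get("band", [0.5, 20.0]) if isinstance(f.get("ecg"), dict) else [0.5, 20.0]
        ppg_band = f.get("ppg", {}).get("band", [0.5, 10.0]) if isinstance(f.get("ppg"), dict) else [0.5, 10.0]
        kw = {}
        kw["ecg_filter"] = FilterSpec(ecg_band[0], ecg_band[1], order, atten)
        kw["ppg_filter"] = FilterSpec(ppg_band[0], ppg_band[1], order, atten)
        al = raw.get("align", {})
        kw["anchor_beat"] = al.get("anchor_beat", 3)
        sp = raw.get("split", {})
        kw["split"] = SplitSpec(sp.get("train_s", 48), sp.get("val_s", 12),
                                sp.get("gap_s", 12), sp.get("test_s", 228),
                                sp.get("segment_s", 1))
        mo = dict(raw.get("model", {}))
        kw["model"] = ReconstructorConfig(**mo)
        ev = raw.get("eval", {})
        kw["align_window_ms"] = ev.get("align_window_ms", al.get("window_ms", 80.0))
        kw["stitched_band_radius_s"] = ev.get("stitched_band_radius_s", 1.0)
        kw["seed"] = raw.get("seed", 0)
        cfg = cls(**kw)
        logger.info("run config: %s", cfg)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    record_id: str
    aligned: AlignedPair
    annotations: PeakAnnotations
    sets: dict[str, SegmentSet]
    model: BiLSTMRegressor
    rec_segments: np.ndarray
    stitched: np.ndarray
    report: EvalReport
    timings_s: dict[str, float]


def run_pipeline(record: Record, config: RunConfig | None = None) -> PipelineResult:
    """Run the full reconstruction pipeline on one record (one subject)."""
    cfg = config if config is not None else RunConfig()
    fs = record.fs
    timings: dict[str, float] = {}

    def tic() -> float:
        return time.perf_counter()

    t0 = tic()
    ecg_f = bandpass(record.ecg, fs, cfg.ecg_filter)
    ppg_f = bandpass(record.ppg, fs, cfg.ppg_filter)
    timings["filter"] = tic() - t0

    t0 = tic()
    try:
        r_peaks = detect_r_peaks(ecg_f, fs)
        s_peaks = detect_systolic_peaks(ppg_f, fs)
        ann = PeakAnnotations(r_peaks=r_peaks, systolic_peaks=s_peaks)
        aligned = align_pair(ecg_f, ppg_f, fs, ann, record_id=record.record_id,
                             anchor_beat=cfg.anchor_beat)
    except Exception as exc:
        raise RuntimeError(f"[alignment] record {record.record_id}: {exc}") from exc
    timings["align"] = tic() - t0
    logger.info("record %s: applied Alignment I lag = %d samples (%.1f ms)",
                record.record_id, aligned.applied_lag,
                1000 * aligned.applied_lag / fs)

    spec = cfg.split
    if aligned.duration_s < spec.total_s:
        spec = spec.shrink_to(aligned.duration_s)
        logger.info("record %s: shortened test interval to %d s", record.record_id,
                    spec.test_s)
    try:
        sets = split(aligned, spec)
    except Exception as exc:
        raise RuntimeError(f"[split] record {record.record_id}: {exc}") from exc
    logger.info("record %s: segments train/val/test = %d/%d/%d (n = %d s)",
                record.record_id, sets["train"].n_segments,
                sets["validation"].n_segments, sets["test"].n_segments,
                spec.segment_s)

    t0 = tic()
    model = build(cfg.model, sets["train"].segment_len)
    try:
        train(model, sets["train"], sets["validation"])
    except Exception as exc:
        raise RuntimeError(f"[train] record {record.record_id}: {exc}") from exc
    timings["train"] = tic() - t0
    logger.info("record %s: trained %d epochs (best %d, val loss %.5g)",
                record.record_id, model.n_epochs_run_, model.best_epoch_,
                model.best_val_loss_)

    t0 = tic()
    rec_segments = reconstruct(model, sets["test"])
    stitched = stitch(rec_segments)
    timings["reconstruct"] = tic() - t0

    t0 = tic()
    report = evaluate(sets["test"].ecg, rec_segments, fs, spec.segment_s,
                      align_window_ms=cfg.align_window_ms,
                      stitched_band_radius_s=cfg.stitched_band_radius_s)
    timings["evaluate"] = tic() - t0
    logger.info("record %s: stitched r = %.3f (aligned %.3f, lag %d)",
                record.record_id, report.r_s, report.r_sa, report.lag_s)

    return PipelineResult(record_id=record.record_id, aligned=aligned,
                          annotations=ann, sets=sets, model=model,
                          rec_segments=rec_segments, stitched=stitched,
                          report=report, timings_s=timings)


def run_cohort(records: list[Record], config: RunConfig | None = None
               ) -> tuple[list[PipelineResult], dict[str, float]]:
    """Run the subject-specific pipeline per record and pool the metrics."""
    results = [run_pipeline(rec, config) for rec in records]
    pooled = summarize([res.report for res in results])
    return results, pooled
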