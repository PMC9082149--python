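"""Dataset splitting into train/validation/gap/test and n-second segmentation.

The aligned record is cut, in order and without overlap, into a 48 s
training interval, a 12 s validation interval, a discarded 12 s gap, and
a 228 s test interval (test:train duration ratio 4.75).  Each interval is
then divided into consecutive n-second windows; for n = 1, 2, 3, 4 this
yields {48, 12, 228}, {24, 6, 114}, {16, 4, 76} and {12, 3, 57} segments.
Stitching is plain concatenation, the exact inverse of segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AlignedPair

__all__ = ["SplitSpec", "SegmentSet", "split", "stitch"]


@dataclass(frozen=True)
class SplitSpec:
    train_s: int = 48
    val_s: int = 12
    gap_s: int = 12
    test_s: int = 228
    segment_s: int = 1

    def __post_init__(self) -> None:
        for name in ("train_s", "val_s", "gap_s", "test_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.segment_s < 1:
            raise ValueError("segment_s must be a positive integer number of seconds")
        if self.test_s % self.segment_s:
            raise ValueError(f"test_s ({self.test_s}) must be divisible by "
                             f"segment_s ({self.segment_s})")

    @property
    def total_s(self) -> int:
        return self.train_s + self.val_s + self.gap_s + self.test_s

    def shrink_to(self, available_s: float) -> "SplitSpec":
        """Shorten test_s to fit a record shorter than the full layout.

        train/val/gap stay fixed; test_s drops to the largest multiple of
        12 s (the least common multiple of the allowed segment lengths
        1-4) that fits.
        """
        spare = available_s - (self.train_s + self.val_s + self.gap_s)
        new_test = int(spare // 12) * 12
        if new_test < 12:
            raise ValueError(f"record too short: {available_s:.1f} s available, "
                             f"{self.train_s + self.val_s + self.gap_s + 12} s required")
        return SplitSpec(self.train_s, self.val_s, self.gap_s,
                         min(new_test, self.test_s), self.segment_s)


@dataclass(frozen=True)
class SegmentSet:
    """Ordered fixed-length paired windows cut from one contiguous interval."""

    ecg: np.ndarray          # (n_segments, segment_s * fs)
    ppg: np.ndarray          # same shape
    role: str                # train | validation | test
    segment_s: int
    fs: float

    def __post_init__(self) -> None:
        if self.ecg.shape != self.ppg.shape:
            raise ValueError("ecg and ppg segment arrays must have equal shape")
        if self.ecg.ndim != 2:
            raise ValueError("segments must form a 2-D (n_segments, length) array")

    @property
    def n_segments(self) -> int:
        return self.ecg.shape[0]

    @property
    def segment_len(self) -> int:
        return self.ecg.shape[1]


def _segment(ecg: np.ndarray, ppg: np.ndarray, fs: float, segment_s: int,
             role: str) -> SegmentSet:
    seg_len = int(round(segment_s * fs))
    n = len(ecg) // seg_len
    ecg = ecg[: n * seg_len].reshape(n, seg_len)
    ppg = ppg[: n * seg_len].reshape(n, seg_len)
    return SegmentSet(ecg=ecg, ppg=ppg, role=role, segment_s=segment_s, fs=fs)


def split(pair: AlignedPair, spec: SplitSpec | None = None) -> dict[str, SegmentSet]:
    """Cut an aligned pair into train/validation/test segment sets.

    Intervals are contiguous and non-overlapping, in the order
    train -> validation -> gap (discarded) -> test.
    """
    spec = spec if spec is not None else SplitSpec()
    fs = pair.fs
    needed = int(round(spec.total_s * fs))
    if pair.n_samples < needed:
        raise ValueError(
            f"record too short for split: {pair.n_samples / fs:.1f} s available, "
            f"{spec.total_s} s required (train {spec.train_s} + val {spec.val_s} "
            f"+ gap {spec.gap_s} + test {spec.test_s})")

    def cut(start_s: int, dur_s: int) -> tuple[np.ndarray, np.ndarray]:
        a, b = int(round(start_s * fs)), int(round((start_s + dur_s) * fs))
        return pair.ecg[a:b], pair.ppg[a:b]

    train = _segment(*cut(0, spec.train_s), fs, spec.segment_s, "train")
    val = _segment(*cut(spec.train_s, spec.val_s), fs, spec.segment_s, "validation")
    test_start = spec.train_s + spec.val_s + spec.gap_s
    test = _segment(*cut(test_start, spec.test_s), fs, spec.segment_s, "test")
    return {"train": train, "validation": val, "test": test}


def stitch(segments: np.ndarray | list[np.ndarray]) -> np.ndarray:
    """Concatenate equal-length windows in order (no overlap, no cross-fade)."""
    if isinstance(segments, np.ndarray) and segments.ndim == 2:
        if segments.shape[0] == 0:
            raise ValueError("cannot stitch an empty segment list")
        return segments.reshape(-1).copy()
    segs = [np.asarray(s, dtype=float) for s in segments]
    if not segs:
        raise ValueError("cannot stitch an empty segment list")
    lengths = {len(s) for s in segs}
    if len(lengths) != 1:
        raise ValueError(f"unequal window lengths: {sorted(lengths)}")
    return np.concatenate(segs)
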