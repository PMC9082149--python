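"""Preprocessing: band-pass filtering, peak detection, Alignment I, normalization.

Both channels are filtered with a fourth-order Chebyshev type-II band-pass
(ECG 0.5-20 Hz, PPG 0.5-10 Hz), applied zero-phase so that peak indices
remain comparable across channels.  R peaks are found with the
Pan-Tompkins method, systolic peaks with the two-event-related-moving-
average block method.  Alignment I removes the pulse arrival time by
shifting the PPG left so that an anchor systolic peak (the third one)
lands exactly on its corresponding R peak, then truncating both channels
to their common support.  Finally the PPG is min-max scaled to [0, 1];
the ECG keeps its mV scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "PeakAnnotations",
    "AlignedPair",
    "AlignmentError",
    "ECG_FILTER",
    "PPG_FILTER",
    "bandpass",
    "detect_r_peaks",
    "detect_systolic_peaks",
    "align_pair",
    "normalize_ppg",
]

logger = logging.getLogger(__name__)


class AlignmentError(RuntimeError):
    """Alignment I could not establish a usable beat correspondence."""


@dataclass(frozen=True)
class FilterSpec:
    """Chebyshev type-II band-pass specification.

    band_low/band_high are the passband edges in Hz; the stopband edges
    are placed at 0.5x the lower and 1.25x the upper passband edge.
    """

    band_low: float
    band_high: float
    order: int = 4
    stopband_atten_db: float = 40.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError(f"need 0 < band_low < band_high, got "
                             f"({self.band_low}, {self.band_high})")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


ECG_FILTER = FilterSpec(0.5, 20.0)
PPG_FILTER = FilterSpec(0.5, 10.0)


@dataclass(frozen=True)
class PeakAnnotations:
    """0-based, strictly ascending sample indices of R and systolic peaks."""

    r_peaks: np.ndarray
    systolic_peaks: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_peaks, dtype=np.int64)
        s = np.asarray(self.systolic_peaks, dtype=np.int64)
        object.__setattr__(self, "r_peaks", r)
        object.__setattr__(self, "systolic_peaks", s)
        for name, idx in (("r_peaks", r), ("systolic_peaks", s)):
            if len(idx) and np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if len(idx) and idx[0] < 0:
                raise ValueError(f"{name} contains negative indices")


@dataclass(frozen=True)
class AlignedPair:
    """Filtered ECG (mV) and [0,1]-scaled PPG after Alignment I."""

    ecg: np.ndarray
    ppg: np.ndarray
    fs: float
    applied_lag: int
    record_id: str = ""

    def __post_init__(self) -> None:
        ecg = np.asarray(self.ecg, dtype=float)
        ppg = np.asarray(self.ppg, dtype=float)
        object.__setattr__(self, "ecg", ecg)
        object.__setattr__(self, "ppg", ppg)
        if len(ecg) != len(ppg):
            raise ValueError("aligned channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs


def _design_sos(fs: float, spec: FilterSpec) -> np.ndarray:
    nyq = fs / 2.0
    if spec.band_high >= nyq:
        raise ValueError(f"band_high {spec.band_high} Hz >= Nyquist {nyq} Hz")
    ws_low = 0.5 * spec.band_low
    ws_high = min(1.25 * spec.band_high, 0.999 * nyq)
    return sps.cheby2(spec.order, spec.stopband_atten_db, [ws_low, ws_high],
                      btype="bandpass", output="sos", fs=fs)


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Chebyshev-II band-pass; output has the input's length."""
    x = np.asarray(x, dtype=float)
    sos = _design_sos(fs, spec)
    min_len = 3 * (2 * sos.shape[0]) + 1  # sosfiltfilt default padlen requirement
    if len(x) <= min_len:
        raise ValueError(f"signal too short to filter: {len(x)} <= {min_len} samples")
    return sps.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, int(width))
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detection.

    Stages: 5-15 Hz band-pass, derivative, squaring, 150 ms moving-window
    integration, adaptive signal/noise thresholds with search-back, and a
    200 ms refractory period.  Detected peaks are refined to the local ECG
    maximum so the returned indices mark the R wave itself.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 2 * fs:
        raise ValueError("need at least 2 s of ECG for QRS detection")
    if not np.any(ecg):
        return np.array([], dtype=np.int64)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", output="sos", fs=fs)
    bp = sps.sosfiltfilt(sos, ecg)
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi = _moving_average(sq, int(round(0.150 * fs)))

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if len(cand) == 0:
        return np.array([], dtype=np.int64)

    # adaptive signal/noise levels (Pan-Tompkins running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    last = -refractory
    for p in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[p] > thr and p - last >= refractory:
            accepted.append(int(p))
            spki = 0.125 * mwi[p] + 0.875 * spki
            last = p
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki

    # search-back: if an RR interval exceeds 1.66x the running average,
    # re-scan it with half the threshold
    if len(accepted) >= 2:
        rr = np.diff(accepted)
        avg_rr = float(np.mean(rr))
        extra: list[int] = []
        for a, b, gap in zip(accepted[:-1], accepted[1:], rr):
            if gap > 1.66 * avg_rr:
                seg = [p for p in cand if a + refractory <= p <= b - refractory]
                thr = 0.5 * (npki + 0.25 * (spki - npki))
                seg = [p for p in seg if mwi[p] > thr]
                if seg:
                    extra.append(int(seg[int(np.argmax(mwi[seg]))]))
        accepted = sorted(accepted + extra)

    # refine each detection to the R wave: local maximum of the ECG in a
    # window trailing the integrator peak (the MWI output lags the QRS)
    win = int(round(0.200 * fs))
    refined = []
    for p in accepted:
        lo = max(0, p - win)
        hi = min(len(ecg), p + int(round(0.050 * fs)) + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = sorted(set(refined))

    # enforce refractory spacing, keeping the taller peak
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if ecg[p] > ecg[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=np.int64)


def detect_systolic_peaks(ppg: np.ndarray, fs: float) -> np.ndarray:
    """Two-event-related-moving-average (block) systolic-peak detection.

    The clipped, squared PPG is smoothed with a short (111 ms, ~ peak
    width) and a long (667 ms, ~ beat width) moving average; blocks where
    the short average exceeds the long average plus an offset
    (beta * mean power, beta = 0.02) and that are at least one peak-width
    wide each contribute their PPG maximum as a systolic peak.
    """
    ppg = np.asarray(ppg, dtype=float)
    if len(ppg) < 2 * fs:
        raise ValueError("need at least 2 s of PPG for systolic-peak detection")
    if not np.any(ppg):
        return np.array([], dtype=np.int64)

    x = ppg - np.mean(ppg)
    clipped = np.clip(x, 0.0, None)
    z = clipped**2
    w1 = int(round(0.111 * fs))
    w2 = int(round(0.667 * fs))
    ma_peak = _moving_average(z, w1)
    ma_beat = _moving_average(z, w2)
    alpha = 0.02 * float(np.mean(z))
    interest = ma_peak > (ma_beat + alpha)

    peaks: list[int] = []
    edges = np.flatnonzero(np.diff(interest.astype(np.int8)))
    starts = [0] if interest[0] else []
    starts += [int(e) + 1 for e in edges if not interest[e]]
    ends = [int(e) + 1 for e in edges if interest[e]]
    if interest[-1]:
        ends.append(len(interest))
    for a, b in zip(starts, ends):
        if b - a >= w1:
            peaks.append(a + int(np.argmax(ppg[a:b])))

    # de-duplicate peaks closer than a physiological minimum RR
    min_dist = int(round(0.250 * fs))
    out: list[int] = []
    for p in sorted(peaks):
        if out and p - out[-1] < min_dist:
            if ppg[p] > ppg[out[-1]]:
                out[-1] = p
        else:
            out.append(p)
    return np.asarray(out, dtype=np.int64)


def _beat_correspondences(r_peaks: np.ndarray, systolic_peaks: np.ndarray) -> list[tuple[int, int]]:
    """(r_idx, s_idx) pairs: the first systolic peak between an R peak and
    the next R peak corresponds to that R peak.  The left edge is
    inclusive so that a zero pulse arrival time still pairs the beats."""
    pairs = []
    for k in range(len(r_peaks) - 1):
        lo, hi = r_peaks[k], r_peaks[k + 1]
        between = systolic_peaks[(systolic_peaks >= lo) & (systolic_peaks < hi)]
        if len(between):
            pairs.append((int(lo), int(between[0])))
    return pairs


def align_pair(ecg: np.ndarray, ppg: np.ndarray, fs: float,
               annotations: PeakAnnotations, record_id: str = "",
               anchor_beat: int = 3) -> AlignedPair:
    """Alignment I: remove the pulse arrival time.

    The anchor systolic peak (the third detected one, or the earliest
    later one with a valid R correspondence) is aligned exactly onto its
    corresponding R peak by shifting the PPG left by the measured lag;
    both channels are truncated to the overlapping support and the PPG is
    then min-max scaled to [0, 1].
    """
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if len(ecg) != len(ppg):
        raise ValueError("ecg and ppg must have equal length")
    r, s = annotations.r_peaks, annotations.systolic_peaks
    if len(r) < 3 or len(s) < 3:
        raise AlignmentError(f"need >= 3 R and systolic peaks, got {len(r)} and {len(s)}")
    pairs = _beat_correspondences(r, s)
    if len(pairs) < 3:
        raise AlignmentError(f"only {len(pairs)} usable beat correspondences (< 3)")

    by_systolic = {s_idx: r_idx for r_idx, s_idx in pairs}
    anchor = None
    for k in range(anchor_beat - 1, len(s)):
        if int(s[k]) in by_systolic:
            anchor = int(s[k])
            if k != anchor_beat - 1:
                logger.warning("anchor beat %d had no R correspondence; using beat %d",
                               anchor_beat, k + 1)
            break
    if anchor is None:
        raise AlignmentError("no systolic peak at or after the anchor beat has an "
                             "R-peak correspondence")
    lag = anchor - by_systolic[anchor]
    if lag < 0:
        raise AlignmentError(
            f"computed lag {lag} samples is negative; the PPG should lag the ECG "
            "physiologically — check channel order and peak detections")

    n = len(ecg) - lag
    aligned_ppg = ppg[lag:]
    aligned_ecg = ecg[:n]
    return AlignedPair(ecg=aligned_ecg, ppg=normalize_ppg(aligned_ppg), fs=fs,
                       applied_lag=int(lag), record_id=record_id)


def normalize_ppg(ppg: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; errors on a constant sequence."""
    ppg = np.asarray(ppg, dtype=float)
    lo, hi = float(np.min(ppg)), float(np.max(ppg))
    if hi == lo:
        raise ValueError("cannot min-max scale a constant sequence")
    return (ppg - lo) / (hi - lo)
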