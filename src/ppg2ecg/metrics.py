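"""Evaluation metrics: Pearson r, rmse, DTW distance, and Alignment II.

The DTW local cost is the Euclidean distance in the (index, amplitude)
plane, ``d_ij = sqrt((i - j)^2 + (ref_i - rec_j)^2)``, with the index
difference in raw sample units — deliberately mixing units, and the
resulting distances are labelled mV to match common reporting practice.
An amplitude-only cost is available via ``index_weight=0``.  The warping
path is anchored at both endpoints with steps (1,0), (0,1), (1,1).

Alignment II searches integer lags within a +/-80 ms window for the lag
maximizing the correlation of the overlapping samples, and all aligned
metrics are computed on the truncated overlap (no padding).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WarpingPath",
    "XcorrAlignment",
    "EvalReport",
    "pearson_r",
    "rmse",
    "dtw",
    "dtw_per_second",
    "xcorr_align",
    "evaluate",
    "summarize",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a declared dependency
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


def pearson_r(ref: np.ndarray, rec: np.ndarray) -> float:
    """Pearson's correlation coefficient between two equal-length series."""
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {rec.shape}")
    if ref.size < 2:
        raise ValueError("need at least 2 samples")
    a = ref - ref.mean()
    b = rec - rec.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(np.clip(np.sum(a * b) / denom, -1.0, 1.0))


def rmse(ref: np.ndarray, rec: np.ndarray) -> float:
    """Root mean square error, in the amplitude units of the inputs (mV)."""
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {rec.shape}")
    return float(np.sqrt(np.mean((ref - rec) ** 2)))


@dataclass(frozen=True)
class WarpingPath:
    """Monotone index pairs from (1, 1) to (m, m), 1-based, endpoint-anchored."""

    steps: np.ndarray        # (L, 2) int array
    total_cost: float


@njit(cache=True)
def _dtw_band(a: np.ndarray, b: np.ndarray, r: int, index_weight: float):
    """Banded DP over the m x m cost lattice; band half-width r around the
    diagonal.  Returns accumulated costs and parent pointers in band storage
    (row i holds columns i-r .. i+r at offsets j - (i - r))."""
    m = a.shape[0]
    w = 2 * r + 1
    D = np.full((m, w), np.inf)
    P = np.zeros((m, w), dtype=np.int8)
    for i in range(m):
        jlo = i - r
        if jlo < 0:
            jlo = 0
        jhi = i + r
        if jhi > m - 1:
            jhi = m - 1
        for j in range(jlo, jhi + 1):
            k = j - (i - r)
            di = index_weight * (i - j) * (i - j) + (a[i] - b[j]) * (a[i] - b[j])
            dij = np.sqrt(di)
            if i == 0 and j == 0:
                D[i, k] = dij
                P[i, k] = -1
                continue
            best = np.inf
            arg = np.int8(0)
            if i > 0 and j > 0:
                kk = (j - 1) - (i - 1 - r)
                if 0 <= kk < w and D[i - 1, kk] < best:
                    best = D[i - 1, kk]
                    arg = 0
            if i > 0:
                kk = j - (i - 1 - r)
                if 0 <= kk < w and D[i - 1, kk] < best:
                    best = D[i - 1, kk]
                    arg = 1
            if j > 0:
                kk = (j - 1) - (i - r)
                if 0 <= kk < w and D[i, kk] < best:
                    best = D[i, kk]
                    arg = 2
            D[i, k] = dij + best
            P[i, k] = arg
    return D, P


def _traceback(P: np.ndarray, r: int, m: int) -> np.ndarray:
    steps = []
    i = j = m - 1
    while True:
        steps.append((i + 1, j + 1))
        if i == 0 and j == 0:
            break
        p = P[i, j - (i - r)]
        if p == 0:
            i -= 1
            j -= 1
        elif p == 1:
            i -= 1
        else:
            j -= 1
    steps.reverse()
    return np.asarray(steps, dtype=np.int64)


def dtw(ref: np.ndarray, rec: np.ndarray, radius: int | None = None,
        index_weight: float = 1.0) -> tuple[float, WarpingPath]:
    """DTW distance and warping path between equal-length series.

    radius: Sakoe-Chiba band half-width in samples; None means the full
    (unbanded) lattice.  index_weight scales the squared index-difference
    term of the local cost (1.0 = the literal mixed-unit cost, 0.0 =
    amplitude-only).
    """
    a = np.ascontiguousarray(ref, dtype=np.float64)
    b = np.ascontiguousarray(rec, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("inputs must be one-dimensional")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    m = a.shape[0]
    if m == 0:
        raise ValueError("cannot compute DTW of empty sequences")
    r = m - 1 if radius is None else int(radius)
    r = max(1, min(r, m - 1)) if m > 1 else 0
    D, P = _dtw_band(a, b, r, float(index_weight))
    dist = float(D[m - 1, (m - 1) - (m - 1 - r)])
    path = WarpingPath(steps=_traceback(P, r, m), total_cost=dist)
    return dist, path


def dtw_per_second(distance: float, duration_s: float) -> float:
    """DTW distance normalized by the signal duration (mV per second)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if distance < 0:
        raise ValueError("distance must be >= 0")
    return distance / duration_s


@dataclass(frozen=True)
class XcorrAlignment:
    """Result of Alignment II: the chosen lag and the truncated overlap.

    Positive lag means the reconstruction lags the reference and was
    shifted earlier; ref and rec are the equal-length overlap on which
    aligned metrics are computed.
    """

    lag: int
    ref: np.ndarray
    rec: np.ndarray


def _overlap(ref: np.ndarray, rec: np.ndarray, lag: int) -> tuple[np.ndarray, np.ndarray]:
    n = len(ref)
    if lag >= 0:
        return ref[: n - lag], rec[lag:]
    return ref[-lag:], rec[: n + lag]


def xcorr_align(ref: np.ndarray, rec: np.ndarray, fs: float,
                window_ms: float = 80.0) -> XcorrAlignment:
    """Find the integer lag within +/-window_ms that best aligns rec to ref.

    The lag maximizing the normalized cross-correlation of the
    overlapping samples wins; ties go to the smallest |lag|, then to the
    negative lag.
    """
    ref = np.asarray(ref, dtype=float)
    rec = np.asarray(rec, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(f"length mismatch: {ref.shape} vs {rec.shape}")
    if window_ms < 0:
        raise ValueError("window_ms must be >= 0")
    w = int(round(window_ms * fs / 1000.0))
    if w >= len(ref):
        raise ValueError(f"alignment window ({w} samples) must be smaller than "
                         f"the signal ({len(ref)} samples)")
    # search order encodes the tie-break: 0, -1, +1, -2, +2, ...
    lags = [0]
    for k in range(1, w + 1):
        lags += [-k, k]
    best_lag, best_score = 0, -np.inf
    for lag in lags:
        a, b = _overlap(ref, rec, lag)
        if len(a) < 2:
            continue
        da = a - a.mean()
        db = b - b.mean()
        denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
        score = np.sum(da * db) / denom if denom > 0 else -np.inf
        if score > best_score:
            best_score, best_lag = score, lag
    a, b = _overlap(ref, rec, best_lag)
    return XcorrAlignment(lag=int(best_lag), ref=a, rec=b)


@dataclass(frozen=True)
class EvalReport:
    """Per-segment and stitched reconstruction metrics.

    Per-segment arrays (one entry per test segment): r, rmse_ (mV), d
    (mV), d_bar (mV/s), and the aligned variants r_a, rmse_a, d_a with
    the per-segment lag.  Stitched scalars: r_s, rmse_s, d_s, d_bar_s and
    aligned r_sa, rmse_sa with one global lag.
    """

    segment_s: int
    fs: float
    r: np.ndarray
    rmse_: np.ndarray
    d: np.ndarray
    d_bar: np.ndarray
    lag: np.ndarray
    r_a: np.ndarray
    rmse_a: np.ndarray
    d_a: np.ndarray
    r_s: float
    rmse_s: float
    d_s: float
    d_bar_s: float
    lag_s: int
    r_sa: float
    rmse_sa: float

    @property
    def n_segments(self) -> int:
        return len(self.r)

    def summary(self) -> dict[str, float]:
        """Mean and sd of each per-segment column plus the stitched scalars."""
        out: dict[str, float] = {}
        for name in ("r", "rmse_", "d", "d_bar", "r_a", "rmse_a", "d_a"):
            col = getattr(self, name)
            key = name.rstrip("_")
            out[f"{key}_mean"] = float(np.mean(col))
            out[f"{key}_sd"] = float(np.std(col, ddof=1)) if len(col) > 1 else 0.0
        for name in ("r_s", "rmse_s", "d_s", "d_bar_s", "r_sa", "rmse_sa"):
            out[name] = float(getattr(self, name))
        out["n_segments"] = self.n_segments
        out["segment_s"] = self.segment_s
        return out

    def to_dict(self) -> dict:
        d = self.summary()
        d["per_segment"] = {
            "r": self.r.tolist(),
            "rmse": self.rmse_.tolist(),
            "d": self.d.tolist(),
            "lag": self.lag.tolist(),
            "r_a": self.r_a.tolist(),
            "rmse_a": self.rmse_a.tolist(),
            "d_a": self.d_a.tolist(),
        }
        d["lag_s"] = int(self.lag_s)
        return d


def evaluate(ref_segments: np.ndarray, rec_segments: np.ndarray, fs: float,
             segment_s: int, align_window_ms: float = 80.0,
             stitched_band_radius_s: float = 1.0) -> EvalReport:
    """Compute per-segment and stitched metrics for a reconstruction.

    Per-segment aligned metrics use a lag per segment; stitched aligned
    metrics use one global lag.  The stitched DTW runs inside a
    Sakoe-Chiba band (default radius 1 s of samples), the per-segment
    DTW on the full lattice.
    """
    ref_segments = np.atleast_2d(np.asarray(ref_segments, dtype=float))
    rec_segments = np.atleast_2d(np.asarray(rec_segments, dtype=float))
    if ref_segments.shape != rec_segments.shape:
        raise ValueError(f"segment count/length mismatch: {ref_segments.shape} "
                         f"vs {rec_segments.shape}")
    n_seg = ref_segments.shape[0]
    if n_seg == 0:
        raise ValueError("no segments to evaluate")

    r = np.empty(n_seg)
    rm = np.empty(n_seg)
    d = np.empty(n_seg)
    lag = np.empty(n_seg, dtype=np.int64)
    r_a = np.empty(n_seg)
    rm_a = np.empty(n_seg)
    d_a = np.empty(n_seg)
    for k in range(n_seg):
        ref_k, rec_k = ref_segments[k], rec_segments[k]
        r[k] = pearson_r(ref_k, rec_k)
        rm[k] = rmse(ref_k, rec_k)
        d[k], _ = dtw(ref_k, rec_k)
        al = xcorr_align(ref_k, rec_k, fs, align_window_ms)
        lag[k] = al.lag
        r_a[k] = pearson_r(al.ref, al.rec)
        rm_a[k] = rmse(al.ref, al.rec)
        d_a[k], _ = dtw(al.ref, al.rec)

    ref_st = ref_segments.reshape(-1)
    rec_st = rec_segments.reshape(-1)
    total_s = len(ref_st) / fs
    r_s = pearson_r(ref_st, rec_st)
    rmse_s = rmse(ref_st, rec_st)
    radius = int(round(stitched_band_radius_s * fs))
    d_s, _ = dtw(ref_st, rec_st, radius=radius)
    al_s = xcorr_align(ref_st, rec_st, fs, align_window_ms)

    return EvalReport(
        segment_s=segment_s, fs=fs,
        r=r, rmse_=rm, d=d, d_bar=d / segment_s, lag=lag,
        r_a=r_a, rmse_a=rm_a, d_a=d_a,
        r_s=r_s, rmse_s=rmse_s, d_s=float(d_s),
        d_bar_s=dtw_per_second(d_s, total_s), lag_s=al_s.lag,
        r_sa=pearson_r(al_s.ref, al_s.rec), rmse_sa=rmse(al_s.ref, al_s.rec),
    )


def summarize(reports: list[EvalReport]) -> dict[str, float]:
    """Cohort aggregation: per-segment columns pooled over all segments of
    all records, stitched columns pooled over records (mean and sd)."""
    if not reports:
        raise ValueError("no reports to summarize")
    out: dict[str, float] = {}
    for name in ("r", "rmse_", "d", "d_bar", "r_a", "rmse_a", "d_a"):
        pooled = np.concatenate([getattr(rep, name) for rep in reports])
        key = name.rstrip("_")
        out[f"{key}_mean"] = float(np.mean(pooled))
        out[f"{key}_sd"] = float(np.std(pooled, ddof=1)) if len(pooled) > 1 else 0.0
    for name in ("r_s", "rmse_s", "d_s", "d_bar_s", "r_sa", "rmse_sa"):
        vals = np.array([getattr(rep, name) for rep in reports], dtype=float)
        out[f"{name}_mean"] = float(np.mean(vals))
        out[f"{name}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    out["n_records"] = len(reports)
    return out
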