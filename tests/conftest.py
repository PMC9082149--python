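import numpy as np
import pytest

from ppg2ecg.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def clean_record_60s():
    """Jitter-free 60 bpm subject, 60 s, no noise: exact beat grid."""
    return generate(SyntheticConfig(duration_s=60.0, rr_jitter_sd_s=0.0, seed=11))


@pytest.fixture(scope="session")
def clean_record_30s():
    """Clean 30 s subject with RR jitter (default config noise-free)."""
    return generate(SyntheticConfig(duration_s=30.0, seed=12))


@pytest.fixture(scope="session")
def clean_record_320s():
    """Clean 320 s subject: long enough for the full 48/12/12/228 split
    after Alignment I truncation."""
    return generate(SyntheticConfig(duration_s=320.0, seed=13))


def brute_force_dtw(ref: np.ndarray, rec: np.ndarray, index_weight: float = 1.0) -> float:
    """Exhaustive enumeration of all monotone warping paths from (0,0) to
    (m-1, m-1) with steps {(1,0),(0,1),(1,1)}; independent of the DP code."""

    m = len(ref)

    def cost(i, j):
        return np.sqrt(index_weight * (i - j) ** 2 + (ref[i] - rec[j]) ** 2)

    best = [np.inf]

    def walk(i, j, acc):
        if acc >= best[0]:
            return
        if i == m - 1 and j == m - 1:
            best[0] = acc
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < m and nj < m:
                walk(ni, nj, acc + cost(ni, nj))

    walk(0, 0, cost(0, 0))
    return best[0]


def match_rate(detected: np.ndarray, truth: np.ndarray, tol_samples: int):
    """(sensitivity, precision) of detected peaks against ground truth."""
    if len(detected) == 0:
        return 0.0, 0.0
    sens = np.mean([np.min(np.abs(detected - t)) <= tol_samples for t in truth])
    prec = np.mean([np.min(np.abs(truth - d)) <= tol_samples for d in detected])
    return float(sens), float(prec)
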