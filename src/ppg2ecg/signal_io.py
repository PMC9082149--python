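"""Reading and writing paired ECG+PPG records.

CSV is the canonical interchange format: comma-separated, header exactly
``time,ecg,ppg``, time in seconds starting at 0 with a constant step of
1/fs.  A minimal reader for WFDB-style records (plain-text header plus a
format-16 signal file) is provided as an optional adapter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Record", "FormatError", "read_record", "write_record"]

_CSV_COLUMNS = ("time", "ecg", "ppg")


class FormatError(ValueError):
    """A record file violates the expected format."""


@dataclass(frozen=True)
class Record:
    """A paired raw ECG/PPG time series.

    ecg is in mV, ppg in arbitrary units; both channels share the
    sampling rate ``fs`` (Hz) and have equal length >= 1.
    """

    record_id: str
    fs: float
    ecg: np.ndarray
    ppg: np.ndarray
    disease_flag: bool | None = None

    def __post_init__(self) -> None:
        ecg = np.asarray(self.ecg, dtype=float)
        ppg = np.asarray(self.ppg, dtype=float)
        object.__setattr__(self, "ecg", ecg)
        object.__setattr__(self, "ppg", ppg)
        if ecg.ndim != 1 or ppg.ndim != 1:
            raise ValueError("ecg and ppg must be one-dimensional")
        if len(ecg) != len(ppg):
            raise ValueError(f"channel length mismatch: ecg {len(ecg)} vs ppg {len(ppg)}")
        if len(ecg) < 1:
            raise ValueError("record must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not (np.all(np.isfinite(ecg)) and np.all(np.isfinite(ppg))):
            raise ValueError("all samples must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.ecg)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _read_csv(path: str | os.PathLike) -> Record:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected header time,ecg,ppg")
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 rows to infer the sampling rate")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0:
        raise FormatError(f"{path}: time column is not strictly increasing")
    if np.max(np.abs(steps - dt)) > 1e-6 * max(abs(dt), 1.0):
        raise FormatError(f"{path}: non-uniform time step (max deviation "
                          f"{np.max(np.abs(steps - dt)):.3g} s from {dt:.6g} s)")
    return Record(
        record_id=os.path.splitext(os.path.basename(os.fspath(path)))[0],
        fs=1.0 / dt,
        ecg=df["ecg"].to_numpy(dtype=float),
        ppg=df["ppg"].to_numpy(dtype=float),
    )


def _read_wfdb(path: str | os.PathLike) -> Record:
    """Minimal WFDB reader: text .hea header + interleaved format-16 .dat.

    Supports exactly two signals; channel names containing 'ecg'/'ii' and
    'ppg'/'pleth' (case-insensitive) select the channels, otherwise the
    first is taken as ECG and the second as PPG.
    """
    base = os.fspath(path)
    if base.endswith(".hea"):
        base = base[:-4]
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"header not found: {hea}")
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    record_name, n_sig = head[0], int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    if n_sig != 2:
        raise FormatError(f"{hea}: expected 2 signals, found {n_sig}")
    gains, baselines, names, fmts = [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        parts = ln.split()
        fmts.append(parts[1])
        gain_field = parts[2] if len(parts) > 2 else "200"
        gain_str = gain_field.split("/")[0]
        if "(" in gain_str:
            gain_s, base_s = gain_str.split("(")
            baselines.append(int(base_s.rstrip(")")))
        else:
            gain_s = gain_str
            baselines.append(0)
        gains.append(float(gain_s) if float(gain_s) != 0 else 200.0)
        names.append(parts[-1] if len(parts) > 8 else f"sig{len(names)}")
    if any(f.split("+")[0] != "16" for f in fmts):
        raise FormatError(f"{hea}: only format 16 is supported, found {fmts}")
    dat = base + ".dat"
    raw = np.fromfile(dat, dtype="<i2")
    if len(raw) % n_sig:
        raise FormatError(f"{dat}: sample count not divisible by {n_sig} signals")
    sig = raw.reshape(-1, n_sig).astype(float)
    for j in range(n_sig):
        sig[:, j] = (sig[:, j] - baselines[j]) / gains[j]
    lowered = [n.lower() for n in names]
    ecg_j = next((j for j, n in enumerate(lowered) if "ecg" in n or n in ("ii", "i", "v")), 0)
    ppg_j = next((j for j, n in enumerate(lowered) if "ppg" in n or "pleth" in n), 1 - ecg_j)
    return Record(record_id=record_name, fs=fs, ecg=sig[:, ecg_j], ppg=sig[:, ppg_j])


def read_record(path: str | os.PathLike, format: str = "csv") -> Record:
    """Read a paired ECG+PPG record.

    format 'csv' expects columns time,ecg,ppg with a constant sampling
    interval (relative tolerance 1e-6); fs is inferred from the time
    column.  format 'wfdb' reads a WFDB-style header/signal pair.
    """
    if not os.path.exists(os.fspath(path)) and format == "csv":
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "wfdb":
        return _read_wfdb(path)
    raise ValueError(f"unknown format {format!r}; expected 'csv' or 'wfdb'")


def write_record(record: Record, path: str | os.PathLike) -> None:
    """Write a Record as canonical CSV (header time,ecg,ppg, time from 0, step 1/fs).

    Amplitudes are stored at full repr precision so read_record round-trips
    bit-stably.
    """
    t = np.arange(record.n_samples) / record.fs
    df = pd.DataFrame({"time": t, "ecg": record.ecg, "ppg": record.ppg})
    df.to_csv(path, index=False, float_format="%.17g")
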