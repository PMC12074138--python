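"""Heartbeat preprocessing: R-peak detection and fixed-length segmentation.

R peaks are located with the Pan–Tompkins pipeline: band-pass (5–15 Hz),
five-point derivative, squaring, 150 ms moving-window integration, then
adaptive dual thresholds with search-back and a 200 ms refractory period.
Filtering is zero-phase (forward–backward), so no group-delay correction is
needed; each integrated-signal peak is refined to the strongest band-passed
deflection nearby.  All internal constants are overridable keyword arguments
because recordings differ in noise floor and morphology.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.signal


@dataclass
class EcgRecord:
    """A single-lead voltage series with its sampling rate."""

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate fs must be positive")
        if self.samples.size < 2:
            raise ValueError("record must contain at least 2 samples")


@dataclass
class HeartbeatMatrix:
    """Fixed-length beats as columns, anchored on their R peaks."""

    segments: np.ndarray  # window_length x n_beats
    r_peak_indices: np.ndarray  # per-beat index into the source record
    window_length: int
    n_dropped: int = 0
    fs: float = 0.0

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=float)
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        if self.segments.ndim != 2 or self.segments.shape[0] != self.window_length:
            raise ValueError("segments must be (window_length x n_beats)")
        if self.segments.shape[1] != self.r_peak_indices.size:
            raise ValueError("one R-peak index per beat required")
        if np.any(np.diff(self.r_peak_indices) <= 0):
            raise ValueError("r_peak_indices must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return self.segments.shape[1]


def detect_r_peaks(
    record: EcgRecord,
    band=(5.0, 15.0),
    integration_window_s: float = 0.150,
    refractory_s: float = 0.200,
    searchback_factor: float = 1.66,
    threshold_fraction: float = 0.25,
) -> np.ndarray:
    """Pan–Tompkins R-peak detection; returns strictly increasing sample indices.

    An all-flat signal yields an empty result.  Records shorter than the
    2 s threshold-learning phase raise a "too short" error.
    """
    x = record.samples
    fs = record.fs
    if fs < 100:
        warnings.warn(
            f"sampling rate {fs} Hz is low for ECG R-peak detection (>= 100 Hz recommended)",
            stacklevel=2,
        )
    learn_n = int(round(2.0 * fs))
    min_len = max(learn_n, 3 * (2 * 3 + 1) + 1)  # learning phase / filtfilt warm-up
    if x.size < min_len:
        raise ValueError(
            f"record too short for R-peak detection: {x.size} samples, need >= {min_len}"
        )
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    nyq = fs / 2.0
    hi = min(band[1], 0.99 * nyq)
    sos = scipy.signal.butter(2, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    bp = scipy.signal.sosfiltfilt(sos, x)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) / 8.0, mode="same")
    sq = deriv**2
    win = max(1, int(round(integration_window_s * fs)))
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(refractory_s * fs)))
    candidates, _ = scipy.signal.find_peaks(mwi, distance=refractory)
    if candidates.size == 0:
        return np.array([], dtype=int)

    spki = 0.25 * float(np.max(mwi[:learn_n]))
    npki = 0.5 * float(np.mean(mwi[:learn_n]))
    thr1 = npki + threshold_fraction * (spki - npki)

    accepted: list[int] = []
    rejected: list[int] = []
    rr_history: list[float] = []

    def accept(p: int, searchback: bool):
        nonlocal spki
        if searchback:
            spki = 0.25 * mwi[p] + 0.75 * spki
        else:
            spki = 0.125 * mwi[p] + 0.875 * spki
        if accepted:
            rr_history.append(p - accepted[-1])
            if len(rr_history) > 8:
                rr_history.pop(0)
        accepted.append(p)

    for p in candidates:
        # search-back: a long silent gap lowers the bar to half threshold
        if accepted and rr_history:
            avg_rr = float(np.mean(rr_history))
            if p - accepted[-1] > searchback_factor * avg_rr and rejected:
                back = [q for q in rejected if accepted[-1] + refractory <= q <= p - refractory]
                if back:
                    best = max(back, key=lambda q: mwi[q])
                    if mwi[best] > 0.5 * thr1:
                        accept(int(best), searchback=True)
                        rejected = [q for q in rejected if q > best]
        if mwi[p] > thr1:
            accept(int(p), searchback=False)
        else:
            npki = 0.125 * mwi[p] + 0.875 * npki
            rejected.append(int(p))
        thr1 = npki + threshold_fraction * (spki - npki)

    if not accepted:
        return np.array([], dtype=int)

    # refine each detection to the strongest band-passed deflection nearby
    half = win
    refined = []
    for p in accepted:
        lo = max(0, p - half)
        hi_i = min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(bp[lo:hi_i] ** 2)))
    refined = np.array(sorted(set(refined)), dtype=int)

    # enforce the refractory period on the refined indices, keeping the stronger beat
    out: list[int] = []
    for p in refined:
        if out and p - out[-1] < refractory:
            if bp[p] ** 2 > bp[out[-1]] ** 2:
                out[-1] = int(p)
        else:
            out.append(int(p))
    return np.array(out, dtype=int)


def segment_heartbeats(
    record: EcgRecord,
    peaks,
    window_length: int,
    offset_fraction: float = 0.5,
) -> HeartbeatMatrix:
    """Cut one fixed-length window per R peak.

    Each retained beat is the verbatim slice
    [peak - floor(offset_fraction * window_length), ... + window_length); beats
    whose window would cross a record boundary are dropped and counted in
    ``n_dropped``.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if not 0 < offset_fraction < 1:
        raise ValueError("offset_fraction must lie strictly between 0 and 1")
    x = record.samples
    if window_length > x.size:
        raise ValueError(
            f"window_length {window_length} exceeds record length {x.size}"
        )
    peaks = np.asarray(peaks, dtype=int)
    before = int(np.floor(offset_fraction * window_length))
    cols, kept_peaks = [], []
    dropped = 0
    for p in peaks:
        start = p - before
        stop = start + window_length
        if start < 0 or stop > x.size:
            dropped += 1
            continue
        cols.append(x[start:stop])
        kept_peaks.append(int(p))
    segments = (
        np.column_stack(cols) if cols else np.zeros((window_length, 0))
    )
    return HeartbeatMatrix(
        segments=segments,
        r_peak_indices=np.array(kept_peaks, dtype=int),
        window_length=window_length,
        n_dropped=dropped,
        fs=record.fs,
    )


def read_trace(path, fs: float | None = None, column: int = 0, record_id: str | None = None) -> EcgRecord:
    """Read a raw voltage trace from a delimited text file (one channel per column).

    ``fs`` may instead live in a JSON sidecar ``<path>.json`` with key "fs".
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    if fs is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError("sampling rate fs required (argument or JSON sidecar)")
        fs = float(json.loads(sidecar.read_text())["fs"])
    return EcgRecord(samples=data[:, column], fs=fs, record_id=record_id or path.stem)


def write_heartbeats(beats: HeartbeatMatrix, path) -> None:
    """Segments as a delimited matrix (one column per beat) + JSON sidecar."""
    path = Path(path)
    np.savetxt(path, beats.segments, delimiter=",")
    sidecar = {
        "r_peak_indices": beats.r_peak_indices.tolist(),
        "fs": beats.fs,
        "window_length": beats.window_length,
        "n_dropped": beats.n_dropped,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_heartbeats(path) -> HeartbeatMatrix:
    path = Path(path)
    segments = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return HeartbeatMatrix(
        segments=segments,
        r_peak_indices=np.array(meta["r_peak_indices"], dtype=int),
        window_length=int(meta["window_length"]),
        n_dropped=int(meta.get("n_dropped", 0)),
        fs=float(meta.get("fs", 0.0)),
    )
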