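"""1-D multi-resolution local binary pattern (LBP) features for heartbeats.

For each interior sample of a heartbeat segment, the values at offsets
+/-radius, +/-2*radius, ... are compared with the center value; each neighbor
>= center contributes a 1 bit (ties count as 1), giving one integer code per
position.  Codes are computed at several radii (the multi-resolution part) and
summarized as histograms over sliding windows; the concatenated, optionally
normalized histograms form one feature column.

Conventions (fixed and documented here):
* bit order: neighbors sorted by signed offset (left to right), packed
  MSB-first — e.g. radius 1, one neighbor per side on a rising ramp gives
  binary 01 = 1;
* boundary positions without a full neighborhood are truncated, so a code
  series is 2 * radius * neighbors_per_side shorter than the segment;
* the histogram window is clipped to the code-series length, so a window
  longer than the series yields a single whole-series histogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class LbpConfig:
    radii: tuple = (1, 2, 4)
    neighbors_per_side: int = 2
    window: int = 64
    stride: int = 32
    normalize: bool = True

    def __post_init__(self):
        radii = tuple(int(r) for r in self.radii)
        if len(radii) == 0 or any(r < 1 for r in radii) or len(set(radii)) != len(radii):
            raise ValueError("radii must be distinct positive integers")
        object.__setattr__(self, "radii", radii)
        if self.neighbors_per_side < 1:
            raise ValueError("neighbors_per_side must be >= 1")
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")

    @property
    def n_bins(self) -> int:
        return 2 ** (2 * self.neighbors_per_side)

    def feature_dim(self, segment_length: int) -> int:
        """d implied by this config for a given segment length (data-independent)."""
        d = 0
        for radius in self.radii:
            code_len = segment_length - 2 * radius * self.neighbors_per_side
            if code_len < 1:
                raise ValueError(
                    f"segment length {segment_length} too short for radius {radius} "
                    f"with {self.neighbors_per_side} neighbors per side"
                )
            w = min(self.window, code_len)
            d += (1 + (code_len - w) // self.stride) * self.n_bins
        return d


@dataclass
class FeatureChunk:
    """One round's feature matrix X (d x n_t) with per-column individual labels."""

    X: np.ndarray
    labels: list
    round_index: int = 1

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (d x n_t)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        self.labels = list(self.labels)
        if len(self.labels) != self.X.shape[1]:
            raise ValueError(
                f"labels length {len(self.labels)} != number of columns {self.X.shape[1]}"
            )
        if self.round_index < 1:
            raise ValueError("round_index must be >= 1")

    @property
    def d(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


def lbp_codes_1d(segment, radius: int, neighbors_per_side: int) -> np.ndarray:
    """Integer LBP code series for one segment at one radius.

    Output length = len(segment) - 2 * radius * neighbors_per_side.
    """
    x = np.asarray(segment, dtype=float).ravel()
    margin = radius * neighbors_per_side
    out_len = x.size - 2 * margin
    if out_len < 1:
        raise ValueError(
            f"segment of length {x.size} too short for radius {radius} with "
            f"{neighbors_per_side} neighbors per side; need > {2 * margin} samples"
        )
    center = x[margin : margin + out_len]
    # signed offsets left to right: -P*r, ..., -r, +r, ..., +P*r
    offsets = [-k * radius for k in range(neighbors_per_side, 0, -1)]
    offsets += [k * radius for k in range(1, neighbors_per_side + 1)]
    n_bits = len(offsets)
    codes = np.zeros(out_len, dtype=np.int64)
    for bit, off in enumerate(offsets):
        neighbor = x[margin + off : margin + off + out_len]
        codes |= (neighbor >= center).astype(np.int64) << (n_bits - 1 - bit)
    return codes


def _windowed_histograms(codes: np.ndarray, cfg: LbpConfig) -> np.ndarray:
    w = min(cfg.window, codes.size)
    starts = range(0, codes.size - w + 1, cfg.stride)
    blocks = []
    for s in starts:
        hist = np.bincount(codes[s : s + w], minlength=cfg.n_bins).astype(float)
        if cfg.normalize:
            hist /= hist.sum()
        blocks.append(hist)
    return np.concatenate(blocks)


def extract_features(beats, cfg: LbpConfig = LbpConfig()) -> np.ndarray:
    """Feature matrix X (d x n_beats) from heartbeat segments.

    ``beats`` is a HeartbeatMatrix or a (window_length x n_beats) array; every
    beat must have the same length.  Per beat: code series at every radius,
    windowed histograms of each series, all concatenated into one column.
    """
    segments = np.asarray(getattr(beats, "segments", beats), dtype=float)
    if segments.ndim != 2:
        raise ValueError("beats must form a 2-D (window_length x n_beats) matrix")
    seg_len, n_beats = segments.shape
    d = cfg.feature_dim(seg_len)  # validates the config against seg_len
    X = np.empty((d, n_beats))
    for j in range(n_beats):
        col = [
            _windowed_histograms(lbp_codes_1d(segments[:, j], radius, cfg.neighbors_per_side), cfg)
            for radius in cfg.radii
        ]
        X[:, j] = np.concatenate(col)
    return X
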