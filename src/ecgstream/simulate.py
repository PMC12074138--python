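"""Synthetic test beds: labeled feature streams and pseudo-ECG records.

Two generators back every experiment in this package:

* ``simulate_feature_stream`` — Gaussian class clusters delivered as an
  ordered chunk schedule.  Class means are random directions rescaled so the
  minimum pairwise distance equals ``class_separation * within_sd``; samples
  add isotropic noise.  A fraction of individuals can be withheld from early
  rounds to exercise the class-incremental path, and five samples per
  individual are reserved as the held-out test set.
* ``simulate_ecg_record`` — pseudo-ECG beats built from three Gaussian bumps
  (P, QRS, T) with jittered RR intervals and additive noise, returning the
  ground-truth R-peak indices.

Both are fully seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import pdist

from .features import FeatureChunk
from .preprocess import EcgRecord

MITBIH_LIKE_SCHEDULE = (70, 70, 70, 70, 49)
CYBHIDB_LIKE_SCHEDULE = (108, 108, 108, 108, 108, 27)


@dataclass
class StreamSpec:
    """Conditions for a synthetic labeled feature stream."""

    n_individuals: int = 20
    chunk_sizes: tuple = MITBIH_LIKE_SCHEDULE
    d: int = 40
    class_separation: float = 8.0
    within_sd: float = 0.1
    incremental_fraction: float = 0.0
    introduce_round: int = 2
    n_test_per_individual: int = 5
    seed: int = 0

    def __post_init__(self):
        if any(int(n) < 1 for n in self.chunk_sizes):
            raise ValueError("chunk sizes must be positive")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")
        if not 0 <= self.incremental_fraction < 1:
            raise ValueError("incremental_fraction must lie in [0, 1)")
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if not 1 < self.introduce_round <= len(self.chunk_sizes):
            if self.incremental_fraction > 0:
                raise ValueError("introduce_round must lie in (1, n_chunks]")


@dataclass
class SimulatedStream:
    chunks: list
    test: FeatureChunk
    spec: StreamSpec
    class_means: np.ndarray
    train_counts: dict


@dataclass
class EcgSpec:
    """Conditions for a pseudo-ECG record (Gaussian P/QRS/T bumps)."""

    fs: float = 360.0
    n_beats: int = 100
    rr_mean: float = 0.8
    rr_sd: float = 0.04
    p_amp: float = 0.15
    p_offset: float = -0.16  # seconds relative to the R peak
    p_width: float = 0.025
    r_amp: float = 1.0
    r_width: float = 0.012
    t_amp: float = 0.3
    t_offset: float = 0.30
    t_width: float = 0.05
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.rr_mean <= max(self.p_width, self.r_width, self.t_width):
            raise ValueError("rr_mean must exceed the wave widths")

    def randomized(self, rng: np.random.Generator) -> "EcgSpec":
        """Per-individual morphology: jitter amplitudes/widths/offsets."""
        return replace(
            self,
            p_amp=self.p_amp * rng.uniform(0.7, 1.3),
            p_width=self.p_width * rng.uniform(0.8, 1.2),
            r_amp=self.r_amp * rng.uniform(0.8, 1.2),
            r_width=self.r_width * rng.uniform(0.8, 1.2),
            t_amp=self.t_amp * rng.uniform(0.7, 1.3),
            t_offset=self.t_offset * rng.uniform(0.9, 1.1),
            t_width=self.t_width * rng.uniform(0.8, 1.2),
        )


def _class_means(rng: np.random.Generator, spec: StreamSpec) -> np.ndarray:
    """Random directions rescaled so min pairwise distance = separation * within_sd."""
    means = rng.normal(size=(spec.n_individuals, spec.d))
    if spec.class_separation == 0:
        return np.zeros_like(means)
    min_dist = pdist(means).min()
    if min_dist == 0:  # vanishing odds, but keep the contract exact
        means += 1e-6 * rng.normal(size=means.shape)
        min_dist = pdist(means).min()
    return means * (spec.class_separation * spec.within_sd / min_dist)


def simulate_feature_stream(spec: StreamSpec) -> SimulatedStream:
    """Labeled chunks on the given schedule plus a held-out test chunk.

    Withheld individuals (``incremental_fraction``) never appear before
    ``introduce_round`` and all debut in that round.  Within a chunk the
    available individuals are cycled (balanced occupancy) and the order
    shuffled.  Raises if a chunk cannot cover the individuals that must
    appear in it.
    """
    rng = np.random.default_rng(spec.seed)
    means = _class_means(rng, spec)
    ids = [f"id{c:03d}" for c in range(spec.n_individuals)]

    n_withheld = int(round(spec.incremental_fraction * spec.n_individuals))
    withheld = set(rng.choice(spec.n_individuals, size=n_withheld, replace=False).tolist())
    initial = [c for c in range(spec.n_individuals) if c not in withheld]
    if len(initial) == 0:
        raise ValueError("incremental_fraction leaves no individuals for round 1")
    if spec.chunk_sizes[0] < len(initial):
        raise ValueError(
            f"round-1 chunk size {spec.chunk_sizes[0]} cannot cover the "
            f"{len(initial)} initially available individuals"
        )
    if n_withheld and spec.chunk_sizes[spec.introduce_round - 1] < n_withheld:
        raise ValueError(
            f"chunk {spec.introduce_round} size cannot cover the {n_withheld} withheld individuals"
        )

    chunks = []
    train_counts = {iid: 0 for iid in ids}
    for t, n_t in enumerate(spec.chunk_sizes, start=1):
        if n_withheld and t >= spec.introduce_round:
            available = list(range(spec.n_individuals))
        else:
            available = list(initial)
        label_idx = []
        if n_withheld and t == spec.introduce_round:
            label_idx.extend(sorted(withheld))  # debut: at least one sample each
        while len(label_idx) < n_t:
            take = min(len(available), n_t - len(label_idx))
            label_idx.extend(rng.permutation(available)[:take].tolist())
        label_idx = np.array(label_idx[:n_t])
        rng.shuffle(label_idx)
        X = means[label_idx].T + spec.within_sd * rng.normal(size=(spec.d, n_t))
        labels = [ids[c] for c in label_idx]
        for lab in labels:
            train_counts[lab] += 1
        chunks.append(FeatureChunk(X=X, labels=labels, round_index=t))

    n_test = spec.n_test_per_individual
    test_idx = np.repeat(np.arange(spec.n_individuals), n_test)
    X_test = means[test_idx].T + spec.within_sd * rng.normal(size=(spec.d, test_idx.size))
    test = FeatureChunk(X=X_test, labels=[ids[c] for c in test_idx], round_index=1)
    return SimulatedStream(
        chunks=chunks, test=test, spec=spec, class_means=means, train_counts=train_counts
    )


def simulate_ecg_record(spec: EcgSpec, snr_db: float | None = None):
    """Pseudo-ECG record and its ground-truth R-peak sample indices.

    ``snr_db`` overrides ``noise_sd`` with the value giving that signal-to-noise
    ratio against the clean trace RMS.  R peaks are grid-aligned, so at zero
    noise the QRS maxima coincide exactly with the returned indices.
    """
    rng = np.random.default_rng(spec.seed)
    rr = spec.rr_mean + spec.rr_sd * rng.normal(size=spec.n_beats)
    rr = np.clip(rr, 0.4 * spec.rr_mean, None)
    first_r = 0.4 * spec.rr_mean
    r_times = first_r + np.concatenate([[0.0], np.cumsum(rr[:-1])])
    r_idx = np.round(r_times * spec.fs).astype(int)
    n_samples = int(r_idx[-1] + round((spec.rr_mean) * spec.fs))
    t = np.arange(n_samples) / spec.fs

    clean = np.zeros(n_samples)
    for ti in r_idx / spec.fs:
        for amp, off, width in (
            (spec.p_amp, spec.p_offset, spec.p_width),
            (spec.r_amp, 0.0, spec.r_width),
            (spec.t_amp, spec.t_offset, spec.t_width),
        ):
            clean += amp * np.exp(-0.5 * ((t - ti - off) / width) ** 2)

    noise_sd = spec.noise_sd
    if snr_db is not None:
        rms = float(np.sqrt(np.mean(clean**2)))
        noise_sd = rms / (10 ** (snr_db / 20.0))
    samples = clean + noise_sd * rng.normal(size=n_samples)
    record = EcgRecord(samples=samples, fs=spec.fs, record_id=f"synthetic-{spec.seed}")
    return record, r_idx
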