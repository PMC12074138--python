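"""Matching and biometric metrics.

Queries and registered samples are projected to the latent space with the
learned W; identification assigns each query the label of its nearest gallery
row (Euclidean distance), and verification sweeps a distance threshold to find
the equal error rate (EER), the operating point where the false acceptance
rate equals the false rejection rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class Gallery:
    """Registered representations (m x r) with per-row labels."""

    reps: np.ndarray
    labels: list
    mode: str = "per-sample"

    def __post_init__(self):
        self.reps = np.asarray(self.reps, dtype=float)
        self.labels = list(self.labels)
        if self.reps.ndim != 2 or self.reps.shape[0] != len(self.labels):
            raise ValueError("gallery reps must be (m x r) with one label per row")
        if not np.all(np.isfinite(self.reps)):
            raise ValueError("gallery reps must be finite")


@dataclass
class VerificationScores:
    genuine: np.ndarray  # same-individual distances
    impostor: np.ndarray  # different-individual distances

    def __post_init__(self):
        self.genuine = np.asarray(self.genuine, dtype=float).ravel()
        self.impostor = np.asarray(self.impostor, dtype=float).ravel()
        if np.any(self.genuine < 0) or np.any(self.impostor < 0):
            raise ValueError("distances must be non-negative")


def project(X, W) -> np.ndarray:
    """Latent representations X^T W (one row per sample)."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if X.shape[0] != W.shape[0]:
        raise ValueError(f"dimension mismatch: X is {X.shape}, W is {W.shape}")
    return X.T @ W


def build_gallery(reps, labels, mode: str = "per-sample") -> Gallery:
    """Per-sample gallery, or one mean row per individual (``class-mean``)."""
    reps = np.asarray(reps, dtype=float)
    labels = list(labels)
    if mode == "per-sample":
        return Gallery(reps=reps, labels=labels, mode=mode)
    if mode == "class-mean":
        order, rows = [], {}
        for i, lab in enumerate(labels):
            rows.setdefault(lab, []).append(i)
            if len(rows[lab]) == 1:
                order.append(lab)
        means = np.array([reps[rows[lab]].mean(axis=0) for lab in order])
        return Gallery(reps=means, labels=order, mode=mode)
    raise ValueError(f"unknown gallery mode {mode!r}")


def identify(query_reps, gallery: Gallery, return_ties: bool = False):
    """Nearest-gallery-row label per query; ties go to the lowest gallery index."""
    if len(gallery.labels) == 0:
        raise ValueError("gallery is empty")
    Q = np.asarray(query_reps, dtype=float)
    D = cdist(Q, gallery.reps)
    nearest = np.argmin(D, axis=1)  # argmin returns the first (lowest) index on ties
    pred = [gallery.labels[j] for j in nearest]
    if return_ties:
        mins = D[np.arange(D.shape[0]), nearest]
        n_ties = int(np.sum(np.sum(D == mins[:, None], axis=1) > 1))
        return pred, n_ties
    return pred


def identification_accuracy(pred, truth) -> float:
    """Percentage of correctly identified queries."""
    pred, truth = list(pred), list(truth)
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if len(pred) == 0:
        raise ValueError("empty input")
    return 100.0 * sum(p == t for p, t in zip(pred, truth)) / len(pred)


def verification_scores(query_reps, query_labels, gallery: Gallery) -> VerificationScores:
    """All query-gallery distances, split into genuine and impostor pairs."""
    Q = np.asarray(query_reps, dtype=float)
    D = cdist(Q, gallery.reps)
    glab = np.asarray(gallery.labels, dtype=object)
    qlab = np.asarray(list(query_labels), dtype=object)
    same = qlab[:, None] == glab[None, :]
    return VerificationScores(genuine=D[same], impostor=D[~same])


def compute_eer(scores: VerificationScores) -> tuple[float, float]:
    """Equal error rate (percent) and its distance threshold.

    Candidate thresholds are the sorted pooled distances; FAR(t) is the
    fraction of impostor distances below t and FRR(t) the fraction of genuine
    distances above t.  The crossing of the two step functions is located and
    both are linearly interpolated between the bracketing thresholds.
    """
    g, im = scores.genuine, scores.impostor
    if g.size == 0 or im.size == 0:
        raise ValueError("both genuine and impostor scores are required")
    if np.ptp(np.concatenate([g, im])) == 0:
        warnings.warn("degenerate verification scores (all equal)", stacklevel=2)
    taus = np.unique(np.concatenate([g, im]))
    g_sorted = np.sort(g)
    im_sorted = np.sort(im)
    far = np.searchsorted(im_sorted, taus, side="left") / im.size  # P(impostor < t)
    frr = 1.0 - np.searchsorted(g_sorted, taus, side="right") / g.size  # P(genuine > t)
    diff = far - frr
    k = int(np.argmax(diff >= 0))  # first crossing; exists because frr -> 0 at the top
    if diff[k] == 0 or k == 0:
        eer = 0.5 * (far[k] + frr[k])
        thr = taus[k]
    else:
        s = (frr[k - 1] - far[k - 1]) / ((far[k] - far[k - 1]) - (frr[k] - frr[k - 1]))
        eer = far[k - 1] + s * (far[k] - far[k - 1])
        thr = taus[k - 1] + s * (taus[k] - taus[k - 1])
    return 100.0 * float(eer), float(thr)


def biometric_report(W, train_chunks, test_chunk, gallery_mode: str = "per-sample") -> dict:
    """Identification + verification metrics for a trained projection.

    Identification matches each query against the registered samples
    (``gallery_mode``, per-sample by default).  Verification scores each query
    against per-individual enrolled templates (the mean registered
    representation per individual), the standard biometric verification
    protocol; pass ``gallery_mode='per-sample'`` scores to
    :func:`verification_scores` directly for pairwise verification.
    """
    reps = np.vstack([project(c.X, W) for c in train_chunks])
    labels = [l for c in train_chunks for l in c.labels]
    queries = project(test_chunk.X, W)
    gallery = build_gallery(reps, labels, mode=gallery_mode)
    acc = identification_accuracy(identify(queries, gallery), test_chunk.labels)
    templates = build_gallery(reps, labels, mode="class-mean")
    eer, thr = compute_eer(verification_scores(queries, test_chunk.labels, templates))
    return {
        "accuracy_percent": acc,
        "eer_percent": eer,
        "threshold": thr,
        "n_query": len(test_chunk.labels),
        "n_gallery": len(labels),
    }


def per_round_curve(round_states, train_chunks, test_chunk, gallery_mode: str = "per-sample"):
    """Identification accuracy after each round with the then-current W.

    ``round_states`` is the per-round ModelState list from training; the
    gallery after round t contains all training samples delivered up to t,
    projected with W(t).  Returns the accuracy list (percent per round).
    """
    curve = []
    for t, state in enumerate(round_states, start=1):
        reps, labels = [], []
        for chunk in train_chunks[:t]:
            reps.append(project(chunk.X, state.W))
            labels.extend(chunk.labels)
        gallery = build_gallery(np.vstack(reps), labels, mode=gallery_mode)
        pred = identify(project(test_chunk.X, state.W), gallery)
        curve.append(identification_accuracy(pred, test_chunk.labels))
    return curve
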