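"""Hadamard code assignment for individual prototypes.

Each enrolled individual receives one row of a Sylvester Hadamard matrix as a
fixed, maximally separated target in latent space.  Rows of distinct
individuals are mutually orthogonal, which is what makes them useful as
prototype-learning targets: pulling every sample representation toward its
individual's code pushes different individuals apart by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard


@dataclass
class HadamardCodebook:
    """A Sylvester Hadamard matrix plus an id -> row assignment.

    Attributes
    ----------
    H_full : (2**k, 2**k) ndarray of +/-1 (int64)
    k : log2 of the order.
    assignment : mapping from individual id to row index; injective.
    """

    H_full: np.ndarray
    k: int
    assignment: dict = field(default_factory=dict)

    @property
    def next_free_row(self) -> int:
        return len(self.assignment)

    @property
    def capacity(self) -> int:
        return self.H_full.shape[0]

    def code_row(self, individual_id, r: int | None = None) -> np.ndarray:
        """Code row for an assigned id, truncated to the first ``r`` columns."""
        row = self.H_full[self.assignment[individual_id]]
        return row if r is None else row[:r]


def build_hadamard(k: int) -> HadamardCodebook:
    """Build an empty codebook over the order-2**k Sylvester Hadamard matrix.

    H satisfies H @ H.T == 2**k * I exactly (integer arithmetic).
    """
    if k < 0:
        raise ValueError(f"Hadamard log-order k must be >= 0, got {k}")
    H = hadamard(2**k, dtype=np.int64)
    return HadamardCodebook(H_full=H, k=k)


def assign_codes(codebook: HadamardCodebook, individual_ids) -> HadamardCodebook:
    """Assign codebook rows to previously unseen ids, in first-appearance order.

    Already-assigned ids keep their rows; assignment is therefore reproducible
    when the same labeled stream is replayed.  Mutates and returns ``codebook``.
    """
    unseen = []
    seen_local = set(codebook.assignment)
    for iid in individual_ids:
        if iid not in seen_local:
            unseen.append(iid)
            seen_local.add(iid)
    if codebook.next_free_row + len(unseen) > codebook.capacity:
        raise ValueError(
            f"Hadamard codebook capacity exceeded: {codebook.next_free_row} rows assigned, "
            f"{len(unseen)} new individuals, capacity {codebook.capacity} (2**{codebook.k}). "
            "Raise k to enroll more individuals."
        )
    for iid in unseen:
        codebook.assignment[iid] = codebook.next_free_row
    return codebook


def chunk_code_matrix(codebook: HadamardCodebook, labels, r: int | None = None) -> np.ndarray:
    """Per-sample code matrix H_t (n_t x r): row i is the code of labels[i].

    ``r`` defaults to the full order 2**k; smaller r takes the leading columns
    (orthogonality between distinct rows is then only approximate).
    """
    labels = list(labels)
    missing = [l for l in labels if l not in codebook.assignment]
    if missing:
        raise KeyError(f"labels without an assigned Hadamard code: {sorted(set(map(str, missing)))}")
    rows = np.array([codebook.assignment[l] for l in labels], dtype=int)
    H_t = codebook.H_full[rows].astype(float)
    if r is not None:
        if r > codebook.capacity:
            raise ValueError(f"requested r={r} exceeds Hadamard order {codebook.capacity}")
        H_t = H_t[:, :r]
    return H_t
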