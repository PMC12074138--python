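"""Memory enhancement store: per-individual running means of learned representations.

The memory bank holds one r-vector per individual ever seen — the running mean
of all latent representations that individual has produced across rounds.  It
is the rehearsal-free device against catastrophic forgetting: when a new chunk
arrives, representations of returning individuals are pulled toward their
stored means, and brand-new individuals expand the bank (class-incremental
case).  Storage is O(c_old * r), never proportional to the number of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MemoryBank:
    """Per-individual running means with counts, in first-appearance order."""

    ids: list = field(default_factory=list)
    counts: list = field(default_factory=list)
    means: np.ndarray | None = None  # (c_old, r); None when empty

    @property
    def n_individuals(self) -> int:
        return len(self.ids)


def update_memory(bank: MemoryBank, V_t: np.ndarray, labels) -> MemoryBank:
    """Absorb one round's representations into the bank (returns a new bank).

    Unseen individuals are appended with mean = their group mean; seen
    individuals get the count-weighted running-mean update
        mean <- (count * mean + sum(group rows)) / (count + group size),
    which keeps each stored mean equal to the arithmetic mean of every
    representation row that individual has ever produced.
    """
    V_t = np.asarray(V_t, dtype=float)
    labels = list(labels)
    if V_t.ndim != 2 or V_t.shape[0] != len(labels):
        raise ValueError(
            f"V_t rows ({V_t.shape[0] if V_t.ndim == 2 else V_t.shape}) must align with labels ({len(labels)})"
        )
    r = V_t.shape[1]
    ids = list(bank.ids)
    counts = list(bank.counts)
    means = (
        np.zeros((0, r)) if bank.means is None or bank.means.size == 0 else np.array(bank.means, dtype=float)
    )
    if means.shape[0] != len(ids):
        raise ValueError("corrupt bank: means rows do not align with ids")

    index = {iid: c for c, iid in enumerate(ids)}
    # first-appearance order over this chunk
    group_order, group_rows = [], {}
    for i, lab in enumerate(labels):
        if lab not in group_rows:
            group_rows[lab] = []
            group_order.append(lab)
        group_rows[lab].append(i)

    new_rows = []
    for lab in group_order:
        rows = V_t[group_rows[lab]]
        g = len(rows)
        if lab in index:
            c = index[lab]
            means[c] = (counts[c] * means[c] + rows.sum(axis=0)) / (counts[c] + g)
            counts[c] += g
        else:
            index[lab] = len(ids)
            ids.append(lab)
            counts.append(g)
            new_rows.append(rows.mean(axis=0))
    if new_rows:
        means = np.vstack([means, np.array(new_rows)])
    return MemoryBank(ids=ids, counts=counts, means=means)


def memory_matrix(bank: MemoryBank, r: int | None = None):
    """Aligned mean matrix V_m (c_old x r) and the id order used to build S.

    An empty bank yields a (0, r) matrix (r required in that case to fix the
    width; defaults to 0 columns).
    """
    if bank.means is None or bank.n_individuals == 0:
        width = 0 if r is None else r
        return np.zeros((0, width)), []
    return np.array(bank.means, dtype=float), list(bank.ids)
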