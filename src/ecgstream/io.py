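"""On-disk formats: feature streams (delimited matrices + JSON manifest) and
model checkpoints (delimited matrices + JSON metadata).

A stream directory holds one ``chunk_<t>.csv`` (d rows x n_t columns) and
``chunk_<t>.json`` sidecar per round, an optional ``test.csv``/``test.json``
pair, and a ``manifest.json`` listing the chunk order.  ``StreamReader``
counts file opens so the online contract — each chunk read at most once during
training — is auditable.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .features import FeatureChunk
from .learner import Hyperparams, ModelState, SufficientStats
from .memory import MemoryBank

FORMAT_VERSION = 1


def _write_chunk(directory: Path, stem: str, chunk: FeatureChunk) -> dict:
    np.savetxt(directory / f"{stem}.csv", chunk.X, delimiter=",")
    meta = {
        "round_index": chunk.round_index,
        "labels": [str(l) for l in chunk.labels],
        "d": chunk.d,
        "n": chunk.n,
    }
    (directory / f"{stem}.json").write_text(json.dumps(meta))
    return {"X": f"{stem}.csv", "meta": f"{stem}.json"}


def write_stream(directory, chunks, test: FeatureChunk | None = None, spec=None, seed=None) -> Path:
    """Write an ordered chunk sequence (and optional test chunk) with a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "seed": seed,
        "spec": dataclasses.asdict(spec) if dataclasses.is_dataclass(spec) else spec,
        "chunks": [_write_chunk(directory, f"chunk_{c.round_index}", c) for c in chunks],
    }
    if test is not None:
        manifest["test"] = _write_chunk(directory, "test", test)
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


class StreamReader:
    """Reads a stream directory; tracks how often each file is opened."""

    def __init__(self, manifest_path):
        self.manifest_path = Path(manifest_path)
        if self.manifest_path.is_dir():
            self.manifest_path = self.manifest_path / "manifest.json"
        self.directory = self.manifest_path.parent
        self.manifest = json.loads(self.manifest_path.read_text())
        self.open_counts: dict[str, int] = {}

    def _load_chunk(self, entry: dict) -> FeatureChunk:
        for key in ("X", "meta"):
            self.open_counts[entry[key]] = self.open_counts.get(entry[key], 0) + 1
        X = np.loadtxt(self.directory / entry["X"], delimiter=",", ndmin=2)
        meta = json.loads((self.directory / entry["meta"]).read_text())
        return FeatureChunk(X=X, labels=meta["labels"], round_index=int(meta["round_index"]))

    def __iter__(self):
        for entry in self.manifest["chunks"]:
            yield self._load_chunk(entry)

    @property
    def n_chunks(self) -> int:
        return len(self.manifest["chunks"])

    def test_chunk(self) -> FeatureChunk:
        if "test" not in self.manifest:
            raise FileNotFoundError("stream has no test chunk")
        return self._load_chunk(self.manifest["test"])


def save_checkpoint(directory, state: ModelState, hyper: Hyperparams, memory: MemoryBank, codebook) -> Path:
    """Model checkpoint: W, G, C1, C2, C3 as delimited matrices + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, M in (
        ("W", state.W), ("G", state.G),
        ("C1", state.stats.C1), ("C2", state.stats.C2), ("C3", state.stats.C3),
    ):
        np.savetxt(directory / f"{name}.csv", M, delimiter=",")
    if memory.n_individuals > 0:
        np.savetxt(directory / "memory_means.csv", memory.means, delimiter=",")
    meta = {
        "format_version": FORMAT_VERSION,
        "round": state.round,
        "rounds_absorbed": state.stats.rounds_absorbed,
        "d": state.d,
        "r": state.r,
        "hyperparams": dataclasses.asdict(hyper),
        "codebook": {"k": codebook.k, "assignment": {str(k): v for k, v in codebook.assignment.items()}},
        "memory": {"ids": [str(i) for i in memory.ids], "counts": list(memory.counts)},
        "seed": hyper.seed,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return directory


def load_checkpoint(directory):
    """Returns (state, hyper, memory, codebook)."""
    from .codes import build_hadamard

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    mats = {
        name: np.loadtxt(directory / f"{name}.csv", delimiter=",", ndmin=2)
        for name in ("W", "G", "C1", "C2", "C3")
    }
    stats = SufficientStats(
        C1=mats["C1"], C2=mats["C2"], C3=mats["C3"], rounds_absorbed=int(meta["rounds_absorbed"])
    )
    state = ModelState(
        W=mats["W"], G=mats["G"], stats=stats,
        round=int(meta["round"]), d=int(meta["d"]), r=int(meta["r"]),
    )
    hyper = Hyperparams(**meta["hyperparams"])
    mem_meta = meta["memory"]
    means_path = directory / "memory_means.csv"
    memory = MemoryBank(
        ids=list(mem_meta["ids"]),
        counts=[int(c) for c in mem_meta["counts"]],
        means=np.loadtxt(means_path, delimiter=",", ndmin=2) if means_path.exists() else None,
    )
    codebook = build_hadamard(int(meta["codebook"]["k"]))
    codebook.assignment.update(
        {k: int(v) for k, v in meta["codebook"]["assignment"].items()}
    )
    return state, hyper, memory, codebook
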