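"""Transitively closed topologies over a small set of perturbed signalling genes.

A nested effects model (NEM) represents a signalling pathway as a directed
graph on K perturbed genes (S-genes).  Perturbing an S-gene silences it and
every gene downstream of it, so only the reflexive-transitive closure of the
graph is identifiable from data: two graphs with the same closure predict
identical downstream effect patterns and are score equivalent.  This module
therefore works with closed adjacency matrices ``phi`` where ``phi[i, j]``
is true iff ``S_i`` is upstream of (or equal to) ``S_j`` — exactly the set
of preorders on K labelled elements.

The topology space is tiny for focused analyses (1, 4, 29, 355 and 6942
preorders for K = 1..5) and is enumerated exhaustively.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Topology",
    "ENUMERATION_MAX_K",
    "transitive_closure",
    "canonical_key",
    "enumerate_closed",
    "predicted_effects",
    "read_topology_tsv",
    "write_topology_tsv",
]

#: Hard cap on exhaustive enumeration: 2^(K(K-1)) closures must stay cheap.
ENUMERATION_MAX_K = 5


@dataclass(frozen=True)
class Topology:
    """A directed graph on labelled S-genes, optionally transitively closed.

    Parameters
    ----------
    labels
        Ordered, unique S-gene identifiers.
    adjacency
        K x K boolean matrix; entry ``(i, j)`` true iff ``S_i`` is upstream
        of (or equal to) ``S_j``.
    closed
        True iff ``adjacency`` equals its own reflexive-transitive closure.
        Validated at construction when set.
    """

    labels: tuple[str, ...]
    adjacency: np.ndarray = field(repr=False)
    closed: bool = False

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {adj.shape}")
        k = adj.shape[0]
        if k < 1:
            raise ValueError("a topology needs at least one S-gene")
        if len(self.labels) != k:
            raise ValueError(
                f"{len(self.labels)} labels do not match adjacency size {k}"
            )
        if len(set(self.labels)) != k:
            raise ValueError("S-gene labels must be unique")
        adj = adj.copy()
        adj.setflags(write=False)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "labels", tuple(self.labels))
        if self.closed and not _is_closed(adj):
            raise ValueError("closed=True but adjacency is not reflexively transitive")

    @property
    def n_sgenes(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown S-gene label {label!r}") from None

    @classmethod
    def from_edges(
        cls,
        labels: Sequence[str],
        edges: Iterable[tuple[str, str]],
        *,
        close: bool = False,
    ) -> "Topology":
        """Build a topology from a directed edge list over ``labels``."""
        labels = tuple(labels)
        idx = {lab: i for i, lab in enumerate(labels)}
        adj = np.zeros((len(labels), len(labels)), dtype=bool)
        for a, b in edges:
            if a not in idx or b not in idx:
                raise KeyError(f"edge ({a!r}, {b!r}) references an unknown label")
            adj[idx[a], idx[b]] = True
        t = cls(labels, adj)
        return transitive_closure(t) if close else t

    def edges(self, *, include_self_loops: bool = False) -> list[tuple[str, str]]:
        """Directed edges as label pairs, self-loops omitted by default."""
        out = []
        for i, j in zip(*np.nonzero(self.adjacency)):
            if i == j and not include_self_loops:
                continue
            out.append((self.labels[i], self.labels[j]))
        return out


def _is_closed(adj: np.ndarray) -> bool:
    if not adj.diagonal().all():
        return False
    reach = (adj.astype(np.uint8) @ adj.astype(np.uint8)) > 0  # 2-step reachability
    return bool((~reach | adj).all())


def _close_matrix(adj: np.ndarray) -> np.ndarray:
    """Reflexive-transitive closure of a boolean matrix (Warshall)."""
    closed = adj.copy()
    np.fill_diagonal(closed, True)
    for k in range(closed.shape[0]):
        closed |= np.outer(closed[:, k], closed[k, :])
    return closed


def transitive_closure(t: Topology) -> Topology:
    """Return the reflexive-transitive closure of ``t`` (input untouched).

    Idempotent: applying it to an already closed topology returns an equal
    topology.
    """
    return Topology(t.labels, _close_matrix(np.asarray(t.adjacency)), closed=True)


def canonical_key(t: Topology) -> bytes:
    """Opaque key identifying the score-equivalence class of ``t``.

    Two topologies over the same ordered label set receive equal keys iff
    their reflexive-transitive closures are identical matrices, i.e. iff
    they are indistinguishable from perturbation data.
    """
    closed = t if t.closed else transitive_closure(t)
    k = closed.n_sgenes
    return bytes([k]) + np.packbits(closed.adjacency.ravel()).tobytes()


def _default_labels(k: int) -> tuple[str, ...]:
    return tuple(f"S{i + 1}" for i in range(k))


@functools.lru_cache(maxsize=16)
def _enumerate_closed_cached(k: int, labels: tuple[str, ...]) -> tuple[Topology, ...]:
    n_off = k * (k - 1)
    # All 2^(K(K-1)) off-diagonal edge sets as a batch of adjacency matrices.
    n = 1 << n_off
    bits = (
        (np.arange(n, dtype=np.uint32)[:, None] >> np.arange(n_off, dtype=np.uint32))
        & 1
    ).astype(bool)
    mats = np.zeros((n, k, k), dtype=bool)
    off = ~np.eye(k, dtype=bool)
    mats[:, off] = bits
    mats |= np.eye(k, dtype=bool)
    # Batched Warshall closure over all matrices at once.
    for j in range(k):
        mats |= mats[:, :, j, None] & mats[:, None, j, :]
    flat = mats.reshape(n, k * k)
    weights = (1 << np.arange(k * k, dtype=np.uint64))[::-1]
    codes = flat.astype(np.uint64) @ weights
    _, first = np.unique(codes, return_index=True)
    topologies = [
        Topology(labels, mats[i], closed=True) for i in sorted(first.tolist())
    ]
    topologies.sort(key=canonical_key)
    return tuple(topologies)


def enumerate_closed(k: int, labels: Sequence[str] | None = None) -> list[Topology]:
    """Enumerate every transitively closed topology on ``k`` labelled nodes.

    Brute force: close and deduplicate all ``2^(k(k-1))`` digraphs, so the
    result is each preorder exactly once, in deterministic canonical-key
    order.  Capped at ``k <= ENUMERATION_MAX_K``.
    """
    if not 1 <= k <= ENUMERATION_MAX_K:
        raise ValueError(
            f"exhaustive enumeration supports 1 <= K <= {ENUMERATION_MAX_K}, got {k}"
        )
    labels = _default_labels(k) if labels is None else tuple(labels)
    if len(labels) != k:
        raise ValueError(f"expected {k} labels, got {len(labels)}")
    if len(set(labels)) != k:
        raise ValueError("labels must be unique")
    return list(_enumerate_closed_cached(k, labels))


def predicted_effects(t: Topology, attachment_index: int) -> np.ndarray:
    """Expected effect pattern for an E-gene attached to S-gene ``k``.

    Entry ``j`` is true iff perturbing ``S_j`` affects an E-gene attached to
    ``S_k``, i.e. iff ``S_j`` is upstream of ``S_k`` in the closed topology.
    Entry ``k`` itself is always true (perturbing a gene affects its own
    attached E-genes).
    """
    if not t.closed:
        raise ValueError("predicted_effects requires a closed topology")
    k = t.n_sgenes
    if not 0 <= attachment_index < k:
        raise IndexError(
            f"attachment index {attachment_index} out of range for K={k}"
        )
    return np.asarray(t.adjacency)[:, attachment_index].copy()


def read_topology_tsv(path: str | Path, labels: Sequence[str]) -> Topology:
    """Read a directed edge list TSV (header ``from<TAB>to``) over ``labels``."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["from", "to"]:
        raise ValueError(f"{path}: expected header 'from\\tto'")
    edges = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two tab-separated fields")
        edges.append((parts[0], parts[1]))
    return Topology.from_edges(labels, edges)


def write_topology_tsv(t: Topology, edges_path: str | Path, matrix_path: str | Path | None = None) -> None:
    """Write ``t`` as an edge-list TSV, optionally plus its closed adjacency.

    The matrix file is a square TSV with row/column labels, written from the
    reflexive-transitive closure (self-loops implied in the edge list).
    """
    lines = ["from\tto"]
    lines += [f"{a}\t{b}" for a, b in t.edges()]
    Path(edges_path).write_text("\n".join(lines) + "\n")
    if matrix_path is not None:
        closed = t if t.closed else transitive_closure(t)
        rows = ["\t".join(("",) + closed.labels)]
        for i, lab in enumerate(closed.labels):
            rows.append(
                lab + "\t" + "\t".join(str(int(v)) for v in closed.adjacency[i])
            )
        Path(matrix_path).write_text("\n".join(rows) + "\n")
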