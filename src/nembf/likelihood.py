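"""Marginal likelihood of an effect-probability matrix under a topology.

The data are posterior probabilities ``p_lk`` that E-gene ``l`` is
differentially expressed under perturbation of S-gene ``k`` (the output of
a moderated differential-expression analysis such as limma's).  Given a
closed topology and the latent attachment of each E-gene to one S-gene,
each cell contributes ``p_lk`` where an effect is predicted and
``1 - p_lk`` where none is; the attachment is integrated out under a
uniform prior (optionally including an unattached "null" state), and the
per-gene marginals multiply across E-genes:

    P(D | Phi) = prod_l  sum_theta  P(theta) prod_k P(d_lk | Phi, theta)

All sums are done in log space with log-sum-exp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .topology import Topology, transitive_closure

__all__ = [
    "EffectMatrix",
    "AttachmentPrior",
    "clamp_probabilities",
    "egene_log_marginal",
    "topology_log_marginal",
    "score_topologies",
    "DEFAULT_CLAMP_EPS",
]

logger = logging.getLogger(__name__)

#: Default clamp half-width; direct siRNA targets come in with probability
#: effectively 1, which would make log(1 - p) diverge.
DEFAULT_CLAMP_EPS = 1e-6


@dataclass(frozen=True)
class EffectMatrix:
    """L x K matrix of differential-expression posterior probabilities."""

    gene_ids: tuple[str, ...]
    perturbations: tuple[str, ...]
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2:
            raise ValueError(f"probs must be 2-D, got shape {probs.shape}")
        l, k = probs.shape
        if l < 1 or k < 1:
            raise ValueError("effect matrix needs at least one gene and one perturbation")
        if len(self.gene_ids) != l:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {l} rows")
        if len(self.perturbations) != k:
            raise ValueError(f"{len(self.perturbations)} perturbation labels for {k} columns")
        if len(set(self.gene_ids)) != l:
            raise ValueError("gene ids must be unique")
        if len(set(self.perturbations)) != k:
            raise ValueError("perturbation labels must be unique")
        if np.isnan(probs).any() or (probs < 0).any() or (probs > 1).any():
            bad = np.argwhere(np.isnan(probs) | (probs < 0) | (probs > 1))[0]
            raise ValueError(
                f"probability out of [0,1] at gene {self.gene_ids[bad[0]]!r}, "
                f"perturbation {self.perturbations[bad[1]]!r}"
            )
        probs = probs.copy()
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "perturbations", tuple(self.perturbations))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_perturbations(self) -> int:
        return len(self.perturbations)

    def subset_genes(self, keep: np.ndarray) -> "EffectMatrix":
        """Row subset by boolean mask or integer index array."""
        keep = np.asarray(keep)
        ids = tuple(np.asarray(self.gene_ids, dtype=object)[keep])
        return EffectMatrix(ids, self.perturbations, np.asarray(self.probs)[keep])


@dataclass(frozen=True)
class AttachmentPrior:
    """Prior over the latent attachment of an E-gene to an S-gene.

    ``uniform`` puts mass 1/K on each S-gene; ``uniform_with_null`` gives
    mass ``null_weight`` to an unattached state (no effects predicted
    anywhere) and splits the rest equally over the K S-genes.
    """

    kind: str = "uniform"
    null_weight: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "uniform_with_null"):
            raise ValueError(f"unknown attachment prior kind {self.kind!r}")
        if self.kind == "uniform_with_null":
            w = self.null_weight
            if w is not None and not 0.0 < w < 1.0:
                raise ValueError("null_weight must lie in (0, 1)")

    @property
    def has_null(self) -> bool:
        return self.kind == "uniform_with_null"

    def weights(self, k: int) -> np.ndarray:
        """Prior mass over the K attachment states (+ null state last)."""
        if self.kind == "uniform":
            return np.full(k, 1.0 / k)
        w0 = self.null_weight if self.null_weight is not None else 1.0 / (k + 1)
        return np.concatenate([np.full(k, (1.0 - w0) / k), [w0]])


def clamp_probabilities(m: EffectMatrix, eps: float = DEFAULT_CLAMP_EPS) -> EffectMatrix:
    """Map all entries into ``[eps, 1 - eps]``; interior entries unchanged."""
    if not 0.0 < eps < 0.5:
        raise ValueError(f"clamp eps must lie in (0, 0.5), got {eps}")
    probs = np.asarray(m.probs)
    n_clamped = int(((probs < eps) | (probs > 1.0 - eps)).sum())
    if n_clamped:
        logger.info("clamped %d probability entries into [%g, %g]", n_clamped, eps, 1 - eps)
    return EffectMatrix(m.gene_ids, m.perturbations, np.clip(probs, eps, 1.0 - eps))


def _attachment_patterns(t: Topology, prior: AttachmentPrior) -> np.ndarray:
    """Predicted-effect pattern per attachment state, shape (n_states, K).

    Row ``k`` is the expected effect vector for attachment to ``S_k``
    (column ``k`` of the closed adjacency); the null state, if present,
    predicts no effects at all.
    """
    patterns = np.asarray(t.adjacency).T
    if prior.has_null:
        patterns = np.vstack([patterns, np.zeros(t.n_sgenes, dtype=bool)])
    return patterns


def _check_open_interval(p: np.ndarray) -> None:
    if (p <= 0.0).any() or (p >= 1.0).any():
        raise ValueError(
            "probabilities must lie strictly inside (0, 1); "
            "apply clamp_probabilities first"
        )


def egene_log_marginal(
    p_row: Sequence[float] | np.ndarray,
    t: Topology,
    prior: AttachmentPrior = AttachmentPrior(),
) -> float:
    """Log marginal likelihood of one E-gene row, attachment integrated out."""
    if not t.closed:
        raise ValueError("egene_log_marginal requires a closed topology")
    p = np.asarray(p_row, dtype=float)
    if p.shape != (t.n_sgenes,):
        raise ValueError(f"row has shape {p.shape}, expected ({t.n_sgenes},)")
    _check_open_interval(p)
    patterns = _attachment_patterns(t, prior)
    loglik = np.where(patterns, np.log(p), np.log1p(-p)).sum(axis=1)
    return float(logsumexp(loglik, b=prior.weights(t.n_sgenes)))


def _align_columns(m: EffectMatrix, t: Topology) -> np.ndarray:
    """Reorder matrix columns to topology label order; error on mismatch."""
    if set(m.perturbations) != set(t.labels):
        missing = set(t.labels) - set(m.perturbations)
        extra = set(m.perturbations) - set(t.labels)
        raise ValueError(
            "perturbation labels do not match topology labels"
            + (f"; missing from matrix: {sorted(missing)}" if missing else "")
            + (f"; not in topology: {sorted(extra)}" if extra else "")
        )
    order = [m.perturbations.index(lab) for lab in t.labels]
    return np.asarray(m.probs)[:, order]


def topology_log_marginal(
    m: EffectMatrix,
    t: Topology,
    prior: AttachmentPrior = AttachmentPrior(),
) -> float:
    """Log P(D | Phi): sum of per-E-gene log marginals over all rows.

    Columns are matched to topology nodes by label, never by position.
    An unclosed topology is scored through its reflexive-transitive
    closure, so score-equivalent graphs receive identical values by
    construction.
    """
    if not t.closed:
        t = transitive_closure(t)
    probs = _align_columns(m, t)
    _check_open_interval(probs)
    logp, log1mp = np.log(probs), np.log1p(-probs)
    patterns = _attachment_patterns(t, prior).astype(float)
    # (L, n_states): per-row log likelihood under each attachment state
    per_state = logp @ patterns.T + log1mp @ (1.0 - patterns.T)
    row_logs = logsumexp(per_state, axis=1, b=prior.weights(t.n_sgenes))
    return float(row_logs.sum())


def score_topologies(
    m: EffectMatrix,
    topologies: Sequence[Topology],
    prior: AttachmentPrior = AttachmentPrior(),
) -> np.ndarray:
    """Log marginal likelihood for many topologies sharing one label set.

    Equivalent to calling :func:`topology_log_marginal` per topology, but
    the per-row log likelihood of each distinct effect pattern (a column of
    some closed adjacency, at most 2^K of them) is computed once and
    reused, which makes scoring the full K=4 space on thousands of E-genes
    effectively instant.
    """
    if not topologies:
        raise ValueError("need at least one topology to score")
    labels = topologies[0].labels
    for t in topologies:
        if not t.closed:
            raise ValueError("score_topologies requires closed topologies")
        if t.labels != labels:
            raise ValueError("all topologies must share one ordered label set")
    probs = _align_columns(m, topologies[0])
    _check_open_interval(probs)
    logp, log1mp = np.log(probs), np.log1p(-probs)
    k = len(labels)

    pattern_cols: dict[bytes, int] = {}
    col_logliks: list[np.ndarray] = []

    def col_index(pattern: np.ndarray) -> int:
        key = pattern.tobytes()
        if key not in pattern_cols:
            pattern_cols[key] = len(col_logliks)
            col_logliks.append(
                np.where(pattern, logp, log1mp).sum(axis=1)
            )
        return pattern_cols[key]

    state_indices = []
    for t in topologies:
        adj = np.asarray(t.adjacency)
        idxs = [col_index(adj[:, j]) for j in range(k)]
        if prior.has_null:
            idxs.append(col_index(np.zeros(k, dtype=bool)))
        state_indices.append(idxs)

    table = np.column_stack(col_logliks)  # (L, n_distinct_patterns)
    weights = prior.weights(k)
    idx = np.asarray(state_indices)  # (T, n_states); same state count everywhere
    per_state = table[:, idx]  # (L, T, n_states)
    return logsumexp(per_state, axis=2, b=weights).sum(axis=0)
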