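"""Class Bayes factors for structural features of NEM topologies.

Instead of picking a single best topology, the topology space is split in
two by a structural feature ``f`` — e.g. "some edge connects S-gene group A
with group B" — giving a feature class ``C_f`` and its complement
``C_fbar``.  With a uniform prior over topologies within each class, the
Bayes factor of the two classes is

    B = (N_fbar / N_f) * sum_{Phi in C_f} P(D | Phi)
                       / sum_{Phi in C_fbar} P(D | Phi)

where ``N_f`` and ``N_fbar`` are the class sizes.  The size ratio
penalises the larger (more flexible) class, so a positive log B means the
data justify the extra complexity of admitting the feature.

Because only the transitive closure of a topology is identifiable, feature
predicates are evaluated on the closure's off-diagonal entries: an "edge"
from A to B means A is a strict upstream ancestor of B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp, softmax

from .likelihood import AttachmentPrior, EffectMatrix, score_topologies
from .topology import Topology, transitive_closure

__all__ = [
    "FeatureSpec",
    "TopologyClassPartition",
    "BayesFactorResult",
    "partition_topologies",
    "log_bayes_factor",
    "posterior_class_odds",
    "topology_posteriors",
    "STRONG_EVIDENCE_LOG_BF",
]

#: |log BF| above this (natural log) is conventionally strong evidence;
#: exp(10) exceeds odds of 1000:1.
STRONG_EVIDENCE_LOG_BF = 10.0


@dataclass(frozen=True)
class FeatureSpec:
    """Declarative structural feature splitting topology space in two.

    kinds
    -----
    ``cross_group_edge``
        True iff the closed topology has an edge between the disjoint
        S-gene groups ``group_a`` and ``group_b``; ``direction_mode``
        selects ``either`` (default), ``a_to_b`` or ``b_to_a``.
    ``edge_present`` / ``edge_absent``
        True iff the directed edge ``edge = (from, to)`` is present
        (resp. absent) in the closure.
    ``custom_predicate``
        ``predicate(topology)`` decides membership; the topology passed
        in is always closed.
    """

    kind: str
    group_a: frozenset[str] = frozenset()
    group_b: frozenset[str] = frozenset()
    edge: tuple[str, str] | None = None
    direction_mode: str = "either"
    predicate: Callable[[Topology], bool] | None = field(default=None, compare=False)
    name: str = ""

    def __post_init__(self) -> None:
        kinds = ("cross_group_edge", "edge_present", "edge_absent", "custom_predicate")
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {kinds}")
        object.__setattr__(self, "group_a", frozenset(self.group_a))
        object.__setattr__(self, "group_b", frozenset(self.group_b))
        if self.kind == "cross_group_edge":
            if not self.group_a or not self.group_b:
                raise ValueError("cross_group_edge needs two non-empty groups")
            if self.group_a & self.group_b:
                raise ValueError("feature groups must be disjoint")
            if self.direction_mode not in ("either", "a_to_b", "b_to_a"):
                raise ValueError(f"unknown direction_mode {self.direction_mode!r}")
        elif self.kind in ("edge_present", "edge_absent"):
            if self.edge is None or len(self.edge) != 2:
                raise ValueError(f"{self.kind} needs edge=(from, to)")
            if self.edge[0] == self.edge[1]:
                raise ValueError("edge endpoints must be distinct")
            object.__setattr__(self, "edge", (str(self.edge[0]), str(self.edge[1])))
        elif self.predicate is None:
            raise ValueError("custom_predicate needs a predicate callable")

    def required_labels(self) -> frozenset[str]:
        if self.kind == "cross_group_edge":
            return self.group_a | self.group_b
        if self.kind in ("edge_present", "edge_absent"):
            return frozenset(self.edge)
        return frozenset()

    def matches(self, t: Topology) -> bool:
        """Evaluate the predicate on the closure's off-diagonal entries."""
        closed = t if t.closed else transitive_closure(t)
        missing = self.required_labels() - set(closed.labels)
        if missing:
            raise KeyError(f"feature references unknown S-gene labels {sorted(missing)}")
        adj = np.asarray(closed.adjacency)
        if self.kind == "custom_predicate":
            return bool(self.predicate(closed))
        if self.kind in ("edge_present", "edge_absent"):
            i, j = (closed.index_of(lab) for lab in self.edge)
            present = bool(adj[i, j])
            return present if self.kind == "edge_present" else not present
        ia = [closed.index_of(lab) for lab in sorted(self.group_a)]
        ib = [closed.index_of(lab) for lab in sorted(self.group_b)]
        a_to_b = bool(adj[np.ix_(ia, ib)].any())
        b_to_a = bool(adj[np.ix_(ib, ia)].any())
        if self.direction_mode == "a_to_b":
            return a_to_b
        if self.direction_mode == "b_to_a":
            return b_to_a
        return a_to_b or b_to_a

    def describe(self) -> str:
        if self.name:
            return self.name
        if self.kind == "cross_group_edge":
            return (
                f"edge ({self.direction_mode}) between "
                f"{{{', '.join(sorted(self.group_a))}}} and "
                f"{{{', '.join(sorted(self.group_b))}}}"
            )
        if self.kind in ("edge_present", "edge_absent"):
            verb = "present" if self.kind == "edge_present" else "absent"
            return f"edge {self.edge[0]} -> {self.edge[1]} {verb}"
        return "custom predicate"


@dataclass(frozen=True)
class TopologyClassPartition:
    """Complete topology enumeration split into C_f and its complement."""

    feature: FeatureSpec
    in_class: tuple[Topology, ...]
    out_class: tuple[Topology, ...]

    @property
    def n_f(self) -> int:
        return len(self.in_class)

    @property
    def n_fbar(self) -> int:
        return len(self.out_class)

    @property
    def log_penalty(self) -> float:
        """log(N_fbar / N_f), the class-size complexity penalty on C_f."""
        return math.log(self.n_fbar / self.n_f)


@dataclass(frozen=True)
class BayesFactorResult:
    """Log Bayes factor for C_f vs C_fbar with its full decomposition."""

    log_bf: float
    log_sum_f: float
    log_sum_fbar: float
    log_penalty: float
    n_f: int
    n_fbar: int
    n_genes: int

    @property
    def log10_bf(self) -> float:
        return self.log_bf / math.log(10.0)

    def verdict(self) -> str:
        side = "feature class" if self.log_bf > 0 else "complement class"
        strength = (
            "strong" if abs(self.log_bf) > STRONG_EVIDENCE_LOG_BF
            else "weak" if self.log_bf != 0.0 else "no"
        )
        return f"{strength} evidence favours the {side}" if self.log_bf != 0.0 else "no evidence either way"

    def to_dict(self) -> dict:
        return {
            "log_bf": self.log_bf,
            "log10_bf": self.log10_bf,
            "log_sum_f": self.log_sum_f,
            "log_sum_fbar": self.log_sum_fbar,
            "log_penalty": self.log_penalty,
            "n_f": self.n_f,
            "n_fbar": self.n_fbar,
            "n_genes": self.n_genes,
            "verdict": self.verdict(),
        }


def partition_topologies(
    topologies: Sequence[Topology], feature: FeatureSpec
) -> TopologyClassPartition:
    """Assign each enumerated topology to C_f or C_fbar by the feature.

    Both classes must come out non-empty, otherwise the Bayes factor is
    undefined.
    """
    in_class, out_class = [], []
    for t in topologies:
        (in_class if feature.matches(t) else out_class).append(t)
    if not in_class or not out_class:
        empty = "C_f" if not in_class else "C_fbar"
        raise ValueError(
            f"feature '{feature.describe()}' leaves {empty} empty; "
            "the class Bayes factor is undefined"
        )
    return TopologyClassPartition(feature, tuple(in_class), tuple(out_class))


def log_bayes_factor(
    m: EffectMatrix,
    part: TopologyClassPartition,
    prior: AttachmentPrior = AttachmentPrior(),
) -> BayesFactorResult:
    """Class Bayes factor of C_f vs C_fbar on an effect matrix.

    Class sums are log-sum-exp over the per-topology log marginal
    likelihoods; positive ``log_bf`` favours the feature class.
    """
    scores_f = score_topologies(m, part.in_class, prior)
    scores_fbar = score_topologies(m, part.out_class, prior)
    for scores, cls, topos in (
        (scores_f, "C_f", part.in_class),
        (scores_fbar, "C_fbar", part.out_class),
    ):
        if not np.isfinite(scores).all():
            bad = int(np.flatnonzero(~np.isfinite(scores))[0])
            raise FloatingPointError(
                f"non-finite marginal likelihood in {cls} "
                f"(topology edges {topos[bad].edges()})"
            )
    log_sum_f = float(logsumexp(scores_f))
    log_sum_fbar = float(logsumexp(scores_fbar))
    log_penalty = part.log_penalty
    return BayesFactorResult(
        log_bf=log_penalty + log_sum_f - log_sum_fbar,
        log_sum_f=log_sum_f,
        log_sum_fbar=log_sum_fbar,
        log_penalty=log_penalty,
        n_f=part.n_f,
        n_fbar=part.n_fbar,
        n_genes=m.n_genes,
    )


def posterior_class_odds(r: BayesFactorResult, prior_odds: float = 1.0) -> float:
    """Posterior odds of C_f vs C_fbar given prior odds (must be > 0)."""
    if prior_odds <= 0:
        raise ValueError(f"prior odds must be positive, got {prior_odds}")
    return math.exp(r.log_bf) * prior_odds


def topology_posteriors(
    m: EffectMatrix,
    topologies: Sequence[Topology],
    prior: AttachmentPrior = AttachmentPrior(),
) -> np.ndarray:
    """Posterior over the supplied topologies under a uniform topology prior."""
    if not topologies:
        raise ValueError("need at least one topology")
    return softmax(score_topologies(m, topologies, prior))
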