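"""Synthetic effect-probability matrices from a known ground-truth NEM.

Runs the NEM data model generatively: each E-gene either attaches to one
S-gene (its entries then follow a Beta distribution concentrated near 1
where the topology predicts an effect, near 0 where it does not) or is a
pure-noise gene with uniform entries.  The defaults mimic a focused
perturbation screen: K = 4 silenced pathway components, bimodal
probabilities, and a modest fraction of unattached genes.

The default case-study template reproduces the geometry of a Wnt
signalling screen in HCT116 colon cancer cells: perturbations of the
secretion machinery (EVI/WLS, APC) versus the downstream transcriptional
module (CTNNB1/beta-catenin, TCF7L2), with the structural feature "some
edge connects the two groups" (i.e. target activation depends on ligand
secretion) splitting the 355 four-node topologies into 339 vs 16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .likelihood import AttachmentPrior, EffectMatrix
from .model_compare import FeatureSpec, partition_topologies
from .topology import ENUMERATION_MAX_K, Topology, enumerate_closed, predicted_effects

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "NULL_ATTACHMENT",
    "sample_topology",
    "simulate_effect_matrix",
    "case_study_labels",
    "case_study_feature",
]

#: Attachment marker for genes not attached to any S-gene.
NULL_ATTACHMENT = "null"

#: Pinned generator; recorded in dataset metadata for reproducibility.
RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


def case_study_labels() -> tuple[str, ...]:
    """S-gene labels of the K=4 Wnt case-study template."""
    return ("EVI_WLS", "APC", "CTNNB1", "TCF7L2")


def case_study_feature(direction_mode: str = "either") -> FeatureSpec:
    """Feature 'secretion machinery connected to the transcriptional module'."""
    return FeatureSpec(
        kind="cross_group_edge",
        group_a=frozenset({"EVI_WLS", "APC"}),
        group_b=frozenset({"CTNNB1", "TCF7L2"}),
        direction_mode=direction_mode,
        name="Wnt secretion dependence",
    )


@dataclass(frozen=True)
class NoiseModel:
    """Beta-family noise for generated effect probabilities.

    ``Beta(a_effect, b_effect)`` draws entries where the truth predicts an
    effect (default mean 0.8), ``Beta(a_null, b_null)`` where it does not
    (default mean 0.2); a fraction of genes is unattached noise with
    uniform entries.  Defaults give the bimodal, informative pattern seen
    in real screens; they are configuration, not law.
    """

    a_effect: float = 8.0
    b_effect: float = 2.0
    a_null: float = 2.0
    b_null: float = 8.0
    frac_noise_genes: float = 0.1

    def __post_init__(self) -> None:
        for name in ("a_effect", "b_effect", "a_null", "b_null"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Beta shape {name} must be positive")
        if not 0.0 <= self.frac_noise_genes < 1.0:
            raise ValueError("frac_noise_genes must lie in [0, 1)")
        mean_eff = self.a_effect / (self.a_effect + self.b_effect)
        mean_null = self.a_null / (self.a_null + self.b_null)
        if not mean_eff > 0.5 > mean_null:
            raise ValueError(
                "noise model is uninformative: need mean effect probability "
                f"> 0.5 > mean null probability, got {mean_eff:.3f} and {mean_null:.3f}"
            )

    def to_dict(self) -> dict:
        return {
            "a_effect": self.a_effect,
            "b_effect": self.b_effect,
            "a_null": self.a_null,
            "b_null": self.b_null,
            "frac_noise_genes": self.frac_noise_genes,
        }


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated effect matrix plus the ground truth that produced it."""

    truth: Topology
    attachments: tuple[str, ...] = field(repr=False)
    matrix: EffectMatrix = field(repr=False)
    noise: NoiseModel
    seed: int
    rng_algorithm: str = RNG_ALGORITHM

    def __post_init__(self) -> None:
        if len(self.attachments) != self.matrix.n_genes:
            raise ValueError("one attachment record per generated gene required")
        valid = set(self.truth.labels) | {NULL_ATTACHMENT}
        bad = set(self.attachments) - valid
        if bad:
            raise ValueError(f"attachments reference unknown S-genes: {sorted(bad)}")


def sample_topology(
    k: int,
    constraint: FeatureSpec | None = None,
    require_in_class: bool = True,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> Topology:
    """Uniform draw from the enumerated closed topologies on ``k`` nodes.

    With a ``constraint`` feature the draw is restricted to the feature
    class C_f (``require_in_class=True``) or its complement.
    """
    if k > ENUMERATION_MAX_K:
        raise ValueError(f"K={k} exceeds the enumeration cap {ENUMERATION_MAX_K}")
    pool = enumerate_closed(k, labels)
    if constraint is not None:
        part = partition_topologies(pool, constraint)
        pool = list(part.in_class if require_in_class else part.out_class)
    rng = np.random.default_rng(seed)
    return pool[int(rng.integers(len(pool)))]


def simulate_effect_matrix(
    truth: Topology,
    n_genes: int,
    noise: NoiseModel = NoiseModel(),
    prior: AttachmentPrior = AttachmentPrior(),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate an effect-probability matrix from a closed ground truth.

    Per gene: with probability ``frac_noise_genes`` it is unattached noise
    (all entries uniform on [0, 1]); otherwise an attachment is drawn from
    the prior and each entry follows the effect Beta where the truth
    predicts an effect, the null Beta otherwise.  Fully reproducible from
    ``seed``.
    """
    if not truth.closed:
        raise ValueError("simulation requires a closed ground-truth topology")
    if n_genes < 1:
        raise ValueError("need at least one gene")
    k = truth.n_sgenes
    rng = np.random.default_rng(seed)
    weights = prior.weights(k)  # last entry is the null state when present

    probs = np.empty((n_genes, k))
    attachments: list[str] = []
    pad = max(4, len(str(n_genes)))
    for l in range(n_genes):
        if rng.random() < noise.frac_noise_genes:
            attachments.append(NULL_ATTACHMENT)
            probs[l] = rng.uniform(size=k)
            continue
        state = int(rng.choice(len(weights), p=weights))
        if prior.has_null and state == k:
            attachments.append(NULL_ATTACHMENT)
            pattern = np.zeros(k, dtype=bool)
        else:
            attachments.append(truth.labels[state])
            pattern = predicted_effects(truth, state)
        eff = rng.beta(noise.a_effect, noise.b_effect, size=k)
        nul = rng.beta(noise.a_null, noise.b_null, size=k)
        probs[l] = np.where(pattern, eff, nul)

    matrix = EffectMatrix(
        tuple(f"E{l + 1:0{pad}d}" for l in range(n_genes)),
        truth.labels,
        probs,
    )
    return SyntheticDataset(
        truth=truth,
        attachments=tuple(attachments),
        matrix=matrix,
        noise=noise,
        seed=seed,
    )
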