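"""Stability of the class Bayes factor under the E-gene inclusion cutoff.

Which genes count as downstream targets is usually unknown, so the gene
list itself is a nuisance parameter.  Each gene is scored by its maximum
effect probability across the perturbations; for a cutoff ``lambda`` the
analysis includes every gene scoring strictly above ``lambda`` and
recomputes the class Bayes factor on that subset.  Tracing log BF against
the number of included genes shows whether the conclusion depends on the
unknowable true number of targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .likelihood import AttachmentPrior, EffectMatrix
from .model_compare import FeatureSpec, log_bayes_factor, partition_topologies
from .topology import enumerate_closed

__all__ = [
    "CurvePoint",
    "StabilityCurve",
    "gene_scores",
    "sweep_cutoffs",
    "max_supporting_count",
    "write_curve_tsv",
    "plot_curve",
]

logger = logging.getLogger(__name__)

LOG10 = float(np.log(10.0))


@dataclass(frozen=True)
class CurvePoint:
    cutoff: float
    n_genes: int
    log_bf: float


@dataclass(frozen=True)
class StabilityCurve:
    """Bayes-factor trace over inclusion cutoffs, most stringent first.

    Points are ordered by decreasing cutoff, hence non-decreasing number
    of included genes.
    """

    points: tuple[CurvePoint, ...]
    feature: FeatureSpec

    @property
    def max_supporting_n(self) -> int | None:
        return max_supporting_count(self)


def gene_scores(m: EffectMatrix) -> np.ndarray:
    """Per-gene score: the maximum effect probability over perturbations."""
    return np.asarray(m.probs).max(axis=1)


def sweep_cutoffs(
    m: EffectMatrix,
    feature: FeatureSpec,
    cutoffs: Sequence[float] | str = "auto",
    prior: AttachmentPrior = AttachmentPrior(),
) -> StabilityCurve:
    """Recompute the class Bayes factor over a grid of inclusion cutoffs.

    A gene is included at cutoff ``c`` iff its score is strictly greater
    than ``c``.  ``cutoffs="auto"`` uses the distinct gene scores in
    descending order (each the largest cutoff producing its subset),
    followed by 0.0 so the least stringent point contains every gene —
    exact and data-adaptive, with no subset computed twice.  Cutoffs
    admitting no genes are skipped with a logged notice.
    """
    scores = gene_scores(m)
    if isinstance(cutoffs, str):
        if cutoffs != "auto":
            raise ValueError(f"unknown cutoff mode {cutoffs!r}")
        grid = sorted(set(np.unique(scores).tolist()) | {0.0}, reverse=True)
    else:
        grid = sorted({float(c) for c in cutoffs}, reverse=True)
        if not grid:
            raise ValueError("cutoff list is empty")

    labels = m.perturbations
    part = partition_topologies(enumerate_closed(len(labels), labels), feature)

    points: list[CurvePoint] = []
    seen_sizes: set[int] = set()
    for c in grid:
        keep = scores > c
        n = int(keep.sum())
        if n == 0:
            logger.info("cutoff %g admits no genes; skipped", c)
            continue
        if n in seen_sizes:
            # same strict-threshold subset as an earlier cutoff
            continue
        seen_sizes.add(n)
        result = log_bayes_factor(m.subset_genes(keep), part, prior)
        points.append(CurvePoint(cutoff=c, n_genes=n, log_bf=result.log_bf))
    if not points:
        raise ValueError("no cutoff admits any gene; nothing to analyse")
    return StabilityCurve(tuple(points), feature)


def max_supporting_count(curve: StabilityCurve) -> int | None:
    """Largest number of included genes still yielding log BF > 0."""
    supporting = [p.n_genes for p in curve.points if p.log_bf > 0]
    return max(supporting) if supporting else None


def write_curve_tsv(curve: StabilityCurve, path: str | Path) -> None:
    lines = ["cutoff\tn_genes\tlog_bf_natural\tlog_bf_log10"]
    for p in curve.points:
        lines.append(f"{p.cutoff:.10g}\t{p.n_genes}\t{p.log_bf:.10g}\t{p.log_bf / LOG10:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_curve(curve: StabilityCurve, path: str | Path) -> None:
    """Simple log-BF vs n-genes line plot (cosmetic companion to the TSV)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = [p.n_genes for p in curve.points]
    y = [p.log_bf for p in curve.points]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(n, y, marker="o")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("number of included E-genes")
    ax.set_ylabel("log Bayes factor (natural)")
    ax.set_title(curve.feature.describe())
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
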