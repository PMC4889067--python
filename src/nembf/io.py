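"""File formats: effect-matrix TSV, feature configs, results and manifests.

All tabular formats are tab-separated UTF-8 with "." as the decimal mark;
no dialect autodetection, so files round-trip bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .likelihood import (
    DEFAULT_CLAMP_EPS,
    AttachmentPrior,
    EffectMatrix,
    clamp_probabilities,
)
from .model_compare import BayesFactorResult, FeatureSpec
from .synthetic import SyntheticDataset

__all__ = [
    "read_effect_matrix",
    "write_effect_matrix",
    "feature_from_dict",
    "read_feature_config",
    "write_bayes_factor_json",
    "write_manifest",
    "write_synthetic_dataset",
    "RunConfig",
]

logger = logging.getLogger(__name__)


def read_effect_matrix(
    path: str | Path,
    clamp_eps: float | None = DEFAULT_CLAMP_EPS,
) -> EffectMatrix:
    """Read an effect-probability TSV (first column ``gene_id``).

    Remaining column headers are S-gene labels and entries are decimal
    probabilities in [0, 1]; out-of-range or missing values are rejected
    with their coordinates.  Entries are clamped into
    ``[clamp_eps, 1 - clamp_eps]`` unless ``clamp_eps`` is None.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "gene_id":
        raise ValueError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: no perturbation columns found")
    gene_ids = df["gene_id"].tolist()
    perturbations = tuple(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) | (values < 0) | (values > 1))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: entry {values[r, c]!r} out of [0,1] at gene "
            f"{gene_ids[r]!r}, column {perturbations[c]!r}"
        )
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Series(gene_ids)[pd.Series(gene_ids).duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    m = EffectMatrix(tuple(gene_ids), perturbations, values)
    return clamp_probabilities(m, clamp_eps) if clamp_eps is not None else m


def write_effect_matrix(m: EffectMatrix, path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(m.probs), columns=list(m.perturbations))
    df.insert(0, "gene_id", list(m.gene_ids))
    # shortest round-trip decimal representation keeps the file bit-exact
    df.to_csv(path, sep="\t", index=False, float_format=lambda x: repr(float(x)))


def feature_from_dict(spec: dict) -> FeatureSpec:
    """Build a FeatureSpec from a parsed YAML/JSON config block."""
    if "kind" not in spec:
        raise ValueError("feature config needs a 'kind' field")
    kind = spec["kind"]
    kwargs: dict = {"kind": kind, "name": spec.get("name", "")}
    if kind == "cross_group_edge":
        kwargs["group_a"] = frozenset(spec["group_a"])
        kwargs["group_b"] = frozenset(spec["group_b"])
        kwargs["direction_mode"] = spec.get("direction_mode", "either")
    elif kind in ("edge_present", "edge_absent"):
        kwargs["edge"] = tuple(spec["edge"])
    else:
        raise ValueError(f"feature kind {kind!r} cannot be loaded from config")
    return FeatureSpec(**kwargs)


def read_feature_config(path: str | Path) -> FeatureSpec:
    """Read a feature spec from a YAML (or JSON) config file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return feature_from_dict(doc.get("feature", doc))


def write_bayes_factor_json(r: BayesFactorResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(r.to_dict(), indent=2) + "\n")


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Run manifest: tool version, config hash, seed — enough to re-run."""
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "tool": "nembf",
        "version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def write_synthetic_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write matrix TSV, truth edge list, attachment table and metadata JSON."""
    from .topology import write_topology_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "effect_matrix.tsv",
        "truth_edges": out / "truth_topology.tsv",
        "truth_adjacency": out / "truth_adjacency.tsv",
        "attachments": out / "attachments.tsv",
        "metadata": out / "metadata.json",
    }
    write_effect_matrix(ds.matrix, paths["matrix"])
    write_topology_tsv(ds.truth, paths["truth_edges"], paths["truth_adjacency"])
    lines = ["gene_id\tattached_to"]
    lines += [f"{g}\t{a}" for g, a in zip(ds.matrix.gene_ids, ds.attachments)]
    paths["attachments"].write_text("\n".join(lines) + "\n")
    paths["metadata"].write_text(
        json.dumps(
            {
                "seed": ds.seed,
                "rng_algorithm": ds.rng_algorithm,
                "noise": ds.noise.to_dict(),
                "n_genes": ds.matrix.n_genes,
                "s_genes": list(ds.truth.labels),
            },
            indent=2,
        )
        + "\n"
    )
    return paths


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for an end-to-end Bayes-factor run."""

    matrix_path: Path
    feature: FeatureSpec
    prior: AttachmentPrior = AttachmentPrior()
    clamp_eps: float = DEFAULT_CLAMP_EPS
    cutoffs: list[float] | str = "auto"
    out_dir: Path = Path("nembf_out")
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix_path", Path(self.matrix_path))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if not self.matrix_path.exists():
            raise FileNotFoundError(f"effect matrix not found: {self.matrix_path}")
        if not 0.0 < self.clamp_eps < 0.5:
            raise ValueError("clamp_eps must lie in (0, 0.5)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        prior_cfg = doc.get("attachment_prior", {})
        prior = AttachmentPrior(
            kind=prior_cfg.get("kind", "uniform"),
            null_weight=prior_cfg.get("null_weight"),
        )
        return cls(
            matrix_path=doc["matrix_path"],
            feature=feature_from_dict(doc["feature"]),
            prior=prior,
            clamp_eps=doc.get("clamp_eps", DEFAULT_CLAMP_EPS),
            cutoffs=doc.get("cutoffs", "auto"),
            out_dir=doc.get("out_dir", "nembf_out"),
            seed=doc.get("seed"),
        )
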