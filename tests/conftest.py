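import numpy as np
import pytest

import nembf as nb


@pytest.fixture(scope="session")
def case_study_partition():
    """The K=4 Wnt case-study split: cross-group-edge class vs complement."""
    labels = nb.case_study_labels()
    topologies = nb.enumerate_closed(4, labels)
    return nb.partition_topologies(topologies, nb.case_study_feature())


@pytest.fixture(scope="session")
def k2_topologies():
    return nb.enumerate_closed(2, ("A", "B"))


def random_digraph(rng: np.random.Generator, labels, p_edge: float = 0.3) -> nb.Topology:
    k = len(labels)
    adj = rng.random((k, k)) < p_edge
    np.fill_diagonal(adj, False)
    return nb.Topology(tuple(labels), adj)


def uniform_matrix(labels, n_genes: int, value: float = 0.5) -> nb.EffectMatrix:
    return nb.EffectMatrix(
        tuple(f"g{i}" for i in range(n_genes)),
        tuple(labels),
        np.full((n_genes, len(labels)), value),
    )
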