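import numpy as np
import pytest

from gpinn.hierarchy import build_graph, masks, stratify
from gpinn.network import ModelConfig, build_model
from gpinn.synthetic import SyntheticSpec, make_cohort, make_hierarchy


@pytest.fixture
def chain_graph():
    """G1 -> T1 -> T2 -> T3 (root T3)."""
    return build_graph({"T1": {"G1"}}, {("T1", "T2"), ("T2", "T3")})


@pytest.fixture
def star_graph():
    """Four leaf terms, one gene each, all children of root R."""
    gene_sets = {f"T{i}": {f"G{i}"} for i in range(1, 5)}
    relations = {(f"T{i}", "R") for i in range(1, 5)}
    return build_graph(gene_sets, relations)


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(
        n_samples=400, n_genes=24,
        n_terms_per_layer=((8, 4, 2, 1, 1), (6, 3, 2, 1, 1)),
        n_causal=4, beta=2.5, cnv_rate=0.2, seed=5,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    onto, path = make_hierarchy(tiny_spec)
    matrix, labels, truth = make_cohort(tiny_spec, (onto, path))
    return onto, path, matrix, labels, truth


@pytest.fixture(scope="session")
def tiny_masks(tiny_cohort):
    onto, path, matrix, _, _ = tiny_cohort
    stacks = []
    for b in (onto, path):
        g = b.graph()
        stacks.append(masks(stratify(g, n_layers=5), g, gene_roster=matrix.gene_ids))
    return stacks[0], stacks[1]


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_cohort, tiny_masks):
    """One model trained on the tiny planted-signal cohort (shared, read-only)."""
    onto, path, matrix, labels, truth = tiny_cohort
    mo, mp = tiny_masks
    x = matrix.values.astype(float)
    y = labels.to_numpy()
    model = build_model(mo, mp, dict.fromkeys(matrix.gene_ids, 1),
                        ModelConfig(epochs=40, batch_size=100, seed=3))
    from gpinn.training import train_fold
    train_fold(model, x[:300], y[:300], x[300:], y[300:])
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(0)
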