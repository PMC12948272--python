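import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gpinn.explain import (
    _exact_phi,
    _sampled_phi,
    aggregate_folds,
    degree_normalize,
    explain_fold,
    rank_top_fraction,
    sankey_export,
    select_background,
    shap_layer,
)


def oracle_shapley(g, x, bg):
    """Independent brute force: average marginal contribution over all
    feature orderings, with absent features at background values."""
    d = len(x)
    phi = np.zeros(d)
    for perm in itertools.permutations(range(d)):
        cur = bg.copy()
        prev = g(cur).mean()
        for f in perm:
            cur = cur.copy()
            cur[:, f] = x[f]
            v = g(cur).mean()
            phi[f] += v - prev
            prev = v
    return phi / math.factorial(d)


class TestShapleyEstimators:
    def test_linear_subnetwork_recovers_coefficients(self):
        def g(h):
            return 2.0 * h[:, 0] + 3.0 * h[:, 1]

        phi = _exact_phi(g, np.array([1.0, 1.0]), np.zeros((1, 2)))
        assert phi == pytest.approx([2.0, 3.0], abs=1e-12)

    def test_symmetric_features_get_equal_values(self):
        def g(h):
            return np.tanh(h[:, 0] + h[:, 1]) + h[:, 2]

        phi = _exact_phi(g, np.array([0.7, 0.7, 0.1]), np.zeros((1, 3)))
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)

    def test_null_player_gets_zero(self):
        def g(h):
            return h[:, 0] ** 2  # feature 1 unused

        phi = _exact_phi(g, np.array([0.5, 0.9]),
                         np.array([[0.1, 0.3], [0.2, -0.2]]))
        assert phi[1] == 0.0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exact_matches_independent_enumeration(self, seed, rng):
        r = np.random.default_rng(seed)
        d = 5
        W1 = r.normal(size=d)
        W2 = r.normal(size=(d, d))

        def g(h):
            return h @ W1 + 0.5 * np.tanh((h @ W2) ** 2).sum(axis=1)

        x = r.normal(size=d)
        bg = r.normal(size=(4, d))
        assert _exact_phi(g, x, bg) == pytest.approx(oracle_shapley(g, x, bg), abs=1e-10)

    def test_sampled_estimator_converges_and_is_locally_accurate(self, rng):
        d = 6
        W = rng.normal(size=d)

        def g(h):
            return np.tanh(h @ W) + 0.3 * h[:, 0] * h[:, 1]

        x = rng.normal(size=d)
        bg = rng.normal(size=(5, d))
        exact = _exact_phi(g, x, bg)
        sampled = _sampled_phi(g, x, bg, n_perm=600, rng=np.random.default_rng(1))
        assert sampled == pytest.approx(exact, abs=0.02)
        gap = sampled.sum() - (g(x[None, :])[0] - g(bg).mean())
        assert abs(gap) < 1e-10  # telescoping makes the identity exact


class TestShapLayerOnModel:
    def test_local_accuracy_on_every_layer(self, tiny_trained_model, tiny_cohort):
        matrix = tiny_cohort[2]
        x = matrix.values[:6].astype(float)
        bg = matrix.values[100:106].astype(float)
        model = tiny_trained_model
        layers = [(None, 0)] + [(br, l) for br in model.BRANCHES
                                for l in range(1, model.n_layers + 1)]
        for br, l in layers:
            res = shap_layer(model, br, l, x, bg, n_perm=4, seed=0)
            assert res.local_accuracy_gap() < 1e-8

    def test_narrow_layers_use_exact_enumeration(self, tiny_trained_model, tiny_cohort):
        matrix = tiny_cohort[2]
        x = matrix.values[:2].astype(float)
        bg = matrix.values[50:54].astype(float)
        res = shap_layer(tiny_trained_model, "ontology", 2, x, bg, seed=0)
        assert res.method == "exact"
        wide = shap_layer(tiny_trained_model, None, 0, x, bg, n_perm=2, seed=0)
        assert wide.method == "permutation"

    def test_empty_background_rejected(self, tiny_trained_model, tiny_cohort):
        x = tiny_cohort[2].values[:2].astype(float)
        with pytest.raises(ValueError, match="background"):
            shap_layer(tiny_trained_model, "ontology", 1, x, np.empty((0, x.shape[1])))


class TestDegreeNormalize:
    def _table(self):
        return pd.DataFrame({
            "fold": [0, 0, 0], "branch": ["gene"] * 3, "layer": [0] * 3,
            "node": ["a", "b", "c"], "phi": [0.6, 0.0, 0.4],
        })

    def test_division_by_degree(self):
        out = degree_normalize(self._table(), {"a": 3, "b": 7, "c": 2})
        assert out["phi_adjusted"].tolist() == pytest.approx([0.2, 0.0, 0.2])

    def test_degree_zero_guard(self):
        with pytest.warns(UserWarning, match="degree-0"):
            out = degree_normalize(self._table(), {"a": 3, "b": 0, "c": 2})
        assert out.loc[out["node"] == "b", "phi_adjusted"].item() == 0.0

    def test_missing_degree_rejected(self):
        with pytest.raises(KeyError):
            degree_normalize(self._table(), {"a": 3})


class TestAggregateFolds:
    def test_arithmetic_mean(self):
        df = pd.DataFrame({
            "fold": [0, 1, 2], "branch": ["gene"] * 3, "layer": [0] * 3,
            "node": ["a"] * 3, "phi_adjusted": [0.1, 0.2, 0.3],
        })
        out = aggregate_folds(df)
        assert out["phi_combined"].item() == pytest.approx(0.2)
        assert out["full_coverage"].item()

    def test_single_fold_identity(self):
        df = pd.DataFrame({"fold": [0], "branch": ["gene"], "layer": [0],
                           "node": ["a"], "phi_adjusted": [0.42]})
        assert aggregate_folds(df)["phi_combined"].item() == 0.42

    def test_partial_coverage_flagged_and_mean_over_present(self):
        df = pd.DataFrame({
            "fold": [0, 1, 2, 0, 2], "branch": ["gene"] * 5, "layer": [0] * 5,
            "node": ["a", "a", "a", "b", "b"],
            "phi_adjusted": [0.1, 0.1, 0.1, 0.3, 0.5],
        })
        with pytest.warns(UserWarning, match="missing from some folds"):
            out = aggregate_folds(df).set_index("node")
        assert out.loc["b", "phi_combined"] == pytest.approx(0.4)
        assert not out.loc["b", "full_coverage"]
        assert out.loc["a", "full_coverage"]

    def test_property_matches_independent_recomputation(self, rng):
        nodes = [f"n{i}" for i in range(30)]
        rows = []
        for fold in range(5):
            for n in nodes:
                rows.append((fold, "gene", 0, n, rng.normal()))
        df = pd.DataFrame(rows, columns=["fold", "branch", "layer", "node", "phi_adjusted"])
        out = aggregate_folds(df).set_index("node")
        for n in nodes:
            manual = np.mean([r[4] for r in rows if r[3] == n])
            assert out.loc[n, "phi_combined"] == pytest.approx(manual, rel=1e-12)


class TestRanking:
    def _combined(self, scores):
        return pd.DataFrame({
            "branch": ["gene"] * len(scores), "layer": [0] * len(scores),
            "node": [f"g{i:02d}" for i in range(len(scores))],
            "phi_combined": scores,
        })

    def test_top_decile_of_20_is_2(self, rng):
        ranked = rank_top_fraction(self._combined(rng.normal(size=20)), fraction=0.10)
        assert len(ranked.ids) == 2

    def test_fraction_one_returns_all_sorted(self):
        ranked = rank_top_fraction(self._combined([0.1, -0.9, 0.5]), fraction=1.0)
        assert ranked.ids == ["g01", "g02", "g00"]  # by |phi|, sign kept in scores
        assert ranked.features[0][1] == -0.9

    def test_ties_break_lexicographically(self):
        ranked = rank_top_fraction(self._combined([0.5, 0.5, 0.5, 0.1]), fraction=0.5)
        assert ranked.ids == ["g00", "g01"]

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            rank_top_fraction(self._combined([0.1]), fraction=0.0)


class TestSankey:
    def _chain_combined(self):
        rows = [
            ("gene", 0, "G1", 0.8),
            ("ontology", 1, "T1", 0.6),
            ("ontology", 2, "T2", 0.4),
        ]
        return pd.DataFrame(rows, columns=["branch", "layer", "node", "phi_combined"])

    def test_chain_has_one_link_per_layer_pair(self):
        edges = [("G1", "T1", 1), ("T1", "T2", 2)]
        sk = sankey_export(self._chain_combined(), edges, display_top_n=5)
        assert len(sk["links"]) == 2
        weights = {(l["source"], l["target"]): l["value"] for l in sk["links"]}
        assert weights[("G1", "T1")] == pytest.approx(0.8)
        assert weights[("T1", "T2")] == pytest.approx(0.6)

    def test_residual_pooling(self):
        rows = [("ontology", 1, f"T{i}", s) for i, s in enumerate([0.9, 0.1, 0.2, 0.05])]
        rows.append(("ontology", 2, "R", 0.5))
        combined = pd.DataFrame(rows, columns=["branch", "layer", "node", "phi_combined"])
        edges = [(f"T{i}", "R", 2) for i in range(4)]
        sk = sankey_export(combined, edges, display_top_n=1)
        ids = {n["id"] for n in sk["nodes"]}
        assert "T0" in ids and "residual::ontology::L1" in ids
        residual = next(n for n in sk["nodes"] if n["id"].startswith("residual"))
        assert residual["score"] == pytest.approx(0.35)

    def test_zero_attributions_keep_structure(self):
        combined = self._chain_combined().assign(phi_combined=0.0)
        sk = sankey_export(combined, [("G1", "T1", 1), ("T1", "T2", 2)])
        assert all(l["value"] == 0.0 for l in sk["links"])
        assert len(sk["nodes"]) == 3


def test_fold_aggregation_stabilizes_rankings():
    """Averaging attributions over folds yields gene rankings that agree better
    across disjoint fold groups than single-fold rankings do on average."""
    from itertools import combinations

    from scipy.stats import spearmanr

    from gpinn.hierarchy import masks as build_masks
    from gpinn.hierarchy import stratify
    from gpinn.network import ModelConfig
    from gpinn.synthetic import SyntheticSpec, make_cohort, make_hierarchy
    from gpinn.training import cross_validate

    spec = SyntheticSpec(
        n_samples=800, n_genes=60,
        n_terms_per_layer=((12, 6, 3, 2, 1), (10, 5, 2, 1, 1)),
        n_causal=10, beta=2.0, cnv_rate=0.15, seed=9,
    )
    onto, path = make_hierarchy(spec)
    matrix, labels, _ = make_cohort(spec, (onto, path))
    stacks = []
    for b in (onto, path):
        g = b.graph()
        stacks.append(build_masks(stratify(g, 5), g, gene_roster=matrix.gene_ids))
    x = matrix.values.astype(float)
    y = labels.to_numpy()
    res = cross_validate(ModelConfig(epochs=80, batch_size=100, seed=2),
                         stacks[0], stacks[1], dict.fromkeys(matrix.gene_ids, 1),
                         x, y, k=4, seed=2)
    tables = []
    for r in res:
        bg = select_background(x[r.train_idx], y[r.train_idx], size=6, seed=r.fold)
        attr = explain_fold(r.model, x[np.asarray(r.test_idx)[:60]], bg,
                            fold=r.fold, n_perm=6, background_size=6, seed=r.fold)
        tables.append(attr[attr["branch"] == "gene"].set_index("node")["phi"])
    singles = [spearmanr(tables[i], tables[j]).statistic
               for i, j in combinations(range(4), 2)]
    aggregated = spearmanr((tables[0] + tables[1]) / 2,
                           (tables[2] + tables[3]) / 2).statistic
    assert aggregated > np.mean(singles)
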