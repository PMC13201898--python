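import numpy as np
import pandas as pd
import pytest

from novagene.data_model import AnalysisConfig, ExpressionMatrix
from novagene.module_comparison import (
    comparison_matrix,
    correlate_signatures,
    hub_signature,
    module_centrality,
    select_hubs,
)
from novagene.module_detection import cluster_modules, topological_overlap
from novagene.network_builder import (
    ConditionNetwork,
    PowerLawFit,
    SoftThresholdResult,
    TailComparison,
)
from novagene.synthetic_benchmark import generate_dataset, SyntheticConfig


def make_network(adjacency, gene_ids, label="cond"):
    """ConditionNetwork with placeholder fit metadata for unit tests."""
    return ConditionNetwork(
        condition_label=label,
        gene_ids=tuple(gene_ids),
        adjacency=np.asarray(adjacency, dtype=float),
        soft_threshold=SoftThresholdResult(1, 0.0, 0.0, pd.DataFrame(), False),
        powerlaw=PowerLawFit(2.0, 1.0, 0.0, 10),
        tail_comparison=TailComparison(),
        removed_genes=(),
    )


class TestModuleCentrality:
    def test_star_graph_closed_form(self):
        adj = np.zeros((5, 5))
        adj[0, 1:] = 1.0
        adj[1:, 0] = 1.0
        net = make_network(adj, [f"g{i}" for i in range(5)])
        cent = module_centrality(net, net.gene_ids)
        assert cent["g0"] == pytest.approx(1 / np.sqrt(2), abs=1e-6)
        for leaf in ("g1", "g2", "g3", "g4"):
            assert cent[leaf] == pytest.approx(1 / (2 * np.sqrt(2)), abs=1e-6)

    def test_complete_graph_uniform(self):
        adj = np.ones((4, 4))
        np.fill_diagonal(adj, 0.0)
        net = make_network(adj, list("abcd"))
        cent = module_centrality(net, net.gene_ids)
        assert np.allclose(list(cent.values()), 0.5)

    def test_single_gene_module(self):
        adj = np.zeros((3, 3))
        net = make_network(adj, list("abc"))
        assert module_centrality(net, ["b"]) == {"b": 1.0}

    def test_edgeless_module_uniform_with_warning(self):
        adj = np.zeros((3, 3))
        net = make_network(adj, list("abc"))
        with pytest.warns(UserWarning):
            cent = module_centrality(net, list("abc"))
        assert np.allclose(list(cent.values()), 1 / np.sqrt(3))

    def test_unit_norm(self, rng):
        a = np.abs(rng.normal(size=(8, 8)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        net = make_network(a, [f"g{i}" for i in range(8)])
        cent = module_centrality(net, net.gene_ids)
        assert np.linalg.norm(list(cent.values())) == pytest.approx(1.0)


class TestSelectHubs:
    def test_small_module_returns_all(self):
        cent = {f"g{i}": float(i) for i in range(7)}
        assert len(select_hubs(cent)) == 7

    def test_large_module_truncated_to_ten(self):
        cent = {f"g{i:02d}": float(i) for i in range(50)}
        hubs = select_hubs(cent)
        assert len(hubs) == 10
        assert hubs[0] == "g49"

    def test_ties_broken_by_gene_id(self):
        cent = {"zeta": 1.0, "alpha": 1.0, "mid": 1.0}
        assert select_hubs(cent, AnalysisConfig(n_hubs=2)) == ("alpha", "mid")


class TestHubSignature:
    def test_single_hub_is_standardized_profile(self, small_expr):
        sig = hub_signature(small_expr, ["g0"], small_expr.sample_ids)
        profile = small_expr.values[0]
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert sig.orientation_sign == 1
        assert sig.variance_explained == pytest.approx(1.0)
        assert np.allclose(
            sig.pca1_scores / np.linalg.norm(sig.pca1_scores),
            z / np.linalg.norm(z),
        )

    def test_duplicated_hub_gene_rank_one(self, rng):
        profile = rng.normal(size=6)
        values = np.vstack([profile, profile])
        expr = ExpressionMatrix(("h1", "h2"), tuple(f"s{j}" for j in range(6)), values)
        sig = hub_signature(expr, ["h1", "h2"], expr.sample_ids)
        assert sig.variance_explained == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.normal(size=(3, 6))
        expr = ExpressionMatrix(
            ("a", "b", "c"), tuple(f"s{j}" for j in range(6)), values
        )
        sig = hub_signature(expr, ["a", "b", "c"], expr.sample_ids)
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(
            axis=1, ddof=1, keepdims=True
        )
        cov = z @ z.T / (6 - 1)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, -1]
        oracle_scores = lead @ z
        cosine = np.dot(sig.pca1_scores, oracle_scores) / (
            np.linalg.norm(sig.pca1_scores) * np.linalg.norm(oracle_scores)
        )
        assert abs(cosine) == pytest.approx(1.0, abs=1e-9)
        assert sig.variance_explained == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-9
        )

    def test_orientation_deterministic_across_reruns(self, small_expr):
        a = hub_signature(small_expr, ["g0", "g1", "g2"], small_expr.sample_ids)
        b = hub_signature(small_expr, ["g0", "g1", "g2"], small_expr.sample_ids)
        assert np.array_equal(a.pca1_scores, b.pca1_scores)
        assert a.orientation_sign == b.orientation_sign

    def test_constant_hub_dropped(self):
        values = np.vstack([np.ones(6), np.arange(6.0)])
        expr = ExpressionMatrix(("flat", "ok"), tuple(f"s{j}" for j in range(6)), values)
        with pytest.warns(UserWarning):
            sig = hub_signature(expr, ["flat", "ok"], expr.sample_ids)
        assert sig.hub_genes == ("ok",)


class TestCorrelateSignatures:
    def _sig(self, scores, samples=None):
        from novagene.module_comparison import HubSignature

        scores = np.asarray(scores, dtype=float)
        if samples is None:
            samples = tuple(f"s{i}" for i in range(scores.size))
        return HubSignature("c", "m", ("g",), samples, scores, 1.0, 1)

    def test_self_correlation_is_plus_one(self):
        sig = self._sig([1.0, 2.0, 0.5, 3.0, -1.0])
        r, p = correlate_signatures(sig, sig)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_negation_gives_minus_one(self):
        sig = self._sig([1.0, 2.0, 0.5, 3.0, -1.0])
        neg = self._sig(-np.asarray([1.0, 2.0, 0.5, 3.0, -1.0]))
        r, p = correlate_signatures(sig, neg)
        assert r == pytest.approx(-1.0)
        assert p == 0.0

    def test_hand_computation_with_three_degrees_of_freedom(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        r, p = correlate_signatures(self._sig(a), self._sig(b))
        # explicit sums: r = S_ab / sqrt(S_aa * S_bb)
        da, db = a - a.mean(), b - b.mean()
        r_hand = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
        assert r == pytest.approx(r_hand)
        from scipy import stats

        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3))

    def test_symmetry(self, rng):
        a = self._sig(rng.normal(size=8))
        b = self._sig(rng.normal(size=8))
        assert correlate_signatures(a, b) == correlate_signatures(b, a)

    def test_mismatched_samples_rejected(self):
        a = self._sig(np.arange(5.0))
        b = self._sig(np.arange(5.0), samples=tuple(f"t{i}" for i in range(5)))
        with pytest.raises(ValueError):
            correlate_signatures(a, b)


class TestComparisonMatrix:
    @pytest.fixture(scope="class")
    def diseased_setup(self):
        from novagene.network_builder import build_condition_network

        ds = generate_dataset(SyntheticConfig(p=0.9, seed=1))
        net = build_condition_network(ds.expr, ds.design, "diseased")
        partition = cluster_modules(topological_overlap(net.adjacency, net.gene_ids))
        return ds, net, partition

    def test_self_comparison_diagonal_all_plus_one(self, diseased_setup):
        ds, net, partition = diseased_setup
        result = comparison_matrix(
            net, net, partition, partition, ds.expr, ds.design
        )
        for module in result.modules_a:
            assert result.pearson_r.loc[module, module] == pytest.approx(1.0)
            assert bool(result.significant.loc[module, module])

    def test_matrix_shape(self, diseased_setup):
        ds, net, partition = diseased_setup
        result = comparison_matrix(net, net, partition, partition, ds.expr, ds.design)
        n = len(partition.module_labels)
        assert result.pearson_r.shape == (n, n)

    def test_significance_consistent_with_alpha(self, diseased_setup):
        ds, net, partition = diseased_setup
        result = comparison_matrix(net, net, partition, partition, ds.expr, ds.design)
        assert (
            (result.p_value < 0.05) == result.significant
        ).all().all()
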