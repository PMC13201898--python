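import numpy as np
import pytest

from novagene.data_model import AnalysisConfig, ConditionDesign, ExpressionMatrix
from novagene.network_builder import (
    adjacency_from_correlation,
    build_condition_network,
    compare_tail_distributions,
    fit_power_law,
    node_strengths,
    pick_soft_threshold,
    prune_by_strength,
    scale_free_fit,
    _powerlaw_ks,
)
from novagene.synthetic_benchmark import SyntheticConfig, generate_dataset


def pareto_sample(rng, n, alpha=2.5, xmin=1.0):
    return xmin * (1.0 - rng.random(n)) ** (-1.0 / (alpha - 1.0))


def alpha_mle_at_true_xmin(x, xmin):
    """Closed-form Hill estimator: the independent oracle for the exponent."""
    tail = x[x >= xmin]
    return 1.0 + tail.size / np.log(tail / xmin).sum()


def chung_lu_adjacency(rng, n=500, alpha=2.5):
    """Weighted graph with approximately Pareto expected connectivities."""
    k = pareto_sample(rng, n, alpha=alpha)
    a = np.outer(k, k) / k.sum()
    a = np.minimum(a, 1.0)
    np.fill_diagonal(a, 0.0)
    return a


class TestScaleFreeFit:
    def test_pareto_connectivity_scores_high(self, rng):
        fit, _ = scale_free_fit(chung_lu_adjacency(rng))
        assert fit > 0.8

    def test_complete_graph_degenerate(self):
        adj = np.ones((20, 20))
        np.fill_diagonal(adj, 0.0)
        with pytest.warns(UserWarning):
            fit, mean_k = scale_free_fit(adj)
        assert fit == 0.0
        assert mean_k == pytest.approx(19.0)

    def test_fit_index_bounded_by_one(self, rng):
        for _ in range(5):
            adj = np.abs(rng.normal(size=(40, 40)))
            adj = np.minimum((adj + adj.T) / 2, 1.0)
            np.fill_diagonal(adj, 0.0)
            fit, _ = scale_free_fit(adj)
            assert fit <= 1.0


class TestPickSoftThreshold:
    def test_beta_one_is_identity_power(self, rng):
        corr = np.abs(np.corrcoef(rng.normal(size=(10, 30))))
        adj = adjacency_from_correlation(corr, 1)
        expected = np.abs(corr).copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(adj, expected)

    def test_mean_connectivity_monotone_in_beta(self, rng):
        corr = np.abs(np.corrcoef(rng.normal(size=(30, 25))))
        res = pick_soft_threshold(corr, AnalysisConfig())
        mk = res.table["mean_connectivity"].to_numpy()
        assert np.all(np.diff(mk) <= 1e-9)

    def test_selected_beta_in_grid_and_fallback_flagged(self, rng):
        corr = np.abs(np.corrcoef(rng.normal(size=(30, 25))))
        cfg = AnalysisConfig()
        res = pick_soft_threshold(corr, cfg)
        assert res.beta in cfg.beta_grid
        if not res.reached_target:
            assert res.beta == cfg.fallback_beta

    def test_synthetic_dcor_matrix_reaches_target(self):
        """High-variability diseased-condition networks admit a scale-free fit."""
        from novagene.dcor_engine import dcor_matrix

        ds = generate_dataset(SyntheticConfig(p=0.9, seed=1))
        samples = ds.design.samples_for("diseased")
        corr = dcor_matrix(ds.expr, samples)
        res = pick_soft_threshold(corr, AnalysisConfig())
        assert res.reached_target
        assert res.fit_index >= 0.9


class TestNodeStrengths:
    def test_unit_triangle(self):
        adj = np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        assert np.allclose(node_strengths(adj), [2.0, 2.0, 2.0])

    def test_edgeless(self):
        assert np.allclose(node_strengths(np.zeros((4, 4))), 0.0)


class TestFitPowerLaw:
    def test_recovers_pareto_exponent(self, rng):
        x = pareto_sample(rng, 2000)
        fit = fit_power_law(x)
        assert 2.35 <= fit.alpha <= 2.65
        assert fit.n_tail >= 10
        # closed-form oracle at the true cutoff agrees
        assert alpha_mle_at_true_xmin(x, 1.0) == pytest.approx(2.5, abs=0.15)

    def test_selected_ks_is_minimal(self, rng):
        x = pareto_sample(rng, 500)
        fit = fit_power_law(x)
        for xmin in np.quantile(x, [0.1, 0.5, 0.8]):
            xmin = x[x >= xmin].min()  # snap to an observed candidate
            tail = x[x >= xmin]
            if tail.size < 10:
                continue
            alpha = 1.0 + tail.size / np.log(tail / xmin).sum()
            assert fit.ks_statistic <= _powerlaw_ks(tail, xmin, alpha) + 1e-12

    def test_nonpositive_strengths_excluded_with_warning(self, rng):
        x = np.concatenate([pareto_sample(rng, 200), [0.0, -1.0]])
        with pytest.warns(UserWarning):
            fit = fit_power_law(x)
        assert fit.xmin > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law(np.arange(1.0, 9.0))

    def test_mean_alpha_error_small_over_replicates(self):
        errors = []
        for seed in range(20):
            r = np.random.default_rng(1000 + seed)
            fit = fit_power_law(pareto_sample(r, 2000))
            errors.append(abs(fit.alpha - 2.5))
        assert np.mean(errors) < 0.1


class TestTailComparison:
    def test_exponential_tail_rejects_power_law(self, rng):
        """Evaluated at the generating cutoff, where the tail is the full
        sample; the adaptive cutoff search would otherwise shrink the tail
        until the two families are indistinguishable."""
        from novagene.network_builder import PowerLawFit

        x = 1.0 + rng.exponential(scale=1.0, size=2000)
        alpha = 1.0 + x.size / np.log(x).sum()
        fit = PowerLawFit(alpha=alpha, xmin=1.0, ks_statistic=0.0, n_tail=x.size)
        r, p = compare_tail_distributions(x, fit).ratios["exponential"]
        assert r < 0
        assert p < 0.05

    def test_truncated_family_nests_pure_power_law(self, rng):
        from novagene.network_builder import _loglik_powerlaw, _loglik_truncated_powerlaw

        x = pareto_sample(rng, 800)
        fit = fit_power_law(x)
        tail = x[x >= fit.xmin]
        ll_pure = _loglik_powerlaw(tail, fit.xmin, fit.alpha).sum()
        ll_trunc = _loglik_truncated_powerlaw(tail, fit.xmin, fit.alpha).sum()
        assert ll_trunc >= ll_pure - 1e-6

    def test_pvalues_in_unit_interval(self, rng):
        x = pareto_sample(rng, 400)
        fit = fit_power_law(x)
        for r, p in compare_tail_distributions(x, fit).ratios.values():
            assert 0.0 <= p <= 1.0


class TestPruneByStrength:
    # 4-node weighted graph with strengths (0.4, 0.8, 1.6, 2.0)
    ADJ = np.array(
        [
            [0.0, 0.2, 0.1, 0.1],
            [0.2, 0.0, 0.1, 0.5],
            [0.1, 0.1, 0.0, 1.4],
            [0.1, 0.5, 1.4, 0.0],
        ]
    )

    def test_hand_counted_survivors(self):
        pruned, retained, removed = prune_by_strength(
            self.ADJ, ("a", "b", "c", "d"), xmin=1.0
        )
        assert retained == ("c", "d")
        assert removed == ("a", "b")
        assert pruned.shape == (2, 2)

    def test_low_xmin_keeps_everything(self):
        _, retained, removed = prune_by_strength(
            self.ADJ, ("a", "b", "c", "d"), xmin=0.0
        )
        assert retained == ("a", "b", "c", "d")
        assert removed == ()

    def test_partition_property(self):
        _, retained, removed = prune_by_strength(
            self.ADJ, ("a", "b", "c", "d"), xmin=1.0
        )
        assert set(retained) | set(removed) == {"a", "b", "c", "d"}
        assert set(retained) & set(removed) == set()

    def test_pruning_never_increases_strength(self):
        strengths = node_strengths(self.ADJ)
        pruned, retained, _ = prune_by_strength(
            self.ADJ, ("a", "b", "c", "d"), xmin=1.0
        )
        after = node_strengths(pruned)
        before = {g: s for g, s in zip(("a", "b", "c", "d"), strengths)}
        for g, s in zip(retained, after):
            assert s <= before[g] + 1e-12

    def test_error_when_fewer_than_two_survive(self):
        with pytest.raises(ValueError):
            prune_by_strength(self.ADJ, ("a", "b", "c", "d"), xmin=10.0)


class TestBuildConditionNetwork:
    def test_end_to_end_on_synthetic_diseased(self):
        ds = generate_dataset(SyntheticConfig(p=0.9, seed=1))
        net = build_condition_network(ds.expr, ds.design, "diseased")
        assert net.n_genes >= 50
        assert net.powerlaw.alpha > 1
        assert net.powerlaw.xmin > 0
        assert set(net.tail_comparison.ratios) == {
            "lognormal", "exponential", "truncated_powerlaw",
        }
        assert np.allclose(net.adjacency, net.adjacency.T)
        assert np.all(np.diag(net.adjacency) == 0)

    def test_deterministic(self):
        ds = generate_dataset(SyntheticConfig(p=0.9, seed=3))
        a = build_condition_network(ds.expr, ds.design, "diseased")
        b = build_condition_network(ds.expr, ds.design, "diseased")
        assert a.gene_ids == b.gene_ids
        assert np.array_equal(a.adjacency, b.adjacency)
        assert a.powerlaw == b.powerlaw

    def test_too_few_samples_rejected(self, rng):
        values = rng.normal(size=(5, 5))
        expr = ExpressionMatrix(
            tuple(f"g{i}" for i in range(5)), tuple(f"s{j}" for j in range(5)), values
        )
        import pandas as pd

        design = ConditionDesign(
            tuple(f"s{j}" for j in range(5)),
            ("a", "a", "b", "b", "b"),
            pd.DataFrame(),
        )
        with pytest.raises(ValueError, match="minimum 3"):
            build_condition_network(expr, design, "a")

    def test_adjacency_below_correlation_for_beta_ge_one(self, rng):
        corr = np.abs(np.corrcoef(rng.normal(size=(12, 20))))
        for beta in (1, 2, 5):
            adj = adjacency_from_correlation(corr, beta)
            off = ~np.eye(12, dtype=bool)
            assert np.all(adj[off] <= np.abs(corr)[off] + 1e-12)
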