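"""Generator behavior: planted correlation structure, determinism, planted
PPI and annotation rates against binomial/Monte-Carlo oracles."""

import numpy as np
import pandas as pd
import pytest

from coseed import (
    ModuleSpec,
    SimParams,
    simulate_annotations,
    simulate_compendium,
    simulate_ppi,
)


def _params(**kw):
    defaults = dict(
        n_datasets=3, samples_per_dataset=20, n_genes=60,
        module_specs=(ModuleSpec("m1", 10, 1.0, 0.0),),
        noise_sd=0.3, seed_overlap_fraction=0.5,
        dropout_fraction=0.0, rng_seed=5,
    )
    defaults.update(kw)
    return SimParams(**defaults)


class TestCompendium:
    def test_noise_free_module_correlates_perfectly(self):
        comp, truth = simulate_compendium(_params(noise_sd=1e-9))
        module = sorted(truth.module_genes("m1"))
        for ds in comp.datasets:
            x = ds.expr.loc[module].to_numpy()
            r = np.corrcoef(x)
            assert np.all(np.abs(r - 1.0) < 1e-6)

    def test_null_pair_tail_matches_monte_carlo_oracle(self):
        # with no planted loading, the fraction of gene pairs with sample
        # |r| >= 0.5 must match the null Pearson tail at n = 20
        comp, _ = simulate_compendium(
            _params(n_genes=400, module_specs=(ModuleSpec("m1", 10, 0.0, 0.0),),
                    n_datasets=1, rng_seed=3)
        )
        x = comp.datasets[0].expr.to_numpy()
        x = x - x.mean(axis=1, keepdims=True)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        rng = np.random.default_rng(99)
        pairs = rng.integers(0, 400, size=(10_000, 2))
        pairs = pairs[pairs[:, 0] != pairs[:, 1]]
        r = np.einsum("ij,ij->i", x[pairs[:, 0]], x[pairs[:, 1]])
        observed = float((np.abs(r) >= 0.5).mean())

        # independent Monte-Carlo oracle: 10,000 fresh null pairs at n = 20
        a = rng.standard_normal((10_000, 20))
        b = rng.standard_normal((10_000, 20))
        a = a - a.mean(1, keepdims=True)
        b = b - b.mean(1, keepdims=True)
        r0 = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        expected = float((np.abs(r0) >= 0.5).mean())
        se = np.sqrt(expected * (1 - expected) / 10_000
                     + observed * (1 - observed) / len(pairs))
        assert abs(observed - expected) <= 3 * se

    def test_same_seed_reproduces_identical_output(self):
        c1, t1 = simulate_compendium(_params(dropout_fraction=0.3))
        c2, t2 = simulate_compendium(_params(dropout_fraction=0.3))
        assert t1.seed_set == t2.seed_set
        for d1, d2 in zip(c1.datasets, c2.datasets):
            pd.testing.assert_frame_equal(d1.expr, d2.expr)

    def test_dropout_rate_matches_binomial_expectation(self):
        p = 0.4
        comp, _ = simulate_compendium(
            _params(n_genes=500, n_datasets=6, dropout_fraction=p, rng_seed=8)
        )
        n_slots = 500 * 6
        present = sum(len(ds.gene_ids) for ds in comp.datasets)
        absent_frac = 1 - present / n_slots
        se = np.sqrt(p * (1 - p) / n_slots)
        assert abs(absent_frac - p) <= 3 * se

    @pytest.mark.parametrize(
        "kw",
        [
            dict(noise_sd=0.0),
            dict(noise_sd=-1.0),
            dict(module_specs=(ModuleSpec("m1", 100, 1.0, 0.0),)),  # > n_genes
            dict(dropout_fraction=1.0),
            dict(seed_overlap_fraction=1.5),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            _params(**kw)


class TestPPI:
    def test_complete_within_module_graph(self):
        _, truth = simulate_compendium(
            _params(module_specs=(ModuleSpec("m1", 4, 1.0, 0.0),))
        )
        edges = simulate_ppi(truth, p_within=1.0, p_between=0.0, rng_seed=1)
        module = truth.module_genes("m1")
        assert len(edges) == 6
        assert all(a in module and b in module for a, b in edges.edges)

    def test_zero_probabilities_give_empty_list(self):
        _, truth = simulate_compendium(_params())
        assert len(simulate_ppi(truth, 0.0, 0.0, rng_seed=1)) == 0

    def test_between_edge_count_matches_binomial_oracle(self):
        _, truth = simulate_compendium(
            _params(n_genes=50, module_specs=(ModuleSpec("m1", 4, 1.0, 0.0),),
                    rng_seed=2)
        )
        # 50 genes: 1225 pairs, 6 within-module -> 1219 between pairs
        p = 0.05
        edges = simulate_ppi(truth, p_within=1.0, p_between=p, rng_seed=2)
        module = truth.module_genes("m1")
        n_within = sum(a in module and b in module for a, b in edges.edges)
        assert n_within == 6
        n_between_drawn = len(edges) - n_within
        n_between = 1219
        se = np.sqrt(n_between * p * (1 - p))
        assert abs(n_between_drawn - n_between * p) <= 3 * se

    def test_probability_order_enforced(self):
        _, truth = simulate_compendium(_params())
        with pytest.raises(ValueError):
            simulate_ppi(truth, p_within=0.1, p_between=0.5, rng_seed=1)

    def test_deterministic_under_seed(self):
        _, truth = simulate_compendium(_params(n_genes=100))
        e1 = simulate_ppi(truth, 0.8, 0.02, rng_seed=9)
        e2 = simulate_ppi(truth, 0.8, 0.02, rng_seed=9)
        assert e1.edges == e2.edges


class TestAnnotations:
    def _truth(self, module_size=100, n_genes=1000):
        _, truth = simulate_compendium(
            _params(n_genes=n_genes,
                    module_specs=(ModuleSpec("m1", module_size, 1.0, 0.0),))
        )
        return truth

    def test_certain_module_rate_recovers_module_exactly(self):
        truth = self._truth()
        aug = simulate_annotations(truth, 1.0, 0.0, [], rng_seed=4)
        assert aug.regulator_responsive_set == truth.module_genes("m1")

    def test_zero_rates_give_empty_set(self):
        truth = self._truth()
        aug = simulate_annotations(truth, 0.0, 0.0, [], rng_seed=4)
        assert aug.regulator_responsive_set == set()

    def test_planted_rates_match_binomial_oracle(self):
        truth = self._truth(module_size=100, n_genes=1000)
        aug = simulate_annotations(truth, 0.8, 0.05, [("t", 0.8, 0.05)], rng_seed=6)
        module = truth.module_genes("m1")
        for flagged in (aug.regulator_responsive_set, aug.pathway_annotations["t"]):
            in_mod = len(flagged & module)
            in_bg = len(flagged) - in_mod
            assert abs(in_mod - 80) <= 3 * np.sqrt(100 * 0.8 * 0.2)
            assert abs(in_bg - 45) <= 3 * np.sqrt(900 * 0.05 * 0.95)

    def test_unknown_module_id_rejected(self):
        truth = self._truth()
        with pytest.raises(KeyError):
            simulate_annotations(truth, 0.5, 0.0, [("t", 0.5, 0.0, "nope")], rng_seed=1)
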