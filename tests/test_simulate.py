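"""Determinism and statistical structure of the synthetic generator."""

import numpy as np
import pytest

from slp_biogeo.geo import CodingConfig
from slp_biogeo.signal_d import phylo_d
from slp_biogeo.simulate import (SimConfig, assign_families, make_benchmark,
                                 simulate_geography, simulate_richness,
                                 simulate_trait, simulate_tree)


class TestSimulateTree:
    def test_deterministic(self):
        a = simulate_tree(SimConfig(n_tips=50, seed=1))
        b = simulate_tree(SimConfig(n_tips=50, seed=1))
        assert a.to_newick() == b.to_newick()

    def test_ultrametric_yule(self):
        t = simulate_tree(SimConfig(n_tips=80, seed=2))
        assert t.n_tips == 80
        depths = t.depths[:80]
        assert depths.max() - depths.min() < 1e-9 * max(1.0, depths.max())

    def test_birthdeath_ultrametric(self):
        t = simulate_tree(SimConfig(n_tips=40, seed=3, tree_model="birthdeath",
                                    birth=1.0, death=0.4))
        assert t.n_tips == 40
        assert t.is_ultrametric()

    def test_too_few_tips(self):
        with pytest.raises(ValueError):
            SimConfig(n_tips=3)

    def test_death_exceeding_birth(self):
        with pytest.raises(ValueError):
            simulate_tree(SimConfig(n_tips=10, tree_model="birthdeath",
                                    birth=1.0, death=1.5))


class TestGeography:
    def test_tropic_fraction(self):
        cfg = SimConfig(n_tips=50, n_regions=100, tropic_fraction=0.5, seed=4)
        tree = simulate_tree(cfg)
        cat, _ = simulate_geography(cfg, tree)
        flags = cat.tropical_flags(CodingConfig())
        # binomial(100, ~0.5): allow 3 sigma (regions near the band edge can
        # only add tropical hits, so the observed share may sit slightly high)
        assert abs(flags.mean() - 0.5) < 3 * 0.05 + 0.05

    def test_occupancy_never_empty(self):
        cfg = SimConfig(n_tips=60, seed=5)
        tree = simulate_tree(cfg)
        _, occ = simulate_geography(cfg, tree)
        assert all(len(v) >= 1 for v in occ.values())

    def test_sister_tips_share_more_regions(self):
        """Phylogenetic structure in geography: sister pairs overlap more
        than random pairs (Jaccard), averaged over simulations."""
        rng = np.random.default_rng(0)
        sister_j, random_j = [], []
        for rep in range(30):
            cfg = SimConfig(n_tips=40, seed=600 + rep)
            tree = simulate_tree(cfg)
            _, occ = simulate_geography(cfg, tree)
            sets = {g: set(v) for g, v in occ.items()}
            labels = tree.tip_labels
            # sister pairs: tips sharing a parent
            for node in range(tree.n_tips, tree.n_nodes):
                kids = [k for k in tree.children[node] if k < tree.n_tips]
                if len(kids) >= 2:
                    a, b = labels[kids[0]], labels[kids[1]]
                    sister_j.append(len(sets[a] & sets[b]) / len(sets[a] | sets[b]))
            for _ in range(10):
                a, b = rng.choice(labels, size=2, replace=False)
                random_j.append(len(sets[a] & sets[b]) / len(sets[a] | sets[b]))
        assert np.mean(sister_j) > np.mean(random_j)


class TestRichnessAndTrait:
    def test_richness_at_least_one(self):
        r = simulate_richness(SimConfig(n_tips=10, seed=1), 500)
        assert r.min() >= 1
        assert r.dtype == np.int64

    def test_trait_has_both_states(self):
        cfg = SimConfig(n_tips=100, seed=7)
        tree = simulate_tree(cfg)
        X = np.zeros((100, 3))
        X[:, 2] = 10
        y = simulate_trait(tree, X, cfg)
        assert 0 < y.sum() < 100

    def test_symmetric_threshold_prevalence(self):
        cfg = SimConfig(n_tips=1000, seed=8, signal_sd=0.0,
                        beta=(0.0, 0.0, 0.0, 0.0), trait_mode="logistic")
        tree = simulate_tree(cfg)
        y = simulate_trait(tree, np.zeros((1000, 3)), cfg)
        assert y.mean() == pytest.approx(0.5, abs=0.05)

    def test_signal_sd_lowers_d(self):
        """With a fixed non-phylogenetic liability component, increasing the
        Brownian share moves the trait from random (D ~ 1) towards
        Brownian-conserved (D ~ 0): mean D decreases along the grid."""
        rng = np.random.default_rng(1)
        means = []
        for sd in (0.0, 1.0, 3.0):
            ds = []
            for rep in range(25):
                cfg = SimConfig(n_tips=100, seed=900 + rep, signal_sd=sd,
                                beta=(-0.2, 1.5, 0.0, 0.0))
                tree = simulate_tree(cfg)
                X = np.zeros((100, 3))
                X[:, 0] = np.random.default_rng(rep).standard_normal(100)
                y = simulate_trait(tree, X, cfg,
                                   rng=np.random.default_rng(10_000 + rep))
                if 0 < y.sum() < 100:
                    ds.append(phylo_d(tree, y, n_sim=200, seed=rng).D)
            means.append(np.mean(ds))
        assert means[0] > means[1] > means[2]
        assert means[0] > 0.7   # covariate-only trait is phylogenetically random
        assert means[2] < 0.4   # Brownian-dominated trait is conserved

    def test_tropical_effect_raises_association(self):
        """Larger b_tropical -> stronger trait-tropical association."""
        from slp_biogeo.exploratory import contingency_2x2, phi_coefficient

        phis = []
        for bt in (0.0, 1.0, 3.0):
            vals = []
            for rep in range(40):
                cfg = SimConfig(n_tips=120, seed=3000 + rep, signal_sd=0.5,
                                beta=(-0.5, bt, 0.0, 0.0))
                tree = simulate_tree(cfg)
                X = np.zeros((120, 3))
                X[:, 0] = np.random.default_rng(rep).random(120) < 0.5
                y = simulate_trait(tree, X, cfg,
                                   rng=np.random.default_rng(20_000 + rep))
                try:
                    vals.append(phi_coefficient(
                        contingency_2x2(y, X[:, 0].astype(int))).statistic)
                except ValueError:
                    continue
            phis.append(np.mean(vals))
        assert phis[0] < phis[1] < phis[2]


class TestBenchmark:
    def test_deterministic(self):
        a = make_benchmark(SimConfig(n_tips=80, seed=9))
        b = make_benchmark(SimConfig(n_tips=80, seed=9))
        np.testing.assert_array_equal(a.dataset.trait, b.dataset.trait)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert a.truth == b.truth

    def test_truth_carries_generating_parameters(self):
        cfg = SimConfig(n_tips=60, seed=10, beta=(-2.0, 1.0, 0.5, 0.01))
        bench = make_benchmark(cfg)
        assert tuple(bench.truth["beta"]) == cfg.beta
        assert bench.truth["signal_sd"] == cfg.signal_sd
        assert bench.truth["focal_family"] in set(bench.dataset.families)

    def test_families_are_clades(self):
        tree = simulate_tree(SimConfig(n_tips=100, seed=12))
        fams = assign_families(tree, cut=0.35)
        assert len(fams) == 100
        assert len(set(fams)) >= 2

    def test_large_scale_smoke(self):
        bench = make_benchmark(SimConfig(n_tips=2000, seed=13))
        assert bench.dataset.n == 2000
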