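import numpy as np
import pandas as pd
import pytest

import assemblage as A
from assemblage.null_models import bray_curtis
from assemblage.synthetic_data import SimulationConfig, scenario_dataset


class TestSimulateTree:
    def test_deterministic_given_seed(self):
        t1 = A.simulate_tree(20, rng_seed=42)
        t2 = A.simulate_tree(20, rng_seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_two_tips_is_ultrametric_cherry(self):
        t = A.simulate_tree(2, rng_seed=0)
        depths = t.root_depths()
        assert len(depths) == 2
        assert depths.iloc[0] == pytest.approx(depths.iloc[1])

    def test_ultrametric_for_any_size(self):
        t = A.simulate_tree(50, rng_seed=1)
        depths = t.root_depths().values
        assert np.allclose(depths, depths[0], rtol=1e-9)

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            A.simulate_tree(1)

    def test_pure_birth_depth_matches_expectation(self):
        # E[depth] of a Yule tree grown to n tips (one extra wait at n):
        # sum_{k=2..n} 1/(b k)  +  1/(b n)
        n, b = 30, 1.0
        expected = sum(1.0 / (b * k) for k in range(2, n + 1)) + 1.0 / (b * n)
        depths = [
            A.simulate_tree(n, birth_rate=b, rng_seed=s).root_depths().iloc[0]
            for s in range(200)
        ]
        se = np.std(depths) / np.sqrt(len(depths))
        assert abs(np.mean(depths) - expected) < 4 * se

    def test_crown_compression_keeps_ultrametricity_and_depth(self):
        plain = A.simulate_tree(40, rng_seed=3)
        warped = A.simulate_tree(40, rng_seed=3, crown_compression=0.5)
        assert np.allclose(warped.root_depths().values,
                           plain.root_depths().values, rtol=1e-9)
        # nearest-neighbour distances shrink relative to the median distance
        def nnd_ratio(t):
            D = A.patristic_distances(t).values.copy()
            np.fill_diagonal(D, np.inf)
            iu = np.isfinite(D)
            return D.min(axis=1).mean() / np.median(D[iu])
        assert nnd_ratio(warped) < nnd_ratio(plain)


class TestEvolveTrait:
    def test_lambda_bounds(self):
        t = A.simulate_tree(5, rng_seed=0)
        with pytest.raises(ValueError):
            A.evolve_trait(t, trait_lambda=1.5)

    def test_lambda0_variance_scales_with_depth(self):
        t = A.simulate_tree(10, rng_seed=2)
        depth = t.root_depths().values
        draws = np.array([
            A.evolve_trait(t, trait_sigma2=2.0, trait_lambda=0.0, rng_seed=s).values
            for s in range(800)
        ])
        assert np.allclose(draws.var(axis=0), 2.0 * depth, rtol=0.2)
        # off-diagonal: independent
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_cherry_covariance_is_shared_stem(self):
        # ((A:t,B:t):s,C:s+t); cov(A,B) = sigma2 * s under full BM
        tree = A.PhyloTree.from_newick("((A:1.0,B:1.0):2.0,C:3.0);")
        draws = np.array([
            A.evolve_trait(tree, trait_sigma2=1.5, trait_lambda=1.0, rng_seed=s).values
            for s in range(1500)
        ])
        labels = tree.tip_labels
        ia, ib = labels.index("A"), labels.index("B")
        cov = np.cov(draws[:, ia], draws[:, ib])[0, 1]
        assert cov == pytest.approx(1.5 * 2.0, rel=0.15)

    def test_mc_covariance_matches_analytic(self):
        tree = A.simulate_tree(40, rng_seed=4)
        C = tree.shared_path_matrix().values
        draws = np.array([
            A.evolve_trait(tree, trait_lambda=1.0, rng_seed=s).values
            for s in range(500)
        ])
        emp = np.cov(draws.T)
        scale = np.abs(C).max()
        assert np.abs(emp - C).max() / scale < 0.35  # Monte-Carlo tolerance


class TestAssembleCommunities:
    def test_neutral_limit_recovers_base_abundances(self):
        tree = A.simulate_tree(30, rng_seed=8)
        traits = A.evolve_trait(tree, rng_seed=9)
        cfg = SimulationConfig(n_tips=30, scenario="neutral", n_samples=1,
                               n_individuals=10**6, rng_seed=10)
        cm, md, truth = A.assemble_communities(tree, traits, cfg)
        base = np.array([truth["base_abundance"][t] for t in tree.tip_labels])
        rel = cm.values[0] / cm.values.sum()
        assert np.abs(rel - base / base.sum()).max() < 0.005

    def test_degenerate_filter_selects_one_taxon(self):
        tree = A.simulate_tree(20, rng_seed=11)
        traits = A.evolve_trait(tree, rng_seed=12)
        target = traits.index[3]
        cfg = SimulationConfig(
            n_tips=20, scenario="homogeneous_selection", n_samples=1,
            n_individuals=5000, env_values=[traits[target]],
            filter_width=1e-8, rng_seed=13,
        )
        cm, _, _ = A.assemble_communities(tree, traits, cfg)
        assert cm.iloc[0][target] / cm.values.sum() > 0.999

    def test_environment_beyond_every_niche_errors(self):
        tree = A.simulate_tree(10, rng_seed=14)
        traits = A.evolve_trait(tree, rng_seed=15)
        cfg = SimulationConfig(
            n_tips=10, scenario="homogeneous_selection", n_samples=1,
            n_individuals=100, env_values=[traits.max() + 1e4],
            filter_width=1e-3, rng_seed=16,
        )
        with pytest.raises(ValueError, match="filter_width"):
            A.assemble_communities(tree, traits, cfg)

    def test_variable_selection_separates_environment_blocks(self):
        tree = A.simulate_tree(100, rng_seed=17)
        traits = A.evolve_trait(tree, trait_lambda=1.0, rng_seed=18)
        cfg = SimulationConfig(n_tips=100, scenario="variable_selection",
                               n_samples=10, n_individuals=500, rng_seed=19)
        cm, md, _ = A.assemble_communities(tree, traits, cfg)
        bc = bray_curtis(cm).values
        same = md["group"].values[:, None] == md["group"].values[None, :]
        iu = np.triu_indices(10, k=1)
        within = bc[iu][same[iu]]
        between = bc[iu][~same[iu]]
        assert between.mean() > within.mean()

    def test_reproducible_from_config(self):
        tree = A.simulate_tree(20, rng_seed=20)
        traits = A.evolve_trait(tree, rng_seed=21)
        cfg = SimulationConfig(n_tips=20, scenario="dispersal_limited",
                               n_samples=4, n_individuals=100, rng_seed=22)
        cm1, md1, _ = A.assemble_communities(tree, traits, cfg)
        cm2, md2, _ = A.assemble_communities(tree, traits, cfg)
        pd.testing.assert_frame_equal(cm1, cm2)
        pd.testing.assert_frame_equal(md1, md2)


class TestPulseSeries:
    def test_single_taxon_pool(self):
        tree = A.simulate_tree(2, rng_seed=23)
        traits = A.evolve_trait(tree, rng_seed=24)
        base = np.array([1.0, 0.0])  # only the first taxon exists
        cfg = SimulationConfig(n_tips=2, n_individuals=50, rng_seed=25)
        cm, md, _ = A.simulate_pulse_series(tree, traits, cfg, base_abundance=base)
        assert (cm[tree.tip_labels[0]] == 50).all()

    def test_nonpositive_time_rejected(self):
        tree = A.simulate_tree(4, rng_seed=26)
        traits = A.evolve_trait(tree, rng_seed=27)
        cfg = SimulationConfig(n_tips=4, rng_seed=28)
        with pytest.raises(ValueError, match="positive"):
            A.simulate_pulse_series(tree, traits, cfg, times_h=[0.0, 1.0])

    def test_early_optimum_taxon_peaks_early(self):
        tree = A.simulate_tree(16, rng_seed=29)
        traits = A.evolve_trait(tree, rng_seed=30)
        cfg = SimulationConfig(n_tips=16, n_individuals=20000, rng_seed=31)
        cm, md, truth = A.simulate_pulse_series(tree, traits, cfg, n_replicates=2)
        optima = pd.Series(truth["ln_time_optima"])
        earliest = optima.idxmin()  # optimum at the first time point
        rel = cm.div(cm.sum(axis=1), axis=0)[earliest].groupby(md["time_h"]).mean()
        assert rel.idxmax() == rel.index.min()

    def test_niche_optima_recover_true_ln_time_optima(self):
        tree = A.simulate_tree(64, rng_seed=32)
        traits = A.evolve_trait(tree, trait_lambda=1.0, rng_seed=33)
        cfg = SimulationConfig(n_tips=64, n_individuals=10**5, rng_seed=34)
        cm, md, truth = A.simulate_pulse_series(tree, traits, cfg)
        est = A.niche_optima(cm, md["ln_time"])
        true = pd.Series(truth["ln_time_optima"]).loc[est.index]
        r = np.corrcoef(est["optimum"], true)[0, 1]
        assert r > 0.8


def test_scenario_dataset_shapes_and_truth():
    tree, traits, cm, md, truth = scenario_dataset(
        "neutral", rng_seed=1, n_tips=64, n_samples=4, n_individuals=100
    )
    assert cm.shape == (4, 64)
    assert set(md.columns) >= {"group", "env"}
    assert truth["scenario"] == "neutral"
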