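"""Synthetic landscapes, trees, traits and community assembly."""

import json

import numpy as np
import pandas as pd
import pytest

from phylorao import pipeline
from phylorao.nullmodels import alpha_pd_ses
from phylorao.phylo_io import mean_distance_matrix, patristic_distances
from phylorao.spatial import euclidean_plot_distances, pcnm_basis
from phylorao.synthetic_data import (
    ScenarioConfig,
    make_fixture,
    neutral_config,
    simulate_communities,
    simulate_dataset,
    simulate_landscape,
    simulate_posterior,
    simulate_traits,
    simulate_tree,
    strong_filtering_config,
)


class TestSimulateTree:
    def test_tip_count_and_labels(self, rng):
        tree = simulate_tree(12, rng=rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        assert len(labels) == 12
        assert all(lbl.startswith("sp") for lbl in labels)

    def test_ultrametric(self, rng):
        tree = simulate_tree(15, rng=rng)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_two_tips_is_a_cherry(self, rng):
        tree = simulate_tree(2, rng=rng)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert depths[0] == pytest.approx(depths[1])

    @pytest.mark.parametrize("b, d", [(0.5, 0.5), (0.5, 1.0), (1.0, -0.1)])
    def test_invalid_rates_rejected(self, b, d):
        with pytest.raises(ValueError):
            simulate_tree(5, birth_rate=b, death_rate=d, rng=0)


class TestSimulatePosterior:
    def test_zero_jitter_identical_matrices(self, rng):
        tree = simulate_tree(8, rng=rng)
        tp = simulate_posterior(tree, 5, jitter_cv=0.0, rng=rng)
        base = patristic_distances(tree)
        for t in tp:
            np.testing.assert_allclose(
                patristic_distances(t).data, base.data, atol=1e-12
            )

    def test_mean_matrix_law_of_large_numbers(self, rng):
        tree = simulate_tree(6, rng=rng)
        cv = 0.2
        tp = simulate_posterior(tree, 400, jitter_cv=cv, rng=rng)
        base = patristic_distances(tree)
        mean = mean_distance_matrix(tp)
        rel = np.abs(mean.data - base.data)[base.data > 0] \
            / base.data[base.data > 0]
        assert rel.max() < 4 * cv / np.sqrt(400)

    def test_posterior_of_one(self, rng):
        tree = simulate_tree(5, rng=rng)
        assert len(simulate_posterior(tree, 1, rng=rng)) == 1


class TestSimulateTraits:
    def test_variance_scales_with_depth(self):
        # pooled over replicate simulations, tip variance tracks
        # root-to-tip length
        tree = simulate_tree(10, rng=np.random.default_rng(0))
        depth = max(l.distance_from_root() for l in tree.leaf_node_iter())
        vals = np.array([
            simulate_traits(tree, 1.0, rng=seed).to_numpy()
            for seed in range(300)
        ])
        est = vals.var()
        # total tip variance under BM = sigma^2 * depth (ultrametric)
        assert est == pytest.approx(depth, rel=0.3)

    def test_cherry_tips_more_similar_than_random_pairs(self):
        tree = simulate_tree(30, rng=np.random.default_rng(3))
        dm = patristic_distances(tree)
        labels = list(dm.ids)
        close = min(
            ((i, j) for i in range(30) for j in range(i + 1, 30)),
            key=lambda ij: dm.data[ij],
        )
        diffs_close, diffs_rand = [], []
        rng = np.random.default_rng(0)
        for seed in range(200):
            t = simulate_traits(tree, 1.0, rng=seed)
            diffs_close.append(
                abs(t[labels[close[0]]] - t[labels[close[1]]])
            )
            i, j = rng.integers(0, 30, 2)
            while i == j:
                i, j = rng.integers(0, 30, 2)
            diffs_rand.append(abs(t[labels[i]] - t[labels[j]]))
        assert np.mean(diffs_close) < np.mean(diffs_rand)

    def test_small_sigma_limit(self):
        tree = simulate_tree(6, rng=np.random.default_rng(1))
        t = simulate_traits(tree, 1e-6, rng=0)
        assert np.abs(t.to_numpy()).max() < 1e-3

    def test_multivariate_shape(self):
        tree = simulate_tree(7, rng=np.random.default_rng(2))
        T = simulate_traits(tree, 1.0, rng=0, n_traits=3)
        assert T.shape == (7, 3)

    def test_early_burst_concentrates_deep_divergence(self):
        # with a strong early burst, trait distance correlates with
        # patristic distance more tightly than under plain BM
        tree = simulate_tree(40, rng=np.random.default_rng(5))
        d = patristic_distances(tree)
        tri = np.triu_indices(40, 1)

        def signal(eb, seed):
            t = simulate_traits(tree, 1.0, rng=seed, early_burst=eb)
            t = t.reindex(list(d.ids)).to_numpy()
            dt = np.abs(t[:, None] - t[None, :])
            return np.corrcoef(dt[tri], d.data[tri])[0, 1]

        plain = np.mean([signal(0.0, s) for s in range(20)])
        burst = np.mean([signal(4.0, s) for s in range(20)])
        assert burst > plain


class TestSimulateLandscape:
    def test_noiseless_gradient_recovery(self):
        from phylorao.environment import derive_axes

        config = ScenarioConfig(n_plots=30, env_noise=0.0, seed=2)
        env, truth = simulate_landscape(config, rng=2)
        axes, _ = derive_axes(env)
        r = np.corrcoef(axes["disturbance"], truth["true_disturbance"])[0, 1]
        assert abs(r) > 0.97

    def test_default_noise_recovery(self):
        from phylorao.environment import derive_axes

        config = ScenarioConfig(n_plots=30, seed=3)
        env, truth = simulate_landscape(config, rng=3)
        axes, _ = derive_axes(env)
        r = np.corrcoef(axes["disturbance"], truth["true_disturbance"])[0, 1]
        assert abs(r) > 0.8

    def test_coordinates_support_pcnm(self):
        config = ScenarioConfig(n_plots=12, seed=4)
        env, _ = simulate_landscape(config, rng=4)
        basis = pcnm_basis(euclidean_plot_distances(env))
        assert basis.n_axes >= 1

    def test_class_assignment(self):
        config = ScenarioConfig(n_plots=30, n_classes=5, seed=0)
        env, _ = simulate_landscape(config, rng=0)
        assert env["modification_class"].nunique() == 5
        assert env["modification_class"].value_counts().eq(6).all()


class TestSimulateCommunities:
    def test_abundance_totals_match_effort(self, rng):
        config = ScenarioConfig(n_plots=8, n_plant_species=20, seed=9)
        _, truth = simulate_landscape(config, rng=9)
        tree = simulate_tree(20, rng=rng, prefix="plant")
        traits = simulate_traits(tree, 1.0, rng=rng, n_traits=3)
        comms = simulate_communities(traits, truth, config, rng=rng)
        for stage in config.stages:
            totals = comms[stage].sum(axis=1)
            assert (totals == config.individuals[stage]).all()

    def test_neutral_assembly_near_nominal_flag_rate(self):
        flagged = total = 0
        for seed in range(8):
            cfg = neutral_config(seed=seed, n_plots=20,
                                 n_plant_species=60, n_bird_species=10)
            b = simulate_dataset(cfg)
            comms = {
                "adult": pipeline.observed_table(b["communities"]["adult"])
            }
            D = pipeline.regional_distance(b["plant_tree"], comms)
            out = alpha_pd_ses(comms, D, n_perm=300, rng=seed)
            flagged += (out["classification"]
                        .isin(["overdispersed", "underdispersed"])).sum()
            total += len(out)
        assert flagged / total < 0.15

    def test_filtering_depresses_pd_with_disturbance(self):
        cfg = strong_filtering_config(seed=2, n_plots=20,
                                      n_plant_species=80)
        b = simulate_dataset(cfg)
        comms = {
            "seedling": pipeline.observed_table(b["communities"]["seedling"])
        }
        D = pipeline.regional_distance(b["plant_tree"], comms)
        out = alpha_pd_ses(comms, D, n_perm=300, rng=0)
        s = out.set_index("target")["ses"]
        td = b["truth"]["true_disturbance"]
        r = np.corrcoef(s.reindex(td.index).fillna(0), td)[0, 1]
        assert r < -0.3

    def test_repulsion_produces_overdispersion(self):
        cfg = ScenarioConfig(
            n_plots=10, n_plant_species=60, seed=6,
            filter_strength={"adult": -1.0},
            disturbance_effect=0.0, optimum_shift=0.0,
            stages=("adult",),
        )
        b = simulate_dataset(cfg)
        comms = {"adult": pipeline.observed_table(b["communities"]["adult"])}
        D = pipeline.regional_distance(b["plant_tree"], comms)
        out = alpha_pd_ses(comms, D, n_perm=300, rng=1)
        assert out["ses"].mean() > 0.5


class TestMakeFixture:
    def test_roundtrip_and_manifest(self, tmp_path):
        config = ScenarioConfig(n_plots=6, n_plant_species=12,
                                n_bird_species=8, seed=3)
        out = make_fixture(config, tmp_path / "bundle", n_posterior=3)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 3
        bundle = pipeline.load_bundle(out)
        assert set(bundle["communities"]) == {"adult", "sapling",
                                              "seedling", "bird"}
        assert len(bundle["plant_posterior"]) == 3
        assert bundle["environment"].shape[0] == 6

    def test_same_seed_byte_identical(self, tmp_path):
        config = ScenarioConfig(n_plots=6, n_plant_species=12,
                                n_bird_species=8, seed=11)
        p1 = make_fixture(config, tmp_path / "a", n_posterior=2)
        p2 = make_fixture(config, tmp_path / "b", n_posterior=2)
        for f in sorted(p1.iterdir()):
            assert f.read_bytes() == (p2 / f.name).read_bytes()

    def test_refuses_nonempty_directory(self, tmp_path):
        target = tmp_path / "busy"
        target.mkdir()
        (target / "keep.txt").write_text("data")
        config = ScenarioConfig(n_plots=6, n_plant_species=12, seed=0)
        with pytest.raises(FileExistsError):
            make_fixture(config, target)
        make_fixture(config, target, force=True)  # explicit override

    def test_tiny_config_is_fast(self, tmp_path):
        import time

        config = ScenarioConfig(n_plots=6, n_plant_species=12,
                                n_bird_species=8, seed=1)
        t0 = time.time()
        make_fixture(config, tmp_path / "tiny")
        assert time.time() - t0 < 5.0
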