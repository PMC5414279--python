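"""The synthetic study generator: validity, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from phyloniche import pic_correlation_report
from phyloniche.envelope import (
    BIOCLIM_COLUMNS,
    EnvelopeGrid,
    climate_envelope,
    fit_climate_pca,
    project,
)
from phyloniche.genomics import count_duplicated_genes, count_nogf
from phyloniche.simulate import (
    SimulationConfig,
    generate_study,
    simulate_bm,
    simulate_hit_table,
    simulate_niche_samples,
    simulate_traits,
    simulate_tree,
    write_study,
)


class TestYuleTree:
    def test_two_tip_shape(self):
        tree = simulate_tree(2, seed=4)
        assert tree.n_tips == 2
        C = np.diag(np.ones(2))
        cov = np.asarray(
            __import__("phyloniche").brownian_covariance(tree)
        )
        assert cov[0, 0] == pytest.approx(cov[1, 1])  # ultrametric pair
        assert cov[0, 0] > 0

    def test_deterministic_per_seed(self):
        a = simulate_tree(32, seed=99).to_newick()
        b = simulate_tree(32, seed=99).to_newick()
        assert a == b
        assert a != simulate_tree(32, seed=100).to_newick()

    @pytest.mark.parametrize("seed", range(30))
    def test_valid_binary_positive_lengths(self, seed):
        n = 2 + seed % 15
        tree = simulate_tree(n, seed=seed)
        assert tree.n_tips == n
        assert tree.is_binary()
        assert tree.has_positive_lengths()

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1)


class TestBrownianSimulator:
    def test_tip_variance_scales_with_depth(self, rng):
        tree = simulate_tree(2, seed=0)
        draws = np.array([
            simulate_bm(tree, 1.0, np.random.default_rng(s))[0].to_numpy()
            for s in range(400)
        ])
        depth = __import__("phyloniche").brownian_covariance(tree)[0, 0]
        assert draws[:, 0].var() == pytest.approx(depth, rel=0.25)

    def test_contrast_variance_equals_rate(self):
        """Standardized contrasts of a Brownian trait have variance = rate."""
        from phyloniche import pic

        tree = simulate_tree(32, seed=8)
        rng = np.random.default_rng(8)
        contrasts = np.concatenate([
            pic(tree, simulate_bm(tree, 4.0, rng)[0].to_dict()).values
            for _ in range(30)
        ])
        assert contrasts.var() == pytest.approx(4.0, rel=0.15)


class TestTraits:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_species=12, n_categories=20, seed=5)
        tree = simulate_tree(12, seed=1)
        t1, _ = simulate_traits(tree, cfg, np.random.default_rng(7))
        t2, _ = simulate_traits(tree, cfg, np.random.default_rng(7))
        pd.testing.assert_frame_equal(t1, t2)

    def test_null_effect_gives_centred_contrast_correlation(self):
        cfg = SimulationConfig(n_species=16, n_categories=10, beta_star=0.0,
                               seed=0)
        slopes = []
        for seed in range(40):
            tree = simulate_tree(16, seed=seed)
            traits, truth = simulate_traits(tree, cfg,
                                            np.random.default_rng(seed))
            rep = pic_correlation_report(
                traits[f"NOGF_{cfg.planted_category}"], truth.breadth, tree
            )
            slopes.append(rep["slope"])
        t_stat = np.mean(slopes) / (np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
        assert abs(t_stat) < 4  # no systematic association when beta* = 0

    def test_planted_effect_reaches_half_contrast_variance(self):
        """At defaults the planted category explains roughly half the
        contrast-level variance of latent niche breadth."""
        r2 = []
        for seed in range(12):
            cfg = SimulationConfig(seed=seed)
            tree = simulate_tree(cfg.n_species, seed=seed)
            traits, truth = simulate_traits(tree, cfg,
                                            np.random.default_rng(seed))
            rep = pic_correlation_report(
                traits[f"NOGF_{cfg.planted_category}"], truth.breadth, tree
            )
            r2.append(rep["r2"])
        assert 0.35 < float(np.median(r2)) < 0.75

    def test_constraints_hold(self):
        cfg = SimulationConfig(n_species=10, n_categories=15, seed=3)
        tree = simulate_tree(10, seed=3)
        traits, truth = simulate_traits(tree, cfg, np.random.default_rng(3))
        assert (traits["N_d"] <= traits["N_g"]).all()
        assert (traits[[c for c in traits if c.startswith("NOGF_")]] >= 1).all().all()
        assert (truth.breadth > 0).all()


class TestNicheSamples:
    def test_tiny_breadth_collapses_to_one_cell(self):
        cfg = SimulationConfig(rows_per_species=100, seed=0, ambient_sd=0.0)
        breadths = pd.Series({"sp1": 1e-9, "sp2": 5.0})
        clim = simulate_niche_samples(breadths, cfg, np.random.default_rng(0))
        model = fit_climate_pca(clim)
        scores = project(clim, model)
        grid = EnvelopeGrid.from_scores(scores)
        sp1 = scores[scores["species"] == "sp1"]
        assert climate_envelope(sp1, grid) == 1

    def test_broader_species_occupy_more_cells(self):
        cfg = SimulationConfig(rows_per_species=300)
        wins = 0
        for seed in range(20):
            breadths = pd.Series({"narrow": 2.0, "broad": 8.0})
            clim = simulate_niche_samples(breadths, cfg,
                                          np.random.default_rng(seed))
            scores = project(clim, fit_climate_pca(clim))
            grid = EnvelopeGrid.from_scores(scores)
            env = {
                sp: climate_envelope(scores[scores["species"] == sp], grid)
                for sp in breadths.index
            }
            wins += env["broad"] > env["narrow"]
        assert wins >= 18

    def test_pooled_pca_concentrates_on_two_components(self):
        cfg = SimulationConfig(seed=2)
        breadths = pd.Series(np.linspace(3, 10, 16),
                             index=[f"s{i}" for i in range(16)])
        clim = simulate_niche_samples(breadths, cfg, np.random.default_rng(2))
        model = fit_climate_pca(clim)
        assert model.explained_variance_ratio[:2].sum() > 0.90

    def test_nonpositive_breadth_rejected(self):
        cfg = SimulationConfig()
        with pytest.raises(ValueError, match="sp1"):
            simulate_niche_samples(pd.Series({"sp1": 0.0}), cfg,
                                   np.random.default_rng(0))


class TestHitTables:
    def test_zero_pairs_zero_duplicates(self):
        df, expected = simulate_hit_table(10, 0, np.random.default_rng(0))
        assert expected == 0
        assert count_duplicated_genes(df).get("sp1", 0) == 0

    def test_planted_duplicates_recovered_exactly(self):
        df, expected = simulate_hit_table(10, 3, np.random.default_rng(1))
        assert expected == 6
        assert count_duplicated_genes(df)["sp1"] == 6

    def test_boundary_decoys_never_counted(self):
        df, expected = simulate_hit_table(60, 5, np.random.default_rng(2))
        boundary = df[(df["evalue"] == 1e-5) | (df["qcov"] == 30.0)]
        assert len(boundary) > 0  # decoys present in the table
        assert count_duplicated_genes(df)["sp1"] == expected

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError):
            simulate_hit_table(4, 3, np.random.default_rng(0))


class TestWholeStudy:
    small = SimulationConfig(n_species=8, n_categories=12,
                             rows_per_species=60, base_dup_pairs=10, seed=21)

    def test_gene_map_realizes_nogf_counts(self):
        study = generate_study(self.small)
        recovered = count_nogf(study.gene_map, list(study.catalogue))
        recovered.columns = [f"NOGF_{c}" for c in recovered.columns]
        nogf_cols = [c for c in study.traits.columns if c.startswith("NOGF_")]
        pd.testing.assert_frame_equal(
            recovered.loc[study.traits.index, nogf_cols],
            study.traits[nogf_cols],
            check_names=False,
        )

    def test_hit_tables_realize_duplicate_counts(self):
        study = generate_study(self.small)
        recovered = count_duplicated_genes(study.hits)
        expected = study.truth.expected_n_d
        # pairs are floor(N_d / 2); regenerated count is 2 * pairs
        assert (recovered.loc[expected.index]
                == 2 * (expected // 2)).all()

    def test_byte_identical_outputs_per_seed(self, tmp_path):
        s1 = write_study(self.small, tmp_path / "a")
        s2 = write_study(self.small, tmp_path / "b")
        for name in ["tree.nwk", "traits.tsv", "climate.tsv", "hits.tsv",
                     "gene_categories.tsv", "habitat_classes.tsv",
                     "ground_truth.json"]:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name
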