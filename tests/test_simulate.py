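import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phylomilk.core import read_newick_string
from phylomilk.pmm import build_design
from phylomilk.simulate import (
    SimulationConfig,
    impose_missingness,
    make_dataset,
    make_preset,
    plant_shifts,
    simulate_bm_traits,
    simulate_covariates,
    simulate_planted_clade_tree,
    simulate_scou_traits,
    simulate_tree,
)


class TestSimulateTree:
    def test_three_tips_binary(self):
        t = simulate_tree(3, seed=0)
        assert t.n_tips == 3
        assert t.n_nodes == 5

    def test_seed_determinism(self):
        a = simulate_tree(12, seed=5)
        b = simulate_tree(12, seed=5)
        assert a.newick() == b.newick()

    def test_unit_height_ultrametric(self):
        t = simulate_tree(30, seed=2)
        assert t.height == pytest.approx(1.0, abs=1e-9)
        assert t.is_ultrametric()

    def test_distinct_tip_positions(self):
        # the generator extends pendant branches past the stopping event,
        # so no two tips are identical (covariance stays invertible)
        t = simulate_tree(40, seed=9)
        A = t.mrca_depths()
        assert np.linalg.eigvalsh(A).min() > 1e-12


class TestBrownianTraits:
    def test_zero_rate_constant(self, five_tip_tree):
        vals = simulate_bm_traits(five_tip_tree, np.zeros((3, 3)), 1.5, seed=0)
        np.testing.assert_allclose(vals.to_numpy(), 1.5)

    def test_two_tip_contrast_variance(self):
        # var(x_A - x_B) = 2 sigma for unit branches
        tree = read_newick_string("(A:1,B:1);")
        sigma = np.array([[1.0, 0.6], [0.6, 2.0]])
        diffs = np.array([
            simulate_bm_traits(tree, sigma, 0.0, seed=s).to_numpy()[0, :2]
            - simulate_bm_traits(tree, sigma, 0.0, seed=s).to_numpy()[1, :2]
            for s in range(2000)
        ])
        np.testing.assert_allclose(np.cov(diffs.T), 2 * sigma, atol=0.35)

    def test_tip_covariance_matches_tree(self, three_tip_tree):
        # cov(tip_i, tip_j) = A[i, j] * sigma across replicates
        reps = np.array([
            simulate_bm_traits(three_tip_tree, np.eye(1), 0.0, seed=s).to_numpy()[:, 0]
            for s in range(3000)
        ])
        A = three_tip_tree.mrca_depths()
        np.testing.assert_allclose(np.cov(reps.T), A, atol=0.3)


class TestScalarOU:
    def test_alpha_zero_matches_bm_distribution(self, five_tip_tree):
        bm = np.array([
            simulate_bm_traits(five_tip_tree, np.eye(1), 0.0, seed=s).iloc[0, 0]
            for s in range(400)
        ])
        ou = np.array([
            simulate_scou_traits(five_tip_tree, 0.0, np.eye(1), 0.0, (), seed=10_000 + s).iloc[0, 0]
            for s in range(400)
        ])
        assert stats.ks_2samp(bm, ou).pvalue > 0.01

    def test_strong_pull_pins_tips_to_optimum(self, five_tip_tree):
        shifts = [(1, np.array([4.0]))]  # node 1 is the first root child
        vals = simulate_scou_traits(five_tip_tree, 500.0, 0.0001 * np.eye(1),
                                    0.0, shifts, seed=0)
        below = five_tip_tree.tips_below()[1]
        np.testing.assert_allclose(vals.to_numpy()[below, 0], 4.0, atol=0.05)
        np.testing.assert_allclose(vals.to_numpy()[~below, 0], 0.0, atol=0.05)

    def test_stationary_variance_on_long_branch(self):
        tree = read_newick_string("(A:60,B:60);")
        alpha, rate = 0.5, 2.0
        vals = np.array([
            simulate_scou_traits(tree, alpha, rate * np.eye(1), 0.0, (), seed=s).iloc[0, 0]
            for s in range(1500)
        ])
        assert np.var(vals) == pytest.approx(rate / (2 * alpha), rel=0.15)

    def test_duplicate_shift_edge_rejected(self, five_tip_tree):
        with pytest.raises(ValueError, match="two shifts"):
            simulate_scou_traits(five_tip_tree, 0.1, np.eye(1), 0.0,
                                 [(1, [1.0]), (1, [2.0])], seed=0)

    def test_missing_edge_rejected(self, five_tip_tree):
        with pytest.raises(ValueError, match="does not exist"):
            simulate_scou_traits(five_tip_tree, 0.1, np.eye(1), 0.0,
                                 [(99, [1.0])], seed=0)


class TestCovariatesAndEffects:
    def test_design_has_nine_columns(self):
        tree = simulate_tree(40, seed=1)
        covs = simulate_covariates(tree, seed=1)
        X, names = build_design(covs)
        assert X.shape == (40, 9)
        assert len(names) == 9

    def test_zero_effects_leave_traits_unchanged(self):
        from phylomilk.simulate import DEFAULT_B, attach_covariates_and_effects

        tree = simulate_tree(20, seed=2)
        vals = simulate_bm_traits(tree, np.eye(3), 0.0, seed=2)
        covs = simulate_covariates(tree, seed=2)
        B0 = DEFAULT_B * 0.0
        out = attach_covariates_and_effects(tree, vals, covs, B0)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy())

    def test_binary_effect_recovered_as_group_difference(self):
        from phylomilk.simulate import DEFAULT_B, attach_covariates_and_effects

        beta = 1.0
        diffs = []
        for s in range(40):
            tree = simulate_tree(60, seed=s)
            vals = simulate_bm_traits(tree, 0.05 * np.eye(3), 0.0, seed=s)
            covs = simulate_covariates(tree, seed=s)
            B = DEFAULT_B * 0.0
            B.loc["arid", "fat"] = beta
            out = attach_covariates_and_effects(tree, vals, covs, B)
            arid = covs.data["arid"].to_numpy().astype(bool)
            diffs.append(out["fat"].to_numpy()[arid].mean()
                         - out["fat"].to_numpy()[~arid].mean())
        assert np.mean(diffs) == pytest.approx(beta, abs=0.2)

    def test_covariates_deterministic(self):
        tree = simulate_tree(25, seed=4)
        a = simulate_covariates(tree, seed=9).data
        b = simulate_covariates(tree, seed=9).data
        pd.testing.assert_frame_equal(a, b)


class TestMissingness:
    def test_zero_fraction_identity(self, small_traits):
        out = impose_missingness(small_traits.data, 0.0, "sugar", seed=0)
        pd.testing.assert_frame_equal(out, small_traits.data)

    def test_fifteen_of_124(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(124, 3)),
                          columns=["fat", "protein", "sugar"])
        out = impose_missingness(df, 15 / 124, "sugar", seed=1)
        assert out["sugar"].isna().sum() == 15
        assert out[["fat", "protein"]].notna().all(axis=None)

    def test_mask_reproducible(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)),
                          columns=["fat", "protein", "sugar"])
        a = impose_missingness(df, 0.2, "sugar", seed=7)
        b = impose_missingness(df, 0.2, "sugar", seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestPresets:
    def test_study_scale_preset(self):
        ds = make_preset("paper124", seed=0)
        assert ds.dataset.n == 124
        assert ds.dataset.traits.data["sugar"].isna().sum() == 15
        np.testing.assert_allclose(ds.truth["h2"], [0.976, 0.997, 0.872], atol=1e-12)
        rp = ds.truth["r_p"]
        assert rp[0, 1] > 0 and rp[0, 2] < 0 and rp[1, 2] < 0

    def test_truth_records_generating_parameters(self):
        cfg = SimulationConfig(n_tips=32, n_shifts=1, alpha=0.5,
                               with_covariates=False, min_shift_clade=5,
                               sigma_r=np.zeros((3, 3)), sugar_missing_frac=0.0)
        ds = make_dataset(cfg, seed=3)
        assert len(ds.truth["shift_clades"]) == 1
        assert ds.truth["alpha"] == 0.5
        assert ds.truth["sigma_p"].shape == (3, 3)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("nope", seed=0)

    def test_write_round_trips_through_readers(self, tmp_path):
        from phylomilk import core

        ds = make_preset("tiny", seed=1)
        ds.write(tmp_path)
        tree = core.read_newick(tmp_path / "tree.nwk")
        traits = core.read_traits(tmp_path / "traits.csv")
        covs = core.read_covariates(tmp_path / "covariates.csv")
        aligned = core.trim_and_align(tree, traits, covs)
        assert aligned.n == ds.dataset.n
        np.testing.assert_allclose(
            aligned.traits.to_logit().data.to_numpy(),
            ds.dataset.traits.data.to_numpy(), atol=1e-6)


class TestPlantedCladeTree:
    def test_half_split_not_root_child(self):
        tree, edge = simulate_planted_clade_tree(64, seed=0)
        assert tree.n_tips == 64
        below = tree.tips_below()
        assert below[edge].sum() == 32
        assert tree.parent[edge] != 0
        assert tree.is_ultrametric(1e-6)

    def test_plant_shifts_disjoint_clades(self):
        tree = simulate_tree(124, seed=1)
        shifts, clades = plant_shifts(tree, 2, 8.0, np.eye(3), seed=1)
        assert len(shifts) == 2
        assert not (clades[0] & clades[1])
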