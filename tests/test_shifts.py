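import numpy as np
import pandas as pd
import pytest

from phylomilk.core import read_newick_string
from phylomilk.shifts import (
    back_transform_optima,
    equivalent_solutions,
    fit_shifts_em,
    half_life,
    scou_loglik,
    select_K,
    shift_design,
    tip_coloring,
)
from phylomilk.simulate import (
    SimulationConfig,
    make_dataset,
    make_preset,
    simulate_bm_traits,
    simulate_tree,
)
from phylomilk.transforms import logit


class TestHalfLife:
    def test_ln2_alpha_unit_height(self):
        assert half_life(np.log(2.0), 1.0) == pytest.approx(1.0)

    def test_weak_selection_value(self):
        # the fitted mammalian pull of 0.07 corresponds to ~9.9 tree heights
        assert half_life(0.07, 1.0) == pytest.approx(np.log(2) / 0.07, rel=1e-12)
        assert half_life(0.07, 1.0) == pytest.approx(9.902, abs=5e-3)

    def test_doubling_alpha_halves_half_life(self):
        assert half_life(0.4) == pytest.approx(2 * half_life(0.8))

    def test_nonpositive_alpha_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert half_life(0.0) == np.inf


class TestBackTransform:
    def test_zero_maps_to_fifty_percent(self):
        assert back_transform_optima(0.0) == pytest.approx(50.0)

    def test_pinniped_scale_value(self):
        assert back_transform_optima(logit(0.5978315)) == pytest.approx(
            59.78315, abs=1e-9)

    def test_round_trip(self, rng):
        theta = rng.normal(size=5)
        back = logit(back_transform_optima(theta) / 100.0)
        np.testing.assert_allclose(back, theta, atol=1e-10)


class TestScouLoglik:
    def test_alpha_zero_equals_bm_mixed_model(self, rng):
        from phylomilk.core import phylo_covariance
        from phylomilk.pmm import pmm_loglik

        tree = simulate_tree(9, seed=21)
        Y = rng.standard_normal((9, 3))
        rates = np.diag([0.5, 1.0, 1.5])
        root = np.array([0.2, -0.1, 0.4])
        A = phylo_covariance(tree)
        expected = pmm_loglik(Y, np.ones((9, 1)), A, rates, np.zeros((3, 3)),
                              root[None, :], jitter=0.0)
        got = scou_loglik(Y, tree, [], root, 0.0, rates, jitter=0.0)
        assert got == pytest.approx(expected, abs=1e-8)

    def test_continuity_at_alpha_zero(self, rng):
        tree = simulate_tree(8, seed=22)
        Y = rng.standard_normal((8, 2))
        rates = np.eye(2)
        root = np.zeros(2)
        l0 = scou_loglik(Y, tree, [], root, 0.0, rates)
        l_eps = scou_loglik(Y, tree, [], root, 1e-8, rates)
        assert abs(l_eps - l0) < 1e-4

    def test_long_branch_reaches_stationary_density(self):
        from scipy import stats

        tree = read_newick_string("(A:80,B:80);")
        alpha, rate, theta = 1.0, 2.0, 1.5
        y = np.array([[1.2], [1.9]])
        got = scou_loglik(y, tree, [], np.array([0.0]), alpha,
                          np.array([[rate]]), jitter=0.0)
        stationary = stats.norm.logpdf(y[:, 0], loc=theta * 0,
                                       scale=np.sqrt(rate / (2 * alpha))).sum()
        assert got == pytest.approx(stationary, abs=1e-6)

    def test_shift_order_irrelevant(self, rng):
        tree = simulate_tree(12, seed=23)
        internal = [i for i in range(1, tree.n_nodes) if not tree.is_tip[i]]
        e1, e2 = internal[0], internal[-1]
        Y = rng.standard_normal((12, 2))
        kw = dict(root=np.zeros(2), alpha=0.3, rates=np.eye(2))
        a = scou_loglik(Y, tree, [(e1, [1.0, 0.0]), (e2, [0.0, 1.0])], **kw)
        b = scou_loglik(Y, tree, [(e2, [0.0, 1.0]), (e1, [1.0, 0.0])], **kw)
        assert a == pytest.approx(b, abs=1e-10)

    def test_bad_edge_rejected(self, rng):
        tree = simulate_tree(6, seed=24)
        with pytest.raises(ValueError, match="does not exist"):
            scou_loglik(rng.standard_normal((6, 1)), tree, [(999, [1.0])],
                        np.zeros(1), 0.1, np.eye(1))


class TestDesignAndColoring:
    def test_coloring_partitions_tips(self):
        tree = simulate_tree(20, seed=25)
        internal = [i for i in range(1, tree.n_nodes) if not tree.is_tip[i]]
        edges = internal[:2]
        color = tip_coloring(tree, edges)
        assert color.shape == (20,)
        assert set(color) <= {0, 1, 2}

    def test_design_weights_bounded(self):
        tree = simulate_tree(15, seed=26)
        internal = [i for i in range(1, tree.n_nodes) if not tree.is_tip[i]]
        U = shift_design(tree, internal[:2], alpha=1.3)
        assert np.all(U[:, 0] == 1.0)
        assert np.all((U[:, 1:] >= 0) & (U[:, 1:] <= 1))
        U0 = shift_design(tree, internal[:2], alpha=0.0)
        assert set(np.unique(U0[:, 1:])) <= {0.0, 1.0}


def _shifted_dataset(seed):
    return make_preset("paper124_shifts", seed=seed)


class TestFitShifts:
    def test_k0_reduces_to_single_optimum(self):
        tree = simulate_tree(30, seed=27)
        vals = simulate_bm_traits(tree, np.eye(3), 0.5, seed=27)
        fit = fit_shifts_em(vals, tree, K=0)
        assert fit.K == 0
        assert fit.optima.shape == (1, 3)
        assert fit.shift_edges == ()
        assert list(fit.tip_regimes.unique()) == [0]

    def test_nested_loglik_improvement(self):
        tree = simulate_tree(40, seed=28)
        vals = simulate_bm_traits(tree, np.eye(3), 0.0, seed=28)
        lls = [fit_shifts_em(vals, tree, K=k, seed=0).loglik for k in range(3)]
        assert lls[1] >= lls[0] - 1e-6
        assert lls[2] >= lls[1] - 1e-6

    def test_strong_shifts_recovered_with_optima(self):
        ds = _shifted_dataset(seed=41)
        fit = fit_shifts_em(ds.dataset.traits.data, ds.dataset.tree, K=2, seed=1)
        got = set(map(frozenset, fit.shift_clades))
        truth = set(map(frozenset, ds.truth["shift_clades"]))
        assert got == truth
        # fitted displacement at the tips matches the planted displacement
        below = ds.dataset.tree.tips_below()
        tips = np.array(ds.dataset.tree.tip_labels)
        U = shift_design(ds.dataset.tree, fit.shift_edges, fit.alpha)
        fitted_disp = U[:, 1:] @ fit.deltas
        true_edges = ds.truth["shift_edges"]
        true_U = shift_design(ds.dataset.tree, true_edges, ds.truth["alpha"])
        true_disp = true_U[:, 1:] @ np.array(ds.truth["shift_deltas"])
        corr = np.corrcoef(fitted_disp.ravel(), true_disp.ravel())[0, 1]
        assert corr > 0.95

    def test_criterion_curve_and_selection(self):
        ds = _shifted_dataset(seed=42)
        fit = select_K(ds.dataset.traits.data, ds.dataset.tree, K_max=4, seed=2)
        assert list(fit.criterion_curve["K"]) == [0, 1, 2, 3, 4]
        assert fit.K == int(fit.criterion_curve.loc[
            fit.criterion_curve["criterion"].idxmin(), "K"])
        # nested improvement along the curve
        lls = fit.criterion_curve["loglik"].to_numpy()
        assert np.all(np.diff(lls) >= -1e-6)

    def test_imputation_recovers_masked_values(self):
        cfg = SimulationConfig(alpha=0.07, n_shifts=2, shift_size=8.0,
                               with_covariates=False, sigma_r=np.zeros((3, 3)),
                               sugar_missing_frac=15 / 124)
        ds = make_dataset(cfg, seed=43)
        # regenerate the unmasked truth by refitting conditional means
        fit = fit_shifts_em(ds.dataset.traits.data, ds.dataset.tree, K=2, seed=3)
        missing = ds.dataset.traits.data["sugar"].isna()
        assert missing.sum() == 15
        imput = fit.imputed.loc[missing, "sugar"]
        assert imput.notna().all()


class TestEquivalentSolutions:
    def test_k0_single_empty_solution(self):
        tree = simulate_tree(10, seed=29)
        assert equivalent_solutions(tree, []) == [()]

    def test_hand_built_degeneracy(self):
        # shifting the stem of one root-child cherry or the other root child
        # colors the tips identically (two blocks)
        tree = read_newick_string("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        cherry_stem = next(
            i for i in range(1, tree.n_nodes)
            if not tree.is_tip[i]
            and set(np.array(tree.tip_labels)[tree.tips_below()[i]]) == {"D", "E"}
        )
        sols = equivalent_solutions(tree, [cherry_stem])
        partitions = set()
        for s in sols:
            color = tip_coloring(tree, s)
            partitions.add(frozenset(
                frozenset(np.flatnonzero(color == c)) for c in np.unique(color)))
        assert len(partitions) == 1
        # the other root child (ABC clade) is the equivalent allocation
        other = next(
            i for i in range(1, tree.n_nodes)
            if not tree.is_tip[i]
            and set(np.array(tree.tip_labels)[tree.tips_below()[i]]) == {"A", "B", "C"}
        )
        assert (other,) in sols
        assert sols[0] == min(sols)

    def test_equivalent_solutions_share_loglik(self, rng):
        tree = read_newick_string("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        Y = rng.standard_normal((5, 2))
        cherry_stem = next(
            i for i in range(1, tree.n_nodes)
            if not tree.is_tip[i]
            and set(np.array(tree.tip_labels)[tree.tips_below()[i]]) == {"D", "E"}
        )
        sols = equivalent_solutions(tree, [cherry_stem])
        lls = []
        for s in sols:
            fit = fit_shifts_em(
                pd.DataFrame(Y, index=tree.tip_labels, columns=["fat", "protein"]),
                tree, K=1, alpha_grid=[0.0], n_restarts=0, seed=0)
            # refit restricted to each allocation via the likelihood directly
            from phylomilk.shifts import _AlphaWorkspace

            ws = _AlphaWorkspace(tree, Y, 0.0, list(s))
            lls.append(ws.gls(list(s))[2])
        assert max(lls) - min(lls) < 1e-6


class TestNullSelection:
    def test_pure_bm_selects_zero_shifts(self):
        ds = make_preset("bm_null", seed=44)
        fit = select_K(ds.dataset.traits.data, ds.dataset.tree, K_max=3, seed=4)
        assert fit.K == 0
        assert fit.equivalence == [()]
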