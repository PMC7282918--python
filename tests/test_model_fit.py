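import numpy as np
import pytest
from conftest import dense_gaussian_reml
from hypothesis import given
from hypothesis import strategies as st

from pulseshift import (
    FitResult,
    GridSettings,
    LevyModelSpec,
    ScaledTraitVector,
    SimulationConfig,
    aic_weights,
    fit_model,
    levy_char_exponent,
    levy_reml_loglik,
    read_newick,
    reml_gaussian_loglik,
    rescale_branches_eb,
    rescale_branches_ou,
    select_best,
    simulate_levy_traits,
    simulate_pure_birth_tree,
)
from pulseshift.model_fit import ComparisonTable


class TestOURescaling:
    def test_zero_pull_is_identity(self, three_tip):
        rt = rescale_branches_ou(three_tip, 0.0)
        assert np.allclose(rt.lengths, three_tip.lengths, atol=1e-9)

    def test_covariance_matches_closed_form(self, three_tip):
        a, T = 0.5, 2.0
        rt = rescale_branches_ou(three_tip, a)

        def V(s):  # OU covariance of two tips whose MRCA sits at depth s
            return np.exp(-2 * a * (T - s)) * (1 - np.exp(-2 * a * s)) / (2 * a)

        assert rt.node_depths[rt.mrca(["A", "B"])] == pytest.approx(V(1.0))
        for tip in rt.tip_indices:
            assert rt.node_depths[tip] == pytest.approx(V(T))

    def test_strong_pull_erases_shared_history(self, three_tip):
        rt = rescale_branches_ou(three_tip, 50.0)
        shared = rt.node_depths[rt.mrca(["A", "B"])]
        tipvar = rt.node_depths[rt.tip_indices[0]]
        assert shared / tipvar < 1e-10
        assert tipvar == pytest.approx(1.0 / 100.0, rel=1e-6)

    def test_small_alpha_continuity(self, yule10):
        rt = rescale_branches_ou(yule10, 1e-9)
        assert np.allclose(rt.lengths, yule10.lengths, rtol=1e-6)


class TestEBRescaling:
    def test_zero_rate_is_identity(self, three_tip):
        assert rescale_branches_eb(three_tip, 0.0) is three_tip

    def test_unit_branch_integral(self):
        t = rescale_branches_eb(read_newick("(A:1,B:1);"), -1.0)
        assert np.allclose(t.lengths[t.tip_indices], 1 - np.exp(-1))

    def test_rescaled_tree_remains_ultrametric(self, yule10):
        rt = rescale_branches_eb(yule10, -0.1)
        tips = rt.node_depths[rt.tip_indices]
        assert tips.max() - tips.min() < 1e-9

    def test_positive_rate_rejected(self, three_tip):
        with pytest.raises(ValueError, match="<= 0"):
            rescale_branches_eb(three_tip, 0.1)


class TestCharExponent:
    def test_bm_value(self):
        psi = levy_char_exponent(LevyModelSpec("BM", {"sigma2": 2.0}), 1.0)
        assert psi == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "spec",
        [
            LevyModelSpec("BM", {"sigma2": 1.0}),
            LevyModelSpec("JN", {"lam": 1.0, "delta": 1.0}),
            LevyModelSpec("NIG", {"alpha_nig": 2.0, "delta_nig": 1.0}),
            LevyModelSpec("BMJN", {"sigma2": 1.0, "lam": 0.5, "delta": 2.0}),
        ],
    )
    def test_zero_frequency_is_zero(self, spec):
        assert levy_char_exponent(spec, 0.0) == 0.0

    def test_jn_small_k_matches_bm_of_rate_lam_delta_sq(self):
        spec = LevyModelSpec("JN", {"lam": 1.0, "delta": 1.0})
        k = 1e-3
        psi = levy_char_exponent(spec, k).real
        assert psi == pytest.approx(-0.5 * 1.0 * k**2, rel=1e-5)

    def test_eb_variants_have_no_homogeneous_exponent(self):
        with pytest.raises(ValueError, match="homogeneous"):
            levy_char_exponent(
                LevyModelSpec("EBJN", {"r": -0.1, "lam": 1.0, "delta": 1.0}), 1.0
            )


class TestGaussianREML:
    def test_two_tip_closed_form(self, cherry):
        trait = ScaledTraitVector(["A", "B"], [0.0, 2.0])
        spec = LevyModelSpec("BM", {"sigma2": 1.0, "sigma_tip": 0.0})
        # one contrast of -2 with variance 2
        expected = -0.5 * np.log(4 * np.pi) - 1.0
        assert reml_gaussian_loglik(cherry, trait, spec) == pytest.approx(expected)

    def test_tip_noise_equals_pendant_lengthening(self, yule10, yule10_bm_trait):
        sigma2, c = 0.7, 0.5
        with_noise = reml_gaussian_loglik(
            yule10, yule10_bm_trait,
            LevyModelSpec("BM", {"sigma2": sigma2, "sigma_tip": np.sqrt(c)}),
        )
        lengths = yule10.lengths.copy()
        lengths[yule10.tip_indices] += c / sigma2
        stretched = yule10.with_lengths(lengths)
        plain = reml_gaussian_loglik(
            stretched, yule10_bm_trait,
            LevyModelSpec("BM", {"sigma2": sigma2, "sigma_tip": 0.0}),
        )
        assert with_noise == pytest.approx(plain, abs=1e-9)

    @pytest.mark.parametrize(
        "spec",
        [
            LevyModelSpec("BM", {"sigma2": 0.8, "sigma_tip": 0.2}),
            LevyModelSpec("OU", {"sigma2": 0.8, "alpha_ou": 0.03, "sigma_tip": 0.2}),
            LevyModelSpec("EB", {"sigma2": 2.0, "r": -0.04, "sigma_tip": 0.2}),
        ],
    )
    def test_matches_dense_covariance_oracle(self, yule10, yule10_bm_trait, spec):
        from pulseshift.model_fit import _rescaled_tree

        ll = reml_gaussian_loglik(yule10, yule10_bm_trait, spec)
        oracle = dense_gaussian_reml(
            yule10, yule10_bm_trait, spec.params["sigma2"], spec.sigma_tip,
            rescaled=_rescaled_tree(yule10, spec),
        )
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_polytomy_accepted(self):
        star = read_newick("(A:1,B:1,C:1,D:1);")
        trait = ScaledTraitVector(list("ABCD"), [0.0, 1.0, -1.0, 0.5])
        spec = LevyModelSpec("BM", {"sigma2": 1.0, "sigma_tip": 0.0})
        ll = reml_gaussian_loglik(star, trait, spec)
        oracle = dense_gaussian_reml(star, trait, 1.0, 0.0)
        assert ll == pytest.approx(oracle, abs=1e-10)


class TestLevyGridLikelihood:
    def test_gaussian_models_agree_with_contrasts(self, yule10, yule10_bm_trait):
        spec = LevyModelSpec("BM", {"sigma2": 0.8, "sigma_tip": 0.2})
        exact = reml_gaussian_loglik(yule10, yule10_bm_trait, spec)
        grid = levy_reml_loglik(yule10, yule10_bm_trait, spec)
        assert grid == pytest.approx(exact, abs=1e-3)

    def test_bmjn_without_jumps_reduces_to_bm(self, yule10, yule10_bm_trait):
        bm = reml_gaussian_loglik(
            yule10, yule10_bm_trait,
            LevyModelSpec("BM", {"sigma2": 0.8, "sigma_tip": 0.2}),
        )
        bmjn = levy_reml_loglik(
            yule10, yule10_bm_trait,
            LevyModelSpec("BMJN", {"sigma2": 0.8, "lam": 0.0, "delta": 1.0,
                                   "sigma_tip": 0.2}),
        )
        assert bmjn == pytest.approx(bm, abs=1e-4)

    def test_grid_refinement_self_consistency(self, yule10, yule10_bm_trait):
        spec = LevyModelSpec("JN", {"lam": 0.05, "delta": 3.0, "sigma_tip": 0.5})
        a = levy_reml_loglik(yule10, yule10_bm_trait, spec, GridSettings(1024))
        b = levy_reml_loglik(yule10, yule10_bm_trait, spec, GridSettings(2048))
        assert a == pytest.approx(b, abs=1e-3)

    def test_invariant_to_adding_a_constant(self, yule10, yule10_bm_trait):
        spec = LevyModelSpec("JN", {"lam": 0.05, "delta": 3.0, "sigma_tip": 0.3})
        shifted = ScaledTraitVector(
            yule10_bm_trait.species, yule10_bm_trait.values + 37.5
        )
        a = levy_reml_loglik(yule10, yule10_bm_trait, spec)
        b = levy_reml_loglik(yule10, shifted, spec)
        assert a == pytest.approx(b, abs=1e-6)

    def test_too_small_grid_extent_is_a_hard_error(self, yule10, yule10_bm_trait):
        spec = LevyModelSpec("JN", {"lam": 10.0, "delta": 50.0, "sigma_tip": 0.1})
        with pytest.raises(ValueError, match="grid extent"):
            levy_reml_loglik(
                yule10, yule10_bm_trait, spec, GridSettings(64, pad=0.5)
            )


class TestFitting:
    def test_nested_jump_model_attains_gaussian_optimum(self):
        tree = simulate_pure_birth_tree(20, 60, seed=21)
        trait = simulate_levy_traits(
            tree, SimulationConfig("BM", {"sigma2": 1.0}, tip_noise_sd=0.1, seed=22)
        )
        bm = fit_model(tree, trait, "BM", restarts=4, seed=0)
        bmjn = fit_model(tree, trait, "BMJN", restarts=4, maxfun=200, seed=0,
                         grid=GridSettings(1024, 2.0))
        assert bmjn.loglik >= bm.loglik - 1e-3
        ou = fit_model(tree, trait, "OU", restarts=4, seed=0)
        eb = fit_model(tree, trait, "EB", restarts=4, seed=0)
        assert ou.loglik >= bm.loglik - 1e-4
        assert eb.loglik >= bm.loglik - 1e-4

    def test_eb_rate_change_near_zero_on_bm_data(self):
        hits = 0
        for rep in range(5):
            tree = simulate_pure_birth_tree(50, 60, seed=40 + rep)
            trait = simulate_levy_traits(
                tree,
                SimulationConfig("BM", {"sigma2": 1.0}, tip_noise_sd=0.1,
                                 seed=50 + rep),
            )
            fit = fit_model(tree, trait, "EB", restarts=4, seed=rep)
            hits += abs(fit.spec.params["r"]) < 0.02
        assert hits >= 4

    def test_sigma_tip_recovery_tracks_truth(self):
        # tip noise must be sizeable relative to pendant-branch variance to
        # be identifiable; 3 replicate measurements feed the species means
        from scipy import stats

        tree = simulate_pure_birth_tree(100, 60, seed=42)
        rng = np.random.default_rng(777)
        truth, est = [], []
        for rep in range(30):
            st_true = float(rng.uniform(0.5, 3.0))
            trait = simulate_levy_traits(
                tree, SimulationConfig("BM", {"sigma2": 1.0}, seed=30_000 + rep)
            )
            reps = trait.values[:, None] + rng.normal(0, st_true, (tree.n_tips, 3))
            means = ScaledTraitVector(trait.species, reps.mean(axis=1))
            fit = fit_model(tree, means, "BM", restarts=3, seed=rep)
            truth.append(st_true)
            est.append(fit.spec.params["sigma_tip"])
        assert stats.spearmanr(truth, est).statistic > 0.5


class TestAkaikeWeights:
    @staticmethod
    def _fit(model, aic):
        k = 2
        return FitResult(
            LevyModelSpec(model, {"sigma2": 1.0}), (2 * k - aic) / 2, k, aic, True, 1
        )

    def test_frozen_weight_example(self):
        fits = [self._fit(m, a) for m, a in zip(("BM", "OU", "EB"), (100, 102, 104))]
        table = aic_weights(fits)
        w = [table.model_weights[m] for m in ("BM", "OU", "EB")]
        assert w == pytest.approx([0.6652, 0.2447, 0.0900], abs=5e-5)
        assert sum(table.model_weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_equal_aic_gives_uniform_weights(self):
        fits = [self._fit(m, 50.0) for m in ("BM", "OU", "EB", "JN")]
        table = aic_weights(fits)
        assert all(
            w == pytest.approx(0.25, abs=1e-12) for w in table.model_weights.values()
        )

    def test_pulsed_class_is_maximum_jump_weight(self):
        # engineer AICs whose weights are known ratios
        names = ("BM", "OU", "EB", "JN", "NIG", "BMJN", "BMNIG", "EBJN", "EBNIG")
        aics = (100.0, 101.0, 102.0, 100.5, 103.0, 104.0, 105.0, 106.0, 107.0)
        table = aic_weights([self._fit(m, a) for m, a in zip(names, aics)])
        assert table.class_weights["pulsed"] == pytest.approx(
            table.model_weights["JN"]
        )
        summed = aic_weights(
            [self._fit(m, a) for m, a in zip(names, aics)], pulsed_aggregate="sum"
        )
        assert summed.class_weights["pulsed"] == pytest.approx(
            sum(table.model_weights[m] for m in names[3:])
        )

    def test_refuses_unconverged_fits(self):
        bad = FitResult(LevyModelSpec("JN", {"lam": 1, "delta": 1}), -np.inf, 3,
                        np.inf, False, 1)
        with pytest.raises(ValueError, match="non-converged"):
            aic_weights([self._fit("BM", 10.0), bad])

    @given(st.lists(st.floats(0, 500), min_size=2, max_size=9, unique=True))
    def test_weights_always_sum_to_one(self, aics):
        names = ("BM", "OU", "EB", "JN", "NIG", "BMJN", "BMNIG", "EBJN", "EBNIG")
        fits = [self._fit(m, a) for m, a in zip(names, aics)]
        table = aic_weights(fits)
        assert sum(table.model_weights.values()) == pytest.approx(1.0, abs=1e-9)


class TestSelectionRule:
    @staticmethod
    def _table(weights):
        return ComparisonTable({}, weights, {}, {}, "")

    def test_twofold_margin_selects(self):
        t = self._table({"pulsed": 0.60, "BM": 0.20, "OU": 0.12, "EB": 0.08})
        assert select_best(t) == "pulsed"

    def test_insufficient_margin_is_inconclusive(self):
        t = self._table({"pulsed": 0.45, "BM": 0.30, "OU": 0.15, "EB": 0.10})
        assert select_best(t) == "inconclusive"

    def test_lectin_like_row_selects_pulsed(self):
        # one venom lectin family shows BM 0.002 and pulsed 0.979
        t = self._table({"BM": 0.002, "OU": 0.0, "EB": 0.0, "pulsed": 0.979})
        assert select_best(t) == "pulsed"
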