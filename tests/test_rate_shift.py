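import numpy as np
import pytest
from scipy import stats

from pulseshift import (
    LevyModelSpec,
    PosteriorSample,
    RegimePainting,
    SamplerSettings,
    ScaledTraitVector,
    Shift,
    ShiftConfiguration,
    SimulationConfig,
    best_shift_configuration,
    branch_rates,
    compute_bayes_factor,
    credible_shift_set,
    effective_branch_lengths,
    ess,
    rate_through_time,
    read_newick,
    reml_gaussian_loglik,
    rjmcmc_run,
    shifted_bm_loglik,
    simulate_levy_traits,
    simulate_pure_birth_tree,
    simulate_shifted_bm,
)
from pulseshift.rate_shift import annotated_newick


class TestEffectiveLengths:
    def test_constant_rate_rectangle(self):
        tree = read_newick("(A:3,B:3);")
        eff = effective_branch_lengths(tree, ShiftConfiguration(root_beta=2.0))
        assert np.allclose(eff[tree.tip_indices], 6.0)

    def test_decaying_rate_integral(self):
        tree = read_newick("(A:1,B:1);")
        eff = effective_branch_lengths(
            tree, ShiftConfiguration(root_beta=1.0, root_b=-1.0)
        )
        assert np.allclose(eff[tree.tip_indices], 1 - np.exp(-1))

    def test_b_to_zero_continuity(self):
        tree = read_newick("(A:3,B:3);")
        eff = effective_branch_lengths(
            tree, ShiftConfiguration(root_beta=2.0, root_b=1e-12)
        )
        assert np.allclose(eff[tree.tip_indices], 6.0, atol=1e-9)

    def test_shift_partitions_branch(self):
        tree = read_newick("(A:4,B:4);")
        tip = int(tree.tip_indices[0])
        cfg = ShiftConfiguration(root_beta=1.0, shifts=(Shift(tip, 1.0, 5.0),))
        eff = effective_branch_lengths(tree, cfg)
        assert eff[tip] == pytest.approx(1.0 * 1.0 + 3.0 * 5.0)

    def test_shift_beyond_branch_rejected(self):
        tree = read_newick("(A:4,B:4);")
        cfg = ShiftConfiguration(
            root_beta=1.0, shifts=(Shift(int(tree.tip_indices[0]), 9.0, 5.0),)
        )
        with pytest.raises(ValueError, match="beyond branch"):
            effective_branch_lengths(tree, cfg)


class TestShiftedBMLoglik:
    def test_zero_shifts_equals_constant_bm(self, yule10, yule10_bm_trait):
        ll = shifted_bm_loglik(yule10, yule10_bm_trait,
                               ShiftConfiguration(root_beta=0.9))
        bm = reml_gaussian_loglik(
            yule10, yule10_bm_trait,
            LevyModelSpec("BM", {"sigma2": 0.9, "sigma_tip": 0.0}),
        )
        assert ll == pytest.approx(bm, abs=1e-9)

    def test_true_shift_raises_likelihood(self):
        wins = []
        for rep in range(6):
            tree = simulate_pure_birth_tree(30, 60, seed=300 + rep)
            br = next(
                int(v) for v in tree.preorder[1:]
                if not tree.is_tip[v] and 8 <= len(tree.descendant_tips(v)) <= 15
            )
            cfg = ShiftConfiguration(
                root_beta=1.0, shifts=(Shift(br, tree.lengths[br] / 2, 8.0),)
            )
            trait = simulate_shifted_bm(
                tree, RegimePainting(cfg),
                SimulationConfig("SHIFTED_BM", seed=400 + rep),
            )
            with_shift = shifted_bm_loglik(tree, trait, cfg)
            without = shifted_bm_loglik(tree, trait,
                                        ShiftConfiguration(root_beta=1.0))
            wins.append(with_shift - without)
        assert np.median(wins) > 0

    def test_location_scale_consistency(self, yule10, yule10_bm_trait):
        # scaling all rates by c and the data by sqrt(c) shifts the REML
        # loglik by -(n-1)/2 * log(c) (Gaussian scaling identity)
        c = 4.0
        cfg = ShiftConfiguration(root_beta=1.0)
        cfg_scaled = ShiftConfiguration(root_beta=c)
        scaled = ScaledTraitVector(
            yule10_bm_trait.species, yule10_bm_trait.values * np.sqrt(c)
        )
        a = shifted_bm_loglik(yule10, yule10_bm_trait, cfg)
        b = shifted_bm_loglik(yule10, scaled, cfg_scaled)
        n = yule10.n_tips
        assert b == pytest.approx(a - 0.5 * (n - 1) * np.log(c), abs=1e-6)


def _make_sample(tree, ks, branches=None, gamma=1.0, betas=None):
    """Construct a PosteriorSample by hand (one shift max per draw)."""
    n = len(ks)
    m = 5
    sbr = np.zeros((n, m), dtype=np.int64)
    spos = np.zeros((n, m))
    sbeta = np.ones((n, m))
    sb = np.zeros((n, m))
    for i, k in enumerate(ks):
        if k:
            sbr[i, 0] = branches[i]
            sbeta[i, 0] = betas[i] if betas is not None else 2.0
    return PosteriorSample(
        tree,
        SamplerSettings(expected_shifts=gamma, max_shifts=m),
        np.asarray(ks, dtype=np.int64),
        np.zeros(n),
        np.zeros(n),
        sbr, spos, sbeta, sb,
        np.ones(n), np.zeros(n),
    )


class TestBayesFactor:
    def test_even_split_arithmetic(self, yule10):
        ks = [0] * 500 + [1] * 500
        branches = [0] * 500 + [int(yule10.tip_indices[0])] * 500
        sample = _make_sample(yule10, ks, branches)
        bf = compute_bayes_factor(sample)
        assert bf.bayes_factor == pytest.approx(1.0 / (np.e - 1.0), rel=1e-9)
        assert not bf.is_lower_bound

    def test_posterior_equal_to_prior_gives_unit_bf(self, yule10):
        n0 = 3679  # ~ e^{-1} of 10000
        ks = [0] * n0 + [1] * (10_000 - n0)
        branches = [0] * n0 + [int(yule10.tip_indices[0])] * (10_000 - n0)
        bf = compute_bayes_factor(_make_sample(yule10, ks, branches))
        assert bf.bayes_factor == pytest.approx(1.0, abs=2e-3)

    def test_no_zero_samples_reports_lower_bound(self, yule10):
        ks = [1] * 1000
        branches = [int(yule10.tip_indices[0])] * 1000
        bf = compute_bayes_factor(_make_sample(yule10, ks, branches))
        assert bf.is_lower_bound
        assert bf.bayes_factor == pytest.approx(999 / ((1 - np.e**-1) / np.e**-1))


class TestCredibleShiftSet:
    def test_all_zero_shift_posterior(self, yule10):
        cs = credible_shift_set(_make_sample(yule10, [0] * 100))
        assert len(cs.entries) == 1
        assert cs.entries[0].branches == frozenset()
        assert cs.entries[0].probability == 1.0

    def test_sixty_forty_configurations_ranked(self, yule10):
        # the 60% class has a shift on one short branch, 40% none
        br = int(np.argmin(np.where(np.arange(yule10.n_nodes) == yule10.root,
                                    np.inf, yule10.lengths)))
        ks = [1] * 60 + [0] * 40
        branches = [br] * 60 + [0] * 40
        cs = credible_shift_set(_make_sample(yule10, ks, branches), 0.95)
        assert [e.branches for e in cs.entries] == [frozenset({br}), frozenset()]
        assert cs.entries[0].probability == pytest.approx(0.6)
        assert best_shift_configuration(
            _make_sample(yule10, ks, branches)
        ).shifts[0].branch == br

    def test_scattered_shifts_collapse_to_empty_key(self, yule10):
        # one shift per draw, placed uniformly on the tree (branch choice
        # proportional to length): every branch's marginal probability then
        # matches its prior expectation, so no core shifts survive
        branches = np.array([v for v in range(yule10.n_nodes) if v != yule10.root])
        p = yule10.lengths[branches] / yule10.lengths[branches].sum()
        rng = np.random.default_rng(0)
        brs = list(rng.choice(branches, size=2000, p=p))
        ks = [1] * len(brs)
        cs = credible_shift_set(_make_sample(yule10, ks, brs, gamma=1.0))
        assert cs.core_branches == frozenset() or all(
            len(e.branches) == 0 for e in cs.entries
        )
        assert cs.entries[0].branches == frozenset()


class TestSampler:
    def test_bit_reproducible_for_fixed_seed(self, yule10, yule10_bm_trait):
        s = SamplerSettings(generations=30_000, thin=50, seed=7)
        a = rjmcmc_run(yule10, yule10_bm_trait, s)
        b = rjmcmc_run(yule10, yule10_bm_trait, s)
        assert np.array_equal(a.k, b.k)
        assert np.array_equal(a.loglik, b.loglik)
        assert np.array_equal(a.shift_beta, b.shift_beta)

    def test_flat_likelihood_matches_prior_mean(self):
        tree = simulate_pure_birth_tree(20, 60, seed=2)
        with pytest.warns(RuntimeWarning):
            post = rjmcmc_run(
                tree, None,
                SamplerSettings(generations=400_000, thin=100, seed=3,
                                flat_likelihood=True),
            )
        assert post.k.mean() == pytest.approx(1.0, abs=0.1)
        assert (post.k == 0).mean() == pytest.approx(np.exp(-1), abs=0.04)

    def test_posterior_rate_concentrates_on_truth(self):
        # zero-shift BM data: posterior mean rate near sigma2 = 1
        hits = 0
        for rep in range(5):
            tree = simulate_pure_birth_tree(100, 60, seed=800 + rep)
            trait = simulate_levy_traits(
                tree, SimulationConfig("BM", {"sigma2": 1.0}, seed=900 + rep)
            )
            post = rjmcmc_run(
                tree, trait, SamplerSettings(generations=400_000, thin=200,
                                             seed=rep)
            )
            eff = post.effective_lengths_matrix()
            nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
            mean_rate = float(
                (eff[:, nonroot].sum(axis=1) / tree.lengths[nonroot].sum()).mean()
            )
            hits += abs(mean_rate - 1.0) <= 0.25
        assert hits >= 4

    def test_event_log_roundtrip(self, yule10, yule10_bm_trait, tmp_path):
        post = rjmcmc_run(
            yule10, yule10_bm_trait,
            SamplerSettings(generations=20_000, thin=100, seed=1),
        )
        path = tmp_path / "events.tsv"
        post.to_event_log(path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(post) + 2  # comment + header


class TestRateThroughTime:
    def test_constant_rate_posterior_is_flat(self, yule10):
        sample = _make_sample(yule10, [0] * 50)
        rtt = rate_through_time(sample, grid=16)
        assert np.allclose(rtt.mean, 1.0)
        assert np.allclose(rtt.upper - rtt.lower, 0.0)

    def test_decaying_regime_is_monotone(self, yule10):
        sample = _make_sample(yule10, [0] * 10)
        sample.root_b[:] = -0.05
        rtt = rate_through_time(sample, grid=24)
        rates_by_age = rtt.mean[np.argsort(rtt.times_before_present)]
        # older times have higher rate when b < 0
        assert np.all(np.diff(rates_by_age) >= -1e-12)

    def test_clade_restriction_sees_shifted_rate(self):
        tree = read_newick("(((A:10,B:10):20,(C:10,D:10):20):30,(E:20,F:20):40);")
        stem = int(tree.mrca(["A", "B", "C", "D"]))
        ks = [1] * 30
        sample = _make_sample(tree, ks, [stem] * 30, betas=[10.0] * 30)
        inside = rate_through_time(sample, clade=["A", "B", "C", "D"], grid=20)
        outside = rate_through_time(sample, clade=["E", "F"], grid=20)
        recent = rtt_idx = np.argmin(inside.times_before_present)
        assert inside.mean[recent] == pytest.approx(10.0)
        assert outside.mean[np.argmin(outside.times_before_present)] == pytest.approx(1.0)

    def test_times_before_clade_origin_absent(self):
        tree = read_newick("(((A:10,B:10):20,(C:10,D:10):20):30,(E:20,F:20):40);")
        sample = _make_sample(tree, [0] * 10)
        rtt = rate_through_time(sample, clade=["A", "B"], grid=30)
        old = rtt.times_before_present > 10.0 + 1e-9  # crown age of (A,B) = 10
        assert np.all(np.isnan(rtt.mean[old]))
        assert not np.any(np.isnan(rtt.mean[~old]))

    def test_branch_rates_and_annotation(self, yule10):
        sample = _make_sample(yule10, [0] * 20)
        df = branch_rates(sample)
        assert np.allclose(df.mean_rate, 1.0)
        nwk = annotated_newick(sample)
        assert "&rate=" in nwk


class TestESS:
    def test_iid_draws_near_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1000)
        assert 800 <= ess(x) <= 1000

    def test_ar1_autocorrelation_time(self):
        rng = np.random.default_rng(2)
        rho, n = 0.9, 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + rng.normal() * np.sqrt(1 - rho**2)
        expected = n * (1 - rho) / (1 + rho)  # ~526
        assert ess(x) == pytest.approx(expected, rel=0.30)

    def test_agrees_with_arviz_on_ar1(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = np.empty(5000)
        x[0] = rng.normal()
        for i in range(1, 5000):
            x[i] = 0.7 * x[i - 1] + rng.normal()
        ours = ess(x)
        theirs = float(az.ess(x))
        assert ours == pytest.approx(theirs, rel=0.3)

    def test_alternating_series_capped_at_n(self):
        x = np.tile([1.0, -1.0], 500)
        assert ess(x) == 1000.0

    def test_constant_series_flagged(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert ess(np.ones(100)) == 100.0
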