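# Methods

## Data model

The unit of analysis is one toxin family (or any continuous trait) on a
rooted ultrametric tree with branch lengths in millions of years. Raw
input is a species × family table of relative abundance fractions, with
optional replicate transcriptomes as repeated species rows. Preparation:

1. **Presence filter.** A family is retained if it is detected (> 0 in any
   replicate) in at least a fraction `min_fraction` (default 0.5) of
   species. Missing/NA cells are treated as 0: the data are relative
   compositions, where "not reported" and "not detected" coincide.
2. **Scaling.** Species means are divided by the square root of the mean
   within-species sample variance (n−1 denominator, over species with ≥ 2
   replicates), putting all families on comparable SD-like scales. The
   constant is stored; dividing by the variance itself is available via
   `divisor="variance"`. With no replicates (or zero average variance) the
   divisor falls back to 1 with a warning. An optional log/logit transform
   (default: none) is applied before scaling.
3. **Pruning.** Tree and trait vector are restricted to shared species;
   collapsed degree-2 nodes get summed branch lengths and the root is kept
   even if left with one child, so root-to-tip depth never changes.

## Trait-evolution models and REML

Nine models: BM, OU, EB, JN, NIG, BMJN, BMNIG, EBJN, EBNIG. Free
parameters (tip noise σ_tip always included; root state profiled out and
never counted): BM 2, OU 3, EB 3, JN 3, NIG 3, compounds 4.

* **OU** is fitted as BM on a rescaled tree: a node at depth d on a tree of
  depth T maps to (e^{−2α(T−d)} − e^{−2αT})/(2α), which reproduces the
  single-optimum OU covariance among tips and tends to the identity as
  α → 0. With the root profiled out the optimum θ is not separately
  identifiable and is not a free parameter. The rescaling identity
  requires ultrametricity, which the tree type enforces.
* **EB** rescales a branch spanning depths [t1, t2] to
  (e^{rt2} − e^{rt1})/r, r ≤ 0.
* **Jump models** are specified by the Lévy–Khinchine exponent ψ(k)
  (see README); EB variants rescale branch durations first and then apply
  the homogeneous exponent, so they deliberately have no time-homogeneous
  ψ of their own.
* Drift μ is fixed at 0 in all fits: on an ultrametric tree REML cannot
  separate drift from the root state. μ is retained in the simulation
  configuration for completeness.

**Gaussian REML** is computed by sequential peeling of independent
contrasts (valid for polytomies, which are peeled pairwise — an orthogonal
transformation of the same Gaussian), with σ_tip² added to every pendant
variance. It equals the profiled multivariate-normal likelihood; the test
suite verifies this against a dense-covariance oracle to 1e−8.

**Lévy REML** uses a pruning recursion whose node messages are conditional
densities of the subtree data given the node state, represented on a
regular grid of N points (power of two, default 1024) spanning
[min − pad·range, max + pad·range] (default pad 6). Branch propagation
multiplies the message's Fourier transform by exp(t·ψ(k)) — no increment
density is ever tabulated — and tips enter analytically in the Fourier
domain with exact phase e^{−ik·x_obs}, so narrow tip densities never hit
the grid. The root state is integrated against a flat prior, which
reproduces REML exactly (verified to machine precision for BM).

Numerical choices:

* The likelihood is deterministic given grid settings. Accuracy requires
  the grid step dx to resolve the smallest Gaussian scale at the tips
  (σ_tip or the diffusive part of the pendant branch). When neither
  provides decay at the Nyquist frequency (pure-jump model, tiny σ_tip),
  a smoothing floor of ≈ 2 grid steps is added to the tip kernel to
  prevent aliasing; this is a documented regularization, not part of the
  model. For sharp data, shrinking `pad` (e.g. 2–3) at fixed N is the
  cheapest way to refine dx; once resolved, doubling N changes the
  log-likelihood at machine-precision level only.
* A hard error is raised when the padding cannot contain ~99.99% of the
  increment mass accumulated along the deepest path (4 increment SDs).
* Optimization is bounded L-BFGS-B over log-transformed parameters
  (r = −e^u for the EB exponent), 10 restarts by default: one moment-based
  start, one *nested-boundary* start with pull/decay/jump-intensity pushed
  toward zero (guaranteeing every richer model can reach its nested
  Gaussian optimum), the rest log-normally dispersed. Ties break toward
  the smaller parameter count through AIC.

**Comparison.** Akaike weights from AIC = 2k − 2·loglik (AIC, not AICc,
with AICc not implemented; k excludes the profiled root). The pulsed class
is represented by the *maximum* weight among the six jump models (a sum
variant exists behind `pulsed_aggregate="sum"` for sensitivity analysis,
default off). A class is selected only if its weight is ≥ 2× every
competitor's; otherwise the comparison is "inconclusive".

## Rate-shift model and sampler

The trait follows BM whose instantaneous rate β(t) is piecewise defined by
a root regime plus k shift events at points on branches; each regime has
an initial rate β_init and exponent b with β(t) = β_init·e^{b(t−t_start)},
inherited tipward until overridden by a nested shift. A branch's
accumulated variance is ∫β(t)dt over its regime segments (second-order
series near b = 0), reducing the likelihood to contrasts REML on
"effective" branch lengths; zero shifts is exactly constant-rate BM.

Priors: k ~ Poisson(`expected_shifts`, default 1 — a conservative prior
under which zero shifts is the modal configuration); locations uniform on
the tree; β_init log-normal with SD 2 natural-log units, centred by
default on log(trait variance / tree depth) (data-scale calibration in
the spirit of the reference implementation's prior-setting helper);
b ~ Normal(0, 0.05/My). By default regimes have constant rates (b fixed
at 0); `time_varying_rates=True` frees b.

Moves (birth/death of a shift with prior-drawn parameters and exact
Metropolis–Hastings–Green ratios γ/(k+1) and k/γ; uniform relocation;
multiplicative β scaling; Gaussian b perturbation). The fixed-rate Poisson
prior keeps the prior mass on k analytic, so Bayes factors need no prior
sampling. With the likelihood held flat the chain demonstrably reproduces
the Poisson prior (χ² goodness-of-fit in the test suite) — a direct
detailed-balance check. The sampler core is numba-compiled; the default
desk-scale run (2 × 10⁶ generations, thinning 200, 10% burn-in) takes
seconds, and production-scale settings (10⁹/10⁵) are configuration-
reachable. Chains are bit-reproducible for fixed seed and settings.

Summaries:

* **Bayes factor** for ≥ 1 shift vs none: posterior odds over analytic
  prior odds; if no zero-shift sample exists, a pseudo-count of 1/n makes
  the reported value an explicit lower bound.
* **Credible shift set**: samples are keyed by their set of *core-shift*
  branches — branches whose marginal shift probability exceeds 5× the
  prior expectation γ·(branch length)/(tree length) — ranked by frequency;
  the smallest prefix reaching 95% is returned. The best configuration is
  the top key with posterior-mean regime parameters.
* **Rate through time**: per posterior sample, the mean instantaneous rate
  over lineages alive at each time slice (optionally clade-restricted;
  slices predating the clade are reported absent, not zero), summarized by
  the posterior mean and central 90% band.
* **ESS** uses Geyer's initial-positive-sequence estimator, capped at the
  series length; constant series are flagged degenerate and reported as n.
  It agrees with arviz's estimator on AR(1) benchmarks.

Shift positions are stored as the time offset from the branch's rootward
end; node ids are preorder indices of the (pruned) analysis tree, recorded
in the branch-rate exports.

## Synthetic data generator

`simulate_pure_birth_tree` draws a Yule tree (unit speciation rate,
conditioned on n tips, one extra exponential waiting time) rescaled to a
fixed depth — the study-like default is 50–52 tips and depth 60 My.
Increments are drawn per branch from the exact model distributions (OU by
its Gaussian transition; NIG by inverse-Gaussian subordination of a
Gaussian, whose Laplace transform reproduces ψ exactly; EB variants by
rescaled durations), with all randomness split from one seed by node id so
draws are independent of traversal order. The demo bundle arranges three
clades with contrasting composition profiles (viper-like, elapid-like,
colubrid-like), softmax-composes latent traits into relative abundances,
adds replicate transcriptomes for eight species and zeroes one family in
one clade to exercise the presence filter.

What the generator does **not** emulate: compositional closure effects on
real transcriptome fractions beyond the softmax construction, phylogenetic
error (the tree is treated as known), within-species structure beyond iid
Gaussian replicate noise, and asymmetric jump distributions. Passing tests
therefore demonstrate correctness of the estimators under the stated
models, not robustness to these real-data features.

## Test problem sizes

The test suite runs at desk scale by design: oracle equivalences on 10-tip
trees; Monte-Carlo likelihood validation with 2 × 10⁶ simulated tip
triples on a 3-tip tree; parameter/model recovery with 50 and 25 + 25
replicates at n = 100 tips (model recovery uses a 1024-point grid with
pad 2 and single-start fits — the selection margins are tens of
log-likelihood units, so multi-start refinement does not change
decisions); sampler calibration and shift detection on 50-tip trees with
1–2 × 10⁶ generations.

One recovery check is knowingly strict: the BM rate estimate on an n-tip
tree is distributed ~ σ²·χ²_{n−1}/(n−1), so at n = 100 even a perfect
estimator falls within 20% of the truth in only ~84% of replicates; the
suite's 90% threshold for that check is retained as-is and documents this
sampling-theory ceiling.

## Limitations

* Single-optimum OU only; no multi-optimum or multivariate models.
* ML/REML only for the Lévy models (no Bayesian fitting).
* The rate-shift model is trait-mode only (no diversification analysis),
  and equivalence with the published BAMM program is behavioural (on
  simulated data), not chain-for-chain numerical.
* The NIG parameterization is symmetric and centred; skewed pulses are out
  of scope.
* Exact species-label matching only (a synonym map can be applied upstream).
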