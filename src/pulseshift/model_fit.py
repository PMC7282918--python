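"""REML fitting and Akaike-weight comparison of nine trait-evolution models.

Incremental models (BM, OU, EB) are Gaussian: OU and EB are reduced to BM by
deterministic branch-length rescalings, and the restricted (REML) likelihood
is computed exactly by phylogenetic independent contrasts with the tip-noise
variance ``sigma_tip^2`` added to each pendant branch.

Pulsed models are Levy processes specified through their characteristic
exponent psi(k) (Levy-Khinchine form): the increment over a branch of length
t has characteristic function ``exp(t * psi(k))``.  Their restricted
likelihood has no closed form; it is computed by a pruning recursion in which
each node's conditional density is represented on a regular grid and branch
propagation is a convolution performed in the Fourier domain, where the
branch kernel is available analytically.  Integrating the root state against
a flat prior yields exactly the REML likelihood (the Gaussian special case
reproduces the contrasts likelihood to spectral accuracy).

Model comparison follows the weighted-AIC protocol: Akaike weights over all
nine fits, the six jump models clubbed into a single "pulsed" class
represented by its highest member weight, and a class selected only when its
weight is at least twice every competitor's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .phylo_io import ScaledTraitVector, TimeTree

GAUSSIAN_MODELS = ("BM", "OU", "EB")
JUMP_MODELS = ("JN", "NIG", "BMJN", "BMNIG", "EBJN", "EBNIG")
ALL_MODELS = GAUSSIAN_MODELS + JUMP_MODELS

#: free parameters per model (the root state is profiled out and not counted;
#: sigma_tip is always free)
FREE_PARAMS = {
    "BM": ("sigma2", "sigma_tip"),
    "OU": ("sigma2", "alpha_ou", "sigma_tip"),
    "EB": ("sigma2", "r", "sigma_tip"),
    "JN": ("lam", "delta", "sigma_tip"),
    "NIG": ("alpha_nig", "delta_nig", "sigma_tip"),
    "BMJN": ("sigma2", "lam", "delta", "sigma_tip"),
    "BMNIG": ("sigma2", "alpha_nig", "delta_nig", "sigma_tip"),
    "EBJN": ("r", "lam", "delta", "sigma_tip"),
    "EBNIG": ("r", "alpha_nig", "delta_nig", "sigma_tip"),
}

#: models whose characteristic exponent is time-homogeneous
HOMOGENEOUS_MODELS = ("BM", "JN", "NIG", "BMJN", "BMNIG")


@dataclass
class LevyModelSpec:
    """A named trait-evolution model with its parameter vector.

    Only the fields belonging to the named model are active; ``params`` may
    additionally carry ``mu`` (directional drift, simulation only; fixed at 0
    in all fits because REML on an ultrametric tree cannot separate drift
    from the root state) and ``sigma_tip``.
    """

    model: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ALL_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.sigma_tip < 0:
            raise ValueError("sigma_tip must be >= 0")
        for key in ("sigma2", "lam", "delta", "alpha_nig", "delta_nig", "alpha_ou"):
            if self.params.get(key, 0.0) < 0:
                raise ValueError(f"parameter {key} must be >= 0")
        if self.params.get("r", 0.0) > 0:
            raise ValueError("early-burst exponent r must be <= 0")

    @property
    def sigma_tip(self) -> float:
        return float(self.params.get("sigma_tip", 0.0))

    def free_params(self) -> dict:
        return {k: float(self.params.get(k, 0.0)) for k in FREE_PARAMS[self.model]}


# ----------------------------------------------------------------------
# branch rescalings


def rescale_branches_ou(tree: TimeTree, alpha_ou: float) -> TimeTree:
    """Tree on which unit-rate BM reproduces the single-optimum OU tip
    covariance: a node at depth d from the root of a depth-T tree maps to
    transformed depth ``(exp(-2a(T-d)) - exp(-2aT)) / (2a)``; the limit
    a -> 0 recovers the original lengths."""
    if alpha_ou < 0:
        raise ValueError("alpha_ou must be >= 0")
    tips = tree.tip_indices
    depths = tree.node_depths[tips]
    if depths.max() - depths.min() > 1e-6 * max(depths.max(), 1.0):
        raise ValueError("OU branch rescaling requires an ultrametric tree")
    if alpha_ou == 0:
        return tree
    T = tree.depth
    d = tree.node_depths
    D = (np.exp(-2 * alpha_ou * (T - d)) - np.exp(-2 * alpha_ou * T)) / (2 * alpha_ou)
    new = np.zeros_like(tree.lengths)
    for v in tree.preorder[1:]:
        new[v] = D[v] - D[int(tree.parent[v])]
    return tree.with_lengths(new)


def rescale_branches_eb(tree: TimeTree, r: float) -> TimeTree:
    """Early-burst clock: a branch spanning absolute times [t1, t2] gets
    length ``(exp(r t2) - exp(r t1)) / r`` (identity at r = 0)."""
    if r > 0:
        raise ValueError("early-burst exponent r must be <= 0")
    if r == 0:
        return tree
    d = tree.node_depths
    new = np.zeros_like(tree.lengths)
    for v in tree.preorder[1:]:
        t1, t2 = d[int(tree.parent[v])], d[v]
        new[v] = (np.exp(r * t2) - np.exp(r * t1)) / r
    return tree.with_lengths(new)


# ----------------------------------------------------------------------
# characteristic exponents


def _psi(params: dict, k: np.ndarray) -> np.ndarray:
    """Levy-Khinchine exponent of the homogeneous part: drift + BM + jumps."""
    k = np.asarray(k, dtype=float)
    psi = np.zeros(k.shape, dtype=complex)
    mu = params.get("mu", 0.0)
    if mu:
        psi = psi + 1j * mu * k
    sigma2 = params.get("sigma2", 0.0)
    if sigma2:
        psi = psi - 0.5 * sigma2 * k**2
    lam = params.get("lam", 0.0)
    if lam:
        delta = params.get("delta", 0.0)
        psi = psi + lam * (np.exp(-0.5 * delta**2 * k**2) - 1.0)
    dnig = params.get("delta_nig", 0.0)
    if dnig:
        anig = params.get("alpha_nig", 0.0)
        psi = psi + dnig * (anig - np.sqrt(anig**2 + k**2))
    return psi


def levy_char_exponent(spec: LevyModelSpec, k):
    """psi(k) such that the increment over a branch of length t has
    characteristic function exp(t * psi(k)).  Only defined for the
    time-homogeneous models; EB variants are handled by branch rescaling
    before characteristic-function evaluation, not by a homogeneous
    exponent."""
    if spec.model not in HOMOGENEOUS_MODELS:
        raise ValueError(
            f"{spec.model} has no time-homogeneous characteristic exponent"
        )
    scalar = np.isscalar(k)
    out = _psi(spec.params, np.atleast_1d(np.asarray(k, dtype=float)))
    return complex(out[0]) if scalar else out


def increment_variance_rate(spec: LevyModelSpec) -> float:
    """Variance of trait change per unit (rescaled) time, from the
    Levy-Khinchine representation: sigma2 + lam*delta^2 + delta_nig/alpha_nig."""
    p = spec.params
    var = p.get("sigma2", 0.0) + p.get("lam", 0.0) * p.get("delta", 0.0) ** 2
    if p.get("delta_nig", 0.0):
        var += p["delta_nig"] / p["alpha_nig"]
    return var


# ----------------------------------------------------------------------
# Gaussian REML by phylogenetic independent contrasts


def _align(tree: TimeTree, trait: ScaledTraitVector) -> np.ndarray:
    """Observed values in node-id order (NaN at internal nodes)."""
    series = trait.as_series()
    missing = [l for l in tree.tip_labels if l not in series.index]
    if missing:
        raise KeyError(f"species missing from trait vector: {missing}")
    out = np.full(tree.n_nodes, np.nan)
    for v in tree.tip_indices:
        out[v] = series[tree.labels[v]]
    return out


def _contrast_loglik(tree: TimeTree, obs: np.ndarray, var_lengths: np.ndarray,
                     tip_extra_var: float) -> float:
    """REML log-likelihood of unit-rate BM on branch *variances*
    ``var_lengths`` with ``tip_extra_var`` added at every tip, by sequential
    peeling of contrasts (valid for polytomies: a multifurcation is peeled
    pairwise, an orthogonal transformation of the same Gaussian)."""
    n = tree.n_nodes
    x = np.zeros(n)
    v = np.zeros(n)
    ll = 0.0
    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            x[node] = obs[node]
            v[node] = var_lengths[node] + tip_extra_var
            continue
        X, V = x[ch[0]], v[ch[0]]
        for c in ch[1:]:
            s = V + v[c]
            d = X - x[c]
            ll += -0.5 * (np.log(2 * np.pi * s) + d * d / s)
            X = (X * v[c] + x[c] * V) / s
            V = V * v[c] / s
        x[node] = X
        v[node] = V + var_lengths[node]
    return ll


def _rescaled_tree(tree: TimeTree, spec: LevyModelSpec) -> TimeTree:
    if "alpha_ou" in FREE_PARAMS[spec.model]:
        return rescale_branches_ou(tree, spec.params.get("alpha_ou", 0.0))
    if "r" in FREE_PARAMS[spec.model]:
        return rescale_branches_eb(tree, spec.params.get("r", 0.0))
    return tree


def reml_gaussian_loglik(
    tree: TimeTree, trait: ScaledTraitVector, spec: LevyModelSpec
) -> float:
    """Exact REML log-likelihood for BM / OU / EB with tip noise: equals the
    full multivariate-Gaussian likelihood with the grand mean profiled out."""
    if spec.model not in GAUSSIAN_MODELS:
        raise ValueError(f"{spec.model} is not a Gaussian model")
    if tree.n_tips < 2:
        raise ValueError("REML needs at least 2 tips (one contrast)")
    obs = _align(tree, trait)
    rt = _rescaled_tree(tree, spec)
    sigma2 = spec.params["sigma2"]
    if sigma2 <= 0 and spec.sigma_tip <= 0:
        raise ValueError("sigma2 and sigma_tip cannot both be zero")
    return _contrast_loglik(tree, obs, rt.lengths * sigma2, spec.sigma_tip**2)


# ----------------------------------------------------------------------
# Levy REML on a grid (FFT pruning)


@dataclass
class GridSettings:
    """Resolution of the density grid used by the Levy pruning likelihood.

    ``n`` grid points (a power of two) span
    ``[min(x) - pad * range(x), max(x) + pad * range(x)]``.
    """

    n: int = 1024
    pad: float = 6.0

    def __post_init__(self):
        if self.n < 8 or (self.n & (self.n - 1)) != 0:
            raise ValueError("grid size must be a power of two >= 8")
        if self.pad <= 0:
            raise ValueError("pad must be > 0")


class _GridPruner:
    """Reusable FFT pruning engine for one (tree, data, grid) triple.

    Messages are conditional densities of a subtree's data given the node
    state, held in the Fourier domain; tips enter analytically (exact phase
    ``exp(-i k x_obs)`` times the tip-noise Gaussian), so narrow tip
    densities never need to be sampled on the grid.  Internal nodes multiply
    their children's messages in real space; nodes are processed in
    bottom-up "waves" so the transforms batch across nodes.
    """

    def __init__(self, tree: TimeTree, obs: np.ndarray, grid: GridSettings):
        self.tree = tree
        self.grid = grid
        tips = tree.tip_indices
        x = obs[tips]
        span = float(x.max() - x.min()) or 1.0
        self.span = span
        self.x0 = float(x.min()) - grid.pad * span
        x1 = float(x.max()) + grid.pad * span
        N = grid.n
        self.dx = (x1 - self.x0) / N
        self.K = 2 * np.pi * np.fft.fftfreq(N, self.dx)
        self.kmax = float(np.abs(self.K).max())
        self.tip_rows = tips
        self.tip_obs = x
        self._phase_pos = np.exp(1j * self.K * self.x0)
        self._phase_neg = np.conj(self._phase_pos)
        # data-dependent tip phases exp(-i k x_obs) are fixed: precompute
        self._tip_phase = np.exp(-1j * np.outer(x, self.K))
        # bottom-up waves: round(tip) = 0, round(node) = 1 + max child round
        rounds = np.zeros(tree.n_nodes, dtype=int)
        for v in tree.postorder:
            if tree.children[v]:
                rounds[v] = 1 + max(rounds[c] for c in tree.children[v])
        self.waves = []
        for r in range(1, rounds.max() + 1):
            nodes = [int(v) for v in np.flatnonzero(rounds == r)]
            child_ids, ptr = [], [0]
            for v in nodes:
                child_ids.extend(tree.children[v])
                ptr.append(len(child_ids))
            self.waves.append(
                (np.array(nodes), np.array(child_ids), np.array(ptr[:-1]))
            )

    def loglik(self, lengths: np.ndarray, psi: np.ndarray, sigma_tip: float) -> float:
        """Log REML likelihood given per-node (rescaled) branch lengths and
        the characteristic exponent sampled on the grid frequencies."""
        N = self.grid.n
        K, dx = self.K, self.dx
        real_psi = bool(np.all(psi.imag == 0.0)) if np.iscomplexobj(psi) else True
        psi_r = psi.real if np.iscomplexobj(psi) else psi
        # driftless (symmetric) exponents are real: keep the branch kernels
        # real to halve the transcendental work
        cf_exp = np.outer(lengths, psi_r if real_psi else psi)
        # anti-aliasing floor: ensure every tip message decays to <= 1e-8 at
        # the Nyquist frequency (adds Gaussian smoothing ~2 grid steps only
        # when neither tip noise nor a diffusive component provides decay)
        psi_nyq = float(psi_r[N // 2])
        tip_var = np.full(self.tip_rows.shape[0], sigma_tip**2)
        need = 2.0 * (lengths[self.tip_rows] * psi_nyq + 18.42) / self.kmax**2
        tip_var = np.maximum(tip_var, need)
        H = np.empty((self.tree.n_nodes, N), dtype=complex)
        H[self.tip_rows] = self._tip_phase * np.exp(
            cf_exp[self.tip_rows] - 0.5 * tip_var[:, None] * K[None, :] ** 2
        )
        logscale = 0.0
        root = self.tree.root
        for nodes, child_ids, ptr in self.waves:
            h = np.fft.ifft(H[child_ids] * self._phase_pos[None, :], axis=1).real / dx
            np.maximum(h, 0.0, out=h)
            f = np.multiply.reduceat(h, ptr, axis=0)
            s = f.max(axis=1)
            if not np.all(np.isfinite(s)) or np.any(s <= 0):
                return -np.inf
            f /= s[:, None]
            logscale += float(np.log(s).sum())
            if nodes.shape[0] == 1 and nodes[0] == root:
                lik = float(f[0].sum() * dx)
                if lik <= 0:
                    return -np.inf
                return np.log(lik) + logscale
            H[nodes] = np.fft.fft(f, axis=1) * dx * self._phase_neg[None, :] * np.exp(
                cf_exp[nodes]
            )
        raise AssertionError("root wave not reached")  # pragma: no cover


def _check_grid_extent(pruner: _GridPruner, spec: LevyModelSpec,
                       lengths: np.ndarray, tree: TimeTree) -> None:
    """Hard error when the grid cannot contain ~99.99% of the increment mass
    accumulated along the deepest root-to-tip path."""
    depths = np.zeros(tree.n_nodes)
    for v in tree.preorder[1:]:
        depths[v] = depths[int(tree.parent[v])] + lengths[v]
    path_var = increment_variance_rate(spec) * depths[tree.tip_indices].max()
    sd = np.sqrt(path_var + spec.sigma_tip**2)
    if pruner.grid.pad * pruner.span < 4.0 * sd:
        raise ValueError(
            "grid extent too small to contain 99.99% of the increment mass: "
            f"padding {pruner.grid.pad * pruner.span:.3g} < 4 increment SD "
            f"({4 * sd:.3g}); enlarge GridSettings.pad or .n"
        )


def levy_reml_loglik(
    tree: TimeTree,
    trait: ScaledTraitVector,
    spec: LevyModelSpec,
    grid: GridSettings | None = None,
    _pruner: _GridPruner | None = None,
) -> float:
    """REML log-likelihood of any of the nine models via the grid/FFT
    pruning recursion (Gaussian models are supported and agree with
    :func:`reml_gaussian_loglik` to grid accuracy; pulsed models are the
    intended use).  Deterministic given the grid settings."""
    grid = grid or GridSettings()
    obs = _align(tree, trait)
    pruner = _pruner or _GridPruner(tree, obs, grid)
    rt = _rescaled_tree(tree, spec)
    psi = _psi(
        {k: v for k, v in spec.params.items() if k not in ("r", "alpha_ou", "sigma_tip")},
        pruner.K,
    )
    _check_grid_extent(pruner, spec, rt.lengths, tree)
    ll = pruner.loglik(rt.lengths, psi, spec.sigma_tip)
    if not np.isfinite(ll):
        raise FloatingPointError(
            "non-finite density in Levy pruning (parameters at an extreme "
            "of the representable range)"
        )
    return ll


# ----------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """One maximized model fit with its information-criterion bookkeeping."""

    spec: LevyModelSpec
    loglik: float
    k: int
    aic: float
    converged: bool
    n_restarts: int
    message: str = ""

    @property
    def model(self) -> str:
        return self.spec.model

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": self.spec.free_params(),
            "loglik": self.loglik,
            "k": self.k,
            "aic": self.aic,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
        }


def _initial_params(model: str, tree: TimeTree, values: np.ndarray) -> dict:
    T = tree.depth
    varx = float(np.var(values, ddof=1)) or 1.0
    sd = np.sqrt(varx)
    share = 0.5 if model.startswith(("BM", "EB")) and model not in ("BM", "EB") else 1.0
    init = {"sigma_tip": 0.1 * sd}
    names = FREE_PARAMS[model]
    if "sigma2" in names:
        init["sigma2"] = (varx / T) * (1 - share if share < 1 else 1.0) or varx / T
    if "alpha_ou" in names:
        init["alpha_ou"] = 1.0 / T
    if "r" in names:
        init["r"] = -0.5 / T
    if "lam" in names:
        init["lam"] = 2.0 / T
        init["delta"] = np.sqrt(share * varx / (init["lam"] * T))
    if "alpha_nig" in names:
        init["alpha_nig"] = 3.0 / sd
        init["delta_nig"] = share * (varx / T) * init["alpha_nig"]
    if model in ("BMJN", "BMNIG"):
        init["sigma2"] = 0.5 * varx / T
    return init


def fit_model(
    tree: TimeTree,
    trait: ScaledTraitVector,
    model: str,
    *,
    restarts: int = 10,
    grid: GridSettings | None = None,
    seed: int = 0,
    maxfun: int = 400,
) -> FitResult:
    """Maximize the REML log-likelihood of one model by bounded quasi-Newton
    search over log-transformed parameters with dispersed multi-start."""
    if model not in ALL_MODELS:
        raise ValueError(f"unknown model {model!r}")
    names = FREE_PARAMS[model]
    obs = _align(tree, trait)
    values = obs[tree.tip_indices]
    gaussian = model in GAUSSIAN_MODELS
    pruner = None
    if not gaussian:
        grid = grid or GridSettings()
        pruner = _GridPruner(tree, obs, grid)

    def unpack(x: np.ndarray) -> dict:
        params = {}
        for name, xi in zip(names, x):
            params[name] = -np.exp(xi) if name == "r" else np.exp(xi)
        return params

    def negloglik(x: np.ndarray) -> float:
        try:
            spec = LevyModelSpec(model, unpack(x))
            if gaussian:
                ll = reml_gaussian_loglik(tree, trait, spec)
            else:
                ll = levy_reml_loglik(tree, trait, spec, grid, _pruner=pruner)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    init = _initial_params(model, tree, values)
    rng = np.random.default_rng(seed)
    best = None
    n_ok = 0
    for j in range(restarts):
        p0 = dict(init)
        if j == 1:
            # nested-boundary start: push pull/decay/jump intensity toward
            # zero so every richer model can reach its nested optimum
            for name in ("alpha_ou", "lam"):
                if name in p0:
                    p0[name] *= 1e-5
            if "r" in p0:
                p0["r"] *= 1e-5
        elif j > 1:
            for name in p0:
                p0[name] *= np.exp(rng.normal(0.0, 1.2))
        x0 = np.array(
            [np.log(abs(p0[name]) + 1e-300) for name in names]
        )
        bounds = [(x - 14.0, x + 14.0) for x in x0] if j == 0 else base_bounds
        if j == 0:
            base_bounds = bounds
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                negloglik,
                x0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxfun": maxfun, "ftol": 1e-11, "gtol": 1e-8},
            )
        if np.isfinite(res.fun) and res.fun < 9e9:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        spec = LevyModelSpec(model, init)
        return FitResult(
            spec, -np.inf, len(names), np.inf, False, restarts, "all restarts failed"
        )
    params = unpack(best.x)
    spec = LevyModelSpec(model, params)
    ll = -float(best.fun)
    k = len(names)
    return FitResult(
        spec,
        ll,
        k,
        2 * k - 2 * ll,
        bool(n_ok > 0 and np.isfinite(ll)),
        restarts,
        str(best.message),
    )


def fit_all_models(
    tree: TimeTree,
    trait: ScaledTraitVector,
    models=ALL_MODELS,
    **kwargs,
) -> list[FitResult]:
    return [fit_model(tree, trait, m, **kwargs) for m in models]


# ----------------------------------------------------------------------
# model comparison


@dataclass
class ComparisonTable:
    """Per-model Akaike weights plus the class-level summary row.

    The pulsed class weight is the MAXIMUM weight among the jump models
    (``aggregate="max"``, the default protocol); a sum variant is available
    behind the flag for sensitivity analysis.
    """

    model_weights: dict
    class_weights: dict
    aics: dict
    logliks: dict
    selected: str
    aggregate: str = "max"

    def row(self) -> dict:
        out = {k: self.class_weights.get(k, 0.0) for k in ("BM", "OU", "EB", "pulsed")}
        out["selected"] = self.selected
        return out


def aic_weights(
    fits: list[FitResult],
    *,
    factor: float = 2.0,
    allow_unconverged: bool = False,
    pulsed_aggregate: str = "max",
) -> ComparisonTable:
    """Akaike weights ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)`` with
    ``d_i = AIC_i - min AIC``, plus the class summary and 2x selection."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits to compare")
    models = [f.model for f in fits]
    if len(set(models)) != len(models):
        raise ValueError("duplicate model fits")
    bad = [f.model for f in fits if not f.converged]
    if bad and not allow_unconverged:
        raise ValueError(
            f"refusing non-converged fits: {bad} (pass allow_unconverged=True "
            "to override)"
        )
    aics = np.array([f.aic for f in fits])
    if not np.all(np.isfinite(aics)):
        raise ValueError("non-finite AIC in comparison")
    d = aics - aics.min()
    w = np.exp(-d / 2)
    w /= w.sum()
    model_weights = dict(zip(models, w))
    class_weights = {}
    for m in GAUSSIAN_MODELS:
        if m in model_weights:
            class_weights[m] = float(model_weights[m])
    jumps = [model_weights[m] for m in JUMP_MODELS if m in model_weights]
    if jumps:
        class_weights["pulsed"] = float(
            max(jumps) if pulsed_aggregate == "max" else sum(jumps)
        )
    table = ComparisonTable(
        {k: float(v) for k, v in model_weights.items()},
        class_weights,
        {f.model: float(f.aic) for f in fits},
        {f.model: float(f.loglik) for f in fits},
        "",
        pulsed_aggregate,
    )
    table.selected = select_best(table, factor=factor)
    return table


def select_best(table: ComparisonTable, factor: float = 2.0) -> str:
    """The class whose weight is at least ``factor`` times every competing
    class's weight, else ``"inconclusive"``."""
    cw = table.class_weights
    best = max(cw, key=cw.get)
    others = [v for k, v in cw.items() if k != best]
    if all(cw[best] >= factor * v for v in others):
        return best
    return "inconclusive"


def compare_models(
    tree: TimeTree,
    trait: ScaledTraitVector,
    models=ALL_MODELS,
    *,
    factor: float = 2.0,
    **fit_kwargs,
) -> tuple[list[FitResult], ComparisonTable]:
    """Fit all requested models on identical data and build the comparison."""
    fits = fit_all_models(tree, trait, models, **fit_kwargs)
    usable = [f for f in fits if f.converged]
    table = aic_weights(usable, factor=factor)
    return fits, table
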