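"""Bayesian rate-shift inference for a continuous trait on a time tree.

The trait evolves by Brownian motion whose instantaneous rate is constant
except at a Poisson-distributed set of shift points on the tree; each shift
starts a new regime with initial rate ``beta_init`` and (optionally) an
exponential time trend ``b``, inherited by all descendants until overridden
by a nested shift.  A reversible-jump MCMC samples the number, locations and
regime parameters of shifts; the outputs are Bayes factors for >= 1 shift
versus none, the credible set of distinct shift configurations, the best
(maximum a posteriori) configuration, per-branch posterior mean rates, and
rate-through-time curves.

The prior on the shift count is Poisson with mean ``expected_shifts``
(analytic, so prior odds for Bayes factors need no sampling), locations are
uniform on the tree, ``beta_init`` is log-normal and ``b`` normal around 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _shiftcore as core
from .phylo_io import ScaledTraitVector, TimeTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Shift:
    """One rate-shift event: ``position`` is the time offset from the
    branch's rootward end (parent node)."""

    branch: int
    position: float
    beta: float
    b: float = 0.0


@dataclass(frozen=True)
class ShiftConfiguration:
    """A set of shift events plus the root regime."""

    root_beta: float
    root_b: float = 0.0
    shifts: tuple = ()

    def __post_init__(self):
        if self.root_beta <= 0:
            raise ValueError("root_beta must be > 0")
        for s in self.shifts:
            if s.beta <= 0:
                raise ValueError("shift beta must be > 0")
            if s.position < 0:
                raise ValueError("shift position must be >= 0")

    @property
    def n_shifts(self) -> int:
        return len(self.shifts)


def _tree_arrays(tree: TimeTree):
    n = tree.n_nodes
    child_list, child_ptr = [], np.zeros(n + 1, dtype=np.int64)
    counts = np.array([len(tree.children[v]) for v in range(n)])
    child_ptr[1:] = np.cumsum(counts)
    for v in range(n):
        child_list.extend(tree.children[v])
    t1 = tree.node_depths
    t0 = np.array(
        [t1[tree.parent[v]] if tree.parent[v] >= 0 else 0.0 for v in range(n)]
    )
    return (
        tree.parent.astype(np.int64),
        tree.preorder.astype(np.int64),
        tree.postorder.astype(np.int64),
        np.array(child_list, dtype=np.int64),
        child_ptr,
        t0.astype(float),
        t1.astype(float),
    )


def _config_arrays(config: ShiftConfiguration, max_shifts: int | None = None):
    k = config.n_shifts
    m = max(k, 1) if max_shifts is None else max_shifts
    sbr = np.zeros(m, dtype=np.int64)
    spos = np.zeros(m)
    sbeta = np.zeros(m)
    sb = np.zeros(m)
    for i, s in enumerate(config.shifts):
        sbr[i], spos[i], sbeta[i], sb[i] = s.branch, s.position, s.beta, s.b
    return k, sbr, spos, sbeta, sb


def effective_branch_lengths(tree: TimeTree, config: ShiftConfiguration) -> np.ndarray:
    """Per-branch accumulated variance: the integral of the painted
    instantaneous rate beta(t) over each branch's regime segments."""
    for s in config.shifts:
        if not 0 <= s.branch < tree.n_nodes or s.branch == tree.root:
            raise ValueError(f"shift on invalid branch {s.branch}")
        if s.position > tree.lengths[s.branch] + 1e-9:
            raise ValueError(
                f"shift position {s.position} beyond branch {s.branch} "
                f"length {tree.lengths[s.branch]}"
            )
    parent, preorder, _, _, _, t0, t1 = _tree_arrays(tree)
    k, sbr, spos, sbeta, sb = _config_arrays(config)
    n = tree.n_nodes
    eff = np.zeros(n)
    core._effective_lengths(
        parent, preorder, t0, t1, k, sbr, spos, sbeta, sb,
        config.root_beta, config.root_b,
        eff, np.zeros(n), np.zeros(n), np.zeros(n),
    )
    return eff


def shifted_bm_loglik(
    tree: TimeTree,
    trait: ScaledTraitVector,
    config: ShiftConfiguration,
    tip_noise_sd: float = 0.0,
) -> float:
    """REML (contrasts) log-likelihood of the multi-regime BM model: BM with
    unit rate on the effective branch lengths.  A zero-shift configuration
    reduces exactly to constant-rate BM with sigma2 = root_beta."""
    if tree.n_tips < 3:
        raise ValueError("need at least 3 tips")
    eff = effective_branch_lengths(tree, config)
    nonroot = np.arange(tree.n_nodes) != tree.root
    if np.any(eff[nonroot] <= 0):
        raise ValueError("non-positive effective branch length")
    from .model_fit import _align

    obs = np.nan_to_num(_align(tree, trait))
    _, _, postorder, child_list, child_ptr, _, _ = _tree_arrays(tree)
    n = tree.n_nodes
    return float(
        core._reml_bm(
            postorder, child_list, child_ptr, eff, obs,
            tip_noise_sd**2, np.zeros(n), np.zeros(n),
        )
    )


# ----------------------------------------------------------------------
# sampler


@dataclass
class SamplerSettings:
    """rjMCMC run settings.

    ``expected_shifts`` is the mean of the analytic Poisson prior on the
    shift count.  ``beta_prior_meanlog = None`` centres the log-normal rate
    prior on the data's variance per unit tree depth (computed at run time).
    ``time_varying_rates`` frees the within-regime exponent ``b``; by default
    regimes have constant rates (b = 0).
    """

    generations: int = 2_000_000
    thin: int = 200
    expected_shifts: float = 1.0
    seed: int = 0
    burnin_fraction: float = 0.1
    time_varying_rates: bool = False
    beta_prior_meanlog: float | None = None
    beta_prior_sdlog: float = 2.0
    b_prior_sd: float = 0.05
    beta_scale_step: float = 1.0
    b_step: float = 0.02
    max_shifts: int = 50
    tip_noise_sd: float = 0.0
    flat_likelihood: bool = False

    def move_probs(self) -> tuple:
        if self.time_varying_rates:
            return (0.2, 0.2, 0.2, 0.3, 0.1)
        return (0.2, 0.2, 0.2, 0.4, 0.0)


@dataclass
class PosteriorSample:
    """Thinned rjMCMC draws of shift configurations with log-likelihood and
    log-prior, plus the settings that produced them (identical seed and
    settings reproduce the sample bit-for-bit)."""

    tree: TimeTree
    settings: SamplerSettings
    k: np.ndarray
    loglik: np.ndarray
    logprior: np.ndarray
    shift_branch: np.ndarray
    shift_pos: np.ndarray
    shift_beta: np.ndarray
    shift_b: np.ndarray
    root_beta: np.ndarray
    root_b: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.k.shape[0])

    def configuration(self, i: int) -> ShiftConfiguration:
        shifts = tuple(
            Shift(
                int(self.shift_branch[i, j]),
                float(self.shift_pos[i, j]),
                float(self.shift_beta[i, j]),
                float(self.shift_b[i, j]),
            )
            for j in range(int(self.k[i]))
        )
        return ShiftConfiguration(
            float(self.root_beta[i]), float(self.root_b[i]), shifts
        )

    @property
    def configurations(self) -> list:
        return [self.configuration(i) for i in range(len(self))]

    def effective_lengths_matrix(self) -> np.ndarray:
        parent, preorder, _, _, _, t0, t1 = _tree_arrays(self.tree)
        out = np.zeros((len(self), self.tree.n_nodes))
        core._eff_matrix(
            parent, preorder, t0, t1,
            self.k, self.shift_branch, self.shift_pos,
            self.shift_beta, self.shift_b, self.root_beta, self.root_b,
            out,
        )
        return out

    def to_event_log(self, path) -> None:
        """BAMM-style event log: one row per thinned sample with its shift
        records serialized as ``branch@position:beta:b`` triples."""
        with open(path, "w") as fh:
            fh.write(
                "# rate-shift event log; position = time offset from the "
                "branch's rootward end (My); beta in trait^2/My\n"
            )
            fh.write("sample\tloglik\tlogprior\tn_shifts\troot_beta\troot_b\tshifts\n")
            for i in range(len(self)):
                recs = ";".join(
                    f"{int(self.shift_branch[i, j])}@"
                    f"{self.shift_pos[i, j]:.4f}:"
                    f"{self.shift_beta[i, j]:.6g}:{self.shift_b[i, j]:.4g}"
                    for j in range(int(self.k[i]))
                )
                fh.write(
                    f"{i}\t{self.loglik[i]:.6f}\t{self.logprior[i]:.6f}\t"
                    f"{int(self.k[i])}\t{self.root_beta[i]:.6g}\t"
                    f"{self.root_b[i]:.4g}\t{recs}\n"
                )


def rjmcmc_run(
    tree: TimeTree, trait: ScaledTraitVector | None, settings: SamplerSettings
) -> PosteriorSample:
    """Run the reversible-jump sampler.  With
    ``settings.flat_likelihood = True`` the likelihood is held constant and
    the chain targets the analytic prior (used for prior-recovery checks);
    ``trait`` may then be None."""
    from .model_fit import _align

    if settings.flat_likelihood:
        values = np.zeros(tree.n_nodes)
    else:
        if trait is None:
            raise ValueError("trait required unless flat_likelihood")
        values = np.nan_to_num(_align(tree, trait))
    parent, preorder, postorder, child_list, child_ptr, t0, t1 = _tree_arrays(tree)
    branch_nodes = np.array(
        [v for v in range(tree.n_nodes) if v != tree.root], dtype=np.int64
    )
    cum_len = np.cumsum(tree.lengths[branch_nodes])
    if settings.beta_prior_meanlog is None:
        tips = tree.tip_indices
        varx = float(np.var(values[tips], ddof=1)) if not settings.flat_likelihood else 1.0
        mulog = float(np.log(max(varx, 1e-12) / tree.depth))
        settings = replace(settings, beta_prior_meanlog=mulog)
    n_samples = max(0, (settings.generations - int(
        settings.burnin_fraction * settings.generations
    ) - 1) // settings.thin + 1)
    burnin = int(settings.burnin_fraction * settings.generations)
    out_k = np.zeros(n_samples, dtype=np.int64)
    out_ll = np.zeros(n_samples)
    out_lp = np.zeros(n_samples)
    out_sbr = np.zeros((n_samples, settings.max_shifts), dtype=np.int64)
    out_spos = np.zeros((n_samples, settings.max_shifts))
    out_sbeta = np.zeros((n_samples, settings.max_shifts))
    out_sb = np.zeros((n_samples, settings.max_shifts))
    out_rbeta = np.zeros(n_samples)
    out_rb = np.zeros(n_samples)
    prop = np.zeros(5, dtype=np.int64)
    acc = np.zeros(5, dtype=np.int64)
    pb, pd_, pm, ps = settings.move_probs()[:4]
    got = core._run_mcmc(
        parent, preorder, postorder, child_list, child_ptr, t0, t1,
        branch_nodes, cum_len,
        values, settings.tip_noise_sd**2,
        settings.generations, settings.thin, burnin,
        settings.expected_shifts,
        settings.beta_prior_meanlog, settings.beta_prior_sdlog,
        settings.b_prior_sd, settings.time_varying_rates,
        pb, pd_, pm, ps,
        settings.beta_scale_step, settings.b_step,
        settings.max_shifts, settings.seed, settings.flat_likelihood,
        out_k, out_ll, out_lp,
        out_sbr, out_spos, out_sbeta, out_sb, out_rbeta, out_rb,
        prop, acc,
    )
    names = ("birth", "death", "move", "scale_beta", "perturb_b")
    rates = {
        nm: (int(p), int(a), (a / p if p else np.nan))
        for nm, p, a in zip(names, prop, acc)
    }
    overall = float(acc.sum() / max(prop.sum(), 1))
    if not 0.05 <= overall <= 0.7:
        warnings.warn(
            f"overall acceptance rate {overall:.3f} outside [0.05, 0.7]; "
            "consider adjusting proposal scales",
            RuntimeWarning,
        )
    sl = slice(0, got)
    return PosteriorSample(
        tree, settings,
        out_k[sl], out_ll[sl], out_lp[sl],
        out_sbr[sl], out_spos[sl], out_sbeta[sl], out_sb[sl],
        out_rbeta[sl], out_rb[sl],
        {"acceptance": rates, "overall_acceptance": overall},
    )


# ----------------------------------------------------------------------
# posterior summaries


@dataclass
class BayesFactorResult:
    """Posterior-vs-prior odds for at least one shift versus none."""

    posterior_p0: float
    posterior_p_ge1: float
    prior_p0: float
    prior_p_ge1: float
    bayes_factor: float
    is_lower_bound: bool = False


def compute_bayes_factor(sample: PosteriorSample) -> BayesFactorResult:
    if len(sample) == 0:
        raise ValueError("empty posterior sample")
    gamma = sample.settings.expected_shifts
    prior_p0 = float(np.exp(-gamma))
    prior_p1 = 1.0 - prior_p0
    n = len(sample)
    n0 = int((sample.k == 0).sum())
    n1 = n - n0
    bound = n0 == 0
    if bound:
        # pseudo-count P(k=0) = 1/n turns the BF into a lower bound
        n0, n1 = 1, n - 1
    bf = (n1 / n0) / (prior_p1 / prior_p0)
    return BayesFactorResult(
        n0 / n, n1 / n, prior_p0, prior_p1, float(bf), bound
    )


@dataclass
class DistinctConfiguration:
    """One distinct shift configuration (keyed by its set of core-shift
    branches) with its posterior frequency and posterior-mean regimes."""

    branches: frozenset
    probability: float
    n_samples: int
    mean_config: ShiftConfiguration


@dataclass
class CredibleShiftSet:
    entries: list
    cumulative: float
    core_branches: frozenset
    branch_shift_prob: dict


def _core_branches(sample: PosteriorSample, core_ratio: float) -> tuple[dict, frozenset]:
    tree = sample.tree
    gamma = sample.settings.expected_shifts
    total = tree.total_branch_length
    n = len(sample)
    prob = {}
    hit = np.zeros(tree.n_nodes)
    for i in range(n):
        branches = np.unique(sample.shift_branch[i, : int(sample.k[i])])
        hit[branches] += 1
    core = set()
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = hit[v] / n
        prob[v] = p
        prior_expect = gamma * tree.lengths[v] / total
        if p >= core_ratio * prior_expect and p > 0:
            core.add(v)
    return prob, frozenset(core)


def credible_shift_set(
    sample: PosteriorSample,
    cumulative: float = 0.95,
    core_ratio: float = 5.0,
) -> CredibleShiftSet:
    """Distinct configurations keyed by the set of core-shift branches
    (branches whose marginal shift probability exceeds ``core_ratio`` times
    its prior expectation), ranked by posterior frequency; the smallest
    prefix reaching ``cumulative`` probability is returned."""
    prob, core = _core_branches(sample, core_ratio)
    n = len(sample)
    keys: dict[frozenset, list[int]] = {}
    for i in range(n):
        branches = frozenset(
            int(b)
            for b in sample.shift_branch[i, : int(sample.k[i])]
            if int(b) in core
        )
        keys.setdefault(branches, []).append(i)
    ranked = sorted(keys.items(), key=lambda kv: (-len(kv[1]), sorted(kv[0])))
    entries: list[DistinctConfiguration] = []
    acc = 0.0
    for branches, idx in ranked:
        entries.append(
            DistinctConfiguration(
                branches, len(idx) / n, len(idx), _mean_config(sample, branches, idx)
            )
        )
        acc += len(idx) / n
        if acc >= cumulative - 1e-12:
            break
    return CredibleShiftSet(entries, acc, core, prob)


def _mean_config(
    sample: PosteriorSample, branches: frozenset, idx: list[int]
) -> ShiftConfiguration:
    shifts = []
    for b in sorted(branches):
        pos, beta, bs = [], [], []
        for i in idx:
            for j in range(int(sample.k[i])):
                if int(sample.shift_branch[i, j]) == b:
                    pos.append(sample.shift_pos[i, j])
                    beta.append(sample.shift_beta[i, j])
                    bs.append(sample.shift_b[i, j])
                    break
        if pos:
            shifts.append(
                Shift(b, float(np.mean(pos)), float(np.mean(beta)), float(np.mean(bs)))
            )
    return ShiftConfiguration(
        float(np.mean(sample.root_beta[idx])),
        float(np.mean(sample.root_b[idx])),
        tuple(shifts),
    )


def best_shift_configuration(sample: PosteriorSample) -> ShiftConfiguration:
    """Maximum a posteriori distinct configuration with posterior-mean
    regime parameters."""
    cs = credible_shift_set(sample)
    return cs.entries[0].mean_config


# ----------------------------------------------------------------------
# rate through time & branch rates


@dataclass
class RateThroughTime:
    """Posterior mean instantaneous rate (with central credible band)
    averaged over lineages alive at each time slice."""

    times_before_present: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    band: float = 0.90
    clade: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_before_present": self.times_before_present,
                "mean_rate": self.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def rate_through_time(
    sample: PosteriorSample,
    tree: TimeTree | None = None,
    clade=None,
    grid: int = 64,
    band: float = 0.90,
) -> RateThroughTime:
    tree = tree or sample.tree
    include = np.ones(tree.n_nodes, dtype=np.bool_)
    if clade is not None:
        include[:] = False
        include[tree.clade_nodes(clade)] = True
        include[tree.mrca(clade)] = False  # crown clade: stem branch excluded
    T = tree.depth
    tbp = np.linspace(0.0, T, grid)
    grid_abs = np.clip(T - tbp, 1e-9, T)
    parent, preorder, _, _, _, t0, t1 = _tree_arrays(tree)
    out = np.zeros((len(sample), grid))
    core._rtt_matrix(
        parent, preorder, t0, t1, include,
        sample.k, sample.shift_branch, sample.shift_pos,
        sample.shift_beta, sample.shift_b, sample.root_beta, sample.root_b,
        grid_abs, out,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(out, axis=0)
        lo = np.nanquantile(out, (1 - band) / 2, axis=0)
        hi = np.nanquantile(out, 1 - (1 - band) / 2, axis=0)
    return RateThroughTime(
        tbp, mean, lo, hi, band, tuple(clade) if clade is not None else ()
    )


def branch_rates(sample: PosteriorSample, band: float = 0.90) -> pd.DataFrame:
    """Posterior mean (and credible interval) of the branch-averaged rate
    ``effective length / branch length`` for every branch."""
    tree = sample.tree
    eff = sample.effective_lengths_matrix()
    nonroot = [v for v in range(tree.n_nodes) if v != tree.root]
    rates = eff[:, nonroot] / tree.lengths[nonroot][None, :]
    lo = np.quantile(rates, (1 - band) / 2, axis=0)
    hi = np.quantile(rates, 1 - (1 - band) / 2, axis=0)
    return pd.DataFrame(
        {
            "branch": nonroot,
            "label": [tree.labels[v] or "" for v in nonroot],
            "mean_rate": rates.mean(axis=0),
            "lower": lo,
            "upper": hi,
        }
    )


def annotated_newick(sample: PosteriorSample) -> str:
    """Newick string with posterior mean branch rates as bracket comments."""
    df = branch_rates(sample)
    comments = {
        int(row.branch): f"&rate={row.mean_rate:.6g}" for row in df.itertuples()
    }
    return sample.tree.to_newick(comments=comments)


# ----------------------------------------------------------------------
# effective sample size


def ess(series) -> float:
    """Effective sample size by Geyer's initial-positive-sequence estimator.

    A constant series is reported as ESS = n (with a degeneracy warning);
    negative autocorrelation is capped at ESS = n.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 10:
        raise ValueError("series too short for ESS (need >= 10)")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        warnings.warn("constant series: ESS degenerate, reporting n", RuntimeWarning)
        return float(n)
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # sum of adjacent pairs Gamma_m = rho_{2m} + rho_{2m+1}, truncated at the
    # first non-positive pair
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        g = rho[2 * m] + rho[2 * m + 1]
        if g <= 0:
            break
        tau += g
        m += 1
    tau = max(2.0 * tau - 1.0, 1e-12)
    return float(min(n / tau, n))
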