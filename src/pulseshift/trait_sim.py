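"""Synthetic trees and trait data under every model in scope.

Trait values evolve along a time-calibrated tree from a root state (0 by
default) by accumulating independent increments on each branch:

* ``BM``      Gaussian increments, variance ``sigma2 * t``.
* ``OU``      exact Ornstein-Uhlenbeck transition with pull ``alpha_ou``
              toward optimum ``theta``.
* ``EB``      early burst: BM whose rate decays as ``exp(r * time)``
              (``r <= 0``); implemented by rescaling branch durations.
* ``JN``      jump normal: compound Poisson with intensity ``lam`` and
              Normal(0, delta^2) jump sizes, plus an optional BM component.
* ``NIG``     symmetric normal-inverse-Gaussian pure-jump process with tail
              parameter ``alpha_nig`` and scale ``delta_nig`` (increment
              variance ``delta_nig / alpha_nig`` per unit time), sampled by
              subordinating a Gaussian to an inverse-Gaussian clock.
* ``BMJN / BMNIG / EBJN / EBNIG``  the obvious compounds.
* ``SHIFTED_BM``  BM whose instantaneous rate follows a regime painting
              (see :mod:`pulseshift.rate_shift`).

Gaussian tip noise with standard deviation ``tip_noise_sd`` is added to the
observed tip values.  All randomness derives from one integer seed through a
seed-splitting scheme keyed by node id, so every branch's draws are
reproducible independently of traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo_io import ScaledTraitVector, TimeTree

SIM_MODELS = (
    "BM",
    "OU",
    "EB",
    "JN",
    "NIG",
    "BMJN",
    "BMNIG",
    "EBJN",
    "EBNIG",
    "SHIFTED_BM",
)

# base increment family and whether the early-burst time rescaling applies
_BASE = {
    "BM": ("BM", False),
    "EB": ("BM", True),
    "JN": ("JN", False),
    "BMJN": ("JN", False),
    "EBJN": ("JN", True),
    "NIG": ("NIG", False),
    "BMNIG": ("NIG", False),
    "EBNIG": ("NIG", True),
}


@dataclass
class SimulationConfig:
    """Model name, parameter vector, tip noise and seed for one simulation."""

    model: str
    params: dict = field(default_factory=dict)
    tip_noise_sd: float = 0.0
    seed: int = 0
    root_state: float = 0.0

    def __post_init__(self):
        if self.model not in SIM_MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.tip_noise_sd < 0:
            raise ValueError("tip_noise_sd must be >= 0")
        for key in ("sigma2", "lam", "delta", "alpha_nig", "delta_nig", "alpha_ou"):
            if key in self.params and self.params[key] < 0:
                raise ValueError(f"parameter {key} must be >= 0")
        if self.params.get("r", 0.0) > 0:
            raise ValueError("early-burst exponent r must be <= 0")


@dataclass
class RegimePainting:
    """Assignment of an instantaneous BM rate to every point on the tree,
    induced by a shift configuration (root regime plus zero or more shifts).
    """

    config: "object"  # rate_shift.ShiftConfiguration

    def effective_lengths(self, tree: TimeTree) -> np.ndarray:
        from .rate_shift import effective_branch_lengths

        return effective_branch_lengths(tree, self.config)


def _branch_rng(seed: int, node: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(node, stream))
    )


def _eb_duration(t0: float, t1: float, r: float) -> float:
    """Effective duration of a branch spanning absolute times [t0, t1] under
    an exponentially decaying clock exp(r * t)."""
    if r == 0:
        return t1 - t0
    return (np.exp(r * t1) - np.exp(r * t0)) / r


def _sample_increments(base, params, t, rng, size):
    """Draw ``size`` iid increments of the homogeneous process over duration
    ``t`` (already EB-rescaled where applicable)."""
    mu = params.get("mu", 0.0)
    sigma2 = params.get("sigma2", 0.0)
    var = np.full(size, sigma2 * t)
    if base == "JN":
        lam, delta = params["lam"], params["delta"]
        if lam > 0:
            n_jumps = rng.poisson(lam * t, size)
            var = var + n_jumps * delta**2
    elif base == "NIG":
        a, d = params["alpha_nig"], params["delta_nig"]
        if d > 0:
            dt = d * t
            # subordinator: V ~ InverseGaussian(mean dt/a, shape dt^2)
            v = stats.invgauss.rvs(
                1.0 / (a * dt), scale=dt**2, size=size, random_state=rng
            )
            var = var + v
    elif base != "BM":
        raise ValueError(f"unknown base process {base!r}")
    return mu * t + rng.normal(0.0, 1.0, size) * np.sqrt(var)


def simulate_levy_traits_ensemble(
    tree: TimeTree, config: SimulationConfig, n_replicates: int = 1
) -> tuple[list[str], np.ndarray]:
    """Simulate ``n_replicates`` independent trait vectors in one pass.

    Returns ``(tip_labels, values)`` with ``values`` of shape
    ``(n_tips, n_replicates)``.  Replicate ``j`` of a single-replicate call
    with the same seed is NOT reproduced here; the ensemble has its own draw
    stream per branch.
    """
    if config.model == "SHIFTED_BM":
        raise ValueError("use simulate_shifted_bm for SHIFTED_BM")
    state = {tree.root: np.full(n_replicates, config.root_state)}
    if config.model == "OU":
        alpha = config.params.get("alpha_ou", 0.0)
        theta = config.params.get("theta", config.root_state)
        sigma2 = config.params["sigma2"]
        for v in tree.preorder[1:]:
            p = int(tree.parent[v])
            t = tree.lengths[v]
            rng = _branch_rng(config.seed, int(v))
            if alpha == 0:
                mean = state[p]
                var = sigma2 * t
            else:
                e = np.exp(-alpha * t)
                mean = theta + (state[p] - theta) * e
                var = sigma2 * (1 - e**2) / (2 * alpha)
            state[v] = mean + rng.normal(0.0, 1.0, n_replicates) * np.sqrt(var)
    else:
        base, uses_eb = _BASE[config.model]
        r = config.params.get("r", 0.0) if uses_eb else 0.0
        for v in tree.preorder[1:]:
            p = int(tree.parent[v])
            t0 = tree.node_depths[p]
            t1 = tree.node_depths[v]
            dur = _eb_duration(t0, t1, r)
            rng = _branch_rng(config.seed, int(v))
            state[v] = state[p] + _sample_increments(
                base, config.params, dur, rng, n_replicates
            )
    tips = tree.tip_indices
    values = np.stack([state[int(v)] for v in tips])
    if config.tip_noise_sd > 0:
        for row, v in enumerate(tips):
            rng = _branch_rng(config.seed, int(v), stream=1)
            values[row] += rng.normal(0.0, config.tip_noise_sd, n_replicates)
    return [tree.labels[i] for i in tips], values


def simulate_levy_traits(tree: TimeTree, config: SimulationConfig) -> ScaledTraitVector:
    """Simulate one trait vector under the configured model."""
    labels, values = simulate_levy_traits_ensemble(tree, config, 1)
    return ScaledTraitVector(labels, values[:, 0], toxin=config.model)


def simulate_shifted_bm_ensemble(
    tree: TimeTree,
    painting: RegimePainting,
    config: SimulationConfig,
    n_replicates: int = 1,
) -> tuple[list[str], np.ndarray]:
    """Multi-regime BM: each branch's increment variance is the integral of
    the painted instantaneous rate over the branch."""
    eff = painting.effective_lengths(tree)
    if np.any(eff[np.arange(tree.n_nodes) != tree.root] <= 0):
        raise ValueError("regime painting yields non-positive branch variance")
    state = {tree.root: np.full(n_replicates, config.root_state)}
    for v in tree.preorder[1:]:
        p = int(tree.parent[v])
        rng = _branch_rng(config.seed, int(v))
        state[v] = state[p] + rng.normal(0.0, 1.0, n_replicates) * np.sqrt(eff[v])
    tips = tree.tip_indices
    values = np.stack([state[int(v)] for v in tips])
    if config.tip_noise_sd > 0:
        for row, v in enumerate(tips):
            rng = _branch_rng(config.seed, int(v), stream=1)
            values[row] += rng.normal(0.0, config.tip_noise_sd, n_replicates)
    return [tree.labels[i] for i in tips], values


def simulate_shifted_bm(
    tree: TimeTree, painting: RegimePainting, config: SimulationConfig
) -> ScaledTraitVector:
    labels, values = simulate_shifted_bm_ensemble(tree, painting, config, 1)
    return ScaledTraitVector(labels, values[:, 0], toxin="SHIFTED_BM")


def simulate_pure_birth_tree(n_tips: int, depth: float, seed: int) -> TimeTree:
    """Ultrametric pure-birth (Yule) tree rescaled to the requested depth.

    Lineages split at unit rate; the chronogram is run until ``n_tips``
    lineages exist plus one final exponential waiting time, then linearly
    rescaled so every tip sits exactly at ``depth``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(seed)
    parent = [-1]
    birth = [0.0]
    split = {}
    active = []

    def spawn(p: int, t: float) -> int:
        parent.append(p)
        birth.append(t)
        return len(parent) - 1

    t = 0.0
    active = [spawn(0, 0.0), spawn(0, 0.0)]  # root splits at time 0
    split[0] = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        j = int(rng.integers(len(active)))
        v = active.pop(j)
        split[v] = t
        active.extend([spawn(v, t), spawn(v, t)])
    t_end = t + rng.exponential(1.0 / n_tips)
    factor = depth / t_end
    lengths = np.zeros(len(parent))
    labels: list[str | None] = [None] * len(parent)
    tip_no = 0
    for v in range(1, len(parent)):
        end = split.get(v, t_end)
        lengths[v] = (end - birth[v]) * factor
        if v not in split:
            tip_no += 1
            labels[v] = f"t{tip_no}"
    return TimeTree(parent, lengths, labels)
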