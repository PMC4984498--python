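"""Two-state Markov (Mk2) model of discrete character evolution on a tree.

Likelihood by Felsenstein pruning with the closed-form 2x2 transition
probabilities, maximum-likelihood fitting of free- and equal-rate models,
likelihood-ratio tests, a slice-sampling MCMC over the two rates with
exponential priors, and marginal ancestral-state reconstruction.

State 0 is GSD (genotypic sex determination) and state 1 is TSD
(temperature-dependent), so ``q01`` is the GSD-to-TSD rate ``q_GT`` and
``q10`` is ``q_TG``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._core import mk2_prune
from .treeio import Phylogeny, TipStateTable

__all__ = [
    "Mk2Model",
    "ModelComparison",
    "MCMCTrace",
    "AsymmetryPP",
    "MarginalReconstruction",
    "mk2_loglik",
    "fit_mk2",
    "lrt",
    "mk2_mcmc",
    "posterior_prob_asymmetry",
    "marginal_asr_mk2",
]

ROOT_PRIORS = ("flat", "stationary", "obs-weighted", "fixed:0", "fixed:1")

#: lower bound for rates during optimization (avoids log(0))
RATE_FLOOR = 1e-9
RATE_CEIL = 1e2


@dataclass
class Mk2Model:
    """Transition rates (per lineage per unit time) and root-prior choice.

    ``root_prior``: 'flat', 'stationary', 'obs-weighted' (weights
    proportional to each state's root partial likelihood) or 'fixed:0' /
    'fixed:1'.
    """

    q01: float
    q10: float
    root_prior: str = "obs-weighted"

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be non-negative")
        if self.root_prior not in ROOT_PRIORS:
            raise ValueError(f"root_prior must be one of {ROOT_PRIORS}")

    # field-standard aliases (GSD = 0, TSD = 1)
    @property
    def q_GT(self) -> float:
        return self.q01

    @property
    def q_TG(self) -> float:
        return self.q10


@dataclass
class ModelComparison:
    """Likelihood-ratio test between two nested models."""

    loglik_null: float
    loglik_alt: float
    df: int
    lrt_stat: float
    p_value: float
    statistic: float | None = None  #: raw statistic for bootstrap harnesses (e.g. dLL)
    details: dict = field(default_factory=dict)


@dataclass
class MCMCTrace:
    """Post-burn-in posterior samples of (q01, q10) with their log-likelihoods."""

    q01: np.ndarray
    q10: np.ndarray
    loglik: np.ndarray
    prior_mean: float
    n_steps: int
    burn_in: float
    seed: int | None = None

    def __len__(self):
        return len(self.q01)


@dataclass
class AsymmetryPP:
    """Posterior probability that q_TG > q_GT, with the two-sided 95% flag."""

    pp: float
    significant: bool


@dataclass
class MarginalReconstruction:
    """Per-node marginal posterior state probabilities, rows summing to 1.

    ``probs[v]`` is (p_state0, p_state1) for node id ``v``; tip rows are
    point masses on the observed state.
    """

    probs: np.ndarray
    n_tips: int
    root: int

    @property
    def root_probs(self) -> np.ndarray:
        return self.probs[self.root]

    def internal_probs(self) -> np.ndarray:
        return self.probs[self.n_tips :]


def transition_matrices(q01: float, q10: float, lengths: np.ndarray) -> np.ndarray:
    """Closed-form exp(Q t) for the 2-state chain, per edge."""
    n = len(lengths)
    P = np.empty((n, 2, 2))
    s = q01 + q10
    if s == 0:
        P[:] = np.eye(2)
        return P
    e = np.exp(-s * lengths)
    P[:, 0, 0] = (q10 + q01 * e) / s
    P[:, 0, 1] = q01 * (1.0 - e) / s
    P[:, 1, 0] = q10 * (1.0 - e) / s
    P[:, 1, 1] = (q01 + q10 * e) / s
    return P


def _root_weights(prior: str, D: np.ndarray, q01: float, q10: float) -> np.ndarray:
    if prior == "flat":
        return np.array([0.5, 0.5])
    if prior == "stationary":
        s = q01 + q10
        if s == 0:
            return np.array([0.5, 0.5])
        return np.array([q10 / s, q01 / s])
    if prior == "obs-weighted":
        tot = D.sum()
        return D / tot if tot > 0 else np.array([0.5, 0.5])
    if prior == "fixed:0":
        return np.array([1.0, 0.0])
    if prior == "fixed:1":
        return np.array([0.0, 1.0])
    raise ValueError(prior)


def _prune(tree: Phylogeny, tip_state: np.ndarray, q01: float, q10: float):
    P = transition_matrices(q01, q10, tree.lengths)
    D0, D1, logscale = mk2_prune(
        tree.postorder, tree.child1, tree.child2, tree.n_tips,
        np.ascontiguousarray(tip_state), P,
    )
    return D0, D1, logscale


def mk2_loglik(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    model: Mk2Model,
    allow_unknown: bool = False,
) -> float:
    """Log-likelihood of the tip states under the Mk2 model.

    With ``allow_unknown`` (or an ndarray containing -1 entries), tips of
    unknown state are marginalized over both states instead of rejected.
    """
    tip_state = (
        states if isinstance(states, np.ndarray)
        else states.states_for(tree, allow_unknown=allow_unknown)
    )
    D0, D1, logscale = _prune(tree, tip_state, model.q01, model.q10)
    if not np.isfinite(logscale):
        return -np.inf
    Droot = np.array([D0[tree.root], D1[tree.root]])
    w = _root_weights(model.root_prior, Droot, model.q01, model.q10)
    L = float(w @ Droot)
    if L <= 0:
        return -np.inf
    return float(np.log(L) + logscale)


def fit_mk2(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    constrain_equal: bool = False,
    root_prior: str = "obs-weighted",
    n_starts: int = 5,
    allow_unknown: bool = False,
) -> tuple[Mk2Model, float]:
    """Maximum-likelihood transition rates (free, or constrained q01 = q10).

    Bounded L-BFGS-B on log rates with multi-starts (one heuristic start at
    the change-per-total-treelength scale plus log-uniform draws from a fixed
    internal stream, so fits are deterministic).  Unknown-state tips are
    marginalized when ``allow_unknown`` is set.
    """
    tip_state = (
        states if isinstance(states, np.ndarray)
        else states.states_for(tree, allow_unknown=allow_unknown)
    )
    counts = np.bincount(tip_state[tip_state >= 0], minlength=2)
    if counts.min() < 2:
        warnings.warn(
            "fewer than 2 tips in one state; rate estimates may sit at a bound",
            stacklevel=2,
        )
    lo, hi = np.log(RATE_FLOOR), np.log(RATE_CEIL)
    ndim = 1 if constrain_equal else 2

    def negll(logq):
        q = np.exp(np.clip(logq, lo, hi))
        q01, q10 = (q[0], q[0]) if constrain_equal else (q[0], q[1])
        model = Mk2Model(q01, q10, root_prior)
        return -mk2_loglik(tree, tip_state, model)

    scale = 1.0 / max(tree.total_length(), 1e-12)
    rng = np.random.default_rng(12345)
    starts = [np.full(ndim, np.log(max(scale, RATE_FLOOR)))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(np.log(1e-7), np.log(10.0), size=ndim))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=[(lo, hi)] * ndim,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Mk2 optimization failed for all starts")
    q = np.exp(best.x)
    q01, q10 = (q[0], q[0]) if constrain_equal else (q[0], q[1])
    return Mk2Model(float(q01), float(q10), root_prior), float(-best.fun)


def lrt(loglik_null: float, loglik_alt: float, df: int, tol: float = 1e-6) -> ModelComparison:
    """Likelihood-ratio test of nested models against a chi-square null."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if loglik_alt < loglik_null - tol:
        raise ValueError(
            f"alternative log-likelihood {loglik_alt:.6f} below null "
            f"{loglik_null:.6f}: optimizer failure"
        )
    stat = max(0.0, 2.0 * (loglik_alt - loglik_null))
    p = float(stats.chi2.sf(stat, df))
    return ModelComparison(
        loglik_null=float(loglik_null),
        loglik_alt=float(loglik_alt),
        df=df,
        lrt_stat=stat,
        p_value=p,
        statistic=float(loglik_alt - loglik_null),
    )


def _slice_sample(logpost, x0, lp0, w, rng, max_steps=100):
    """Univariate slice sampler (Neal 2003) with step-out, on an unbounded axis."""
    logy = lp0 + np.log(rng.random())
    left = x0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logpost(left) <= logy:
            break
        left -= w
    for _ in range(max_steps):
        if logpost(right) <= logy:
            break
        right += w
    for _ in range(max_steps):
        x1 = left + (right - left) * rng.random()
        lp1 = logpost(x1)
        if lp1 >= logy:
            return x1, lp1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0, lp0  # degenerate slice; keep current point


def mk2_mcmc(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    prior_mean: float = 0.1,
    n_steps: int = 2000,
    burn_in: float = 0.25,
    seed: int | None = None,
    root_prior: str = "obs-weighted",
    slice_width: float = 1.0,
) -> MCMCTrace:
    """Posterior sampling of (q01, q10) under independent exponential priors.

    One step = a fixed-order scan (q01 then q10) of univariate slice updates
    on the log-rate axis (step-out width ``slice_width``); the first
    ``burn_in`` fraction of steps is discarded.
    """
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    rng = np.random.default_rng(seed)

    def loglik(q01, q10):
        return mk2_loglik(tree, tip_state, Mk2Model(q01, q10, root_prior))

    def logpost_axis(u, other, axis):
        # u = log q on the updated axis; exponential prior + Jacobian
        q = np.exp(u)
        if q < RATE_FLOOR or q > RATE_CEIL:
            return -np.inf
        q01, q10 = (q, other) if axis == 0 else (other, q)
        return loglik(q01, q10) - q / prior_mean + u

    u = np.log([prior_mean, prior_mean])
    keep = n_steps - int(round(n_steps * burn_in))
    out_q01 = np.empty(keep)
    out_q10 = np.empty(keep)
    out_ll = np.empty(keep)
    k = 0
    for step in range(n_steps):
        u[0], _ = _slice_sample(
            lambda x: logpost_axis(x, np.exp(u[1]), 0), u[0],
            logpost_axis(u[0], np.exp(u[1]), 0), slice_width, rng,
        )
        u[1], _ = _slice_sample(
            lambda x: logpost_axis(x, np.exp(u[0]), 1), u[1],
            logpost_axis(u[1], np.exp(u[0]), 1), slice_width, rng,
        )
        if step >= n_steps - keep:
            q01, q10 = np.exp(u)
            out_q01[k] = q01
            out_q10[k] = q10
            out_ll[k] = loglik(q01, q10)
            k += 1
    return MCMCTrace(out_q01, out_q10, out_ll, prior_mean, n_steps, burn_in, seed)


def posterior_prob_asymmetry(trace: MCMCTrace) -> AsymmetryPP:
    """Fraction of retained MCMC steps with q_TG > q_GT (significant outside
    [0.025, 0.975])."""
    if len(trace) == 0:
        raise ValueError("empty MCMC trace")
    pp = float(np.mean(trace.q10 > trace.q01))
    return AsymmetryPP(pp, pp > 0.975 or pp < 0.025)


def marginal_asr_mk2(
    tree: Phylogeny, states: TipStateTable | np.ndarray, model: Mk2Model
) -> MarginalReconstruction:
    """Marginal ancestral-state probabilities at every node.

    Standard two-pass algorithm: tipward partials D from pruning, rootward
    partials G by a preorder sweep (root row = prior; each child combines the
    parent's G with its sibling's lifted partial), marginal at a node
    proportional to G * D, renormalized.
    """
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    D0, D1, logscale = _prune(tree, tip_state, model.q01, model.q10)
    if not np.isfinite(logscale):
        raise ValueError("data have zero likelihood under this model")
    n = tree.n_nodes
    D = np.stack([D0, D1], axis=1)
    P = transition_matrices(model.q01, model.q10, tree.lengths)
    Droot = D[tree.root]
    pi = _root_weights(model.root_prior, Droot, model.q01, model.q10)
    G = np.zeros((n, 2))
    G[tree.root] = pi
    for v in tree.postorder[::-1]:
        if tree.is_tip(v):
            continue
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        for c, sib in ((c1, c2), (c2, c1)):
            lifted = P[sib] @ D[sib]
            H = G[v] * lifted
            Gc = P[c].T @ H
            tot = Gc.sum()
            G[c] = Gc / tot if tot > 0 else Gc
    probs = G * D
    probs /= probs.sum(axis=1, keepdims=True)
    return MarginalReconstruction(probs=probs, n_tips=tree.n_tips, root=tree.root)
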