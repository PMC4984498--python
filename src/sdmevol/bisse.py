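"""Binary-state speciation and extinction (BiSSE) model.

Joint likelihood of tree shape and tip states with state-dependent
speciation (lambda), extinction (mu), and transition rates (q), integrating
the coupled extinction-probability / data-likelihood ODEs along every branch
(fixed-step RK4, rescaled partials).  Incomplete sampling enters through the
"skeletal tree" boundary conditions E_i(0) = 1 - f_i, D_i(0) = f_i.

Constrained fits support the transition-rate test (lambda and mu shared
between states, free vs. equal q) and the diversification test (shared vs.
state-dependent lambda), plus marginal ancestral-state reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from ._core import bisse_branch_matrices, bisse_prune
from .mk2 import MarginalReconstruction, ModelComparison, fit_mk2, lrt
from .treeio import Phylogeny, TipStateTable

__all__ = [
    "BisseModel",
    "bisse_loglik",
    "yule_loglik",
    "fit_yule",
    "fit_bisse_transition_test",
    "fit_bisse_diversification_test",
    "marginal_asr_bisse",
]

#: RK4 step ceiling as a fraction of the fastest process timescale
_STEP_SCALE = 0.01
_RATE_FLOOR = 1e-9


@dataclass
class BisseModel:
    """Full BiSSE parameter bundle (state 0 = GSD, 1 = TSD).

    ``f0``/``f1`` are sampling fractions in (0, 1]; ``condition_on_survival``
    divides the root partials by lambda_i * (1 - E_i)^2 before the root-prior
    combination (both daughters of the root survive to the present).
    """

    lambda0: float
    lambda1: float
    mu0: float
    mu1: float
    q01: float
    q10: float
    f0: float = 1.0
    f1: float = 1.0
    condition_on_survival: bool = True
    root_prior: str = "obs-weighted"

    def __post_init__(self):
        for r in (self.lambda0, self.lambda1, self.mu0, self.mu1, self.q01, self.q10):
            if r < 0:
                raise ValueError("rates must be non-negative")
        for f in (self.f0, self.f1):
            if not 0 < f <= 1:
                raise ValueError("sampling fractions must be in (0, 1]")

    def rate_scale(self) -> float:
        return max(
            self.lambda0 + self.mu0 + self.q01,
            self.lambda1 + self.mu1 + self.q10,
            1e-8,
        )


def _root_combine(model: BisseModel, Droot: np.ndarray, Eroot: np.ndarray) -> float:
    """Root treatment: optional survival conditioning, then prior weighting.

    Returns the (linear-scale) combined likelihood contribution at the root.
    """
    D = Droot.copy()
    lam = np.array([model.lambda0, model.lambda1])
    if model.condition_on_survival:
        denom = lam * (1.0 - Eroot) ** 2
        if np.any(denom <= 0):
            return 0.0
        D = D / denom
    if model.root_prior == "flat":
        w = np.array([0.5, 0.5])
    elif model.root_prior == "obs-weighted":
        tot = D.sum()
        w = D / tot if tot > 0 else np.array([0.5, 0.5])
    elif model.root_prior == "fixed:0":
        w = np.array([1.0, 0.0])
    elif model.root_prior == "fixed:1":
        w = np.array([0.0, 1.0])
    else:
        raise ValueError(f"unsupported root prior {model.root_prior!r}")
    return float(w @ D)


def bisse_loglik(tree: Phylogeny, states: TipStateTable | np.ndarray, model: BisseModel) -> float:
    """BiSSE log-likelihood of tree + tip states."""
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    dt_max = _STEP_SCALE / model.rate_scale()
    E0, E1, D0, D1, logscale = bisse_prune(
        tree.postorder, tree.child1, tree.child2, tree.lengths, tree.n_tips,
        np.ascontiguousarray(tip_state),
        model.lambda0, model.lambda1, model.mu0, model.mu1,
        model.q01, model.q10, model.f0, model.f1, dt_max,
    )
    if not np.isfinite(logscale):
        return -np.inf
    r = tree.root
    L = _root_combine(model, np.array([D0[r], D1[r]]), np.array([E0[r], E1[r]]))
    if L <= 0:
        return -np.inf
    return float(np.log(L) + logscale)


def yule_loglik(tree: Phylogeny, lam: float, condition_on_survival: bool = True) -> float:
    """Closed-form pure-birth likelihood of the tree shape.

    Each of the n-1 splits contributes log(lambda) and every unit of branch
    length contributes -lambda; survival conditioning removes one factor of
    lambda (matching the BiSSE root treatment with mu = 0, q = 0, f = 1).
    """
    if lam <= 0:
        return -np.inf
    n_splits = tree.n_tips - 1
    ll = n_splits * np.log(lam) - lam * tree.total_length()
    if condition_on_survival:
        ll -= np.log(lam)
    return float(ll)


def fit_yule(tree: Phylogeny, condition_on_survival: bool = True) -> tuple[float, float]:
    """ML speciation rate of the pure-birth model: (n-2)/total length
    (conditioned) or (n-1)/total length; returns (lambda_hat, loglik)."""
    k = tree.n_tips - 2 if condition_on_survival else tree.n_tips - 1
    lam = k / tree.total_length()
    return float(lam), yule_loglik(tree, lam, condition_on_survival)


def _fit(tree, tip_state, build_model, x0s, bounds):
    """Shared bounded multi-start optimizer on log-parameters."""
    lo = np.log(_RATE_FLOOR)

    def negll(x):
        try:
            model = build_model(np.exp(x))
        except ValueError:
            return np.inf
        ll = bisse_loglik(tree, tip_state, model)
        return -ll if np.isfinite(ll) else 1e10

    best = None
    for x0 in x0s:
        res = optimize.minimize(
            negll, np.maximum(np.asarray(x0, dtype=float), lo),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e10:
        raise RuntimeError("BiSSE optimization failed for all starts")
    return build_model(np.exp(best.x)), float(-best.fun)


def _rate_bound(tree: Phylogeny) -> float:
    """Upper bound for any rate: ~200 expected events per root-to-tip path.

    Keeps the optimizer away from regimes where the ODE step count (and the
    data's support) is absurd; generous relative to any identifiable rate.
    """
    return 200.0 / max(tree.height(), 1e-9)


def _heuristic_starts(tree, tip_state, sampling_fraction):
    """Start values: Yule lambda on the skeletal tree, tiny mu, Mk2 q's."""
    lam0, _ = fit_yule(tree)
    # crude sampling correction: more of the clade exists than is in the tree
    lam0 = lam0 / max(sampling_fraction, 0.05) if sampling_fraction < 1 else lam0
    mk2_model, _ = fit_mk2(tree, tip_state, n_starts=2)
    q01 = max(mk2_model.q01, _RATE_FLOOR)
    q10 = max(mk2_model.q10, _RATE_FLOOR)
    return lam0, q01, q10


def fit_bisse_transition_test(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    sampling_fraction: float = 1.0,
    condition_on_survival: bool = True,
    root_prior: str = "obs-weighted",
) -> tuple[BisseModel, ModelComparison]:
    """Free-q vs equal-q BiSSE fits with shared lambda and mu (LRT, df = 1).

    A single sampling fraction is applied to both states (skeletal-tree
    assumption).  Returns the free-rate model and the model comparison.
    """
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    f = sampling_fraction
    lam0, q01h, q10h = _heuristic_starts(tree, tip_state, f)
    mu0 = max(lam0 * 0.05, _RATE_FLOOR)
    lo, hi = np.log(_RATE_FLOOR), np.log(_rate_bound(tree))
    bounds3 = [(lo, hi)] * 3
    bounds4 = [(lo, hi)] * 4

    def model_equal(p):
        lam, mu, q = p
        return BisseModel(lam, lam, mu, mu, q, q, f, f, condition_on_survival, root_prior)

    def model_free(p):
        lam, mu, q01, q10 = p
        return BisseModel(lam, lam, mu, mu, q01, q10, f, f, condition_on_survival, root_prior)

    qg = np.sqrt(q01h * q10h)
    x_eq = [np.log([lam0, mu0, qg]), np.log([lam0 * 2, mu0, qg * 3])]
    m_eq, ll_eq = _fit(tree, tip_state, model_equal, x_eq, bounds3)
    x_free = [
        np.log([lam0, mu0, q01h, q10h]),
        np.log([m_eq.lambda0, max(m_eq.mu0, _RATE_FLOOR), m_eq.q01, m_eq.q10]),
    ]
    m_free, ll_free = _fit(tree, tip_state, model_free, x_free, bounds4)
    ll_free = max(ll_free, ll_eq)  # nesting guard against optimizer slack
    comp = lrt(ll_eq, ll_free, df=1)
    comp.details = {"null_model": m_eq, "alt_model": m_free}
    return m_free, comp


def fit_bisse_diversification_test(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    sampling_fraction: float = 1.0,
    condition_on_survival: bool = True,
    root_prior: str = "obs-weighted",
) -> ModelComparison:
    """State-dependent vs state-independent speciation (LRT, df = 1).

    Null: shared lambda and mu with free q01, q10.  Alternative: per-state
    lambda.  ``statistic`` on the result is the log-likelihood difference
    (dLL) fed to the parametric-bootstrap harness.
    """
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    f = sampling_fraction
    lam0, q01h, q10h = _heuristic_starts(tree, tip_state, f)
    mu0 = max(lam0 * 0.05, _RATE_FLOOR)
    lo, hi = np.log(_RATE_FLOOR), np.log(_rate_bound(tree))

    def model_null(p):
        lam, mu, q01, q10 = p
        return BisseModel(lam, lam, mu, mu, q01, q10, f, f, condition_on_survival, root_prior)

    def model_alt(p):
        la0, la1, mu, q01, q10 = p
        return BisseModel(la0, la1, mu, mu, q01, q10, f, f, condition_on_survival, root_prior)

    x_null = [np.log([lam0, mu0, q01h, q10h])]
    m_null, ll_null = _fit(tree, tip_state, model_null, x_null, [(lo, hi)] * 4)
    mun = max(m_null.mu0, _RATE_FLOOR)
    # start at the null solution, nudged off the symmetric point
    x_alt = [
        np.log([m_null.lambda0 * 1.02, m_null.lambda1 / 1.02, mun,
                max(m_null.q01, _RATE_FLOOR), max(m_null.q10, _RATE_FLOOR)]),
    ]
    m_alt, ll_alt = _fit(tree, tip_state, model_alt, x_alt, [(lo, hi)] * 5)
    ll_alt = max(ll_alt, ll_null)  # nesting guard against optimizer slack
    comp = lrt(ll_null, ll_alt, df=1)
    comp.details = {"null_model": m_null, "alt_model": m_alt}
    return comp


def marginal_asr_bisse(
    tree: Phylogeny, states: TipStateTable | np.ndarray, model: BisseModel
) -> MarginalReconstruction:
    """Marginal ancestral-state probabilities under a BiSSE model.

    Uses the linearity of the D system: each branch is summarized by a 2x2
    transfer matrix (integrated alongside the shared E trajectory), after
    which the same two-pass marginalization as in the Mk2 case applies, with
    speciation-rate factors at the nodes.
    """
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    dt_max = _STEP_SCALE / model.rate_scale()
    E0, E1, M = bisse_branch_matrices(
        tree.postorder, tree.child1, tree.child2, tree.lengths, tree.n_tips,
        model.lambda0, model.lambda1, model.mu0, model.mu1,
        model.q01, model.q10, model.f0, model.f1, dt_max,
    )
    n = tree.n_nodes
    lam = np.array([model.lambda0, model.lambda1])
    D = np.zeros((n, 2))
    D[: tree.n_tips, 0] = np.where(tip_state == 0, model.f0, 0.0)
    D[: tree.n_tips, 1] = np.where(tip_state == 1, model.f1, 0.0)
    for v in tree.postorder:
        if tree.is_tip(v):
            continue
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        d = lam * (M[c1] @ D[c1]) * (M[c2] @ D[c2])
        tot = d.sum()
        if tot <= 0:
            raise ValueError("zero likelihood during BiSSE reconstruction")
        D[v] = d / tot
    r = tree.root
    Dc = D[r].copy()
    if model.condition_on_survival:
        Dc = Dc / (lam * (1.0 - np.array([E0[r], E1[r]])) ** 2)
    if model.root_prior == "flat":
        pi = np.array([0.5, 0.5])
    elif model.root_prior == "obs-weighted":
        pi = Dc / Dc.sum()
    elif model.root_prior == "fixed:0":
        pi = np.array([1.0, 0.0])
    elif model.root_prior == "fixed:1":
        pi = np.array([0.0, 1.0])
    else:
        raise ValueError(f"unsupported root prior {model.root_prior!r}")
    G = np.zeros((n, 2))
    G[r] = pi
    for v in tree.postorder[::-1]:
        if tree.is_tip(v):
            continue
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        for c, sib in ((c1, c2), (c2, c1)):
            H = G[v] * lam * (M[sib] @ D[sib])
            Gc = M[c].T @ H
            tot = Gc.sum()
            G[c] = Gc / tot if tot > 0 else Gc
    probs = G * D
    probs /= probs.sum(axis=1, keepdims=True)
    return MarginalReconstruction(probs=probs, n_tips=tree.n_tips, root=r)
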