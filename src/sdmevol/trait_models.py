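"""Regime-dependent continuous-trait evolution: BM1/BM2/OU1/OUM on log lifespan.

The tree is painted into GSD/TSD regimes (typically from a marginal
ancestral-state reconstruction); lifespans are natural-log transformed.
Four Gaussian models are fitted by maximum likelihood through the exact tip
covariance:

* BM1 - single-rate Brownian motion (sigma^2 shared);
* BM2 - per-regime Brownian rates (covariance is the regime-partitioned
  shared path length weighted by each regime's sigma^2);
* OU1 - single-optimum Ornstein-Uhlenbeck (shared alpha, sigma^2, theta),
  process started at the optimum, non-stationary covariance (so the
  alpha -> 0 limit recovers BM1);
* OUM - per-regime optima theta_GSD, theta_TSD with shared alpha and
  sigma^2; tip expectations weight each optimum by the exponentially
  discounted time the lineage spent in that regime.

Location parameters (optima / root value) and the overall scale are profiled
out in closed form (GLS), leaving a one-dimensional search over alpha (or
the BM2 rate ratio), which makes the fits fast and robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import solve_triangular

from .mk2 import MarginalReconstruction, ModelComparison, lrt
from .treeio import Phylogeny, TipStateTable, TipValueTable, validate_ultrametric

__all__ = [
    "RegimePainting",
    "TraitModelFit",
    "TraitModelComparison",
    "paint_regimes",
    "fit_trait_model",
    "compare_trait_models",
    "MODELS",
]

MODELS = ("BM1", "BM2", "OU1", "OUM")


@dataclass
class RegimePainting:
    """Regime (0 = GSD, 1 = TSD) of the branch above each node.

    ``regimes[root]`` records the root regime (there is no root branch).
    """

    regimes: np.ndarray
    provenance: str = "user"

    def __post_init__(self):
        self.regimes = np.asarray(self.regimes, dtype=np.int8)
        if not np.isin(self.regimes, [0, 1]).all():
            raise ValueError("regimes must be 0 or 1 on every branch")


@dataclass
class TraitModelFit:
    """Fitted parameters, log-likelihood and AIC of one trait model.

    ``sigma2`` and ``theta`` are per-regime pairs (equal entries when the
    model shares them); ``theta`` is None for BM models, on the natural-log
    scale otherwise.  ``root_value`` is the trait value at the root (log
    scale).  ``fingerprint`` identifies the data the model was fitted to.
    """

    model: str
    sigma2: tuple
    alpha: float
    theta: tuple | None
    root_value: float
    loglik: float
    k: int
    aic: float
    fingerprint: tuple = ()

    def optima_years(self) -> tuple | None:
        if self.theta is None:
            return None
        return tuple(float(np.exp(t)) for t in self.theta)


def paint_regimes(
    asr: MarginalReconstruction, states: TipStateTable | np.ndarray, tree: Phylogeny
) -> RegimePainting:
    """Branch regimes from a marginal reconstruction: each branch takes the
    regime of its child node (argmax marginal at internal nodes, observed
    state at tips); exact ties resolve toward the parent's regime (a root tie
    resolves to state 1, the inferred ancestral state in these data)."""
    tip_state = states if isinstance(states, np.ndarray) else states.states_for(tree)
    probs = asr.probs
    if probs.shape[0] != tree.n_nodes:
        raise ValueError("reconstruction does not cover every node")
    reg = np.empty(tree.n_nodes, dtype=np.int8)
    for v in tree.postorder[::-1]:  # preorder: parents before children
        if tree.is_tip(v):
            reg[v] = tip_state[v]
            continue
        p0, p1 = probs[v]
        if p0 > p1:
            reg[v] = 0
        elif p1 > p0:
            reg[v] = 1
        else:
            reg[v] = reg[tree.parent[v]] if tree.parent[v] >= 0 else 1
    return RegimePainting(reg, provenance="asr-max-marginal")


def _regime_path_matrices(tree: Phylogeny, regimes: np.ndarray):
    """Per-regime shared root-to-MRCA path lengths C_r (C_0 + C_1 = C)."""
    n = tree.n_tips
    depth_r = np.zeros((tree.n_nodes, 2))
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p < 0:
            continue
        depth_r[v] = depth_r[p]
        depth_r[v, regimes[v]] += tree.lengths[v]
    C0 = np.zeros((n, n))
    C1 = np.zeros((n, n))
    tipsets: dict[int, np.ndarray] = {}
    for v in tree.postorder:
        if tree.is_tip(v):
            tipsets[v] = np.asarray([v])
            C0[v, v] = depth_r[v, 0]
            C1[v, v] = depth_r[v, 1]
        else:
            a = tipsets.pop(int(tree.child1[v]))
            b = tipsets.pop(int(tree.child2[v]))
            for C, r in ((C0, 0), (C1, 1)):
                C[np.ix_(a, b)] = depth_r[v, r]
                C[np.ix_(b, a)] = depth_r[v, r]
            tipsets[v] = np.concatenate([a, b])
    return C0, C1


def _gls_profile(z: np.ndarray, V0: np.ndarray, X: np.ndarray):
    """Profile the location parameters and overall scale out of a Gaussian
    likelihood with covariance sigma2 * V0 and mean X @ beta.

    Returns (loglik, beta_hat, sigma2_hat).  Raises on a singular V0.
    """
    n = len(z)
    L = np.linalg.cholesky(V0)
    zw = solve_triangular(L, z, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, zw, rcond=None)
    resid = zw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        raise np.linalg.LinAlgError("degenerate residual variance")
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(ll), beta, float(sigma2)


def _ou_covariance(C: np.ndarray, T: float, alpha: float) -> np.ndarray:
    """Non-stationary OU tip covariance (process rooted at its start value):
    V0_ij = exp(-2 alpha (T - t_mrca)) * (1 - exp(-2 alpha t_mrca)) / (2 alpha),
    continuous at alpha -> 0 where it reduces to t_mrca (Brownian motion)."""
    if alpha <= 0:
        return C.copy()
    return np.exp(-2.0 * alpha * (T - C)) * (-np.expm1(-2.0 * alpha * C)) / (2.0 * alpha)


def _ou_design(tree: Phylogeny, regimes: np.ndarray, T: float, alpha: float, per_regime: bool):
    """Tip expectation design matrix.

    For OUM, column r holds the exponentially discounted fraction of each
    root-to-tip path spent in regime r, with the residual root weight
    exp(-alpha T) assigned to the root regime (root value = root optimum);
    rows sum to 1.  For OU1 this collapses to a column of ones.
    """
    n = tree.n_tips
    if not per_regime:
        return np.ones((n, 1))
    depth = tree.depths()
    W = np.zeros((tree.n_nodes, 2))
    # weight of the segment above node v: discounted time in its regime
    for v in tree.postorder[::-1]:
        p = tree.parent[v]
        if p < 0:
            continue
        W[v] = W[p]
        t0, t1 = depth[p], depth[v]
        if alpha > 0:
            w = np.exp(-alpha * (T - t1)) - np.exp(-alpha * (T - t0))
        else:
            w = (t1 - t0) / T if T > 0 else 0.0
        W[v, regimes[v]] += w
    X = W[: tree.n_tips].copy()
    root_w = np.exp(-alpha * T) if alpha > 0 else 0.0
    X[:, regimes[tree.root]] += root_w
    return X


def fit_trait_model(
    tree: Phylogeny,
    values: TipValueTable | np.ndarray,
    painting: RegimePainting | None,
    model: str,
    ultrametric_tol: float = 1e-6,
) -> TraitModelFit:
    """ML fit of one of BM1/BM2/OU1/OUM to log-transformed tip values.

    ``values`` in natural units (log taken here) or an ndarray already on the
    log scale.  BM2 and OUM require a painting.  OU models require an
    ultrametric tree.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if model in ("BM2", "OUM") and painting is None:
        raise ValueError(f"{model} requires a regime painting")
    if isinstance(values, TipValueTable):
        z = values.values_for(tree, log=True)
    else:
        z = np.asarray(values, dtype=float)
        if len(z) != tree.n_tips:
            raise ValueError("log-value array must have one entry per tip")
    if model.startswith("OU"):
        ok, dev = validate_ultrametric(tree, ultrametric_tol)
        if not ok:
            raise ValueError(f"OU models require an ultrametric tree (deviation {dev:.2g})")
    C = tree.mrca_matrix()
    T = tree.height()
    fingerprint = (tree.n_tips, round(float(z.sum()), 10))
    ones = np.ones((tree.n_tips, 1))

    if model == "BM1":
        ll, beta, s2 = _gls_profile(z, C, ones)
        return TraitModelFit("BM1", (s2, s2), 0.0, None, float(beta[0]),
                             ll, 2, 2 * 2 - 2 * ll, fingerprint)

    if model == "BM2":
        C0, C1 = _regime_path_matrices(tree, painting.regimes)

        def nll(log_rho):
            rho = np.exp(log_rho)
            V0 = C0 + rho * C1
            try:
                ll, _b, _s = _gls_profile(z, V0, ones)
            except np.linalg.LinAlgError:
                return np.inf
            return -ll

        res = _scan_minimize(nll, lo=np.log(1e-6), hi=np.log(1e6), n_grid=31)
        rho = float(np.exp(res.x))
        ll, beta, s2g = _gls_profile(z, C0 + rho * C1, ones)
        return TraitModelFit("BM2", (s2g, s2g * rho), 0.0, None, float(beta[0]),
                             ll, 3, 2 * 3 - 2 * ll, fingerprint)

    per_regime = model == "OUM"
    regimes = painting.regimes if painting is not None else None
    alpha_hi = 50.0 / T

    def nll(log_alpha):
        alpha = np.exp(log_alpha)
        V0 = _ou_covariance(C, T, alpha)
        X = _ou_design(tree, regimes, T, alpha, per_regime) if per_regime else ones
        try:
            ll, _b, _s = _gls_profile(z, V0, X)
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    res = _scan_minimize(nll, lo=np.log(1e-8 / T), hi=np.log(alpha_hi), n_grid=61)
    alpha = float(np.exp(res.x))
    V0 = _ou_covariance(C, T, alpha)
    X = _ou_design(tree, regimes, T, alpha, per_regime) if per_regime else ones
    ll, beta, s2 = _gls_profile(z, V0, X)
    if per_regime:
        theta = (float(beta[0]), float(beta[1]))
        root_value = theta[int(regimes[tree.root])]
        k = 4
    else:
        theta = (float(beta[0]), float(beta[0]))
        root_value = theta[0]
        k = 3
    return TraitModelFit(model, (s2, s2), alpha, theta, root_value,
                         ll, k, 2 * k - 2 * ll, fingerprint)


def _scan_minimize(fn, lo, hi, n_grid):
    """Coarse log-grid scan followed by a bounded 1-D refinement."""
    grid = np.linspace(lo, hi, n_grid)
    vals = [fn(g) for g in grid]
    i = int(np.argmin(vals))
    a = grid[max(0, i - 1)]
    b = grid[min(n_grid - 1, i + 1)]
    res = optimize.minimize_scalar(fn, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    if vals[i] < res.fun:
        class R:  # grid point beat the refinement (flat objective)
            x = grid[i]
            fun = vals[i]
        return R
    return res


@dataclass
class TraitModelComparison:
    """LRTs (BM1 vs BM2, OU1 vs OUM) and AIC ranking across the four models."""

    fits: dict
    bm_test: ModelComparison
    ou_test: ModelComparison
    aic_ranking: list = field(default_factory=list)

    def best_model(self) -> str:
        return self.aic_ranking[0]

    def to_row(self) -> dict:
        f = self.fits
        oum = f["OUM"]
        return {
            "loglik_BM1": f["BM1"].loglik,
            "loglik_BM2": f["BM2"].loglik,
            "BM_p_value": self.bm_test.p_value,
            "sigma2_GSD": f["BM2"].sigma2[0],
            "sigma2_TSD": f["BM2"].sigma2[1],
            "loglik_OU1": f["OU1"].loglik,
            "loglik_OUM": oum.loglik,
            "OU_p_value": self.ou_test.p_value,
            "optimum_GSD_years": oum.optima_years()[0],
            "optimum_TSD_years": oum.optima_years()[1],
            "best_AIC": self.best_model(),
        }


def compare_trait_models(fits: dict) -> TraitModelComparison:
    """Compare BM1/BM2 and OU1/OUM by LRT (df = 1 each) and all four by AIC."""
    missing = set(MODELS) - set(fits)
    if missing:
        raise ValueError(f"missing fits for {sorted(missing)}")
    prints = {f.fingerprint for f in fits.values()}
    if len(prints) != 1:
        raise ValueError("fits were not computed on identical data")
    bm = lrt(fits["BM1"].loglik, fits["BM2"].loglik, df=1)
    ou = lrt(fits["OU1"].loglik, fits["OUM"].loglik, df=1)
    ranking = sorted(MODELS, key=lambda m: fits[m].aic)
    return TraitModelComparison(fits=dict(fits), bm_test=bm, ou_test=ou,
                                aic_ranking=ranking)
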