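"""Numba kernels: Felsenstein pruning for the two-state Markov model and
tip-to-root integration of the state-dependent birth-death (E, D) system.

All kernels operate on the flat array representation of
:class:`~sdmevol.treeio.Phylogeny` (tips are ids ``0..n_tips-1``; ``postorder``
visits children before parents and ends at the root).  Partial likelihoods are
rescaled at every internal node; the accumulated log-scaler is returned
separately.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def mk2_prune(post, child1, child2, n_tips, tip_state, P):
    """Pruning pass for a 2-state Markov chain.

    ``P[v]`` is the 2x2 transition-probability matrix along the edge above
    node ``v``.  Returns per-node scaled partials ``(D0, D1)`` and the total
    log-scaler, such that the root likelihood under prior ``pi`` is
    ``log(pi0*D0[root] + pi1*D1[root]) + logscale``.
    """
    n_nodes = child1.shape[0]
    D0 = np.empty(n_nodes)
    D1 = np.empty(n_nodes)
    logscale = 0.0
    for i in range(post.shape[0]):
        v = post[i]
        if v < n_tips:
            if tip_state[v] == 0:
                D0[v] = 1.0
                D1[v] = 0.0
            elif tip_state[v] == 1:
                D0[v] = 0.0
                D1[v] = 1.0
            else:  # unknown state: marginalized (ambiguous tip)
                D0[v] = 1.0
                D1[v] = 1.0
        else:
            c1 = child1[v]
            c2 = child2[v]
            l0 = P[c1, 0, 0] * D0[c1] + P[c1, 0, 1] * D1[c1]
            l1 = P[c1, 1, 0] * D0[c1] + P[c1, 1, 1] * D1[c1]
            r0 = P[c2, 0, 0] * D0[c2] + P[c2, 0, 1] * D1[c2]
            r1 = P[c2, 1, 0] * D0[c2] + P[c2, 1, 1] * D1[c2]
            d0 = l0 * r0
            d1 = l1 * r1
            m = d0 if d0 > d1 else d1
            if m <= 0.0:
                return D0, D1, -np.inf
            D0[v] = d0 / m
            D1[v] = d1 / m
            logscale += np.log(m)
    return D0, D1, logscale


@njit(cache=True, inline="always")
def _bisse_rhs(y, la0, la1, mu0, mu1, q01, q10, out):
    """Right-hand side of the coupled extinction/data ODEs, y = (E0,E1,D0,D1)."""
    E0, E1, D0, D1 = y[0], y[1], y[2], y[3]
    out[0] = mu0 - (la0 + mu0 + q01) * E0 + q01 * E1 + la0 * E0 * E0
    out[1] = mu1 - (la1 + mu1 + q10) * E1 + q10 * E0 + la1 * E1 * E1
    out[2] = -(la0 + mu0 + q01) * D0 + q01 * D1 + 2.0 * la0 * E0 * D0
    out[3] = -(la1 + mu1 + q10) * D1 + q10 * D0 + 2.0 * la1 * E1 * D1


@njit(cache=True)
def _integrate_branch(y, t_len, n_steps, la0, la1, mu0, mu1, q01, q10):
    """Classic RK4 over one branch; clamps E into [0,1] and D to >= 0."""
    h = t_len / n_steps
    k1 = np.empty(4)
    k2 = np.empty(4)
    k3 = np.empty(4)
    k4 = np.empty(4)
    yt = np.empty(4)
    for _ in range(n_steps):
        _bisse_rhs(y, la0, la1, mu0, mu1, q01, q10, k1)
        for j in range(4):
            yt[j] = y[j] + 0.5 * h * k1[j]
        _bisse_rhs(yt, la0, la1, mu0, mu1, q01, q10, k2)
        for j in range(4):
            yt[j] = y[j] + 0.5 * h * k2[j]
        _bisse_rhs(yt, la0, la1, mu0, mu1, q01, q10, k3)
        for j in range(4):
            yt[j] = y[j] + h * k3[j]
        _bisse_rhs(yt, la0, la1, mu0, mu1, q01, q10, k4)
        for j in range(4):
            y[j] += h * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
        for j in range(2):  # E in [0,1] against round-off
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        for j in range(2, 4):
            if y[j] < 0.0:
                y[j] = 0.0
    return y


@njit(cache=True)
def bisse_prune(
    post, child1, child2, lengths, n_tips, tip_state,
    la0, la1, mu0, mu1, q01, q10, f0, f1, dt_max,
):
    """Tip-to-root pass of the binary state speciation-extinction likelihood.

    Tips start at E_i = 1 - f_i (sampling fractions) and D_i = f_i for the
    observed state.  Each branch integrates the (E, D) system by fixed-step
    RK4 with step <= dt_max; at internal nodes daughter D's are multiplied
    together with the state's speciation rate.  Returns per-node E and scaled
    D arrays, the accumulated log-scaler, and an ok flag.
    """
    n_nodes = child1.shape[0]
    E0 = np.empty(n_nodes)
    E1 = np.empty(n_nodes)
    D0 = np.empty(n_nodes)
    D1 = np.empty(n_nodes)
    logscale = 0.0
    y = np.empty(4)
    for i in range(post.shape[0]):
        v = post[i]
        if v < n_tips:
            E0[v] = 1.0 - f0
            E1[v] = 1.0 - f1
            if tip_state[v] == 0:
                D0[v] = f0
                D1[v] = 0.0
            else:
                D0[v] = 0.0
                D1[v] = f1
        else:
            dv0 = 1.0
            dv1 = 1.0
            for ci in range(2):
                c = child1[v] if ci == 0 else child2[v]
                y[0] = E0[c]
                y[1] = E1[c]
                y[2] = D0[c]
                y[3] = D1[c]
                t_len = lengths[c]
                if t_len > 0.0:
                    n_steps = int(t_len / dt_max) + 4
                    if n_steps > 2000:
                        n_steps = 2000
                    y = _integrate_branch(y, t_len, n_steps, la0, la1, mu0, mu1, q01, q10)
                dv0 *= y[2]
                dv1 *= y[3]
                if ci == 0:
                    E0[v] = y[0]
                    E1[v] = y[1]
            d0 = la0 * dv0
            d1 = la1 * dv1
            if not (np.isfinite(d0) and np.isfinite(d1)):
                return E0, E1, D0, D1, -np.inf
            m = d0 if d0 > d1 else d1
            if m <= 0.0:
                return E0, E1, D0, D1, -np.inf
            D0[v] = d0 / m
            D1[v] = d1 / m
            logscale += np.log(m)
    return E0, E1, D0, D1, logscale


@njit(cache=True)
def bisse_branch_matrices(
    post, child1, child2, lengths, n_tips,
    la0, la1, mu0, mu1, q01, q10, f0, f1, dt_max,
):
    """Per-branch 2x2 transfer matrices of the (linear, given E) D system.

    ``M[v] @ D_bottom`` gives D at the top of the edge above node ``v``.
    Because the D equations are linear, the matrices are obtained by
    integrating two unit initial conditions alongside the (data-independent)
    E trajectory.  Also returns E at every node.  Used by the marginal
    ancestral-state reconstruction.
    """
    n_nodes = child1.shape[0]
    E0 = np.empty(n_nodes)  # E at the node (bottom of its edge)
    E1 = np.empty(n_nodes)
    Etop0 = np.empty(n_nodes)  # E at the top of the edge above the node
    Etop1 = np.empty(n_nodes)
    M = np.empty((n_nodes, 2, 2))
    ya = np.empty(4)
    yb = np.empty(4)
    for i in range(post.shape[0]):
        v = post[i]
        if v < n_tips:
            E0[v] = 1.0 - f0
            E1[v] = 1.0 - f1
        else:
            # E is data-independent, so both daughters agree; take the first
            c = child1[v]
            E0[v] = Etop0[c]
            E1[v] = Etop1[c]
        t_len = lengths[v]
        ya[0] = E0[v]
        ya[1] = E1[v]
        ya[2] = 1.0
        ya[3] = 0.0
        yb[0] = E0[v]
        yb[1] = E1[v]
        yb[2] = 0.0
        yb[3] = 1.0
        if t_len > 0.0:
            n_steps = int(t_len / dt_max) + 4
            if n_steps > 2000:
                n_steps = 2000
            ya = _integrate_branch(ya, t_len, n_steps, la0, la1, mu0, mu1, q01, q10)
            yb = _integrate_branch(yb, t_len, n_steps, la0, la1, mu0, mu1, q01, q10)
        Etop0[v] = ya[0]
        Etop1[v] = ya[1]
        M[v, 0, 0] = ya[2]
        M[v, 1, 0] = ya[3]
        M[v, 0, 1] = yb[2]
        M[v, 1, 1] = yb[3]
    return E0, E1, M
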