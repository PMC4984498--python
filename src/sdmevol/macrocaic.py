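"""Species-richness contrasts for a binary predictor (MacroCAIC-style).

At every internal node whose daughters differ in (reconstructed) predictor
value, the response contrast is the log ratio of summed clade richness,
oriented so the daughter with the larger predictor value is in the
numerator; the predictor contrast follows the standard independent-contrasts
rules (Felsenstein weighting, branch lengthening).  Contrasts are filtered
by a minimal clade size (MNS) before a through-origin regression of the
richness contrasts on the predictor contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .treeio import Phylogeny, TipStateTable, TipValueTable

__all__ = [
    "ContrastTable",
    "RegressionResult",
    "compute_contrasts",
    "macrocaic_regression",
    "NotComputableError",
    "MNS_CUTOFFS",
]

MNS_CUTOFFS = (10, 20, 30, 40)

#: floor for adjusted branch lengths (zero-length polytomy resolutions)
_BL_FLOOR = 1e-8


class NotComputableError(ValueError):
    """Too few informative contrasts survive a filter to fit the regression."""


@dataclass
class ContrastTable:
    """Per-node contrasts; ``data`` columns: node, n1, n2, clade_size,
    predictor, response, plus eligibility flags mns10..mns40."""

    data: pd.DataFrame

    def __len__(self):
        return len(self.data)

    @property
    def empty(self) -> bool:
        return len(self.data) == 0

    def surviving(self, mns: int) -> pd.DataFrame:
        return self.data[self.data["clade_size"] >= mns]


@dataclass
class RegressionResult:
    """Through-origin regression summary (r2 is the adjusted R-squared)."""

    r2: float
    slope: float
    f_stat: float
    p_value: float
    n_contrasts: int


def compute_contrasts(
    tree: Phylogeny,
    states: TipStateTable | np.ndarray,
    richness: TipValueTable | np.ndarray | None = None,
) -> ContrastTable:
    """Richness and predictor contrasts at predictor-informative nodes.

    ``richness`` maps each tip to the species count of the clade it
    represents (defaults to 1 per tip, i.e. tip counts of the tree itself).
    Clade size at a node is the richness-weighted species total beneath it.
    """
    x_tip = (states if isinstance(states, np.ndarray) else states.states_for(tree)).astype(float)
    if richness is None:
        N_tip = np.ones(tree.n_tips)
    elif isinstance(richness, np.ndarray):
        N_tip = richness.astype(float)
    else:
        richness.require_integral()
        N_tip = richness.values_for(tree)
    if np.any(N_tip <= 0):
        raise ValueError("richness must be positive")

    n = tree.n_nodes
    x = np.empty(n)
    b = np.empty(n)  # contrast-adjusted branch length above each node
    N = np.empty(n)
    x[: tree.n_tips] = x_tip
    N[: tree.n_tips] = N_tip
    b[:] = np.maximum(tree.lengths, _BL_FLOOR)

    rows = []
    for v in tree.postorder:
        if tree.is_tip(v):
            continue
        c1, c2 = int(tree.child1[v]), int(tree.child2[v])
        b1, b2 = b[c1], b[c2]
        x1, x2, N1, N2 = x[c1], x[c2], N[c1], N[c2]
        if x1 != x2:
            if x1 > x2:
                pc = (x1 - x2) / np.sqrt(b1 + b2)
                rc = np.log(N1 / N2)
                n1, n2 = N1, N2
            else:
                pc = (x2 - x1) / np.sqrt(b1 + b2)
                rc = np.log(N2 / N1)
                n1, n2 = N2, N1
            rows.append(
                dict(node=int(v), n1=n1, n2=n2, clade_size=N1 + N2,
                     predictor=pc, response=rc)
            )
        # Felsenstein down-pass: ancestral value and branch lengthening
        x[v] = (x1 / b1 + x2 / b2) / (1.0 / b1 + 1.0 / b2)
        b[v] = max(tree.lengths[v], _BL_FLOOR) + b1 * b2 / (b1 + b2)
        N[v] = N1 + N2

    df = pd.DataFrame(
        rows, columns=["node", "n1", "n2", "clade_size", "predictor", "response"]
    )
    for mns in MNS_CUTOFFS:
        df[f"mns{mns}"] = df["clade_size"] >= mns if len(df) else pd.Series(dtype=bool)
    return ContrastTable(df)


def macrocaic_regression(
    table: ContrastTable, mns: int, through_origin: bool = True
) -> RegressionResult:
    """Fit richness contrasts ~ predictor contrasts for one MNS cutoff.

    Through the origin by default (the contrasts convention); the F test then
    has (1, k-1) degrees of freedom for k surviving contrasts.
    """
    surv = table.surviving(mns)
    if len(surv) < 2:
        raise NotComputableError(
            f"only {len(surv)} contrasts survive MNS={mns}; need >= 2"
        )
    y = surv["response"].to_numpy()
    X = surv["predictor"].to_numpy()[:, None]
    if not through_origin:
        X = sm.add_constant(X)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[-1])
    return RegressionResult(
        r2=float(res.rsquared_adj),
        slope=slope,
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        n_contrasts=len(surv),
    )
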