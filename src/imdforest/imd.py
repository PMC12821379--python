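"""Inverse minimal depth (IMD) importance.

The minimal depth D_v of a variable is the depth of the shallowest node that
splits on it (predictor side) or the shallowest node where it is the maximal
splitting response variable (response side).  Its inverse minimal depth in a
tree is M_v = 1/(D_v + 1) when the variable appears, 0 otherwise, and the
forest IMD averages M_v over trees.  Larger IMD means the variable splits
early and often — a strong variable.  The classical mean-minimal-depth
threshold derived from the weak-variable depth distribution is provided as a
diagnostic: it collapses when p vastly exceeds the number of tree nodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import MRFForest, MultivariateTree

__all__ = [
    "IMDProfile",
    "TheoreticalMDParams",
    "minimal_depth",
    "imd_per_tree",
    "forest_imd",
    "imd_tscore",
    "weak_variable_md_distribution",
]


@dataclass
class IMDProfile:
    """Per-tree and forest-averaged IMD for one side of the model.

    mu is the mean forest IMD over variables, sigma_m the (sample) SD of the
    forest IMD over variables, se the per-variable standard error of the
    per-tree IMDs over the B trees.
    """

    per_tree_imd: np.ndarray  # (B, p), entries in [0, 1]
    forest_imd: np.ndarray  # (p,)
    mu: float
    sigma_m: float
    se: np.ndarray  # (p,)
    side: str  # "predictor" | "response"
    feature_ids: list[str] | None = None

    @property
    def n_trees(self) -> int:
        return self.per_tree_imd.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        ids = self.feature_ids or [f"f{i}" for i in range(len(self.forest_imd))]
        return pd.DataFrame(
            {
                "feature_id": ids,
                "side": self.side,
                "forest_imd": self.forest_imd,
                "se": self.se,
                "t_score": imd_tscore(self),
            }
        )


@dataclass
class TheoreticalMDParams:
    """Parameters of the theoretical minimal-depth distribution for balanced
    trees: l*_d = 2^d nodes at depth d and L_d = 2^d - 1 nodes above it."""

    p: int
    tree_depth: int

    def nodes_at_depth(self, d: int) -> int:
        return 2**d

    def nodes_above_depth(self, d: int) -> int:
        return 2**d - 1


def _side_depths(tree: MultivariateTree, side: str, n_vars: int) -> np.ndarray:
    """Minimal depth per variable; -1 where the variable never appears."""
    md = np.full(n_vars, -1, dtype=np.int64)
    if side == "predictor":
        idx = tree.feature
    elif side == "response":
        idx = tree.msrv
    else:
        raise ValueError("side must be 'predictor' or 'response'")
    internal = tree.feature >= 0
    for v, d in zip(idx[internal], tree.depth[internal]):
        if md[v] < 0 or d < md[v]:
            md[v] = d
    return md


def minimal_depth(tree: MultivariateTree, side: str, n_vars: int) -> np.ndarray:
    """Minimal depth of every variable in one tree (-1 marks absence)."""
    return _side_depths(tree, side, n_vars)


def imd_per_tree(tree: MultivariateTree, side: str, n_vars: int) -> np.ndarray:
    """M_v = 1/(D_v + 1) for variables in the tree, 0 for absent ones."""
    md = _side_depths(tree, side, n_vars)
    out = np.zeros(n_vars)
    present = md >= 0
    out[present] = 1.0 / (md[present] + 1.0)
    return out


def forest_imd(
    forest: MRFForest, side: str, feature_ids: list[str] | None = None
) -> IMDProfile:
    """Forest IMD: the average per-tree IMD, with its summary statistics."""
    n_vars = forest.n_predictors if side == "predictor" else forest.n_responses
    B = forest.n_trees
    per_tree = np.empty((B, n_vars))
    for b, tree in enumerate(forest.trees):
        per_tree[b] = imd_per_tree(tree, side, n_vars)
    fimd = per_tree.mean(axis=0)
    mu = float(fimd.mean())
    sigma_m = float(fimd.std(ddof=1)) if n_vars > 1 else 0.0
    se = per_tree.std(axis=0, ddof=1) / np.sqrt(B) if B > 1 else np.zeros(n_vars)
    return IMDProfile(
        per_tree_imd=per_tree,
        forest_imd=fimd,
        mu=mu,
        sigma_m=sigma_m,
        se=se,
        side=side,
        feature_ids=feature_ids,
    )


def imd_tscore(profile: IMDProfile) -> np.ndarray:
    """t-score IMD: t_v = (M_v - mu) / SE(M_v).

    Variables never selected in any tree (SE = 0, forest IMD = 0) map to -inf
    so they sort strictly last; a variable with zero over-tree spread but
    nonzero IMD maps to +/-inf according to the sign of M_v - mu.
    """
    if profile.n_trees < 2:
        raise ValueError("t-score IMD needs at least 2 trees")
    eps = 1e-12
    num = profile.forest_imd - profile.mu
    num[np.abs(num) < eps] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / profile.se
    zero_se = profile.se <= eps  # degenerate over-tree spread (incl. fp dust)
    t[zero_se & (profile.forest_imd == 0)] = -np.inf
    t[zero_se & (num > 0)] = np.inf
    t[zero_se & (num < 0) & (profile.forest_imd > 0)] = -np.inf
    t[zero_se & (num == 0)] = 0.0
    return t


def weak_variable_md_distribution(
    params: TheoreticalMDParams, d: int
) -> float:
    """P{D_v = d | v weak} = (1 - 1/p)^{L_d} [1 - (1 - 1/p)^{l_d}].

    Diagnostic for the classical mean-minimal-depth threshold: when
    p >> l_{D(T)} every term approaches 0 and the threshold is uninformative.
    """
    if params.p < 1:
        raise ValueError("p must be >= 1")
    if d < 0:
        raise ValueError("depth must be >= 0")
    frac = 1.0 - 1.0 / params.p
    L_d = params.nodes_above_depth(d)
    l_d = params.nodes_at_depth(d)
    return frac**L_d * (1.0 - frac**l_d)
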