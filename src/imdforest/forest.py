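"""Multivariate random forests with a node-standardized splitting rule.

One omics block is treated as a multivariate response Y (n x q) and the other
as predictors X (n x p).  Each tree is grown on a bootstrap sample; at every
node the responses are re-standardized to mean 0 / mean-square 1 within the
node, and candidate splits are scored by the summed per-response statistic

    G*_q(s, t) = sum_j [ (sum_L Y*_j)^2 / n_L + (sum_R Y*_j)^2 / n_R ],

whose maximization is equivalent to minimizing the within-daughter sum of
squares summed over responses.  The response attaining the largest G_j at a
node is recorded as the maximal splitting response variable (MSRV), which
carries importance over to the response side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _tree

logger = logging.getLogger(__name__)

__all__ = [
    "OmicsBlock",
    "ForestConfig",
    "SplitRecord",
    "MultivariateTree",
    "MRFForest",
    "standardize_node_responses",
    "per_response_split_score",
    "best_split",
    "fit_forest",
    "oob_error_responses",
    "oob_error_predictors",
    "mean_oob_error",
]


@dataclass
class OmicsBlock:
    """One sample x feature numeric matrix with identifiers.

    Invariants enforced at construction: finite values, n >= 2, unique
    sample and feature ids, shapes consistent.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    name: str = "block"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[r]!r}, "
                f"feature {self.feature_ids[c]!r} (and {len(bad) - 1} more)"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "block") -> "OmicsBlock":
        return cls(
            values=df.to_numpy(dtype=np.float64),
            sample_ids=[str(s) for s in df.index],
            feature_ids=[str(f) for f in df.columns],
            name=name,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class ForestConfig:
    """Hyperparameters of the multivariate forest.

    mtry=None means ceil(p/3) (regression-forest convention) and
    max_depth=None is unlimited.  n_split_candidates is the number of
    randomly chosen candidate thresholds scored per predictor (the common
    random-splitting default of regression-forest engines); None scores every
    midpoint of consecutive distinct values, which is markedly greedier —
    with heavy-tailed responses it favors single-outlier isolation at shallow
    nodes and degrades depth-based importance.  response_fraction is the
    share of responses scored at each split; None scores ceil(sqrt(q))
    responses — with many mutually correlated responses the per-node argmax
    (MSRV) would otherwise concentrate on the same few winners and starve the
    rest of the correlated set of response-side credit.
    """

    n_trees: int = 300
    mtry: int | None = None
    nodesize: int = 5
    max_depth: int | None = None
    response_fraction: float | None = None
    n_split_candidates: int | None = 10
    seed: int = 0

    def resolve(self, p: int, q: int) -> "ForestConfig":
        cfg = replace(self)
        if cfg.mtry is None:
            cfg.mtry = max(1, math.ceil(p / 3))
        if not 1 <= cfg.mtry <= p:
            raise ValueError(f"mtry must be in [1, {p}]")
        if cfg.nodesize < 1:
            raise ValueError("nodesize must be >= 1")
        if cfg.n_trees < 1:
            raise ValueError("need at least one tree")
        if cfg.response_fraction is not None and not 0.0 < cfg.response_fraction <= 1.0:
            raise ValueError("response_fraction must be in (0, 1]")
        return cfg

    def n_scored_responses(self, q: int) -> int:
        if self.response_fraction is None:
            return min(q, max(1, math.ceil(math.sqrt(q))))
        return max(1, round(self.response_fraction * q))


@dataclass
class SplitRecord:
    predictor_index: int
    threshold: float
    score: float
    per_response_scores: np.ndarray
    msrv_index: int
    depth: int
    left_size: int
    right_size: int


@dataclass
class MultivariateTree:
    """Flat-array tree: feature[v] < 0 marks a leaf, else x <= threshold[v]
    goes to left[v]."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    depth: np.ndarray
    msrv: np.ndarray
    score: np.ndarray
    left_size: np.ndarray
    right_size: np.ndarray
    per_response_scores: np.ndarray  # (n_nodes, q); zeros for leaves
    inbag_counts: np.ndarray  # (n,)
    leaf_of_sample: np.ndarray  # (n,) terminal node of every training sample

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def max_depth(self) -> int:
        return int(self.depth.max())

    def split_records(self) -> list[SplitRecord]:
        out = []
        for v in range(self.n_nodes):
            if self.feature[v] >= 0:
                out.append(
                    SplitRecord(
                        predictor_index=int(self.feature[v]),
                        threshold=float(self.threshold[v]),
                        score=float(self.score[v]),
                        per_response_scores=self.per_response_scores[v],
                        msrv_index=int(self.msrv[v]),
                        depth=int(self.depth[v]),
                        left_size=int(self.left_size[v]),
                        right_size=int(self.right_size[v]),
                    )
                )
        return out


@dataclass
class MRFForest:
    trees: list[MultivariateTree]
    config: ForestConfig
    n_samples: int
    n_predictors: int
    n_responses: int
    rng_seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def standardize_node_responses(Y_node: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize each response column within a node to mean 0 and
    mean-square 1 (divisor m, the in-node count).

    Returns (Y*, zero_variance_mask).  Zero-variance columns are returned as
    zeros and flagged; they contribute 0 to every split score.
    """
    Y_node = np.asarray(Y_node, dtype=np.float64)
    m = Y_node.shape[0]
    if m < 2:
        raise ValueError("degenerate node: need at least 2 samples to standardize")
    mu = Y_node.mean(axis=0)
    var = np.mean((Y_node - mu) ** 2, axis=0)
    zero_var = var <= 1e-24
    sd = np.sqrt(np.where(zero_var, 1.0, var))
    Z = (Y_node - mu) / sd
    Z[:, zero_var] = 0.0
    return Z, zero_var


def per_response_split_score(ystar_col: np.ndarray, left_mask: np.ndarray) -> float:
    """G_j = (sum_L Y*)^2 / n_L + (sum_R Y*)^2 / n_R for one response column."""
    ystar_col = np.asarray(ystar_col, dtype=np.float64)
    left_mask = np.asarray(left_mask, dtype=bool)
    n_l = int(left_mask.sum())
    n_r = ystar_col.size - n_l
    if n_l == 0 or n_r == 0:
        raise ValueError("invalid split: both daughters must be non-empty")
    s_l = float(ystar_col[left_mask].sum())
    s_r = float(ystar_col[~left_mask].sum())
    return s_l * s_l / n_l + s_r * s_r / n_r


def _as_matrix(block) -> np.ndarray:
    if isinstance(block, OmicsBlock):
        return block.values
    return np.ascontiguousarray(np.asarray(block, dtype=np.float64))


def _grow_one(X, Y, samp, cfg: ForestConfig, tree_seed: int) -> MultivariateTree:
    q = Y.shape[1]
    n_resp = cfg.n_scored_responses(q)
    out = _tree.grow_tree(
        X,
        Y,
        samp,
        cfg.mtry,
        cfg.nodesize,
        -1 if cfg.max_depth is None else cfg.max_depth,
        n_resp,
        0 if cfg.n_split_candidates is None else cfg.n_split_candidates,
        tree_seed,
    )
    feature, threshold, left, right, depth, msrv, score, nl, nr, gains = out
    inbag = np.bincount(samp, minlength=X.shape[0]).astype(np.int64)
    leaf = _tree.apply_tree(feature, threshold, left, right, X)
    return MultivariateTree(
        feature=feature,
        threshold=threshold,
        left=left,
        right=right,
        depth=depth,
        msrv=msrv,
        score=score,
        left_size=nl,
        right_size=nr,
        per_response_scores=gains,
        inbag_counts=inbag,
        leaf_of_sample=leaf,
    )


def best_split(X_node, Y_node, config: ForestConfig) -> SplitRecord | None:
    """Best split of a single node, searched over `mtry` random predictors and
    midpoint thresholds; ties broken by (lower predictor index, lower
    threshold).  Returns None when no score-improving split exists."""
    X_node = _as_matrix(X_node)
    Y_node = _as_matrix(Y_node)
    m = X_node.shape[0]
    cfg = config.resolve(X_node.shape[1], Y_node.shape[1])
    if m < 2 * cfg.nodesize:
        return None
    cfg = replace(cfg, max_depth=1)
    tree = _grow_one(X_node, Y_node, np.arange(m), cfg, cfg.seed)
    if tree.feature[0] < 0:
        return None
    return tree.split_records()[0]


def fit_forest(X, Y, config: ForestConfig | None = None) -> MRFForest:
    """Grow a multivariate random forest of B trees on independent bootstrap
    samples of the shared rows of X (predictors) and Y (responses)."""
    if isinstance(X, OmicsBlock) and isinstance(Y, OmicsBlock):
        if X.sample_ids != Y.sample_ids:
            raise ValueError("predictor and response blocks must share identically ordered sample_ids")
    Xm = _as_matrix(X)
    Ym = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of samples")
    n = Xm.shape[0]
    cfg = (config or ForestConfig()).resolve(Xm.shape[1], Ym.shape[1])
    rng = np.random.default_rng(cfg.seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_trees)
    trees = []
    for b in range(cfg.n_trees):
        samp = rng.integers(0, n, size=n)
        trees.append(_grow_one(Xm, Ym, samp, cfg, int(tree_seeds[b])))
    return MRFForest(
        trees=trees,
        config=cfg,
        n_samples=n,
        n_predictors=Xm.shape[1],
        n_responses=Ym.shape[1],
        rng_seed=cfg.seed,
    )


def _oob_predictions(forest: MRFForest, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag prediction of each column of V.

    Per tree, an OOB sample is predicted by the in-bag mean of its terminal
    node (the forest-weights prediction: the weight of in-bag sample t for
    OOB sample i is 1[same terminal node]/[in-bag terminal-node size],
    averaged over trees where i is out of bag)."""
    n, d = V.shape
    preds = np.zeros((n, d))
    counts = np.zeros(n, dtype=np.int64)
    for tree in forest.trees:
        means = _tree.leaf_inbag_means(
            tree.leaf_of_sample, tree.inbag_counts, V, tree.n_nodes
        )
        _tree.accumulate_oob(tree.leaf_of_sample, tree.inbag_counts, means, preds, counts)
    covered = counts > 0
    preds[covered] /= counts[covered, None]
    return preds, covered


def _oob_mse(forest: MRFForest, V: np.ndarray) -> np.ndarray:
    preds, covered = _oob_predictions(forest, V)
    n_dropped = int((~covered).sum())
    if n_dropped:
        logger.warning("%d samples were never out-of-bag and are excluded from OOB error", n_dropped)
    if not covered.any():
        raise ValueError("no sample is out-of-bag in any tree; cannot compute OOB error")
    resid = V[covered] - preds[covered]
    return np.mean(resid**2, axis=0)


def oob_error_responses(forest: MRFForest, X, Y) -> tuple[np.ndarray, float]:
    """Per-response OOB mean squared error and its mean over responses."""
    del X  # predictions depend only on tree structure, kept for API symmetry
    Ym = _as_matrix(Y)
    err = _oob_mse(forest, Ym)
    return err, float(err.mean())


def oob_error_predictors(forest: MRFForest, X) -> tuple[np.ndarray, float]:
    """Per-predictor OOB error from the forest-weights prediction of X."""
    Xm = _as_matrix(X)
    err = _oob_mse(forest, Xm)
    return err, float(err.mean())


def mean_oob_error(forest: MRFForest, X, Y) -> float:
    """Mean OOB error over all predictor and response variables."""
    err_x, _ = oob_error_predictors(forest, X)
    err_y, _ = oob_error_responses(forest, X, Y)
    return float(np.concatenate([err_x, err_y]).mean())
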