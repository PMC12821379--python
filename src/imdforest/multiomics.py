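"""Multiomics extension: connection inference and cross-model selection.

With K omics blocks, every retained block pair contributes one directed model
(response <- predictor).  Directions come from prior knowledge when supplied,
otherwise each pair is fit in both directions on PCA-reduced data and the
direction with the lower mean out-of-bag error wins.  One full-dimension
forest is then fit per edge; a block's features accumulate IMD from every
model the block participates in (predictor-side IMD when it is the predictor,
response-side when it is the response) and the selection strategy is applied
to the per-block mean IMD (filter, mixture) or by majority vote over
per-model selections (transformation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA

from .forest import ForestConfig, OmicsBlock, fit_forest, mean_oob_error
from .imd import IMDProfile, forest_imd
from .selection import (
    FilterConfig,
    SelectionResult,
    fit_imd_mixture,
    transform_select,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectionEdge",
    "ConnectionGraph",
    "MultiOmicsSelection",
    "infer_connections",
    "multiomics_select",
]


@dataclass
class ConnectionEdge:
    response: str
    predictor: str
    score: float  # mean OOB error of the reduced-data model (NaN for priors)


@dataclass
class ConnectionGraph:
    nodes: list[str]
    edges: list[ConnectionEdge]
    provenance: str = "inferred"  # prior | inferred

    def __post_init__(self):
        for e in self.edges:
            if e.response == e.predictor:
                raise ValueError("self-edges are not allowed")

    def touching(self, block: str) -> list[ConnectionEdge]:
        return [e for e in self.edges if block in (e.response, e.predictor)]


def _pca_scores(block: OmicsBlock, variance_threshold: float, seed: int) -> np.ndarray:
    n, p = block.values.shape
    k_max = min(n, p)
    pca = PCA(n_components=k_max, random_state=seed)
    scores = pca.fit_transform(block.values)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, variance_threshold) + 1)
    k = min(max(k, 1), scores.shape[1])
    if k == k_max and cum[-1] < variance_threshold:
        logger.warning(
            "block %s is rank-deficient for the requested variance; keeping all %d components",
            block.name,
            k,
        )
    return scores[:, :k]


def infer_connections(
    blocks: list[OmicsBlock],
    variance_threshold: float = 0.8,
    forest_config: ForestConfig | None = None,
    seed: int = 0,
    prior: ConnectionGraph | None = None,
) -> ConnectionGraph:
    """Directed connection per block pair by lowest mean OOB error on
    PCA-reduced data; a supplied prior graph is returned unchanged."""
    if prior is not None:
        return prior
    if len(blocks) < 2:
        raise ValueError("need at least 2 blocks to infer connections")
    cfg = forest_config or ForestConfig(n_trees=100)
    ss = np.random.SeedSequence(seed)
    reduced = [_pca_scores(b, variance_threshold, seed) for b in blocks]
    candidates = []  # best direction per unordered pair
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            best = None
            for resp, pred in ((i, j), (j, i)):
                fit_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
                f = fit_forest(reduced[pred], reduced[resp], replace(cfg, seed=fit_seed))
                err = mean_oob_error(f, reduced[pred], reduced[resp])
                if best is None or err < best[0]:
                    best = (err, resp, pred)
            candidates.append(best)
    # keep a spanning tree over the blocks (lowest-error pairs first), so K
    # blocks are covered by K-1 directed models
    candidates.sort(key=lambda t: t[0])
    parent = list(range(len(blocks)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    edges = []
    for err, resp, pred in candidates:
        ra, rb = find(resp), find(pred)
        if ra != rb:
            parent[ra] = rb
            edges.append(
                ConnectionEdge(
                    response=blocks[resp].name, predictor=blocks[pred].name, score=err
                )
            )
    edges.sort(key=lambda e: (e.response, e.predictor))
    return ConnectionGraph(
        nodes=[b.name for b in blocks], edges=edges, provenance="inferred"
    )


@dataclass
class MultiOmicsSelection:
    graph: ConnectionGraph
    mean_imd: dict[str, np.ndarray]  # block -> role-respecting mean IMD
    per_block_result: dict[str, SelectionResult]
    votes: dict[str, np.ndarray] = field(default_factory=dict)  # transformation mode
    strategy: str = ""

    @property
    def selected(self) -> list[str]:
        out = []
        for res in self.per_block_result.values():
            out.extend(res.selected)
        return out

    @property
    def model_size(self) -> int:
        return sum(r.model_size for r in self.per_block_result.values())

    def scores(self, block: str) -> np.ndarray:
        return self.per_block_result[block].scores


def _fit_edge_models(blocks, graph, forest_config, seed):
    by_name = {b.name: b for b in blocks}
    ss = np.random.SeedSequence(seed)
    models = []
    for e in graph.edges:
        if e.predictor not in by_name or e.response not in by_name:
            logger.warning("edge %s<-%s references an absent block; skipped", e.response, e.predictor)
            continue
        pred, resp = by_name[e.predictor], by_name[e.response]
        fit_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        f = fit_forest(pred, resp, replace(forest_config, mtry=None, seed=fit_seed))
        prof_p = forest_imd(f, "predictor", feature_ids=pred.feature_ids)
        prof_r = forest_imd(f, "response", feature_ids=resp.feature_ids)
        models.append({"edge": e, "predictor": pred, "response": resp, "profiles": {pred.name: prof_p, resp.name: prof_r}})
    return models


def _stacked_profile(block: OmicsBlock, profiles: list[IMDProfile]) -> IMDProfile:
    """Pool the per-tree IMD matrices of every model touching a block.

    With equal tree counts per model the pooled forest IMD equals the mean of
    the per-model forest IMDs (the cross-model mean IMD)."""
    per_tree = np.vstack([p.per_tree_imd for p in profiles])
    fimd = per_tree.mean(axis=0)
    B = per_tree.shape[0]
    return IMDProfile(
        per_tree_imd=per_tree,
        forest_imd=fimd,
        mu=float(fimd.mean()),
        sigma_m=float(fimd.std(ddof=1)) if fimd.size > 1 else 0.0,
        se=per_tree.std(axis=0, ddof=1) / np.sqrt(B),
        side="pooled",
        feature_ids=block.feature_ids,
    )


def multiomics_select(
    blocks: list[OmicsBlock],
    graph: ConnectionGraph,
    strategy: str,
    forest_config: ForestConfig | None = None,
    filter_config: FilterConfig | None = None,
    pr: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> MultiOmicsSelection:
    """Fit one forest per connection and select features per block."""
    if strategy not in ("filter", "mixture", "transformation"):
        raise ValueError("strategy must be filter, mixture or transformation")
    forest_config = forest_config or ForestConfig()
    models = _fit_edge_models(blocks, graph, forest_config, seed)
    if not models:
        raise ValueError("connection graph has no usable edges")
    in_graph = {m["edge"].predictor for m in models} | {m["edge"].response for m in models}
    used_blocks = []
    for b in blocks:
        if b.name in in_graph:
            used_blocks.append(b)
        else:
            logger.warning("block %s is absent from the connection graph; excluded", b.name)

    pooled = {}
    for b in used_blocks:
        profs = [m["profiles"][b.name] for m in models if b.name in m["profiles"]]
        pooled[b.name] = _stacked_profile(b, profs)
    mean_imd = {name: prof.forest_imd for name, prof in pooled.items()}

    per_block: dict[str, SelectionResult] = {}
    votes: dict[str, np.ndarray] = {}

    if strategy == "mixture":
        for b in used_blocks:
            _, res = fit_imd_mixture(pooled[b.name], pr=pr, seed=seed)
            per_block[b.name] = res
    elif strategy == "transformation":
        for b in used_blocks:
            touching = [m for m in models if b.name in m["profiles"]]
            n_models = len(touching)
            v = np.zeros(b.n_features, dtype=np.int64)
            t_sum = np.zeros(b.n_features)
            for m in touching:
                res = transform_select(m["profiles"][b.name], alpha=alpha)
                v += res.selected_mask
                t_sum += np.nan_to_num(res.scores, neginf=-1e12, posinf=1e12)
            votes[b.name] = v
            mask = v > n_models / 2.0  # strict majority; exact half excluded
            per_block[b.name] = SelectionResult(
                strategy="transformation",
                feature_ids=b.feature_ids,
                selected_mask=mask,
                scores=t_sum / n_models,
                params={"alpha": alpha, "n_models": n_models},
            )
    else:  # filter
        per_block = _multiomics_filter(
            used_blocks, models, pooled, filter_config or FilterConfig(), forest_config, seed
        )

    return MultiOmicsSelection(
        graph=graph,
        mean_imd=mean_imd,
        per_block_result=per_block,
        votes=votes,
        strategy=strategy,
    )


def _multiomics_filter(blocks, models, pooled, config, forest_config, seed):
    """tau * sigma_m filter on the per-block mean IMD, tuned by the mean OOB
    error over every edge model refit on the kept features."""
    taus = config.tau_grid
    ss = np.random.SeedSequence(seed)
    # single pooled IMD scale across every block in the model collection
    all_imd = np.concatenate([prof.forest_imd for prof in pooled.values()])
    sigma_m = float(all_imd.std(ddof=1))
    cache: dict[bytes, tuple[float, float]] = {}
    means = np.full(taus.size, np.inf)
    ses = np.zeros(taus.size)
    kept_per_tau = []
    for ti, tau in enumerate(taus):
        kept = {
            name: prof.forest_imd > tau * sigma_m for name, prof in pooled.items()
        }
        kept_per_tau.append(kept)
        if any(k.sum() == 0 for k in kept.values()):
            continue
        key = b"".join(kept[name].tobytes() for name in sorted(kept))
        if key not in cache:
            seeds = ss.spawn(1)[0].generate_state(config.repeats) % (2**31 - 1)
            errs = []
            for r in range(config.repeats):
                model_errs = []
                for m in models:
                    kx = kept[m["predictor"].name]
                    ky = kept[m["response"].name]
                    Xk = m["predictor"].values[:, kx]
                    Yk = m["response"].values[:, ky]
                    cfg = replace(
                        forest_config,
                        n_trees=config.tune_trees,
                        mtry=None,
                        seed=int(seeds[r]),
                    )
                    f = fit_forest(Xk, Yk, cfg)
                    # model restricted to kept variables; error over all
                    # original variables of both blocks
                    model_errs.append(
                        mean_oob_error(f, m["predictor"].values, m["response"].values)
                    )
                errs.append(float(np.mean(model_errs)))
            errs = np.asarray(errs)
            se = errs.std(ddof=1) / np.sqrt(len(errs)) if len(errs) > 1 else 0.0
            cache[key] = (float(errs.mean()), float(se))
        means[ti], ses[ti] = cache[key]

    if not np.isfinite(means).any():
        raise ValueError("every tau filtered out all variables of some block")
    i_min = int(np.argmin(means))
    tol = (
        config.tolerance
        if config.tolerance is not None
        else max(ses[i_min], 0.01 * means[i_min])
    )
    ok = means <= means[i_min] + tol
    i_best = int(np.max(np.nonzero(ok)[0]))
    kept = kept_per_tau[i_best]

    out = {}
    for b in blocks:
        out[b.name] = SelectionResult(
            strategy="filter",
            feature_ids=b.feature_ids,
            selected_mask=kept[b.name],
            scores=pooled[b.name].forest_imd,
            params={"tau": float(taus[i_best]), "sigma_m": sigma_m, "tolerance": float(tol)},
        )
    return out
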