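"""Turn IMD profiles into selected feature sets.

Three unsupervised strategies:

* **filter** — keep variables whose forest IMD exceeds tau * sigma_m; tau is
  tuned on a 0.1-step grid by refitting the forest on the kept variables and
  tracking the mean out-of-bag error over predictors and responses, choosing
  the largest tau whose error stays within a tolerance of the grid minimum.
* **mixture** — a zero-inflated 2-component mixture on the forest IMD: the
  point mass p0 absorbs never-selected variables, EM fits the two components
  to the nonzero IMDs (component 1 = smaller mean = noise), and variables
  with posterior noise probability Pr_1(x) < pr are selected.
* **transformation** — standardize each variable's forest IMD to a t-score
  (M_v - mu)/SE(M_v) and keep scores beyond the alpha-level t-distribution
  boundary with df = ntree - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from sklearn.cluster import KMeans

from .forest import ForestConfig, fit_forest, mean_oob_error, _as_matrix
from .imd import IMDProfile, imd_tscore

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "MixtureFit",
    "SelectionResult",
    "filter_select",
    "filter_kept_mask",
    "fit_imd_mixture",
    "transform_select",
]


@dataclass
class SelectionResult:
    strategy: str  # filter | mixture | transformation
    feature_ids: list[str]
    selected_mask: np.ndarray
    scores: np.ndarray
    params: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return [f for f, m in zip(self.feature_ids, self.selected_mask) if m]

    @property
    def model_size(self) -> int:
        return int(self.selected_mask.sum())


def _ids(profile: IMDProfile, prefix: str = "f") -> list[str]:
    if profile.feature_ids is not None:
        return list(profile.feature_ids)
    return [f"{prefix}{i}" for i in range(len(profile.forest_imd))]


# ---------------------------------------------------------------------------
# filter strategy
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    """tau grid runs 0..3 in steps of 0.1; each kept set is refit `repeats`
    times with `tune_trees` trees to stabilize the OOB error; `tolerance`
    None means one standard error of the repeated means at the grid minimum."""

    tau_grid: np.ndarray = field(default_factory=lambda: np.round(np.arange(0.0, 3.0001, 0.1), 10))
    repeats: int = 5
    tolerance: float | None = None
    tune_trees: int = 60

    def __post_init__(self):
        self.tau_grid = np.asarray(self.tau_grid, dtype=float)
        if self.tau_grid.size == 0:
            raise ValueError("tau grid must be nonempty")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def filter_kept_mask(profile: IMDProfile, tau: float) -> np.ndarray:
    """Variables with forest IMD strictly above tau * sigma_m."""
    return profile.forest_imd > tau * profile.sigma_m


def filter_select(
    profile_x: IMDProfile,
    profile_y: IMDProfile,
    X,
    Y,
    config: FilterConfig | None = None,
    forest_config: ForestConfig | None = None,
    seed: int = 0,
) -> SelectionResult:
    """OOB-tuned SD-multiple filter over both sides of the model.

    For each tau, variables on each side with forest IMD > tau * sigma_m of
    that side are kept, the forest is refit on the kept predictors and
    responses `repeats` times, and the mean OOB error (over all kept X and Y
    variables) is averaged.  The largest tau within `tolerance` of the grid
    minimum wins.
    """
    config = config or FilterConfig()
    Xm = _as_matrix(X)
    Ym = _as_matrix(Y)
    base_cfg = forest_config or ForestConfig()
    taus = config.tau_grid
    ss = np.random.SeedSequence(seed)

    # one pooled SD of the forest IMD over every variable in the model: the
    # threshold tau * sigma_m is a single scale shared by both sides
    pooled = np.concatenate([profile_x.forest_imd, profile_y.forest_imd])
    sigma_m = float(pooled.std(ddof=1))

    cache: dict[bytes, tuple[float, float]] = {}
    means = np.full(taus.size, np.inf)
    ses = np.zeros(taus.size)
    masks = []
    for ti, tau in enumerate(taus):
        kx = profile_x.forest_imd > tau * sigma_m
        ky = profile_y.forest_imd > tau * sigma_m
        masks.append((kx, ky))
        if kx.sum() == 0 or ky.sum() == 0:
            continue
        key = kx.tobytes() + ky.tobytes()
        if key not in cache:
            seeds = ss.spawn(1)[0].generate_state(config.repeats) % (2**31 - 1)
            errs = []
            for r in range(config.repeats):
                cfg = replace(
                    base_cfg,
                    n_trees=config.tune_trees,
                    mtry=None,
                    seed=int(seeds[r]),
                )
                f = fit_forest(Xm[:, kx], Ym[:, ky], cfg)
                # the refit model uses only kept variables, but its OOB error
                # is evaluated over ALL original X and Y variables (forest
                # weights predict any column): dropping informative variables
                # then degrades the error instead of silently shrinking the
                # set it is averaged over
                errs.append(mean_oob_error(f, Xm, Ym))
            errs = np.asarray(errs)
            se = errs.std(ddof=1) / np.sqrt(len(errs)) if len(errs) > 1 else 0.0
            cache[key] = (float(errs.mean()), float(se))
        means[ti], ses[ti] = cache[key]

    if not np.isfinite(means).any():
        raise ValueError("every tau filtered out all variables on one side")
    i_min = int(np.argmin(means))
    # default tolerable deviation: one standard error of the repeated means,
    # floored at 1% of the minimum error — the SE alone is microscopic next
    # to the irreducible-noise error scale and would pin tau at the argmin
    tol = (
        config.tolerance
        if config.tolerance is not None
        else max(ses[i_min], 0.01 * means[i_min])
    )
    ok = means <= means[i_min] + tol
    i_best = int(np.max(np.nonzero(ok)[0]))
    kx, ky = masks[i_best]

    ids = _ids(profile_x, "x") + _ids(profile_y, "y")
    mask = np.concatenate([kx, ky])
    scores = np.concatenate([profile_x.forest_imd, profile_y.forest_imd])
    return SelectionResult(
        strategy="filter",
        feature_ids=ids,
        selected_mask=mask,
        scores=scores,
        params={
            "tau": float(taus[i_best]),
            "sigma_m": sigma_m,
            "threshold": float(taus[i_best] * sigma_m),
            "tolerance": float(tol),
            "oob_means": means,
            "tau_grid": taus,
        },
    )


# ---------------------------------------------------------------------------
# mixture strategy
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    p0: float  # mass at IMD = 0
    p: float  # weight of component 1 among nonzeros
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    family: str  # gaussian | truncated_normal
    loglik: float
    posteriors: np.ndarray  # (n_nonzero, 2), rows sum to 1
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True
    variance_floored: bool = False

    @property
    def p1(self) -> float:
        return self.p * (1.0 - self.p0)

    @property
    def p2(self) -> float:
        return (1.0 - self.p) * (1.0 - self.p0)


def _comp1_logpdf(x, mu, sigma, family):
    if family == "gaussian":
        return stats.norm.logpdf(x, mu, sigma)
    # zero-truncated (from below) normal for the noise component
    denom = stats.norm.sf(0.0, mu, sigma)
    return stats.norm.logpdf(x, mu, sigma) - np.log(max(denom, 1e-300))


def _fit_truncated_mstep(x, gamma, mu0, sigma0, var_floor):
    """Weighted MLE of a zero-truncated normal via Nelder-Mead."""

    def nll(theta):
        mu, logsig = theta
        sig = np.exp(logsig)
        return -np.sum(gamma * _comp1_logpdf(x, mu, sig, "truncated_normal"))

    res = optimize.minimize(nll, [mu0, np.log(max(sigma0, np.sqrt(var_floor)))], method="Nelder-Mead")
    mu, logsig = res.x
    return float(mu), float(max(np.exp(logsig), np.sqrt(var_floor)))


def _em_two_component(x, family, max_iter=500, tol=1e-8, var_floor=1e-6, seed=0):
    """EM for a 2-component mixture on the nonzero IMDs.

    Returns (p, mu1, s1, mu2, s2, posteriors, loglik_history, converged,
    floored) with components ordered by increasing mean.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(x.reshape(-1, 1))
    mus = np.empty(2)
    sigmas = np.empty(2)
    ws = np.empty(2)
    floored = False
    for k in range(2):
        xk = x[km.labels_ == k]
        mus[k] = xk.mean() if xk.size else x.mean()
        v = xk.var() if xk.size > 1 else x.var()
        sigmas[k] = np.sqrt(max(v, var_floor))
        ws[k] = max(xk.size / n, 0.05)
    ws /= ws.sum()

    history = []
    prev = -np.inf
    converged = False
    gamma = np.full((n, 2), 0.5)
    for _ in range(max_iter):
        # E step
        log1 = np.log(ws[0]) + _comp1_logpdf(x, mus[0], sigmas[0], family)
        log2 = np.log(ws[1]) + stats.norm.logpdf(x, mus[1], sigmas[1])
        mx = np.maximum(log1, log2)
        lse = mx + np.log(np.exp(log1 - mx) + np.exp(log2 - mx))
        ll = float(lse.sum())
        history.append(ll)
        gamma = np.column_stack([np.exp(log1 - lse), np.exp(log2 - lse)])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M step
        nk = gamma.sum(axis=0)
        ws = np.clip(nk / n, 1e-10, None)
        ws /= ws.sum()
        if family == "truncated_normal":
            mus[0], sigmas[0] = _fit_truncated_mstep(x, gamma[:, 0], mus[0], sigmas[0], var_floor)
        else:
            mus[0] = np.sum(gamma[:, 0] * x) / max(nk[0], 1e-10)
            v0 = np.sum(gamma[:, 0] * (x - mus[0]) ** 2) / max(nk[0], 1e-10)
            if v0 < var_floor:
                floored = True
            sigmas[0] = np.sqrt(max(v0, var_floor))
        mus[1] = np.sum(gamma[:, 1] * x) / max(nk[1], 1e-10)
        v1 = np.sum(gamma[:, 1] * (x - mus[1]) ** 2) / max(nk[1], 1e-10)
        if v1 < var_floor:
            floored = True
        sigmas[1] = np.sqrt(max(v1, var_floor))
    if not converged:
        logger.warning("mixture EM did not converge in %d iterations; best-so-far used", max_iter)

    # component 1 = smaller mean = noise
    if mus[0] > mus[1]:
        if family == "truncated_normal":
            # truncation is tied to the noise slot; refuse silent swap, relabel only
            logger.warning("truncated component converged to the larger mean; labels swapped")
        mus = mus[::-1]
        sigmas = sigmas[::-1]
        ws = ws[::-1]
        gamma = gamma[:, ::-1]
    return (
        float(ws[0]),
        float(mus[0]),
        float(sigmas[0]),
        float(mus[1]),
        float(sigmas[1]),
        gamma,
        np.asarray(history),
        converged,
        floored,
    )


def fit_imd_mixture(
    profile: IMDProfile,
    family: str = "gaussian",
    pr: float = 0.05,
    seed: int = 0,
) -> tuple[MixtureFit, SelectionResult]:
    """Zero-inflated two-component mixture selector.

    p0 is the empirical share of zero forest IMDs; the two components are fit
    to the nonzero IMDs by EM maximizing the zero-inflated log-likelihood
    n0 log p0 + sum log(p f1(x) + (1-p) f2(x)); nonzero-IMD variables with
    posterior noise probability Pr_1(x) < pr are selected.
    """
    if family not in ("gaussian", "truncated_normal"):
        raise ValueError("family must be 'gaussian' or 'truncated_normal'")
    x = profile.forest_imd
    ids = _ids(profile)
    nz_mask = x > 0
    nz = x[nz_mask]
    p0 = float(1.0 - nz_mask.mean())
    if nz.size == 0:
        fit = MixtureFit(
            p0=1.0, p=0.0, mu1=0.0, sigma1=0.0, mu2=0.0, sigma2=0.0,
            family=family, loglik=0.0, posteriors=np.empty((0, 2)),
        )
        empty = SelectionResult(
            strategy="mixture",
            feature_ids=ids,
            selected_mask=np.zeros_like(nz_mask),
            scores=x.copy(),
            params={"pr": pr, "family": family},
            flags={"empty_nonzero": True},
        )
        return fit, empty
    if nz.size < 10:
        raise ValueError("need at least 10 nonzero IMD values for a 2-component fit")

    p, mu1, s1, mu2, s2, gamma, history, converged, floored = _em_two_component(
        nz, family, seed=seed
    )
    n0 = int((~nz_mask).sum())
    zero_term = n0 * np.log(p0) if n0 > 0 and p0 > 0 else 0.0
    loglik = float(zero_term + history[-1]) if history.size else float(zero_term)
    fit = MixtureFit(
        p0=p0, p=p, mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2,
        family=family, loglik=loglik, posteriors=gamma,
        loglik_history=history, converged=converged, variance_floored=floored,
    )
    mask = np.zeros_like(nz_mask)
    mask[nz_mask] = gamma[:, 0] < pr
    result = SelectionResult(
        strategy="mixture",
        feature_ids=ids,
        selected_mask=mask,
        scores=x.copy(),
        params={"pr": pr, "family": family, "p0": p0, "mu1": mu1, "mu2": mu2},
        flags={"converged": converged, "variance_floored": floored},
    )
    return fit, result


# ---------------------------------------------------------------------------
# transformation strategy
# ---------------------------------------------------------------------------


def transform_select(profile: IMDProfile, alpha: float = 0.05) -> SelectionResult:
    """Select variables whose t-score IMD lies beyond the alpha-level
    t-distribution boundary with df = ntree - 1, on the signal side."""
    t = imd_tscore(profile)
    thresh = float(stats.t.ppf(1.0 - alpha, df=profile.n_trees - 1))
    mask = t > thresh
    return SelectionResult(
        strategy="transformation",
        feature_ids=_ids(profile),
        selected_mask=mask,
        scores=t,
        params={"alpha": alpha, "t_threshold": thresh, "df": profile.n_trees - 1},
    )
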