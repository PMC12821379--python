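"""Synthetic multiomics benchmarks with ground-truth labels.

Three generators:

* **latent model** — each block is a rank-one signal g_m(u) w_m^T plus
  Gaussian noise, with a shared latent factor u ~ N(0, 2^2) pushed through a
  block-specific kernel (u^2, exp(u), u).  Only the first p_m^c weights are
  nonzero, so those features are cross-correlated across blocks.
* **nonlinear regression model** — grouped predictors X built from uniform
  basis variables with within-group correlation decaying across the group,
  and responses Y formed from pairs of basis variables through a steep
  exponential-plus-logistic kernel; independent Gaussian noise features are
  appended to both blocks.
* **three-way interaction model** — two responses driven by a shared
  interacting predictor trio plus per-response side predictors.

Every generated column is rescaled to mean 0 / SD 1, generation is
seed-deterministic, and truth labels always accompany the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forest import OmicsBlock

__all__ = [
    "LatentScenario",
    "NonlinearScenario",
    "InteractionScenario",
    "generate_latent",
    "generate_nonlinear",
    "generate_interaction",
    "latent_scenario",
    "nonlinear_scenario",
    "SimulatedData",
]

_LATENT_TABLE = {
    "S1": dict(n=100, p=200, p_true=20),
    "S2": dict(n=200, p=500, p_true=30),
    "S3": dict(n=200, p=1000, p_true=50),
}

_NONLINEAR_TABLE = {
    # setting 1: 20 true X / 5 true Y; setting 2: 40 / 10 (group size 2)
    ("S1", 1): dict(n=100, p=200, p1c=20, p2c=5),
    ("S1", 2): dict(n=100, p=200, p1c=40, p2c=10),
    ("S2", 1): dict(n=200, p=500, p1c=20, p2c=5),
    ("S2", 2): dict(n=200, p=500, p1c=40, p2c=10),
    ("S3", 1): dict(n=200, p=1000, p1c=20, p2c=5),
    ("S3", 2): dict(n=200, p=1000, p1c=40, p2c=10),
}


def _kernel(name: str):
    return {
        "square": lambda u: u**2,
        "exp": np.exp,
        "identity": lambda u: u,
    }[name]


@dataclass
class SimulatedData:
    blocks: list[OmicsBlock]
    truth: dict[str, list[str]]  # block name -> true feature ids
    extras: dict = field(default_factory=dict)

    @property
    def truth_all(self) -> set[str]:
        return {f for ids in self.truth.values() for f in ids}


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mu = M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    return (M - mu) / sd


@dataclass
class LatentScenario:
    n: int
    p: list[int]  # features per block
    p_true: list[int]  # cross-correlated features per block
    kernels: list[str] = field(default_factory=lambda: ["square", "exp"])
    sigma: float = 2.0  # SD of the latent factor
    noise_sd: float = 0.3  # diagonal of the noise covariance is noise_sd^2
    seed: int = 0

    def __post_init__(self):
        if not (len(self.p) == len(self.p_true) == len(self.kernels)):
            raise ValueError("p, p_true and kernels must have one entry per block")
        if any(c > d for c, d in zip(self.p_true, self.p)):
            raise ValueError("true-feature count cannot exceed block dimension")


def latent_scenario(name: str, n_blocks: int = 2, seed: int = 0) -> LatentScenario:
    """Named latent-model scenarios: S1 (n=100, p=200, 20 true per block),
    S2 (200/500/30), S3 (200/1000/50); 2 blocks use kernels (u^2, exp u),
    3 blocks add the identity kernel."""
    row = _LATENT_TABLE[name]
    kernels = ["square", "exp", "identity"][:n_blocks]
    return LatentScenario(
        n=row["n"],
        p=[row["p"]] * n_blocks,
        p_true=[row["p_true"]] * n_blocks,
        kernels=kernels,
        seed=seed,
    )


def generate_latent(scenario: LatentScenario) -> SimulatedData:
    """X^(m) = g_m(u) w_m^T + eps_m with sum w_m^2 = 1 and exactly p_m^c
    nonzero weights (the leading features, which are the truth labels)."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    u = rng.normal(0.0, scenario.sigma, size=n)
    sample_ids = [f"s{i}" for i in range(n)]
    blocks = []
    truth = {}
    weights = []
    for m, (p, pc, kname) in enumerate(
        zip(scenario.p, scenario.p_true, scenario.kernels)
    ):
        w = np.zeros(p)
        w0 = rng.uniform(-1.0, 1.0, size=pc)
        w[:pc] = w0 / np.sqrt(np.sum(w0**2))
        weights.append(w)
        eps = rng.normal(0.0, scenario.noise_sd, size=(n, p))
        M = np.outer(_kernel(kname)(u), w) + eps
        M = _standardize_columns(M)
        name = f"block{m + 1}"
        ids = [f"{name}:f{j}" for j in range(p)]
        blocks.append(OmicsBlock(M, sample_ids, ids, name=name))
        truth[name] = ids[:pc]
    return SimulatedData(
        blocks=blocks, truth=truth, extras={"weights": weights, "u": u}
    )


@dataclass
class NonlinearScenario:
    n: int
    p1: int  # total X features
    p2: int  # total Y features
    g: int = 2  # group size of each correlated X group
    p2c: int = 5  # true (cross-correlated) Y features
    seed: int = 0

    def __post_init__(self):
        self.p_l = 2 * self.p2c  # basis variables forming Y
        self.p1c = self.g * self.p_l  # true X features
        self.p_d1 = self.p1 - self.p1c
        self.p_d2 = self.p2 - self.p2c
        if self.p_d1 < 0 or self.p_d2 < 0:
            raise ValueError("block dimensions smaller than true model size")
        if self.g < 1:
            raise ValueError("group size must be >= 1")


def nonlinear_scenario(name: str, setting: int = 1, seed: int = 0) -> NonlinearScenario:
    row = _NONLINEAR_TABLE[(name, setting)]
    g = row["p1c"] // (2 * row["p2c"])
    return NonlinearScenario(
        n=row["n"], p1=row["p"], p2=row["p"], g=g, p2c=row["p2c"], seed=seed
    )


def generate_nonlinear(scenario: NonlinearScenario) -> SimulatedData:
    """Grouped-X / kernel-Y generator.

    U_i ~ U(0,1) are the basis variables.  Group i of X holds g variables
    X_i^(j) = U_i + (0.01 + 0.5 (j-1)/(g-1)) * eps (so within-group
    correlation with the basis decays in j); each true Y_k pushes a pair of
    basis variables through 0.25 exp(4 u) + 4 / (1 + exp(-20 (u - 0.5))).
    Independent N(0,1) noise features are appended to both blocks and every
    column is standardized.
    """
    rng = np.random.default_rng(scenario.seed)
    n, g, p_l = scenario.n, scenario.g, scenario.p_l
    U = rng.uniform(0.0, 1.0, size=(n, p_l))

    xs = []
    for i in range(p_l):
        if g == 1:
            xs.append(U[:, i] + rng.normal(0.0, 1.0, size=n))
        else:
            for j in range(1, g + 1):
                coef = 0.01 + 0.5 * (j - 1) / (g - 1)
                xs.append(U[:, i] + coef * rng.normal(0.0, 1.0, size=n))
    X_true = np.column_stack(xs)

    ys = []
    for k in range(1, scenario.p2c + 1):
        u_a = U[:, 2 * k - 2]
        u_b = U[:, 2 * k - 1]
        ys.append(0.25 * np.exp(4.0 * u_a) + 4.0 / (1.0 + np.exp(-20.0 * (u_b - 0.5))))
    Y_true = np.column_stack(ys)

    X = np.hstack([X_true, rng.normal(size=(n, scenario.p_d1))])
    Y = np.hstack([Y_true, rng.normal(size=(n, scenario.p_d2))])
    X = _standardize_columns(X)
    Y = _standardize_columns(Y)

    sample_ids = [f"s{i}" for i in range(n)]
    x_ids = [f"X:f{j}" for j in range(scenario.p1)]
    y_ids = [f"Y:f{j}" for j in range(scenario.p2)]
    blocks = [
        OmicsBlock(X, sample_ids, x_ids, name="X"),
        OmicsBlock(Y, sample_ids, y_ids, name="Y"),
    ]
    truth = {"X": x_ids[: scenario.p1c], "Y": y_ids[: scenario.p2c]}
    return SimulatedData(
        blocks=blocks, truth=truth, extras={"basis": U, "X_raw": X_true}
    )


@dataclass
class InteractionScenario:
    n: int = 200
    p: int = 300
    noise_sd: float = 1.0
    seed: int = 0


def eta_interaction(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Latent three-way interaction signals of the interaction model."""
    eta1 = (X[:, 0] ** 2 - 1.0) * (X[:, 1] + 0.5) * (X[:, 2] - 0.5) + X[:, 3] + X[:, 4]
    eta2 = (X[:, 0] ** 2 - 0.5) * (X[:, 1] + 0.5) * (X[:, 2] - 0.5) + X[:, 5] - X[:, 6]
    return eta1, eta2


def generate_interaction(scenario: InteractionScenario) -> SimulatedData:
    """Y1 = 1.5 eta1 + eps, Y2 = 2 eta2 + eps with a shared interacting trio
    (X1, X2, X3) and side predictors (X4, X5) for Y1, (X6, X7) for Y2."""
    rng = np.random.default_rng(scenario.seed)
    n, p = scenario.n, scenario.p
    X = rng.normal(size=(n, p))
    eta1, eta2 = eta_interaction(X)
    Y = np.column_stack(
        [
            1.5 * eta1 + rng.normal(0.0, scenario.noise_sd, size=n),
            2.0 * eta2 + rng.normal(0.0, scenario.noise_sd, size=n),
        ]
    )
    Xs = _standardize_columns(X)
    Ys = _standardize_columns(Y)
    sample_ids = [f"s{i}" for i in range(n)]
    x_ids = [f"X:f{j}" for j in range(p)]
    y_ids = ["Y:f0", "Y:f1"]
    blocks = [
        OmicsBlock(Xs, sample_ids, x_ids, name="X"),
        OmicsBlock(Ys, sample_ids, y_ids, name="Y"),
    ]
    truth = {
        "X": [x_ids[j] for j in range(7)],  # union over both responses
        "Y": y_ids,
    }
    per_response = {
        "Y:f0": [x_ids[j] for j in range(5)],
        "Y:f1": [x_ids[j] for j in (0, 1, 2, 5, 6)],
    }
    return SimulatedData(blocks=blocks, truth=truth, extras={"per_response_truth": per_response})
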