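"""Simulation studies: accuracy of the community-count estimator under DCDFM.

Thirty-six built-in settings (ids "1a".."9d") cover nine edge-weight
families, each with four sub-studies: (a) varying the sparsity rho,
(b) varying the true K, (c) varying rho with a single community, and
(d) varying the off-diagonal connectivity beta.  Defaults follow the
study conventions: n = 50 per community (100 for signed networks),
random equal-probability community assignment, theta_i = U(0,1) * rho
(constant theta_i = sqrt(rho) for the geometric and signed families, so
that Omega = rho * Z P Z' with rho the sparsity), and candidate bound
K0 = 20.

The accuracy rate of a setting at one grid point is the fraction of
repetitions in which K-hat equals the true K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec
from .modularity import modularity_curve
from .samplers import sample_adjacency, theta_from_rho

__all__ = ["ExperimentSetting", "ExperimentResult", "builtin_setting",
           "run_experiment", "EXPERIMENT_IDS"]

DEFAULT_K0 = 20

_P_1A = np.array([[1.0, 0.2, 0.3],
                  [0.2, 0.8, 0.2],
                  [0.3, 0.2, 0.9]])
_P_6A = np.array([[1.0, -0.2, -0.3],
                  [-0.2, 0.8, 0.2],
                  [-0.3, 0.2, 0.9]])


def _P_offdiag(K: int, off: float) -> np.ndarray:
    P = np.full((K, K), off, dtype=float)
    np.fill_diagonal(P, 1.0)
    return P


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    vals = np.arange(start, stop + step / 2, step)
    return tuple(np.round(vals, 10).tolist())


@dataclass(frozen=True)
class ExperimentSetting:
    """One parameter setting: which parameter varies and what is fixed."""

    id: str
    family: str
    grid_param: str               # "rho", "K" or "beta"
    grid: tuple[float, ...]
    K: int | None = None          # fixed K (None when K is the grid)
    rho: float | None = None      # fixed rho (None when rho is the grid)
    P: np.ndarray | None = None   # fixed P (None when beta is the grid)
    theta_mode: str = "uniform_scaled"
    nodes_per_community: int = 50
    m: int | None = None
    sigma2: float | None = None

    def params_at(self, value: float) -> dict:
        """Resolve (K, rho, P, n) at one grid value."""
        K = int(value) if self.grid_param == "K" else self.K
        rho = float(value) if self.grid_param == "rho" else self.rho
        if self.grid_param == "beta":
            P = _P_offdiag(self.K, float(value))
        elif self.grid_param == "K":
            P = _P_offdiag(K, 0.2)
        else:
            P = self.P
        return {"K": K, "rho": rho, "P": P, "n": self.nodes_per_community * K}


@dataclass
class ExperimentResult:
    """Per-grid-point estimated-K lists and accuracy rates."""

    setting_id: str
    grid_param: str
    grid: tuple[float, ...]
    k_hats: dict[float, list[int]]
    true_k: dict[float, int]
    reps: int
    seed_base: int

    @property
    def accuracy(self) -> dict[float, float]:
        return {g: float(np.mean([k == self.true_k[g] for k in self.k_hats[g]]))
                for g in self.grid}

    def to_frame(self) -> pd.DataFrame:
        acc = self.accuracy
        return pd.DataFrame({
            "experiment": self.setting_id,
            "grid_param": self.grid_param,
            "grid_value": list(self.grid),
            "reps": self.reps,
            "accuracy": [acc[g] for g in self.grid],
        })

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path | None = None, ax=None):
        """Accuracy-versus-grid curve for one setting."""
        import matplotlib
        if path is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.2))
        acc = self.accuracy
        ax.plot(list(self.grid), [acc[g] for g in self.grid], "o-")
        ax.set_xlabel(self.grid_param)
        ax.set_ylabel("accuracy rate")
        ax.set_ylim(-0.05, 1.05)
        ax.set_title(f"experiment {self.setting_id} ({self.reps} reps)")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def _settings() -> dict[str, ExperimentSetting]:
    S: dict[str, ExperimentSetting] = {}

    def add(id, family, grid_param, grid, **kw):
        S[id] = ExperimentSetting(id=id, family=family, grid_param=grid_param,
                                  grid=tuple(grid), **kw)

    # 1: Bernoulli (binary networks; DCSBM reduction)
    add("1a", "bernoulli", "rho", _grid(0.2, 1.0, 0.1), K=3, P=_P_1A)
    add("1b", "bernoulli", "K", _grid(2, 6, 1), rho=0.9)
    add("1c", "bernoulli", "rho", _grid(0.1, 1.0, 0.1), K=1, P=np.array([[1.0]]))
    add("1d", "bernoulli", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=1.0)

    # 2: Binomial counts, m = 5 trials
    add("2a", "binomial", "rho", _grid(0.5, 5.0, 0.5), K=3, P=_P_1A, m=5)
    add("2b", "binomial", "K", _grid(2, 6, 1), rho=2.0, m=5)
    add("2c", "binomial", "rho", _grid(0.5, 5.0, 0.5), K=1, P=np.array([[1.0]]), m=5)
    add("2d", "binomial", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=1.0, m=5)

    # 3: Poisson counts
    add("3a", "poisson", "rho", _grid(0.5, 5.0, 0.5), K=3, P=_P_1A)
    add("3b", "poisson", "K", _grid(2, 6, 1), rho=2.0)
    add("3c", "poisson", "rho", _grid(0.5, 5.0, 0.5), K=1, P=np.array([[1.0]]))
    add("3d", "poisson", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=2.0)

    # 4: Geometric weights >= 1; constant theta = sqrt(rho), so
    #    Omega = rho * Z P Z' and the grids keep min Omega = rho*min(P) >= 1
    add("4a", "geometric", "rho", _grid(5, 15, 1), K=3, P=_P_1A, theta_mode="constant_sqrt")
    add("4b", "geometric", "K", _grid(2, 6, 1), rho=10.0, theta_mode="constant_sqrt")
    add("4c", "geometric", "rho", _grid(2, 20, 2), K=1, P=np.array([[1.0]]), theta_mode="constant_sqrt")
    add("4d", "geometric", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=10.0, theta_mode="constant_sqrt")

    # 5: Exponential weights
    add("5a", "exponential", "rho", _grid(1, 10, 1), K=3, P=_P_1A)
    add("5b", "exponential", "K", _grid(2, 6, 1), rho=5.0)
    add("5c", "exponential", "rho", _grid(1, 10, 1), K=1, P=np.array([[1.0]]))
    add("5d", "exponential", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=5.0)

    # 6: Normal weights, sigma2 = 1 (P may be negative)
    add("6a", "normal", "rho", _grid(1, 10, 1), K=3, P=_P_6A, sigma2=1.0)
    add("6b", "normal", "K", _grid(2, 6, 1), rho=3.0, sigma2=1.0)
    add("6c", "normal", "rho", _grid(0.5, 10.0, 0.5), K=1, P=np.array([[1.0]]), sigma2=1.0)
    add("6d", "normal", "beta", _grid(-0.5, 0.9, 0.1), K=2, rho=2.0, sigma2=1.0)

    # 7: Laplace weights, sigma2 = 1
    add("7a", "laplace", "rho", _grid(1, 10, 1), K=3, P=_P_6A, sigma2=1.0)
    add("7b", "laplace", "K", _grid(2, 6, 1), rho=3.0, sigma2=1.0)
    add("7c", "laplace", "rho", _grid(0.5, 10.0, 0.5), K=1, P=np.array([[1.0]]), sigma2=1.0)
    add("7d", "laplace", "beta", _grid(-0.5, 0.9, 0.1), K=2, rho=2.0, sigma2=1.0)

    # 8: Uniform(0, Omega) weights
    add("8a", "uniform", "rho", _grid(2, 20, 2), K=3, P=_P_1A)
    add("8b", "uniform", "K", _grid(2, 6, 1), rho=0.3)
    add("8c", "uniform", "rho", _grid(2, 20, 2), K=1, P=np.array([[1.0]]))
    add("8d", "uniform", "beta", _grid(0.1, 0.8, 0.1), K=2, rho=1.0)

    # 9: signed +/-1 networks; n = 100 per community, constant theta
    add("9a", "signed", "rho", _grid(0.1, 1.0, 0.1), K=3, P=_P_6A,
        theta_mode="constant_sqrt", nodes_per_community=100)
    add("9b", "signed", "K", _grid(2, 6, 1), rho=0.5,
        theta_mode="constant_sqrt", nodes_per_community=100)
    add("9c", "signed", "rho", _grid(0.1, 1.0, 0.1), K=1, P=np.array([[1.0]]),
        theta_mode="constant_sqrt", nodes_per_community=100)
    add("9d", "signed", "beta", _grid(-0.5, 0.9, 0.1), K=2, rho=0.5,
        theta_mode="constant_sqrt", nodes_per_community=100)

    return S


_SETTINGS = _settings()
EXPERIMENT_IDS = tuple(sorted(_SETTINGS))


def builtin_setting(id: str) -> ExperimentSetting:
    """Look up one of the 36 built-in simulation settings by id ("1a".."9d")."""
    try:
        return _SETTINGS[id]
    except KeyError:
        raise KeyError(f"unknown experiment id {id!r}; known: {', '.join(EXPERIMENT_IDS)}") from None


def spec_at(setting: ExperimentSetting, grid_value: float,
            rng: np.random.Generator) -> ModelSpec:
    """Draw one ModelSpec realization at a grid point.

    Labels are assigned to communities with equal probability (redrawn in
    the vanishingly unlikely event a community comes up empty) and theta
    is redrawn per realization in uniform_scaled mode.
    """
    p = setting.params_at(grid_value)
    K, rho, P, n = p["K"], p["rho"], p["P"], p["n"]
    while True:
        labels = rng.integers(1, K + 1, size=n)
        if np.unique(labels).size == K:
            break
    theta = theta_from_rho(n, rho, mode=setting.theta_mode, seed=rng)
    return ModelSpec(n=n, K=K, labels=labels, theta=theta, P=P,
                     family=setting.family, m=setting.m, sigma2=setting.sigma2)


def run_experiment(
    setting: ExperimentSetting | str,
    reps: int = 20,
    seed_base: int = 0,
    *,
    K0: int = DEFAULT_K0,
    restarts: int = 10,
    grid: tuple[float, ...] | None = None,
) -> ExperimentResult:
    """Estimate K on ``reps`` sampled networks per grid point.

    Repetition r at grid point g uses seed ``seed_base + 10000*g + r``
    for the spec draw, the network sample and the k-means restarts, so
    grid points are independent reproducible streams.  ``grid`` restricts
    the run to a subset of the setting's grid values.
    """
    if isinstance(setting, str):
        setting = builtin_setting(setting)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    grid_vals = setting.grid if grid is None else tuple(grid)
    unknown = set(grid_vals) - set(setting.grid)
    if unknown:
        raise ValueError(f"grid values {sorted(unknown)} not in setting {setting.id}")

    k_hats: dict[float, list[int]] = {}
    true_k: dict[float, int] = {}
    for g_idx, g in enumerate(grid_vals):
        true_k[g] = setting.params_at(g)["K"]
        hats = []
        for r in range(reps):
            seed = seed_base + 10000 * setting.grid.index(g) + r
            rng = np.random.default_rng(seed)
            spec = spec_at(setting, g, rng)
            net = sample_adjacency(spec, rng, validate=False, clip=True)
            curve = modularity_curve(net.A, K0=min(K0, spec.n),
                                     restarts=restarts, seed=seed)
            hats.append(curve.K_hat)
        k_hats[g] = hats
    return ExperimentResult(setting_id=setting.id, grid_param=setting.grid_param,
                            grid=grid_vals, k_hats=k_hats, true_k=true_k,
                            reps=reps, seed_base=seed_base)
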