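"""Synthetic data generators for the two simulation scenarios.

Functional predictors are Karhunen-Loeve sums over an orthonormal Fourier
system on [0, 1]:

    Z_l(t) = sum_j varsigma_j xi_jl phi_j(t),   varsigma_j = 45 * 0.64**j,

with iid standard-normal scores ``xi_jl``.  The probit transform
``zeta = Phi(xi)`` maps each score onto (0, 1); the outcome is

    y_i = 2 x_i + h(zeta_i) + eps_i,    eps_i ~ N(0, 1),

where ``h`` is a sparse, nonlinear, non-additive function of a few signal
features.  Scenario 1 uses a single functional predictor with 15 components
and signal features {zeta_2, zeta_9}; Scenario 2 uses four predictors with 9
components each and signal features {zeta_11, zeta_31, zeta_41} of the first
predictor and {zeta_22, zeta_72} of the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ScenarioConfig",
    "SimulatedDataset",
    "fourier_basis",
    "sample_time_grid",
    "simulate_dataset",
    "true_h",
]

EIGEN_SCALE = 45.0
EIGEN_DECAY = 0.64

#: (group index, within-group index), zero-based, of the signal features.
SCENARIO1_SIGNALS = [(0, 1), (0, 8)]
SCENARIO2_SIGNALS = [(0, 0), (0, 2), (0, 3), (1, 1), (1, 6)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Configuration of one simulated replicate.

    Parameters
    ----------
    scenario : {1, 2}
        Scenario 1: one functional predictor, 15 Fourier components.
        Scenario 2: four functional predictors, 9 components each.
    n_subjects : int
        Number of iid functional paths (split 75/25 into train/test).
    n_grid : int
        Number of sampling points on [0, 1].
    jitter_var : float
        Variance of the Gaussian jitter added to the equally spaced grid.
    eigen_scale, eigen_decay : float
        Karhunen-Loeve coefficients varsigma_j = eigen_scale * eigen_decay**j.
    noise_sd : float
        Standard deviation of the outcome noise.
    """

    scenario: int = 2
    n_subjects: int = 1000
    n_grid: int = 100
    jitter_var: float = 0.001
    n_basis_per_functional: int | None = None
    eigen_scale: float = EIGEN_SCALE
    eigen_decay: float = EIGEN_DECAY
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError(f"scenario must be 1 or 2, got {self.scenario}")
        if self.n_grid < 2:
            raise ValueError("n_grid must be at least 2")
        if not 0.0 < self.eigen_decay < 1.0:
            raise ValueError("eigen_decay must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.jitter_var < 0:
            raise ValueError("jitter_var must be nonnegative")
        if self.n_basis_per_functional is None:
            object.__setattr__(
                self, "n_basis_per_functional", 15 if self.scenario == 1 else 9
            )

    @property
    def n_functionals(self) -> int:
        return 1 if self.scenario == 1 else 4

    @property
    def group_sizes(self) -> tuple[int, ...]:
        return (self.n_basis_per_functional,) * self.n_functionals


@dataclass
class SimulatedDataset:
    """One simulated replicate with full ground truth exposed."""

    config: ScenarioConfig
    grid: np.ndarray
    curves: list[np.ndarray]  # per functional, n x m
    x: np.ndarray  # n-vector scalar covariate
    y: np.ndarray
    true_zeta: np.ndarray  # n x s, groups contiguous
    true_h: np.ndarray
    signal_feature_indices: list[int] = field(default_factory=list)
    signal_group_indices: list[int] = field(default_factory=list)
    train_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    test_index: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def fourier_basis(j: int, t: np.ndarray) -> np.ndarray:
    """Evaluate the j-th orthonormal Fourier basis function on [0, 1].

    The system is phi_1 = 1, phi_{2k} = sqrt(2) sin(2 pi k t),
    phi_{2k+1} = sqrt(2) cos(2 pi k t), orthonormal in L2[0, 1].
    """
    if j < 1:
        raise ValueError(f"basis index must be >= 1, got {j}")
    t = np.asarray(t, dtype=float)
    if j == 1:
        return np.ones_like(t)
    k = j // 2
    if j % 2 == 0:
        return np.sqrt(2.0) * np.sin(2.0 * np.pi * k * t)
    return np.sqrt(2.0) * np.cos(2.0 * np.pi * k * t)


def sample_time_grid(cfg: ScenarioConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the jittered common sampling grid for one replicate.

    Equally spaced points on [0, 1] perturbed by N(0, jitter_var) deviations,
    clipped back to [0, 1] and sorted; the grid is shared by all subjects.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = np.linspace(0.0, 1.0, cfg.n_grid)
    if cfg.jitter_var == 0:
        return base
    jitter = rng.normal(0.0, np.sqrt(cfg.jitter_var), size=cfg.n_grid)
    return np.sort(np.clip(base + jitter, 0.0, 1.0))


def eigen_coefficients(cfg: ScenarioConfig) -> np.ndarray:
    """Karhunen-Loeve scale coefficients varsigma_j = 45 * 0.64**j, j = 1..J."""
    j = np.arange(1, cfg.n_basis_per_functional + 1)
    return cfg.eigen_scale * cfg.eigen_decay**j


def true_h(scenario: int, zeta: np.ndarray) -> np.ndarray:
    """The scenario's true nonparametric effect h(zeta), excluding 2x and noise.

    Feature columns are ordered group-by-group: Scenario 1 expects 15 columns
    of the single functional; Scenario 2 expects 36 columns (9 per functional).
    """
    zeta = np.atleast_2d(np.asarray(zeta, dtype=float))
    if scenario == 1:
        if zeta.shape[1] != 15:
            raise ValueError(f"Scenario 1 expects 15 features, got {zeta.shape[1]}")
        z2, z9 = zeta[:, 1], zeta[:, 8]
        return 20.0 * np.cos(2 * np.pi * z2) - 10.0 * np.sin(2 * np.pi * z9) + z2 * z9
    if scenario == 2:
        if zeta.shape[1] != 36:
            raise ValueError(f"Scenario 2 expects 36 features, got {zeta.shape[1]}")
        z11, z31, z41 = zeta[:, 0], zeta[:, 2], zeta[:, 3]
        z22, z72 = zeta[:, 9 + 1], zeta[:, 9 + 6]
        return (
            z11 + z31 + z41 + z22 + z72
            + 10.0 * np.cos(2 * np.pi * z11)
            - 10.0 * z22**2
            + 10.0 * z72**2
            - 10.0 * z31**2
            + 10.0 * np.exp(-z31) * z41
            - 8.0 * np.sin(2 * np.pi * z72) * np.cos(2 * np.pi * z31)
            + 20.0 * z11 * z72
        )
    raise ValueError(f"unknown scenario {scenario}")


def simulate_dataset(cfg: ScenarioConfig) -> SimulatedDataset:
    """Generate one full replicate (curves, covariate, outcome, ground truth).

    All randomness flows from ``cfg.seed``; identical configs give
    bit-identical datasets.  The first 75% of subjects form the training set.
    """
    rng = np.random.default_rng(cfg.seed)
    n, J, p = cfg.n_subjects, cfg.n_basis_per_functional, cfg.n_functionals
    grid = sample_time_grid(cfg, rng)
    varsigma = eigen_coefficients(cfg)
    basis = np.stack([fourier_basis(j, grid) for j in range(1, J + 1)])  # J x m

    curves, xi_blocks = [], []
    for _ in range(p):
        xi = rng.standard_normal((n, J))
        curves.append((xi * varsigma) @ basis)
        xi_blocks.append(xi)
    xi_all = np.hstack(xi_blocks)
    zeta = norm.cdf(xi_all)

    x = rng.standard_normal(n)
    h = true_h(cfg.scenario, zeta)
    y = 2.0 * x + h + rng.normal(0.0, cfg.noise_sd, size=n)

    signals = SCENARIO1_SIGNALS if cfg.scenario == 1 else SCENARIO2_SIGNALS
    feat_idx = sorted(g * J + j for g, j in signals)
    group_idx = sorted({g for g, _ in signals})

    n_train = int(round(0.75 * n))
    return SimulatedDataset(
        config=cfg,
        grid=grid,
        curves=curves,
        x=x,
        y=y,
        true_zeta=zeta,
        true_h=h,
        signal_feature_indices=feat_idx,
        signal_group_indices=group_idx,
        train_index=np.arange(n_train),
        test_index=np.arange(n_train, n),
    )
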