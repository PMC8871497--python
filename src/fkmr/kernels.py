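"""Garrote-scaled Gaussian kernel and the gradient of F(gamma) = K(gamma) alpha.

The kernel is K(u, v) = exp(-||u - v||^2 / p) with the bandwidth denominator
p held fixed at the total number of features; feature selection acts through
the scaling vector gamma that multiplies the features inside the kernel:

    [K(gamma; Z)]_ik = exp(-(1/p) sum_j gamma_j^2 (z_ij - z_kj)^2).

The dependence on gamma is through gamma_j^2, so the sign of gamma is
immaterial everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "kernel_matrix", "kernel_cross", "grad_F"]


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel with a fixed bandwidth denominator (identifiability)."""

    bandwidth_denominator: float

    def __post_init__(self) -> None:
        if not self.bandwidth_denominator > 0:
            raise ValueError("bandwidth denominator must be positive")


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite values in kernel inputs")


def kernel_matrix(Z: np.ndarray, gamma: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Gram matrix of the gamma-scaled Gaussian kernel on the rows of Z."""
    Z = np.asarray(Z, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    _check_finite(Z, gamma)
    S = Z * gamma
    sq = np.einsum("ij,ij->i", S, S)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (S @ S.T)
    np.clip(d2, 0.0, None, out=d2)
    K = np.exp(-d2 / spec.bandwidth_denominator)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def kernel_cross(Z_new: np.ndarray, Z_train: np.ndarray, gamma: np.ndarray,
                 spec: KernelSpec) -> np.ndarray:
    """Cross-kernel matrix: rows index new subjects, columns training subjects."""
    Z_new = np.atleast_2d(np.asarray(Z_new, dtype=float))
    Z_train = np.asarray(Z_train, dtype=float)
    if Z_new.shape[1] != Z_train.shape[1]:
        raise ValueError("feature-count mismatch between new and training data")
    gamma = np.asarray(gamma, dtype=float)
    _check_finite(Z_new, Z_train, gamma)
    A = Z_new * gamma
    B = Z_train * gamma
    d2 = (np.einsum("ij,ij->i", A, A)[:, None]
          + np.einsum("ij,ij->i", B, B)[None, :] - 2.0 * (A @ B.T))
    np.clip(d2, 0.0, None, out=d2)
    return np.exp(-d2 / spec.bandwidth_denominator)


def grad_F(Z: np.ndarray, gamma: np.ndarray, alpha: np.ndarray,
           spec: KernelSpec, K: np.ndarray | None = None) -> np.ndarray:
    """Gradient of F(gamma) = K(gamma; Z) alpha with respect to gamma.

    Entry (i, j) is sum_k alpha_k K_ik * (-2/p) gamma_j (z_ij - z_kj)^2,
    assembled from three Gram-matrix products via the expansion
    (z_ij - z_kj)^2 = z_ij^2 + z_kj^2 - 2 z_ij z_kj.
    """
    Z = np.asarray(Z, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if K is None:
        K = kernel_matrix(Z, gamma, spec)
    Z2 = Z * Z
    Ka = K @ alpha  # n
    t1 = Z2 * Ka[:, None]  # z_ij^2 sum_k alpha_k K_ik
    t2 = K @ (alpha[:, None] * Z2)  # sum_k alpha_k K_ik z_kj^2
    t3 = Z * (K @ (alpha[:, None] * Z))  # z_ij sum_k alpha_k K_ik z_kj
    return (-2.0 / spec.bandwidth_denominator) * gamma * (t1 + t2 - 2.0 * t3)
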