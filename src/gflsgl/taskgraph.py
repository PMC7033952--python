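"""Gaussian-kernel task-dependency graph and the fused-Laplacian transform.

Tasks are longitudinal time points.  Each task ``t`` is coupled to every
other task through Gaussian-kernel weights over the visit positions, and
the transform ``D`` turns the coefficient matrix ``Theta`` into per-task
deviations from the kernel-weighted average of the other tasks:

    column t of Theta @ D  =  theta_t - sum_{l != t} w_{l,t} theta_l.

Penalizing those deviations shrinks each feature group's trajectory
toward a smooth curve instead of only tying consecutive visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TaskGraph", "gaussian_weights", "build_transform"]


def gaussian_weights(k: int, sigma: float,
                     times: np.ndarray | None = None) -> np.ndarray:
    """Column-normalized Gaussian kernel weights.

    ``W[l, t] = exp(-(times_l - times_t)^2 / sigma^2)`` for ``l != t``,
    normalized so every column sums to one; the diagonal is zero.
    """
    if k < 2:
        raise ValueError("temporal coupling requires >= 2 tasks")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if times is None:
        times = np.arange(1, k + 1, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape != (k,):
        raise ValueError(f"times must have length k={k}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    diff = times[:, None] - times[None, :]
    with np.errstate(under="ignore"):
        W = np.exp(-(diff ** 2) / sigma ** 2)
    np.fill_diagonal(W, 0.0)
    colsum = W.sum(axis=0)
    if np.any(colsum == 0):
        # sigma so small every kernel value underflows: fall back to
        # nearest-neighbour weights (the sigma -> 0 limit).
        W = _nearest_neighbour_weights(times)
        colsum = W.sum(axis=0)
    return W / colsum


def _nearest_neighbour_weights(times: np.ndarray) -> np.ndarray:
    k = times.size
    W = np.zeros((k, k))
    for t in range(k):
        d = np.abs(times - times[t])
        d[t] = np.inf
        near = d == d.min()
        W[near, t] = 1.0 / near.sum()
    return W


def build_transform(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Transform ``D`` (unit diagonal, ``-W`` off-diagonal) and ``Phi = D D^T``."""
    k = W.shape[0]
    D = np.eye(k) - W
    Phi = D @ D.T
    return D, Phi


@dataclass
class TaskGraph:
    """Bundle of kernel weights W, transform D and Phi = D D^T.

    Parameters
    ----------
    k : int
        Number of tasks (time points); must be >= 2.
    sigma : float
        Kernel bandwidth in the units of `times`.  Small sigma couples
        only adjacent visits; large sigma couples all visits equally.
    times : array-like, optional
        Task positions.  Defaults to indices 1..k; pass visit months for
        irregular spacing.
    symmetrize : bool
        If True, replace D by (D + D^T)/2.  The per-column normalization
        makes W (hence D) asymmetric at edge tasks; the solver handles
        the asymmetric transform exactly, so this is off by default.
    """

    k: int
    sigma: float = 1.0
    times: np.ndarray | None = None
    symmetrize: bool = False
    W: np.ndarray = field(init=False)
    D: np.ndarray = field(init=False)
    Phi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.times is None:
            self.times = np.arange(1, self.k + 1, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.W = gaussian_weights(self.k, self.sigma, self.times)
        self.D, self.Phi = build_transform(self.W)
        if self.symmetrize:
            self.D = 0.5 * (self.D + self.D.T)
            self.Phi = self.D @ self.D.T
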