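"""Structured-sparsity norms and their proximal operators.

All operators act on a coefficient matrix ``theta`` of shape (p, k):
rows index features, columns index tasks (time points).  Group blocks
are defined by a :class:`~gflsgl.data.GroupStructure`.

The three penalties combined in the model objective are

* elementwise l1 (feature-level sparsity),
* the task-common group norm ``sum_l w_l * ||theta[G_l, :]||_F`` that
  switches whole feature groups on or off jointly for all tasks,
* the group-guided fused-Laplacian norm, the task-specific group norm
  applied to ``theta @ D``, which shrinks each group's coefficients
  toward their kernel-weighted temporal average blockwise.
"""

from __future__ import annotations

import numpy as np

from .data import GroupStructure, LongitudinalDataset
from .taskgraph import TaskGraph

__all__ = [
    "norm_l21", "norm_g21_common", "norm_g21_specific", "norm_fused_lasso",
    "norm_gfl", "objective", "soft_threshold", "prox_group_rows",
    "prox_sgl", "prox_gfl_blocks",
]


# ---------------------------------------------------------------- norms

def norm_l21(theta: np.ndarray) -> float:
    """Row-wise l2,1 norm: sum of l2 norms of the feature rows."""
    return float(np.linalg.norm(theta, axis=1).sum())


def norm_g21_common(theta: np.ndarray, groups: GroupStructure) -> float:
    """Task-common group norm: sum_l w_l ||theta[G_l, :]||_F."""
    return float(sum(
        w * np.linalg.norm(theta[g, :])
        for g, w in zip(groups.groups, groups.weights)
    ))


def norm_g21_specific(theta: np.ndarray, groups: GroupStructure) -> float:
    """Task-specific group norm: sum_l sum_m w_l ||theta[G_l, m]||_2."""
    return float(sum(
        w * np.linalg.norm(theta[g, :], axis=0).sum()
        for g, w in zip(groups.groups, groups.weights)
    ))


def norm_fused_lasso(theta: np.ndarray) -> float:
    """Chain fused-Lasso norm: sum_m ||theta[:, m] - theta[:, m+1]||_1.

    Diagnostic only — the model's temporal penalty is :func:`norm_gfl`.
    """
    return float(np.abs(np.diff(theta, axis=1)).sum())


def norm_gfl(theta: np.ndarray, groups: GroupStructure,
             task_graph: TaskGraph) -> float:
    """Group-guided fused-Laplacian norm: task-specific group norm of theta @ D."""
    return norm_g21_specific(theta @ task_graph.D, groups)


def masked_loss(theta: np.ndarray, ds: LongitudinalDataset) -> float:
    """Half squared error over observed response cells."""
    R = np.where(ds.mask.astype(bool), ds.Y - ds.X @ theta, 0.0)
    return 0.5 * float(np.sum(R * R))


def objective(theta: np.ndarray, ds: LongitudinalDataset,
              groups: GroupStructure, task_graph: TaskGraph,
              lambda1: float, lambda2: float, lambda3: float) -> float:
    """Full penalized objective of the model."""
    val = masked_loss(theta, ds)
    if lambda1:
        val += lambda1 * float(np.abs(theta).sum())
    if lambda2:
        val += lambda2 * norm_g21_common(theta, groups)
    if lambda3:
        val += lambda3 * norm_gfl(theta, groups, task_graph)
    return val


# ------------------------------------------------------ proximal operators

def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise sign(x) * max(|x| - tau, 0); the prox of tau*||.||_1."""
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _shrink_factor(norm: float, threshold: float) -> float:
    # limit of max(norm - thr, 0)/norm at norm -> 0 is 0
    if norm <= threshold or norm == 0.0:
        return 0.0
    return (norm - threshold) / norm


def prox_group_rows(pi: np.ndarray, tau: float,
                    groups: GroupStructure) -> np.ndarray:
    """Prox of the task-common group norm: blockwise Frobenius shrinkage.

    Every row block ``pi[G_l, :]`` is scaled by
    ``max(||pi[G_l, :]||_F - tau * w_l, 0) / ||pi[G_l, :]||_F``.
    """
    out = np.zeros_like(pi)
    for g, w in zip(groups.groups, groups.weights):
        blk = pi[g, :]
        out[g, :] = blk * _shrink_factor(float(np.linalg.norm(blk)), tau * w)
    return out


def prox_sgl(omega: np.ndarray, tau1: float, tau2: float,
             groups: GroupStructure) -> np.ndarray:
    """Prox of ``tau1*||.||_1 + tau2*(task-common group norm)``.

    Exact two-step composition (soft-threshold, then group shrinkage) —
    the standard sparse-group-Lasso decomposition, valid because the
    groups do not overlap.
    """
    return prox_group_rows(soft_threshold(omega, tau1), tau2, groups)


def prox_gfl_blocks(z: np.ndarray, tau: float,
                    groups: GroupStructure) -> np.ndarray:
    """Prox of the task-specific group norm: per (group, task) l2 shrinkage."""
    out = np.zeros_like(z)
    for g, w in zip(groups.groups, groups.weights):
        blk = z[g, :]
        norms = np.linalg.norm(blk, axis=0)
        scale = np.array([_shrink_factor(float(nm), tau * w) for nm in norms])
        out[g, :] = blk * scale[None, :]
    return out
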