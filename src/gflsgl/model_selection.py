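"""Nested cross-validation over log-scale penalty grids, plus baselines.

The protocol: outer K-fold (default 10) over subjects; within each outer
training fold, standardize features on the training rows, run an inner
K-fold (default 5) grid search over (lambda1, lambda2, lambda3)
minimizing mean inner-validation nMSE, refit on the whole training fold
at the selected point, and score the held-out outer fold.  Folds are
subject-wise, so all time points of a subject stay on one side of every
split.

Baselines: per-task ridge regression (closed form on observed rows) and
per-task Lasso, realized as the main model with the group and temporal
penalties switched off (the objective then decouples across tasks).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .data import (GroupStructure, LongitudinalDataset, apply_standardizer,
                   fit_standardizer)
from .metrics import EvaluationReport, evaluate
from .solver import GFLSGL, GFLSGLResults, ConvergenceError, SolverConfig
from .taskgraph import TaskGraph

__all__ = ["GridSpec", "CVResult", "nested_cv", "fit_ridge", "fit_lasso"]

DEFAULT_LADDER = (0.1, 1.0, 10.0, 100.0, 1000.0)


@dataclass
class GridSpec:
    """Hyperparameter grid and fold layout for nested CV."""

    lambda1: tuple = DEFAULT_LADDER
    lambda2: tuple = DEFAULT_LADDER
    lambda3: tuple = DEFAULT_LADDER
    sigma: float = 1.0
    rho: float = 1.0
    outer_folds: int = 10
    inner_folds: int = 5
    seed: int = 0
    max_iter: int = 2000
    tol_primal: float = 1e-5
    tol_obj: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            vals = tuple(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} grid is empty")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} values must be nonnegative")
            setattr(self, name, vals)
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")

    def points(self) -> list[tuple[float, float, float]]:
        return list(itertools.product(self.lambda1, self.lambda2, self.lambda3))


@dataclass
class CVResult:
    """Aggregated outer-fold metrics and the per-fold selections."""

    fold_reports: list[EvaluationReport]
    selected: list[tuple[float, float, float]]
    nmse_mean: float = field(init=False)
    nmse_sd: float = field(init=False)
    wr_mean: float = field(init=False)
    wr_sd: float = field(init=False)
    rmse_mean: np.ndarray = field(init=False)
    rmse_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        nmse = np.array([r.nmse for r in self.fold_reports])
        wr = np.array([r.wr for r in self.fold_reports])
        rmse = np.vstack([r.rmse for r in self.fold_reports])
        self.nmse_mean, self.nmse_sd = float(nmse.mean()), float(nmse.std())
        self.wr_mean, self.wr_sd = float(np.nanmean(wr)), float(np.nanstd(wr))
        self.rmse_mean = rmse.mean(axis=0)
        self.rmse_sd = rmse.std(axis=0)

    def summary(self) -> str:
        lines = [
            "Nested cross-validation",
            "=" * 44,
            f"outer folds: {len(self.fold_reports)}",
            f"nMSE: {self.nmse_mean:.4f} +/- {self.nmse_sd:.4f}",
            f"wR:   {self.wr_mean:.4f} +/- {self.wr_sd:.4f}",
            "selected (lambda1, lambda2, lambda3) per fold:",
        ]
        lines += [f"  fold {i}: {sel}" for i, sel in enumerate(self.selected)]
        return "\n".join(lines)


def _fit_point(train: LongitudinalDataset, groups: GroupStructure,
               tg: TaskGraph, lams: tuple[float, float, float],
               grid: GridSpec) -> "GFLSGLResults":
    cfg = SolverConfig(lambda1=lams[0], lambda2=lams[1], lambda3=lams[2],
                       rho=grid.rho, max_iter=grid.max_iter,
                       tol_primal=grid.tol_primal, tol_obj=grid.tol_obj)
    return GFLSGL(train, groups, tg).fit(config=cfg)


def _score(ds_test: LongitudinalDataset, theta: np.ndarray) -> float:
    pred = ds_test.X @ theta
    return evaluate(ds_test.Y, pred, ds_test.mask).nmse


def _mask_ok(ds: LongitudinalDataset, rows: np.ndarray) -> bool:
    return bool(np.all(ds.mask[rows].sum(axis=0) >= 1))


def nested_cv(ds: LongitudinalDataset, groups: GroupStructure,
              task_graph: TaskGraph | None, grid: GridSpec,
              seed: int | None = None) -> CVResult:
    """Run the nested CV protocol; returns per-fold metrics and selections.

    A grid point whose inner fit diverges is recorded as infinitely bad
    rather than aborting the search.  Ties on inner nMSE are broken by
    the lexicographically smallest (lambda3, lambda2, lambda1).
    """
    if seed is None:
        seed = grid.seed
    tg = task_graph if task_graph is not None \
        else TaskGraph(ds.k, sigma=grid.sigma)
    if ds.n < grid.outer_folds:
        raise ValueError("need at least as many samples as outer folds")
    outer = KFold(n_splits=grid.outer_folds, shuffle=True, random_state=seed)
    points = grid.points()
    reports, selected = [], []
    for fold, (tr, te) in enumerate(outer.split(np.arange(ds.n))):
        train, test = ds.subset(tr), ds.subset(te)
        std = fit_standardizer(train)
        train_z, test_z = apply_standardizer(train, std), \
            apply_standardizer(test, std)
        best = _grid_search(train_z, groups, tg, points, grid,
                            seed=seed + 1000 + fold)
        res = _fit_point(train_z, groups, tg, best, grid)
        reports.append(evaluate(test_z.Y, res.predict(test_z.X), test_z.mask,
                                task_labels=list(ds.time_labels)))
        selected.append(best)
    return CVResult(reports, selected)


def _grid_search(train: LongitudinalDataset, groups: GroupStructure,
                 tg: TaskGraph, points, grid: GridSpec,
                 seed: int) -> tuple[float, float, float]:
    inner = KFold(n_splits=grid.inner_folds, shuffle=True, random_state=seed)
    splits = []
    for itr, iva in inner.split(np.arange(train.n)):
        # a validation fold that loses every observation of some task
        # cannot be scored; such folds are skipped
        if _mask_ok(train, itr) and _mask_ok(train, iva):
            splits.append((itr, iva))
    if not splits:
        raise ValueError("no usable inner folds (tasks fully unobserved)")
    scores = {}
    for lams in points:
        vals = []
        for itr, iva in splits:
            sub_tr, sub_va = train.subset(itr), train.subset(iva)
            std = fit_standardizer(sub_tr)
            try:
                res = _fit_point(apply_standardizer(sub_tr, std), groups, tg,
                                 lams, grid)
                vals.append(_score(apply_standardizer(sub_va, std), res.theta))
            except (ConvergenceError, np.linalg.LinAlgError):
                vals.append(np.inf)
        scores[lams] = float(np.mean(vals))
    best_score = min(scores.values())
    ties = [l for l, s in scores.items() if s <= best_score]
    # prefer the smallest (lambda3, lambda2, lambda1) among exact ties
    ties.sort(key=lambda l: (l[2], l[1], l[0]))
    return ties[0]


# ------------------------------------------------------------- baselines

def fit_ridge(ds: LongitudinalDataset, lam: float) -> np.ndarray:
    """Per-task ridge on observed rows: (X_t'X_t + lam I)^-1 X_t'y_t."""
    if lam < 0:
        raise ValueError("ridge penalty must be nonnegative")
    p, k = ds.p, ds.k
    theta = np.empty((p, k))
    obs = ds.mask.astype(bool)
    for t in range(k):
        Xt = ds.X[obs[:, t]]
        yt = ds.Y[obs[:, t], t]
        A = Xt.T @ Xt + lam * np.eye(p)
        if lam == 0:
            theta[:, t] = np.linalg.pinv(Xt) @ yt
        else:
            theta[:, t] = np.linalg.solve(A, Xt.T @ yt)
    return theta


def fit_lasso(ds: LongitudinalDataset, lam: float,
              **solver_kwargs) -> np.ndarray:
    """Per-task Lasso via the main solver with lambda2 = lambda3 = 0."""
    cfg = SolverConfig(lambda1=lam, lambda2=0.0, lambda3=0.0, **solver_kwargs)
    res = GFLSGL(ds, GroupStructure.singletons(ds.p)).fit(config=cfg)
    return res.theta
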