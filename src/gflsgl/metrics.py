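"""Mask-aware evaluation measures for multitask longitudinal prediction.

Per task h (time point) with n_h observed responses:

* rMSE_h — root mean squared error over observed cells,
* CC_h   — Pearson correlation over observed cells,

and two aggregates over all tasks,

* nMSE = sum_h ||Y_h - Yhat_h||^2 / Var(Y_h)  /  sum_h n_h,
* wR   = sum_h CC_h * n_h / sum_h n_h,

where Var is the population variance of the observed responses of task
h.  Under that convention the per-task mean predictor scores nMSE = 1
exactly, making nMSE a variance-normalized error against the trivial
baseline.  Tasks whose observed responses are constant (or fewer than
two) have no defined correlation and are flagged rather than given a
number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvaluationReport", "evaluate"]


@dataclass
class EvaluationReport:
    """Per-task and aggregate prediction quality."""

    rmse: np.ndarray            # (k,)
    cc: np.ndarray              # (k,), nan where undefined
    cc_defined: np.ndarray      # (k,) bool
    nmse: float
    wr: float
    n_obs: np.ndarray           # (k,)
    task_labels: list[str] | None = None

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse.tolist(),
            "cc": [c if d else None for c, d in zip(self.cc, self.cc_defined)],
            "nmse": self.nmse,
            "wr": self.wr,
            "n_obs": self.n_obs.tolist(),
            "task_labels": self.task_labels,
        }

    def table(self) -> str:
        labels = self.task_labels or [f"t{h + 1}" for h in range(len(self.rmse))]
        lines = [f"{'task':>8} {'n':>6} {'rMSE':>12} {'CC':>10}"]
        for h, lab in enumerate(labels):
            cc = f"{self.cc[h]:.4f}" if self.cc_defined[h] else "undef"
            lines.append(f"{lab:>8} {self.n_obs[h]:>6d} "
                         f"{self.rmse[h]:>12.6g} {cc:>10}")
        lines.append(f"nMSE = {self.nmse:.6g}   wR = {self.wr:.6g}")
        return "\n".join(lines)


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             mask: np.ndarray | None = None,
             task_labels: list[str] | None = None,
             nmse_sigma: str = "var") -> EvaluationReport:
    """Score predictions over observed cells only.

    Parameters
    ----------
    y_true, y_pred : (n, k) arrays
    mask : (n, k) binary array, optional
        Defaults to the non-NaN cells of `y_true`.
    nmse_sigma : {"var", "std"}
        Normalizer per task in nMSE; "var" (population variance) is the
        multitask-learning convention and makes the mean predictor score 1.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    if mask is None:
        mask = (~np.isnan(y_true)).astype(np.int8)
    mask = np.asarray(mask)
    if mask.shape != y_true.shape:
        raise ValueError("mask shape must match y_true")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    if nmse_sigma not in ("var", "std"):
        raise ValueError("nmse_sigma must be 'var' or 'std'")

    n, k = y_true.shape
    obs = mask.astype(bool)
    n_obs = obs.sum(axis=0)
    if np.any(n_obs == 0):
        raise ValueError("a task has zero observed cells")

    rmse = np.empty(k)
    cc = np.full(k, np.nan)
    cc_defined = np.zeros(k, dtype=bool)
    sse = np.empty(k)
    sigma = np.empty(k)
    for h in range(k):
        yt = y_true[obs[:, h], h]
        yp = y_pred[obs[:, h], h]
        err = yt - yp
        sse[h] = float(err @ err)
        rmse[h] = np.sqrt(sse[h] / n_obs[h])
        var = float(yt.var())  # population variance
        sigma[h] = var if nmse_sigma == "var" else np.sqrt(var)
        # a degenerate (numerically constant) vector has no correlation
        yp_spread = yp.std() > 1e-12 * (np.abs(yp).max() + 1.0)
        yt_spread = var > (1e-12 * (np.abs(yt).max() + 1.0)) ** 2
        if n_obs[h] >= 2 and yt_spread and yp_spread:
            cc[h] = float(np.corrcoef(yt, yp)[0, 1])
            cc_defined[h] = True
        if sigma[h] <= 0:
            raise ValueError(
                f"task {h} has zero-variance observed responses; "
                "nMSE normalizer undefined")

    nmse = float(np.sum(sse / sigma) / n_obs.sum())
    defined = cc_defined
    if not defined.any():
        wr = np.nan
    else:
        wr = float(np.sum(cc[defined] * n_obs[defined]) / n_obs[defined].sum())
    return EvaluationReport(rmse=rmse, cc=cc, cc_defined=cc_defined,
                            nmse=nmse, wr=wr, n_obs=n_obs,
                            task_labels=task_labels)
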