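"""Core data containers and I/O for longitudinal multitask regression.

The data model mirrors how longitudinal cognitive-score studies are laid
out: one row per subject, one feature matrix ``X`` shared by all time
points, and a response matrix ``Y`` with one column per visit.  Later
visits are typically missing for many subjects (attrition), so ``Y``
carries an explicit binary observation mask rather than imputed values.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalDataset",
    "GroupStructure",
    "Standardizer",
    "read_dataset",
    "write_dataset",
    "read_groups",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass
class LongitudinalDataset:
    """Feature matrix, response matrix and observation mask.

    Parameters
    ----------
    X : (n, p) ndarray
        Covariates; must be finite.
    Y : (n, k) ndarray
        Responses per time point; unobserved cells are ``nan`` internally.
    mask : (n, k) ndarray of {0, 1}
        ``mask[i, t] == 1`` iff ``Y[i, t]`` was observed.
    feature_ids : list of str
    time_labels : list of str
    sample_ids : list of str, optional
    """

    X: np.ndarray
    Y: np.ndarray
    mask: np.ndarray
    feature_ids: list[str] = field(default_factory=list)
    time_labels: list[str] = field(default_factory=list)
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but Y has {self.Y.shape[0]}"
            )
        if self.mask.shape != self.Y.shape:
            raise ValueError("mask shape must match Y")
        if not self.feature_ids:
            self.feature_ids = [f"x{j + 1}" for j in range(self.p)]
        if not self.time_labels:
            self.time_labels = [f"t{t + 1}" for t in range(self.k)]
        if len(self.feature_ids) != self.p:
            raise ValueError("feature_ids length does not match X columns")
        if len(self.time_labels) != self.k:
            raise ValueError("time_labels length does not match Y columns")
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def k(self) -> int:
        return self.Y.shape[1]

    def validate(self) -> None:
        """Enforce the container invariants (finiteness, mask consistency)."""
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        observed = self.mask.astype(bool)
        if not np.all(np.isfinite(self.Y[observed])):
            raise ValueError("observed Y cells must be finite")
        if np.any(np.isfinite(self.Y[~observed])):
            raise ValueError("masked Y cells must carry the missing sentinel (nan)")
        counts = observed.sum(axis=0)
        if np.any(counts < 1):
            t = int(np.argmin(counts))
            raise ValueError(
                f"task has no observed responses: {self.time_labels[t]!r}"
            )

    def subset(self, rows: np.ndarray) -> "LongitudinalDataset":
        """Row-subset (e.g. a CV fold) preserving metadata."""
        rows = np.asarray(rows)
        sids = None
        if self.sample_ids is not None:
            sids = [self.sample_ids[i] for i in np.arange(self.n)[rows]] \
                if rows.dtype == bool else [self.sample_ids[i] for i in rows]
        return LongitudinalDataset(
            self.X[rows], self.Y[rows], self.mask[rows],
            list(self.feature_ids), list(self.time_labels), sids,
        )


@dataclass
class GroupStructure:
    """Disjoint partition of the p features into q groups.

    In imaging applications a group is one region of interest whose
    derived measures (volume, area, thickness statistics) enter as
    separate columns; ungrouped covariates are singleton groups.
    """

    groups: list[np.ndarray]
    weights: np.ndarray | None = None
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=int) for g in self.groups]
        all_idx = np.concatenate(self.groups) if self.groups else np.array([], int)
        if len(np.unique(all_idx)) != all_idx.size:
            raise ValueError("overlapping groups: a feature appears twice")
        if self.weights is None:
            self.weights = np.sqrt(self.sizes.astype(float))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("group weights must be positive")
        if self.labels is None:
            self.labels = [f"g{l + 1}" for l in range(self.q)]

    @property
    def q(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([g.size for g in self.groups], dtype=int)

    @property
    def p(self) -> int:
        return int(sum(g.size for g in self.groups))

    def covers(self, p: int) -> bool:
        if self.p != p:
            return False
        return bool(np.array_equal(np.sort(np.concatenate(self.groups)), np.arange(p)))

    @classmethod
    def singletons(cls, p: int) -> "GroupStructure":
        return cls([np.array([j]) for j in range(p)])


def _sniff_sep(path: str) -> str:
    with open(path) as fh:
        head = fh.readline()
    return "\t" if head.count("\t") > head.count(",") else ","


def _read_table(path: str, missing_token: str | None = None) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    na = [missing_token] if missing_token is not None else []
    df = pd.read_csv(path, sep=sep, index_col=0, keep_default_na=False,
                     na_values=na, dtype=str)
    return df


def read_dataset(x_path: str, y_path: str,
                 missing_token: str = "NA") -> LongitudinalDataset:
    """Read X and Y from delimited text (header row, sample-ID column).

    Cells of ``Y`` equal to `missing_token` become masked entries; any
    other non-numeric cell raises a parse error locating it.
    """
    xdf = _read_table(x_path)
    ydf = _read_table(y_path, missing_token)
    if len(xdf) != len(ydf):
        raise ValueError(
            f"dimension mismatch: {x_path} has {len(xdf)} rows, "
            f"{y_path} has {len(ydf)}"
        )
    X = _to_float(xdf, x_path)
    Y = _to_float(ydf, y_path, allow_nan=True)
    mask = (~np.isnan(Y)).astype(np.int8)
    return LongitudinalDataset(
        X, Y, mask,
        feature_ids=list(xdf.columns), time_labels=list(ydf.columns),
        sample_ids=[str(s) for s in xdf.index],
    )


def _to_float(df: pd.DataFrame, path: str, allow_nan: bool = False) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    vals = df.to_numpy()
    for (i, j), cell in np.ndenumerate(vals):
        if allow_nan and (cell is np.nan or (isinstance(cell, float) and np.isnan(cell))):
            out[i, j] = np.nan
            continue
        try:
            out[i, j] = float(cell)
        except (TypeError, ValueError):
            raise ValueError(
                f"parse error in {path}: non-numeric cell at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}: {cell!r}"
            ) from None
    return out


def write_dataset(ds: LongitudinalDataset, x_path: str, y_path: str,
                  missing_token: str = "NA") -> None:
    """Write X/Y back to delimited text, full precision (round-trip safe)."""
    sids = ds.sample_ids or [f"s{i + 1}" for i in range(ds.n)]
    xdf = pd.DataFrame(ds.X, index=sids, columns=ds.feature_ids)
    ydf = pd.DataFrame(ds.Y, index=sids, columns=ds.time_labels)
    fmt = lambda v: missing_token if np.isnan(v) else repr(float(v))  # noqa: E731
    _atomic_write(x_path, xdf.to_csv(float_format=lambda v: repr(float(v))))
    buf = io.StringIO()
    ydf.map(fmt).to_csv(buf)
    _atomic_write(y_path, buf.getvalue())


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def read_groups(path: str, feature_ids: list[str]) -> GroupStructure:
    """Read a two-column ``feature,group`` map into a GroupStructure.

    Features absent from the file become singleton groups, so ungrouped
    covariates (e.g. intracranial volume) are representable.  A feature
    mapped to two groups, or an unknown feature id, is an error.
    """
    sep = _sniff_sep(path) if os.path.getsize(path) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    pos = {f: j for j, f in enumerate(feature_ids)}
    seen: dict[str, str] = {}
    by_group: dict[str, list[int]] = {}
    for _, row in df.iterrows():
        feat, grp = str(row.iloc[0]), str(row.iloc[1])
        if feat not in pos:
            raise ValueError(f"unknown feature_id in group file: {feat!r}")
        if feat in seen:
            raise ValueError(f"overlapping groups: {feat!r} mapped to "
                             f"{seen[feat]!r} and {grp!r}")
        seen[feat] = grp
        by_group.setdefault(grp, []).append(pos[feat])
    groups, labels = [], []
    for grp in by_group:
        groups.append(np.sort(by_group[grp]))
        labels.append(grp)
    for feat in feature_ids:
        if feat not in seen:
            groups.append(np.array([pos[feat]]))
            labels.append(feat)
    return GroupStructure(groups, labels=labels)


@dataclass
class Standardizer:
    """Per-column z-scoring learned on training rows only.

    Uses population (1/n) standard deviations.  Responses are left on
    their original scale by default so error metrics stay interpretable.
    """

    mean: np.ndarray
    std: np.ndarray
    y_mean: np.ndarray | None = None
    y_std: np.ndarray | None = None

    def transform(self, ds: LongitudinalDataset) -> LongitudinalDataset:
        X = (ds.X - self.mean) / self.std
        Y = ds.Y
        if self.y_mean is not None:
            Y = ds.Y.copy()
            obs = ds.mask.astype(bool)
            Y[obs] = ((ds.Y - self.y_mean) / self.y_std)[obs]
        return LongitudinalDataset(X, Y, ds.mask.copy(), list(ds.feature_ids),
                                   list(ds.time_labels), ds.sample_ids)

    def inverse_transform_x(self, X: np.ndarray) -> np.ndarray:
        return X * self.std + self.mean


def fit_standardizer(ds: LongitudinalDataset, rows: np.ndarray | None = None,
                     with_y: bool = False) -> Standardizer:
    """Learn z-scoring statistics from the given training rows."""
    if rows is None:
        rows = np.arange(ds.n)
    rows = np.asarray(rows)
    if rows.size == 0:
        raise ValueError("rows must be non-empty")
    Xtr = ds.X[rows]
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0)  # population sd
    zero = np.where(std <= 0)[0]
    if zero.size:
        names = ", ".join(ds.feature_ids[j] for j in zero)
        raise ValueError(f"zero-variance feature column(s): {names}")
    y_mean = y_std = None
    if with_y:
        Ytr, Mtr = ds.Y[rows], ds.mask[rows].astype(bool)
        y_mean = np.empty(ds.k)
        y_std = np.empty(ds.k)
        for t in range(ds.k):
            col = Ytr[Mtr[:, t], t]
            y_mean[t] = col.mean()
            y_std[t] = col.std()
        if np.any(y_std <= 0):
            raise ValueError("zero-variance observed response column")
    return Standardizer(mean, std, y_mean, y_std)


def apply_standardizer(ds: LongitudinalDataset, s: Standardizer) -> LongitudinalDataset:
    return s.transform(ds)
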