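"""Synthetic longitudinal data with the structure the model assumes.

The generator emulates an imaging-cohort layout: features arrive in
small disjoint groups (one region of interest contributes 1-4 derived
measures), only a few groups carry signal, the signal of an active group
varies smoothly over the k time points, and response observation rates
decay monotonically at later visits (cohort attrition).

Defaults follow a mid-sized longitudinal study: n = 200 subjects,
p = 60 features in q = 15 groups of 4, k = 4 visits, 4 active groups,
smooth group trajectories with jitter sd 0.2, noise calibrated to a
signal-to-noise ratio of 5, and visit observation probabilities
(1.0, 0.9, 0.8, 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GroupStructure, LongitudinalDataset
from .taskgraph import TaskGraph

__all__ = ["SyntheticSpec", "generate", "temporal_profile", "default_group_sizes"]


def default_group_sizes(p: int, q: int) -> list[int]:
    """Split p features into q groups using sizes 4 and 1 where possible.

    Mirrors region-of-interest layouts where most regions contribute four
    measures and some contribute one.  Falls back to near-equal sizes
    when (p, q) cannot be hit with 4s and 1s exactly.
    """
    if q > p:
        raise ValueError("more groups than features")
    # a groups of 4 and b of 1 with a+b=q, 4a+b=p  =>  a=(p-q)/3
    a, rem = divmod(p - q, 3)
    if rem == 0 and 0 <= a <= q:
        return [4] * a + [1] * (q - a)
    base, extra = divmod(p, q)
    return [base + 1] * extra + [base] * (q - extra)


@dataclass
class SyntheticSpec:
    """Sizes, effect structure and missingness of a simulated study."""

    n: int = 200
    p: int = 60
    k: int = 4
    q: int = 15
    group_sizes: list[int] | None = None
    s_groups: int = 4
    signal_sd: float = 1.0        # sd of the per-group base effect
    jitter_sd: float = 0.2        # temporal wobble around the smooth curve
    noise_sd: float | None = None  # overrides snr when given
    snr: float = 5.0              # Var(signal)/Var(noise) when noise_sd is None
    pi: tuple | None = None       # per-task observation probabilities
    sigma: float = 1.0            # task-graph bandwidth of the smoother
    misspecified: bool = False    # piecewise-constant profiles instead
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            self.group_sizes = default_group_sizes(self.p, self.q)
        if sum(self.group_sizes) != self.p or len(self.group_sizes) != self.q:
            raise ValueError("group_sizes must sum to p with q entries")
        if not 0 <= self.s_groups <= self.q:
            raise ValueError("s_groups must lie in [0, q]")
        if self.pi is None:
            # monotone attrition: full baseline, then ~10% lost per visit
            # with a sharper final drop, as longitudinal cohorts show
            self.pi = (1.0, 0.9, 0.8, 0.6) if self.k == 4 else \
                tuple(max(0.3, round(1.0 - 0.1 * t, 10)) for t in range(self.k))
        self.pi = tuple(self.pi)
        if len(self.pi) != self.k:
            raise ValueError("pi must have one probability per task")
        if any(not 0 < x <= 1 for x in self.pi):
            raise ValueError("pi entries must be in (0, 1]")
        if any(a < b for a, b in zip(self.pi, self.pi[1:])):
            raise ValueError("pi must be non-increasing (monotone dropout)")


def temporal_profile(base: np.ndarray, task_graph: TaskGraph,
                     jitter_sd: float, seed) -> np.ndarray:
    """Smooth coefficient block: base vector plus smoothed temporal jitter.

    Column t deviates from the kernel-weighted average of the other
    columns by an amount proportional to `jitter_sd`; at zero jitter all
    columns equal `base` (the fixed point of the smoother).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    base = np.asarray(base, dtype=float)
    k = task_graph.k
    Z = rng.normal(size=(base.size, k))
    smoothed = 0.5 * (Z + Z @ task_graph.W)  # one smoothing pass
    return base[:, None] + jitter_sd * smoothed


def _piecewise_profile(base: np.ndarray, k: int, rng) -> np.ndarray:
    """One change point, two plateaus — temporally rough on purpose."""
    cut = int(rng.integers(1, k))
    other = base + rng.normal(0, 1.0, size=base.size)
    block = np.empty((base.size, k))
    block[:, :cut] = base[:, None]
    block[:, cut:] = other[:, None]
    return block


def generate(spec: SyntheticSpec) -> tuple[LongitudinalDataset, np.ndarray,
                                           GroupStructure]:
    """Draw (dataset, theta_true, groups) reproducibly from `spec.seed`."""
    rng = np.random.default_rng(spec.seed)
    edges = np.cumsum([0] + list(spec.group_sizes))
    groups = GroupStructure([np.arange(edges[l], edges[l + 1])
                             for l in range(spec.q)])
    tg = TaskGraph(spec.k, sigma=spec.sigma)

    X = rng.normal(size=(spec.n, spec.p))
    theta = np.zeros((spec.p, spec.k))
    active = np.sort(rng.choice(spec.q, size=spec.s_groups, replace=False))
    for l in active:
        idx = groups.groups[l]
        base = rng.normal(0, spec.signal_sd, size=idx.size)
        if spec.misspecified:
            theta[idx, :] = _piecewise_profile(base, spec.k, rng)
        else:
            theta[idx, :] = temporal_profile(base, tg, spec.jitter_sd, rng)

    signal = X @ theta
    if spec.noise_sd is not None:
        noise_sd = spec.noise_sd
    elif spec.s_groups == 0:
        noise_sd = 1.0
    else:
        noise_sd = float(np.sqrt(signal.var() / spec.snr))
    Y = signal + rng.normal(0, noise_sd, size=signal.shape)

    mask = np.empty((spec.n, spec.k), dtype=np.int8)
    for t in range(spec.k):
        col = (rng.random(spec.n) < spec.pi[t]).astype(np.int8)
        while col.sum() == 0:  # resample the all-missing-task outcome
            col = (rng.random(spec.n) < spec.pi[t]).astype(np.int8)
        mask[:, t] = col
    Y = np.where(mask.astype(bool), Y, np.nan)

    ds = LongitudinalDataset(X, Y, mask)
    return ds, theta, groups
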