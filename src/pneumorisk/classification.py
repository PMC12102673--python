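"""Fisher-Jenks natural-breaks classification.

Partitions a 1-D value set into k contiguous classes minimizing the total
within-class sum of squared deviations from the class means, by Fisher's
O(k n^2) dynamic program over the distinct sorted values (so identical
values always share a class, and the optimum is global). Also provides
classification against fixed break boundaries (upper-inclusive classes)
and the goodness-of-variance-fit diagnostic GVF = 1 - SSD_within/SSD_total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedGVFError

__all__ = ["BreakSet", "jenks_breaks", "classify_with_breaks",
           "goodness_of_variance_fit", "DEFAULT_LABELS"]

DEFAULT_LABELS = ("low", "medium", "high")


@dataclass(frozen=True)
class BreakSet:
    """k ordered classes: boundaries b0 < b1 < ... < bk.

    Class j covers (b_j, b_{j+1}] except the lowest class, which is closed
    at both ends. Labels default to low/medium/high for k=3 and
    class_1..class_k otherwise.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        # k >= 2 for natural-breaks output; k = 1 permitted so the GVF of a
        # single all-covering class (identically 0) is expressible.
        if len(b) < 2:
            raise InvalidArgumentError("need at least 1 class (2 boundaries)")
        # boundaries are [data min, class maxima...]: class maxima ascend
        # strictly, but b0 may equal b1 when the lowest class is the single
        # minimum value (the lowest class is closed at both ends).
        if any(b[i] >= b[i + 1] for i in range(1, len(b) - 1)) or b[0] > b[1]:
            raise InvalidArgumentError(f"boundaries must be ascending: {b}")
        object.__setattr__(self, "boundaries", b)
        labels = tuple(self.labels)
        if not labels:
            labels = DEFAULT_LABELS if self.k == 3 else tuple(
                f"class_{j + 1}" for j in range(self.k)
            )
        if len(labels) != self.k:
            raise InvalidArgumentError(
                f"need {self.k} labels, got {len(labels)}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def k(self) -> int:
        return len(self.boundaries) - 1


def _weighted_prefixes(values: np.ndarray):
    """Distinct sorted values with multiplicities and their prefix sums."""
    u, w = np.unique(values, return_counts=True)
    w = w.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * u)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * u * u)])
    return u, cw, cwx, cwx2


def _group_cost(cw, cwx, cwx2, i, j):
    """Within-group SS of distinct values i..j inclusive (0-based)."""
    W = cw[j + 1] - cw[i]
    S = cwx[j + 1] - cwx[i]
    S2 = cwx2[j + 1] - cwx2[i]
    return S2 - S * S / W


def jenks_breaks(values, k: int, labels=()) -> BreakSet:
    """Globally optimal natural breaks of ``values`` into ``k`` classes.

    Boundaries are [min, max of class 1, ..., max of class k]. Requires at
    least ``k`` distinct values.
    """
    vals = np.asarray(values, dtype=float)
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if not np.all(np.isfinite(vals)):
        raise InvalidArgumentError("values must be finite")
    u, cw, cwx, cwx2 = _weighted_prefixes(vals)
    m = len(u)
    if m < k:
        raise InvalidArgumentError(f"need >= {k} distinct values, got {m}")

    # D[c][j]: optimal cost of splitting distinct values 0..j into c+1 groups
    cost = np.full((m, m), np.inf)
    for i in range(m):
        for j in range(i, m):
            cost[i, j] = _group_cost(cw, cwx, cwx2, i, j)
    D = cost[0].copy()
    back = np.zeros((k, m), dtype=int)
    for c in range(1, k):
        D_new = np.full(m, np.inf)
        for j in range(c, m):
            # last group starts at i; previous c groups cover 0..i-1
            best, best_i = np.inf, c
            for i in range(c, j + 1):
                val = D[i - 1] + cost[i, j]
                if val < best:
                    best, best_i = val, i
            D_new[j] = best
            back[c, j] = best_i
        D = D_new

    # backtrack group start indices
    bounds = [float(u[-1])]
    j = m - 1
    for c in range(k - 1, 0, -1):
        i = back[c, j]
        bounds.append(float(u[i - 1]))  # max of the previous group
        j = i - 1
    bounds.append(float(u[0]))
    return BreakSet(tuple(reversed(bounds)), labels=tuple(labels))


def within_class_ss(values, break_set: BreakSet) -> float:
    """Total within-class sum of squared deviations under ``break_set``."""
    vals = np.asarray(values, dtype=float)
    labels = classify_with_breaks(vals, break_set, warn=False)
    total = 0.0
    for lab in break_set.labels:
        grp = vals[labels == lab]
        if grp.size:
            total += float(np.sum((grp - grp.mean()) ** 2))
    return total


def classify_with_breaks(values, break_set: BreakSet, warn: bool = True) -> np.ndarray:
    """Assign each value its class label.

    Value v gets class j where b_j < v <= b_{j+1}; the lowest class is
    closed at both ends, so interior boundary values fall in the lower
    class. Values outside [b0, bk] clamp to the extreme classes (with a
    warning unless ``warn=False``).
    """
    vals = np.asarray(values, dtype=float)
    b = np.asarray(break_set.boundaries)
    interior = b[1:-1]
    idx = np.searchsorted(interior, vals, side="left")  # count of boundaries < v
    out_of_range = (vals < b[0]) | (vals > b[-1])
    if warn and out_of_range.any():
        warnings.warn(
            f"{int(out_of_range.sum())} value(s) outside [{b[0]}, {b[-1]}] "
            "clamped to the extreme classes",
            stacklevel=2,
        )
    return np.asarray(break_set.labels, dtype=object)[idx]


def goodness_of_variance_fit(values, break_set: BreakSet) -> float:
    """GVF = 1 - SSD_within / SSD_total, in [0, 1] for optimal breaks."""
    vals = np.asarray(values, dtype=float)
    if len(np.unique(vals)) < 2:
        raise UndefinedGVFError("GVF undefined: fewer than 2 distinct values")
    sst = float(np.sum((vals - vals.mean()) ** 2))
    if sst == 0:
        raise UndefinedGVFError("GVF undefined: zero total deviation")
    return 1.0 - within_class_ss(vals, break_set) / sst
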