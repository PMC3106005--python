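"""u-scores under a partial order, and rank correlation of u-scores.

The u-score of an observation is the number of cohort members it
definitely exceeds minus the number that definitely exceed it.  The
partial order accommodates every scale kind in the cohort at once:
binary, ordinal and continuous items are degenerate intervals that
compare by value (ties contribute nothing), while interval-censored
items compare only when the intervals are disjoint.  Pearson correlation
of u-scores equals midrank Spearman exactly for totally ordered data,
via the identity ``u_i = 2·midrank_i − (n + 1)``, and extends it to
partially ordered data.

Implementation notes: u-scores are computed in O(n log n) with two
sorted-array rank queries (the count of upper bounds strictly below an
observation's lower bound, minus the count of lower bounds strictly
above its upper bound), which is exactly the pairwise sum of comparison
signs.  Missing values (NaN) propagate to NaN scores; correlations use
pairwise-complete observations, with u-scores recomputed on each
complete subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .intervals import Interval, as_interval

__all__ = [
    "ObservationVector",
    "CorrelationMatrix",
    "po_compare",
    "u_scores",
    "u_correlation",
    "correlation_matrix",
]


def po_compare(a, b) -> int:
    """Compare two (possibly interval-valued) observations.

    Returns +1 if ``a`` is definitely greater (its lower bound exceeds
    ``b``'s upper bound), −1 in the symmetric case, and 0 for ties or
    overlapping intervals (incomparable).  Scalars are degenerate
    intervals.
    """
    ia, ib = as_interval(a), as_interval(b)
    if ia.lo > ib.hi:
        return 1
    if ia.hi < ib.lo:
        return -1
    return 0


class ObservationVector:
    """One item measured across the cohort.

    Values may be scalars, :class:`Interval` objects, ``(lo, hi)`` pairs,
    or NaN/None for missing.  Stored internally as parallel ``lo`` / ``hi``
    float arrays (NaN marks missing).
    """

    def __init__(
        self,
        values: Iterable,
        item_id: str = "",
        scale_kind: str = "continuous",
    ):
        los, his = [], []
        for v in values:
            if v is None:
                los.append(np.nan)
                his.append(np.nan)
            elif isinstance(v, Interval):
                los.append(v.lo)
                his.append(v.hi)
            elif isinstance(v, (tuple, list)):
                lo, hi = float(v[0]), float(v[1])
                if not (np.isnan(lo) or np.isnan(hi)) and lo > hi:
                    raise ValueError(f"malformed interval ({lo}, {hi})")
                los.append(lo)
                his.append(hi)
            else:
                x = float(v)
                los.append(x)
                his.append(x)
        self.lo = np.asarray(los, dtype=float)
        self.hi = np.asarray(his, dtype=float)
        if np.any(self.lo > self.hi):
            raise ValueError("malformed interval: lo > hi")
        self.item_id = item_id
        self.scale_kind = scale_kind

    def __len__(self) -> int:
        return self.lo.size

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing entries."""
        return ~(np.isnan(self.lo) | np.isnan(self.hi))


def _u_scores_bounds(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """u-scores for fully observed lo/hi bound arrays (vectorised).

    score_i = #{j : hi_j < lo_i} − #{j : lo_j > hi_i}; the index i itself
    contributes 0 to both counts since lo_i ≤ hi_i.
    """
    n = lo.size
    sorted_hi = np.sort(hi)
    sorted_lo = np.sort(lo)
    below = np.searchsorted(sorted_hi, lo, side="left")
    above = n - np.searchsorted(sorted_lo, hi, side="right")
    return (below - above).astype(float)


def u_scores(x: ObservationVector | Sequence) -> np.ndarray:
    """Per-observation u-scores for one item.

    For observation *i*, the sum over all *j* of
    ``po_compare(x_i, x_j)``.  Scores sum to zero over the observed
    entries and lie in ``[−(n−1), n−1]``; for totally ordered tie-free
    data, ``score_i = 2·rank_i − n − 1``.  Missing entries get NaN
    scores and do not enter any comparison.
    """
    if not isinstance(x, ObservationVector):
        x = ObservationVector(x)
    mask = x.observed
    n_obs = int(mask.sum())
    if n_obs < 2:
        raise ValueError("u-scores require at least 2 observed values")
    out = np.full(len(x), np.nan)
    out[mask] = _u_scores_bounds(x.lo[mask], x.hi[mask])
    return out


def u_correlation(x: ObservationVector | Sequence, y: ObservationVector | Sequence) -> float:
    """Pearson correlation of the u-scores of two items.

    Equals midrank Spearman exactly for scalar data (with any ties) and
    extends it to interval-censored data.  Uses pairwise-complete
    observations; u-scores are recomputed on the complete subset.
    Returns NaN when either item has zero u-score variance there
    (an undefined correlation is reported as missing, never as 0).
    """
    if not isinstance(x, ObservationVector):
        x = ObservationVector(x)
    if not isinstance(y, ObservationVector):
        y = ObservationVector(y)
    if len(x) != len(y):
        raise ValueError("items must be measured on the same patients")
    mask = x.observed & y.observed
    if int(mask.sum()) < 2:
        return float("nan")
    ux = _u_scores_bounds(x.lo[mask], x.hi[mask])
    uy = _u_scores_bounds(y.lo[mask], y.hi[mask])
    return _pearson(ux, uy)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0.0:
        return float("nan")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """Labelled symmetric correlation matrix with unit diagonal.

    Undefined cells (constant items, no overlapping observations) are
    NaN.
    """

    labels: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match label count")

    def loc(self, a: str, b: str) -> float:
        return float(self.r[self.labels.index(a), self.labels.index(b)])

    def submatrix_mean(self, rows: Sequence[str], cols: Sequence[str], absolute: bool = False) -> float:
        """Mean correlation over a block of item pairs (diagonal cells of
        the full matrix excluded; NaN cells ignored)."""
        ri = [self.labels.index(x) for x in rows]
        ci = [self.labels.index(x) for x in cols]
        block = self.r[np.ix_(ri, ci)].astype(float).copy()
        for i, a in enumerate(ri):
            for j, b in enumerate(ci):
                if a == b:
                    block[i, j] = np.nan
        if absolute:
            block = np.abs(block)
        if np.all(np.isnan(block)):
            return float("nan")
        return float(np.nanmean(block))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.r, index=self.labels, columns=self.labels)

    def to_json_dict(self) -> dict:
        vals = [[None if np.isnan(v) else float(v) for v in row] for row in self.r]
        return {"labels": list(self.labels), "values": vals}


def correlation_matrix(items: Sequence[ObservationVector]) -> CorrelationMatrix:
    """Pairwise u-score correlation matrix over a list of items.

    Symmetric with unit diagonal; pairwise-complete deletion per item
    pair.  When no item has missing entries the u-score matrix is
    computed once and correlated in a single vectorised pass.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    n = len(items[0])
    for it in items:
        if len(it) != n:
            raise ValueError("all items must be measured on the same patients")
    labels = [it.item_id or f"item_{k}" for k, it in enumerate(items)]
    m = len(items)

    if all(bool(it.observed.all()) for it in items):
        U = np.empty((m, n))
        for k, it in enumerate(items):
            U[k] = _u_scores_bounds(it.lo, it.hi)
        Uc = U - U.mean(axis=1, keepdims=True)
        ss = np.sqrt(np.einsum("ij,ij->i", Uc, Uc))
        r = np.full((m, m), np.nan)
        ok = ss > 0
        denom = np.outer(ss, ss)
        cov = Uc @ Uc.T
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(np.outer(ok, ok), cov / np.where(denom == 0, np.nan, denom), np.nan)
        r = np.clip(r, -1.0, 1.0)
    else:
        r = np.full((m, m), np.nan)
        for i in range(m):
            for j in range(i + 1, m):
                r[i, j] = r[j, i] = u_correlation(items[i], items[j])
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(labels=labels, r=r)
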