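"""Calibrated match probabilities from raw search scores.

Isotonic regression (pool-adjacent-violators, exact least-squares minimizer
under the nondecreasing constraint) turns scores with binary correctness
labels into a monotone step function; the Venn-Abers construction runs two
isotonic fits with hypothetical test labels to produce a finite-sample valid
probability interval ``[p0, p1]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "IsotonicModel",
    "VennAbersOutput",
    "pava_fit",
    "isotonic_predict",
    "venn_abers",
    "venn_abers_batch",
    "venn_abers_gap",
    "ece",
]


@dataclass(frozen=True)
class IsotonicModel:
    """A fitted nondecreasing step function.

    ``knots`` are the distinct training scores (ascending); ``values`` the
    fitted probabilities at each knot; ``weights`` how many training points
    were pooled into each knot (the tie-pooling record).
    """

    knots: np.ndarray
    values: np.ndarray
    weights: np.ndarray
    label_sum: float  # of the training labels; preserved by pooling

    def __post_init__(self) -> None:
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly ascending")
        if np.any(np.diff(self.values) < -1e-12):
            raise ValueError("fitted values must be nondecreasing")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("fitted values must lie in [0, 1]")


@dataclass(frozen=True)
class VennAbersOutput:
    """Probability interval for one test score."""

    p0: float
    p1: float
    point: float

    def __post_init__(self) -> None:
        if self.p0 > self.p1 + 1e-12:
            raise ValueError("p0 must not exceed p1")

    @property
    def gap(self) -> float:
        return self.p1 - self.p0


def _pava(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators in one linear pass.

    Maintains a stack of blocks (mean, weight, length); a new block is merged
    backwards while it violates the ordering.
    """
    means: list = []
    wsum: list = []
    count: list = []
    for v, w in zip(values, weights):
        cur_m, cur_w, cur_c = float(v), float(w), 1
        while means and means[-1] > cur_m + 1e-15:
            pm, pw, pc = means.pop(), wsum.pop(), count.pop()
            cur_m = (pm * pw + cur_m * cur_w) / (pw + cur_w)
            cur_w += pw
            cur_c += pc
        means.append(cur_m)
        wsum.append(cur_w)
        count.append(cur_c)
    out = np.empty(len(values))
    pos = 0
    for m, c in zip(means, count):
        out[pos : pos + c] = m
        pos += c
    return out


def pava_fit(scores: Sequence[float], labels: Sequence[float]) -> IsotonicModel:
    """Least-squares isotonic fit of 0/1 labels against scores.

    Tied scores are pre-pooled to their label mean (making the minimizer and
    the resulting prediction function unique), then a single weighted PAVA
    pass produces the exact constrained minimizer.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.ndim != 1 or s.shape != y.shape:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if s.size == 0:
        raise ValueError("need at least one training pair")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0/1")
    order = np.argsort(s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    knots, start = np.unique(s_sorted, return_index=True)
    # mean label and weight per distinct score
    sums = np.add.reduceat(y_sorted, start)
    weights = np.diff(np.append(start, s_sorted.size)).astype(float)
    pooled = sums / weights
    fitted = _pava(pooled, weights)
    return IsotonicModel(
        knots=knots,
        values=np.clip(fitted, 0.0, 1.0),
        weights=weights,
        label_sum=float(y.sum()),
    )


def isotonic_predict(model: IsotonicModel, score) -> np.ndarray | float:
    """Step-function evaluation of a fitted model.

    A score between two knots takes the left knot's fitted value; scores
    outside the knot range clamp to the terminal fitted values.
    """
    arr = np.asarray(score, dtype=float)
    idx = np.searchsorted(model.knots, arr, side="right") - 1
    idx = np.clip(idx, 0, model.knots.size - 1)
    out = model.values[idx]
    if np.isscalar(score) or arr.ndim == 0:
        return float(out)
    return out


def venn_abers(
    cal_scores: Sequence[float],
    cal_labels: Sequence[float],
    test_score: float,
    point: str = "midpoint",
) -> VennAbersOutput:
    """Venn-Abers probability interval for one test score.

    For each hypothetical label ``b`` in {0, 1} the calibration set is
    augmented with ``(test_score, b)``, refit isotonically, and the fitted
    value at the test score is read off; ``p0 <= p1`` always holds.  The
    reported point estimate is the midpoint by default, or the log-loss
    blend ``p1 / (1 - p0 + p1)`` with ``point='logloss'``.
    """
    s = np.asarray(cal_scores, dtype=float)
    y = np.asarray(cal_labels, dtype=float)
    ps = []
    for b in (0.0, 1.0):
        model = pava_fit(np.append(s, test_score), np.append(y, b))
        ps.append(float(isotonic_predict(model, test_score)))
    p0, p1 = min(ps), max(ps)
    if point == "midpoint":
        pt = 0.5 * (p0 + p1)
    elif point == "logloss":
        pt = p1 / (1.0 - p0 + p1)
    else:
        raise ValueError(f"unknown point rule {point!r}")
    return VennAbersOutput(p0=p0, p1=p1, point=pt)


def venn_abers_batch(
    cal_scores: Sequence[float],
    cal_labels: Sequence[float],
    test_scores: Sequence[float],
    point: str = "midpoint",
) -> list:
    """Inductive Venn-Abers output for each test score, one at a time."""
    return [venn_abers(cal_scores, cal_labels, t, point=point) for t in test_scores]


def venn_abers_gap(outputs: Sequence[VennAbersOutput]) -> dict:
    """Summary of the interval widths ``p1 - p0``."""
    if len(outputs) == 0:
        raise ValueError("no outputs supplied")
    gaps = np.array([o.gap for o in outputs])
    return {
        "mean": float(gaps.mean()),
        "median": float(np.median(gaps)),
        "max": float(gaps.max()),
        "n": int(gaps.size),
    }


def ece(
    probabilities: Sequence[float],
    labels: Sequence[float],
    n_bins: int = 10,
) -> float:
    """Expected calibration error over equal-width bins of [0, 1].

    Sum over bins of (bin weight) * |mean label - mean probability|; empty
    bins contribute nothing.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("probabilities and labels must be equal-length 1-D")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    idx = np.clip((p * n_bins).astype(int), 0, n_bins - 1)
    total = 0.0
    for k in range(n_bins):
        mask = idx == k
        n_k = int(mask.sum())
        if n_k == 0:
            continue
        total += (n_k / p.size) * abs(y[mask].mean() - p[mask].mean())
    return float(total)
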