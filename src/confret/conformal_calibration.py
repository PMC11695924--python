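"""Threshold selection with distribution-free risk guarantees.

Two calibration routes share one representation of per-query loss curves
over a finite threshold grid (always stored in the canonical permissiveness
orientation, ascending = more permissive):

* :func:`crc_threshold` — conformal risk control for monotone losses.  For a
  loss that shrinks as sets grow (FNR) it returns the *least* permissive
  grid value whose empirical risk is at most ``alpha - (B - alpha)/n``; for
  a loss that grows with the set (hierarchical max-mismatch) the search is
  mirrored and the *most* permissive qualifying value is returned.  With
  B = 1 the adjustment reduces to the usual ``(1 - alpha)/n`` fudge term.

* :func:`ltt_threshold` — Learn-then-Test for non-monotone losses (FDR).
  Thresholds are traversed from restrictive to permissive (fixed-sequence
  testing, which preserves the delta guarantee without a Bonferroni split)
  and each is validated with a Hoeffding upper confidence bound
  ``R+(t) = R_hat(t) + B * sqrt(log(1/delta) / (2n))``.

The expected-loss guarantee ``E[loss(X_test)] <= alpha`` rests on the
calibration queries and the test query being exchangeable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_types import ScoreKind, ScoreMatrix, AnnotationTable
from .losses import CostVector, MatchSpec, cost_matrix, match_matrix

__all__ = [
    "LossCurveSet",
    "CalibrationResult",
    "default_grid",
    "build_loss_curves",
    "crc_threshold",
    "ltt_threshold",
    "hierarchical_risk_certificate",
]

#: per-row monotonicity violations below this are treated as float noise
MONOTONE_TOL = 1e-12


@dataclass
class LossCurveSet:
    """Per-query loss evaluated on a grid of canonical thresholds.

    ``grid`` is ascending in permissiveness; ``losses[i, k]`` is the loss of
    calibration query ``i`` at threshold ``grid[k]``.  The first grid point
    is guaranteed to yield empty retrieval sets so the fully-restrictive
    fallback is always on the grid.
    """

    grid: np.ndarray
    losses: np.ndarray
    bound: float
    query_ids: list
    loss_name: str
    score_kind: ScoreKind
    no_match_queries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.losses = np.asarray(self.losses, dtype=float)
        if self.losses.shape != (len(self.query_ids), self.grid.size):
            raise ValueError("loss array shape does not match ids/grid")
        if np.any(self.losses < -MONOTONE_TOL) or np.any(
            self.losses > self.bound + 1e-9
        ):
            raise ValueError("loss values outside [0, B]")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly ascending")

    @property
    def n(self) -> int:
        return len(self.query_ids)

    @property
    def rows_nonincreasing(self) -> np.ndarray:
        return np.all(np.diff(self.losses, axis=1) <= MONOTONE_TOL, axis=1)

    @property
    def rows_nondecreasing(self) -> np.ndarray:
        return np.all(np.diff(self.losses, axis=1) >= -MONOTONE_TOL, axis=1)

    @property
    def monotone(self) -> bool:
        """True when every per-query curve is monotone in permissiveness."""
        return bool(self.rows_nonincreasing.all() or self.rows_nondecreasing.all())

    def empirical_risk(self) -> np.ndarray:
        return self.losses.mean(axis=0)

    def user_grid(self) -> np.ndarray:
        """Grid mapped back to the user's score orientation."""
        if self.score_kind is ScoreKind.SIMILARITY:
            return -self.grid
        return self.grid


@dataclass
class CalibrationResult:
    """A calibrated threshold with its certificate and diagnostics."""

    lambda_hat: float          # in the user's score orientation
    canonical_threshold: float
    alpha: float
    method: str                # "crc" | "ltt"
    n: int
    bound: float
    empirical_risk: float
    adjusted_risk: float       # CRC: (n R + B)/(n+1); LTT: Hoeffding R+
    score_kind: ScoreKind
    loss_name: str
    delta: Optional[float] = None
    criterion_met: bool = True
    mirrored: bool = False
    diagnostics: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "lambda_hat": self.lambda_hat,
            "canonical_threshold": self.canonical_threshold,
            "alpha": self.alpha,
            "method": self.method,
            "n": self.n,
            "bound": self.bound,
            "empirical_risk": self.empirical_risk,
            "adjusted_risk": self.adjusted_risk,
            "score_kind": self.score_kind.value,
            "loss_name": self.loss_name,
            "delta": self.delta,
            "criterion_met": self.criterion_met,
            "mirrored": self.mirrored,
        }
        if self.diagnostics is not None:
            out["diagnostics"] = self.diagnostics.to_dict(orient="list")
        return out


def default_grid(matrix: ScoreMatrix, n_points: int = 200) -> np.ndarray:
    """Quantile grid of the calibration scores plus both extremes.

    Returned in canonical orientation, ascending.  A sentinel below the
    minimum canonical score is prepended so the most restrictive grid value
    always produces empty sets.
    """
    canon = np.sort(np.unique(matrix.canonical_scores().ravel()))
    if canon.size > n_points:
        qs = np.linspace(0.0, 1.0, n_points)
        pts = np.quantile(canon, qs)
    else:
        pts = canon
    span = max(canon[-1] - canon[0], 1.0)
    sentinel = canon[0] - 1e-6 * span
    grid = np.unique(np.concatenate([[sentinel], pts, [canon[-1]]]))
    return grid


def _coerce_grid(matrix: ScoreMatrix, grid) -> np.ndarray:
    """Accept a policy string, an int, or an explicit user-orientation list."""
    if grid is None:
        return default_grid(matrix)
    if isinstance(grid, int):
        return default_grid(matrix, n_points=grid)
    if isinstance(grid, str):
        if grid == "all":
            canon = np.unique(matrix.canonical_scores().ravel())
            span = max(canon[-1] - canon[0], 1.0)
            return np.unique(np.concatenate([[canon[0] - 1e-6 * span], canon]))
        raise ValueError(f"unknown grid policy {grid!r}")
    user = np.asarray(list(grid), dtype=float)
    if user.size == 0:
        raise ValueError("empty threshold grid")
    canon = np.array([matrix.to_canonical_threshold(v) for v in user])
    return np.unique(canon)


def build_loss_curves(
    matrix: ScoreMatrix,
    annotations: AnnotationTable,
    spec: MatchSpec,
    grid=None,
    loss: str = "fnr",
    reduce: str = "max",
) -> LossCurveSet:
    """Evaluate ``loss`` for every (calibration query, grid threshold) pair.

    ``loss`` is one of ``fdr``, ``fnr`` (binary match predicate from
    ``spec``) or ``hierarchical`` (graded cost from ``spec.cost_vector``).
    Retrieval membership uses the inclusive boundary rule.
    """
    if loss not in ("fdr", "fnr", "hierarchical"):
        raise ValueError(f"unknown loss {loss!r}")
    grid_c = _coerce_grid(matrix, grid)
    canon = matrix.canonical_scores()
    n_q, n_l = canon.shape
    curves = np.zeros((n_q, grid_c.size), dtype=float)
    no_match: list = []

    if loss == "hierarchical":
        if spec.cost_vector is None:
            raise ValueError("hierarchical loss needs a cost vector")
        costs = cost_matrix(
            annotations,
            matrix.query_ids,
            matrix.lookup_ids,
            spec.cost_vector,
            spec.wildcard_matches,
        )
        bound = spec.cost_vector.bound
        for i in range(n_q):
            order = np.argsort(canon[i], kind="stable")
            sorted_s = canon[i][order]
            prefix_max = np.maximum.accumulate(costs[i][order])
            k = np.searchsorted(sorted_s, grid_c, side="right")
            row = np.zeros(grid_c.size)
            nz = k > 0
            row[nz] = prefix_max[k[nz] - 1]
            curves[i] = row
            if reduce == "mean":
                prefix_mean = np.cumsum(costs[i][order]) / np.arange(1, n_l + 1)
                row = np.zeros(grid_c.size)
                row[nz] = prefix_mean[k[nz] - 1]
                curves[i] = row
    else:
        matches = match_matrix(annotations, matrix.query_ids, matrix.lookup_ids, spec)
        bound = 1.0
        for i in range(n_q):
            order = np.argsort(canon[i], kind="stable")
            sorted_s = canon[i][order]
            cum_match = np.cumsum(matches[i][order])
            k = np.searchsorted(sorted_s, grid_c, side="right")
            hits_in = np.where(k > 0, cum_match[np.maximum(k - 1, 0)], 0)
            if loss == "fdr":
                with np.errstate(invalid="ignore", divide="ignore"):
                    curves[i] = np.where(k > 0, (k - hits_in) / np.maximum(k, 1), 0.0)
            else:
                total = int(matches[i].sum())
                if total == 0:
                    no_match.append(matrix.query_ids[i])
                    curves[i] = 0.0
                else:
                    curves[i] = (total - hits_in) / total
    return LossCurveSet(
        grid=grid_c,
        losses=curves,
        bound=bound,
        query_ids=list(matrix.query_ids),
        loss_name=loss,
        score_kind=matrix.score_kind,
        no_match_queries=no_match,
    )


def _diagnostics(curves: LossCurveSet, risk, extra: dict) -> pd.DataFrame:
    data = {
        "lambda": curves.user_grid(),
        "canonical": curves.grid,
        "empirical_risk": risk,
    }
    data.update(extra)
    return pd.DataFrame(data)


def crc_threshold(curves: LossCurveSet, alpha: float) -> CalibrationResult:
    """Conformal-risk-control threshold for a monotone loss.

    Selects on the grid the boundary value whose empirical risk satisfies
    ``R_hat <= alpha - (B - alpha)/n``; the direction of the search follows
    the loss's monotonicity.  If no grid value qualifies the fully
    restrictive threshold (empty sets) is returned with a warning.
    """
    n, B = curves.n, curves.bound
    if n == 0:
        raise ValueError("no calibration queries")
    nonincreasing = bool(curves.rows_nonincreasing.all())
    nondecreasing = bool(curves.rows_nondecreasing.all())
    if not (nonincreasing or nondecreasing):
        raise ValueError(
            "loss curves are not monotone in the threshold; "
            "use ltt_threshold for non-monotone risks"
        )
    if not (0 < alpha < B):
        raise ValueError(f"alpha must lie in (0, B={B})")
    target = alpha - (B - alpha) / n
    if alpha < B / (n + 1):
        warnings.warn(
            f"alpha={alpha} <= B/(n+1)={B / (n + 1):.4g}: the CRC criterion "
            "is unattainable; returning the fully restrictive threshold"
        )
    risk = curves.empirical_risk()
    qualifies = risk <= target + 1e-12
    mirrored = nondecreasing and not nonincreasing
    if not qualifies.any():
        idx = 0
        met = False
        warnings.warn("no grid threshold meets the CRC criterion; falling back "
                      "to the most restrictive (empty-set) threshold")
    else:
        met = True
        if mirrored:
            # loss grows with the set: most permissive qualifying value
            idx = int(np.max(np.flatnonzero(qualifies)))
        else:
            # loss shrinks as sets grow: least permissive qualifying value
            idx = int(np.min(np.flatnonzero(qualifies)))
    t_hat = float(curves.grid[idx])
    diag = _diagnostics(curves, risk, {"qualifies": qualifies})
    return CalibrationResult(
        lambda_hat=float(-t_hat if curves.score_kind is ScoreKind.SIMILARITY else t_hat),
        canonical_threshold=t_hat,
        alpha=alpha,
        method="crc",
        n=n,
        bound=B,
        empirical_risk=float(risk[idx]),
        adjusted_risk=float((n * risk[idx] + B) / (n + 1)),
        score_kind=curves.score_kind,
        loss_name=curves.loss_name,
        criterion_met=met,
        mirrored=mirrored,
        diagnostics=diag,
    )


def ltt_threshold(
    curves: LossCurveSet,
    alpha: float,
    delta: float = 0.1,
    bound: str = "hoeffding",
) -> CalibrationResult:
    """Learn-then-Test threshold for a (possibly) non-monotone loss.

    Fixed-sequence testing: grid values are traversed from most restrictive
    to most permissive and the last value before the first failure of
    ``R+(t) <= alpha`` is returned.  ``R+`` is the Hoeffding upper bound at
    miscoverage ``delta``.
    """
    if bound != "hoeffding":
        raise ValueError(f"unsupported concentration bound {bound!r}")
    if not (0 < delta < 1):
        raise ValueError("delta must lie in (0, 1)")
    n, B = curves.n, curves.bound
    if n == 0:
        raise ValueError("no calibration queries")
    risk = curves.empirical_risk()
    margin = B * math.sqrt(math.log(1.0 / delta) / (2.0 * n))
    r_plus = risk + margin
    passes = r_plus <= alpha + 1e-12
    if not passes[0]:
        idx = 0
        met = False
        warnings.warn("the most restrictive threshold already fails the LTT "
                      "bound; falling back to it without a certificate")
    else:
        met = True
        fail = np.flatnonzero(~passes)
        idx = int(fail[0] - 1) if fail.size else int(passes.size - 1)
    t_hat = float(curves.grid[idx])
    diag = _diagnostics(curves, risk, {"risk_upper": r_plus, "passes": passes})
    return CalibrationResult(
        lambda_hat=float(-t_hat if curves.score_kind is ScoreKind.SIMILARITY else t_hat),
        canonical_threshold=t_hat,
        alpha=alpha,
        method="ltt",
        n=n,
        bound=B,
        empirical_risk=float(risk[idx]),
        adjusted_risk=float(r_plus[idx]),
        score_kind=curves.score_kind,
        loss_name=curves.loss_name,
        delta=delta,
        criterion_met=met,
        diagnostics=diag,
    )


def hierarchical_risk_certificate(
    losses_at_lambda: Sequence[float],
    cost_vector: CostVector,
    alpha: float,
) -> pd.DataFrame:
    """Per-level mismatch-probability bounds implied by E[loss] <= alpha.

    Controlling the expected cost simultaneously bounds every mismatch
    level: ``P(loss == c_i) <= alpha / c_i`` (infinite for ``c_i = 0``).
    Returns one row per cost level with the implied bound, the empirical
    frequency, and a flag for violations beyond 3 binomial standard errors.
    """
    losses = np.asarray(losses_at_lambda, dtype=float)
    n = losses.size
    if n == 0:
        raise ValueError("no losses supplied")
    rows = []
    for depth, c in enumerate(cost_vector.costs):
        bound = math.inf if c == 0 else alpha / c
        freq = float(np.mean(np.isclose(losses, c, atol=1e-9)))
        if math.isinf(bound):
            violated = False
            slack = math.inf
        else:
            p = min(bound, 1.0)
            se = math.sqrt(p * (1.0 - p) / n)
            slack = bound + 3.0 * se
            violated = freq > slack
        rows.append(
            {
                "depth": depth,
                "cost": c,
                "bound": bound,
                "empirical_frequency": freq,
                "tolerance": slack,
                "violated": violated,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
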