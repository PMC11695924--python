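"""Apply calibrated thresholds and evaluate the resulting selections.

Covers: retrieval-set construction at a threshold, the Kneedle elbow finder
for structural Z-score curves, prefilter FNR/TPR/FDR reporting against a
structural ground truth, the max-separation and empirical p-value baseline
selectors, and the two-sample loss-CDF exchangeability diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_types import InclusionRule, RetrievalSet, ScoreMatrix

__all__ = [
    "PrefilterReport",
    "build_retrieval_sets",
    "kneedle_elbow",
    "prefilter_stats",
    "maxsep_select",
    "pvalue_select",
    "loss_cdf_compare",
]

_COMPARATORS = {
    InclusionRule.GEQ: np.greater_equal,
    InclusionRule.GT: np.greater,
    InclusionRule.LEQ: np.less_equal,
    InclusionRule.LT: np.less,
}


def build_retrieval_sets(
    matrix: ScoreMatrix,
    lambda_hat: float,
    rule: Optional[Union[InclusionRule, str]] = None,
) -> list:
    """One retrieval set per query: lookups whose score passes the threshold.

    ``lambda_hat`` is in the matrix's own score orientation.  The default
    rule is >= for similarity and <= for distance.
    """
    if rule is None:
        rule = matrix.default_rule()
    rule = InclusionRule(rule)
    cmp = _COMPARATORS[rule]
    mask = cmp(matrix.scores, lambda_hat)
    lookup = np.asarray(matrix.lookup_ids, dtype=object)
    return [
        RetrievalSet(
            query_id=qid,
            members=tuple(lookup[mask[i]]),
            threshold=float(lambda_hat),
            rule=rule,
        )
        for i, qid in enumerate(matrix.query_ids)
    ]


def kneedle_elbow(values: Sequence[float], tol: float = 1e-12) -> tuple:
    """Elbow of a descending sorted curve (no-smoothing Kneedle).

    Index and value axes are min-max normalized to [0, 1]; the elbow is the
    point of maximum vertical distance below the chord joining the
    endpoints.  Constant or exactly linear sequences have no elbow and raise
    ``ValueError``.  Returns ``(index, original value at the elbow)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 values to locate an elbow")
    if np.any(np.diff(v) > tol):
        raise ValueError("values must be sorted in descending order")
    span = v[0] - v[-1]
    if span <= tol:
        raise ValueError("no elbow: constant sequence")
    x = np.arange(v.size) / (v.size - 1)
    y = (v - v[-1]) / span
    dist = (1.0 - x) - y  # chord runs from (0, 1) to (1, 0)
    if dist.max() <= tol:
        raise ValueError("no elbow: curve does not bend below its chord")
    idx = int(np.argmax(dist))
    return idx, float(v[idx])


@dataclass
class PrefilterReport:
    """FNR/TPR/FDR of a calibrated prefilter against structural ground truth."""

    per_query: pd.DataFrame
    aggregate: pd.DataFrame  # mean/std/min/median/max per metric
    z_threshold: float
    z_threshold_policy: str
    frac_low_z: float        # N(Z < low_z_cut) / N over the whole table
    low_z_cut: float
    n_queries: int
    n_no_hits: int           # queries with zero ground-truth hits
    unreported_z_value: float = 0.0

    def to_dict(self) -> dict:
        return {
            "z_threshold": self.z_threshold,
            "z_threshold_policy": self.z_threshold_policy,
            "frac_low_z": self.frac_low_z,
            "low_z_cut": self.low_z_cut,
            "n_queries": self.n_queries,
            "n_no_hits": self.n_no_hits,
            "unreported_z_value": self.unreported_z_value,
            "aggregate": self.aggregate.to_dict(orient="index"),
            "per_query": self.per_query.to_dict(orient="list"),
        }


def _z_row(z_table, query_id, lookup_ids, unreported) -> np.ndarray:
    if isinstance(z_table, pd.DataFrame):
        row = z_table.loc[query_id] if query_id in z_table.index else None
        if row is None:
            return np.full(len(lookup_ids), unreported)
        return np.array([float(row.get(l, unreported)) for l in lookup_ids])
    return np.array([float(z_table.get(l, unreported)) for l in lookup_ids])


def prefilter_stats(
    retrieval_sets: Sequence[RetrievalSet],
    z_table: Union[Mapping, pd.DataFrame],
    z_threshold: Union[float, str] = "kneedle",
    unreported_z_value: float = 0.0,
    low_z_cut: float = 2.0,
) -> PrefilterReport:
    """Score a prefilter's retrieval sets against structural Z ground truth.

    ``z_table`` maps lookup id -> Z (shared by every query), or is a
    DataFrame indexed by query id with lookup ids as columns for per-query Z.
    Ground-truth *hits* are lookups with ``Z >= z_threshold``; the threshold
    is either numeric or ``"kneedle"`` (elbow of the descending sorted Z
    values, the Z' convention).  Lookups without a reported Z take
    ``unreported_z_value`` (structural aligners do not output Z < 2).
    """
    if not retrieval_sets:
        raise ValueError("no retrieval sets supplied")
    if isinstance(z_table, pd.DataFrame):
        lookup_ids = [str(c) for c in z_table.columns]
        all_z = z_table.to_numpy(dtype=float).ravel()
    else:
        lookup_ids = list(z_table.keys())
        all_z = np.array([float(z_table[l]) for l in lookup_ids])
    all_z = np.where(np.isnan(all_z), unreported_z_value, all_z)

    policy = "kneedle" if isinstance(z_threshold, str) else "fixed"
    if policy == "kneedle":
        if z_threshold != "kneedle":
            raise ValueError(f"unknown z-threshold policy {z_threshold!r}")
        # the elbow is located on the *reported* Z values: scores below the
        # aligner's floor come back as the unreported placeholder and would
        # otherwise dominate the curve with a flat tail
        reported = all_z[all_z >= low_z_cut]
        if reported.size < 3:
            raise ValueError("too few reported Z values to locate an elbow")
        _, thr = kneedle_elbow(np.sort(reported)[::-1])
    else:
        thr = float(z_threshold)

    n_universe = len(lookup_ids)
    rows = []
    n_no_hits = 0
    for rset in retrieval_sets:
        z = _z_row(z_table, rset.query_id, lookup_ids, unreported_z_value)
        hit_mask = z >= thr
        retrieved = rset.member_set
        retrieved_mask = np.array([l in retrieved for l in lookup_ids])
        n_hits = int(hit_mask.sum())
        n_ret = int(retrieved_mask.sum())
        if n_hits == 0:
            n_no_hits += 1
            fnr = tpr = np.nan
        else:
            fnr = float((hit_mask & ~retrieved_mask).sum() / n_hits)
            tpr = 1.0 - fnr
        fdr = float((retrieved_mask & ~hit_mask).sum() / n_ret) if n_ret else 0.0
        rows.append(
            {
                "query_id": rset.query_id,
                "n_hits": n_hits,
                "n_retrieved": n_ret,
                "fnr": fnr,
                "tpr": tpr,
                "fdr": fdr,
                "retained_fraction": n_ret / n_universe,
            }
        )
    per_query = pd.DataFrame(rows).set_index("query_id")
    metrics = ["fnr", "tpr", "fdr", "retained_fraction"]
    with warnings.catch_warnings():
        # rate columns are all-NaN when every query lacks ground-truth hits
        warnings.simplefilter("ignore", RuntimeWarning)
        aggregate = per_query[metrics].agg(["mean", "std", "min", "median", "max"]).T
    return PrefilterReport(
        per_query=per_query,
        aggregate=aggregate,
        z_threshold=float(thr),
        z_threshold_policy=policy,
        frac_low_z=float(np.mean(all_z < low_z_cut)),
        low_z_cut=low_z_cut,
        n_queries=len(retrieval_sets),
        n_no_hits=n_no_hits,
        unreported_z_value=unreported_z_value,
    )


def maxsep_select(distances: Mapping, window: int = 10) -> set:
    """Greedy max-separation baseline: cut at the largest gap in the sorted
    distances (searched within the first ``window`` candidates) and return
    everything before it.  Always returns at least one class.
    """
    if len(distances) < 2:
        raise ValueError("max-sep needs at least 2 classes")
    items = sorted(distances.items(), key=lambda kv: (kv[1], str(kv[0])))
    d = np.array([v for _, v in items])
    m = min(window, d.size - 1)
    gaps = d[1 : m + 1] - d[:m]
    i_star = int(np.argmax(gaps))  # argmax takes the first (smallest) on ties
    cut = d[i_star]
    return {k for k, v in items if v <= cut}


def pvalue_select(
    distances: Mapping,
    background: Sequence[float],
    p_cut: float = 0.05,
) -> set:
    """Empirical p-value baseline against a background distance sample.

    ``p = (1 + #{background <= d}) / (1 + |background|)`` (smaller distance
    = more extreme; add-one correction avoids p = 0).  May return the empty
    set when nothing stands out.
    """
    if not (0 < p_cut < 1):
        raise ValueError("p_cut must lie in (0, 1)")
    bg = np.sort(np.asarray(background, dtype=float))
    if bg.size == 0:
        raise ValueError("background sample is empty")
    selected = set()
    for cls, d in distances.items():
        p = (1 + int(np.searchsorted(bg, d, side="right"))) / (1 + bg.size)
        if p <= p_cut:
            selected.add(cls)
    return selected


def loss_cdf_compare(
    losses_a: Sequence[float], losses_b: Sequence[float]
) -> tuple:
    """Two-sample empirical CDF comparison (exchangeability diagnostic).

    Evaluates both empirical CDFs on the pooled support and returns the
    maximum absolute gap (the Kolmogorov-Smirnov distance) together with the
    per-point table for plotting.
    """
    a = np.sort(np.asarray(losses_a, dtype=float))
    b = np.sort(np.asarray(losses_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both loss samples must be non-empty")
    support = np.unique(np.concatenate([a, b]))
    cdf_a = np.searchsorted(a, support, side="right") / a.size
    cdf_b = np.searchsorted(b, support, side="right") / b.size
    table = pd.DataFrame({"value": support, "cdf_a": cdf_a, "cdf_b": cdf_b})
    gap = float(np.max(np.abs(cdf_a - cdf_b)))
    return gap, table
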