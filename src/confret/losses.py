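"""Loss functions the calibrator can control.

Set-level losses (FDR, FNR, hierarchical mismatch) are built from pairwise
match predicates: exact / partial Pfam-set matching, or depth-of-first-
mismatch against a four-level hierarchy.

Conventions (all chosen for well-definedness and monotonicity):

* FDR of an empty retrieval set is 0 — no discoveries, no false ones.
* Hierarchical loss of an empty set is 0 — abstention is never penalized.
* FNR of a query with no true matches is 0; the event is counted in a
  module-level counter so such queries can be excluded from calibration.
* An unannotated retrieved item counts as a non-match (dropping it would
  bias FDR downward).
* A wildcard level counts as agreement when comparing hierarchy labels
  (partial, "preliminary" annotations should not be punished); the
  symmetric alternative is available via ``wildcard_matches=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_types import AnnotationTable, HierarchyLabel, RetrievalSet

__all__ = [
    "CostVector",
    "MatchSpec",
    "pair_match_depth",
    "pair_matches",
    "hierarchical_set_loss",
    "fdr_loss",
    "fnr_loss",
    "match_matrix",
    "cost_matrix",
    "no_true_match_count",
    "reset_no_true_match_count",
]

_N_LEVELS = 4

# queries seen by fnr_loss with an empty true-match pool
_no_true_match_count = 0


def no_true_match_count() -> int:
    return _no_true_match_count


def reset_no_true_match_count() -> None:
    global _no_true_match_count
    _no_true_match_count = 0


@dataclass(frozen=True)
class CostVector:
    """Per-depth mismatch costs ``c[0..4]`` (0 = exact match).

    Costs must be nonnegative and nondecreasing in mismatch depth; the loss
    bound ``B`` is the largest cost.
    """

    costs: tuple = (0.0, 1.0, 2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        costs = tuple(float(c) for c in self.costs)
        object.__setattr__(self, "costs", costs)
        if len(costs) != _N_LEVELS + 1:
            raise ValueError("cost vector must have exactly 5 entries")
        if any(c < 0 for c in costs):
            raise ValueError("costs must be nonnegative")
        if any(b < a for a, b in zip(costs, costs[1:])):
            raise ValueError("costs must be nondecreasing in mismatch depth")
        if not all(np.isfinite(costs)):
            raise ValueError("costs must be finite")

    @property
    def bound(self) -> float:
        """Loss bound B = max cost."""
        return max(self.costs)

    @classmethod
    def unit(cls) -> "CostVector":
        return cls((0.0, 1.0, 2.0, 3.0, 4.0))


@dataclass(frozen=True)
class MatchSpec:
    """How a (query, retrieved item) pair is judged.

    ``pfam_exact`` / ``pfam_partial`` compare accession sets (identical vs
    overlapping).  ``hierarchical`` compares label vectors: for the binary
    rate losses a pair matches when its mismatch depth is <= ``max_depth``
    (0 = exact); the cost vector is used by the graded set loss only.
    """

    mode: str = "pfam_exact"
    cost_vector: Optional[CostVector] = None
    max_depth: int = 0
    wildcard_matches: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("pfam_exact", "pfam_partial", "hierarchical"):
            raise ValueError(f"unknown match mode {self.mode!r}")
        if self.mode == "hierarchical" and self.cost_vector is None:
            object.__setattr__(self, "cost_vector", CostVector.unit())
        if not (0 <= self.max_depth <= _N_LEVELS):
            raise ValueError("max_depth must lie in [0, 4]")


def pair_match_depth(
    query_label: HierarchyLabel,
    hit_label: HierarchyLabel,
    wildcard_matches: bool = True,
) -> int:
    """Depth of first mismatch between two labels: 0 = exact, 4 = top-level.

    Returns ``4 - L`` where ``L`` is the number of leading levels that
    agree.  A wildcard level counts as agreeing unless
    ``wildcard_matches=False``.
    """
    if query_label.scheme != hit_label.scheme:
        raise ValueError(
            f"cannot compare labels across schemes "
            f"({query_label.scheme.value} vs {hit_label.scheme.value})"
        )
    agree = 0
    for ql, hl, qw, hw in zip(
        query_label.levels, hit_label.levels, query_label.wildcard, hit_label.wildcard
    ):
        if qw or hw:
            if not wildcard_matches:
                break
            agree += 1
        elif ql == hl:
            agree += 1
        else:
            break
    return _N_LEVELS - agree


def _min_pair_cost(
    query_labels: Sequence[HierarchyLabel],
    item_labels: Sequence[HierarchyLabel],
    cost_vector: CostVector,
    wildcard_matches: bool,
) -> float:
    return min(
        cost_vector.costs[pair_match_depth(q, h, wildcard_matches)]
        for q in query_labels
        for h in item_labels
    )


def hierarchical_set_loss(
    query_labels: Sequence[HierarchyLabel],
    retrieved_labels: Sequence[Sequence[HierarchyLabel]],
    cost_vector: CostVector = CostVector.unit(),
    reduce: str = "max",
    wildcard_matches: bool = True,
) -> float:
    """Graded loss of a retrieval set against a multi-label query truth.

    Each retrieved item contributes the *minimum* cost over all (query
    label, item label) pairs — a query with several valid assignments is
    scored against its most favorable one.  The set loss is the *max* over
    items by default (``reduce='mean'`` behind the flag).  An empty set is
    abstention and costs 0.
    """
    if not query_labels:
        raise ValueError("query_labels must be non-empty")
    if reduce not in ("max", "mean"):
        raise ValueError("reduce must be 'max' or 'mean'")
    if len(retrieved_labels) == 0:
        return 0.0
    per_item = [
        _min_pair_cost(query_labels, item, cost_vector, wildcard_matches)
        for item in retrieved_labels
    ]
    return float(max(per_item) if reduce == "max" else np.mean(per_item))


def pair_matches(query_ann, hit_ann, spec: MatchSpec) -> bool:
    """Binary match predicate for one (query, hit) annotation pair.

    Either side being unannotated (``None``) is a non-match.
    """
    if query_ann is None or hit_ann is None:
        return False
    if spec.mode == "pfam_exact":
        return frozenset(query_ann) == frozenset(hit_ann)
    if spec.mode == "pfam_partial":
        return bool(frozenset(query_ann) & frozenset(hit_ann))
    depth = min(
        pair_match_depth(q, h, spec.wildcard_matches)
        for q in query_ann
        for h in hit_ann
    )
    return depth <= spec.max_depth


def fdr_loss(
    query_id: str,
    retrieval: RetrievalSet,
    annotations: AnnotationTable,
    spec: MatchSpec,
) -> float:
    """Fraction of the retrieved set that fails the match predicate.

    FP / (FP + TP) over the retrieval set; 0 for an empty set.
    """
    if len(retrieval) == 0:
        return 0.0
    query_ann = annotations.get(query_id)
    bad = sum(
        not pair_matches(query_ann, annotations.get(member), spec)
        for member in retrieval.members
    )
    return bad / len(retrieval)


def fnr_loss(
    query_id: str,
    retrieval: RetrievalSet,
    annotations: AnnotationTable,
    spec: MatchSpec,
    lookup_ids: Iterable[str],
) -> float:
    """Fraction of the query's true matches missing from the retrieval set.

    FN / (FN + TP) against the full lookup universe.  A query with no true
    matches scores 0 and bumps :func:`no_true_match_count`.
    """
    global _no_true_match_count
    query_ann = annotations.get(query_id)
    true_matches = {
        lid
        for lid in lookup_ids
        if pair_matches(query_ann, annotations.get(lid), spec)
    }
    if not true_matches:
        _no_true_match_count += 1
        return 0.0
    missed = len(true_matches - retrieval.member_set)
    return missed / len(true_matches)


# ---------------------------------------------------------------------------
# Vectorized pairwise structure, used by the calibration loss curves.


def match_matrix(
    annotations: AnnotationTable,
    query_ids: Sequence[str],
    lookup_ids: Sequence[str],
    spec: MatchSpec,
) -> np.ndarray:
    """Boolean (n_query, n_lookup) matrix of the binary match predicate."""
    n_q, n_l = len(query_ids), len(lookup_ids)
    out = np.zeros((n_q, n_l), dtype=bool)
    if spec.mode == "pfam_exact":
        # identical accession sets <=> identical canonical codes
        codes: dict = {}

        def code(ann):
            if ann is None:
                return -1
            key = frozenset(ann)
            return codes.setdefault(key, len(codes))

        l_codes = np.array([code(annotations.get(l)) for l in lookup_ids])
        for i, qid in enumerate(query_ids):
            c = code(annotations.get(qid))
            if c >= 0:
                out[i] = l_codes == c
        return out
    if spec.mode == "pfam_partial":
        inverted: dict = {}
        for j, lid in enumerate(lookup_ids):
            ann = annotations.get(lid)
            if ann is None:
                continue
            for acc in ann:
                inverted.setdefault(acc, []).append(j)
        for i, qid in enumerate(query_ids):
            ann = annotations.get(qid)
            if ann is None:
                continue
            for acc in ann:
                out[i, inverted.get(acc, [])] = True
        return out
    depth = _depth_matrix(annotations, query_ids, lookup_ids, spec.wildcard_matches)
    return depth <= spec.max_depth


def _label_arrays(labels: Sequence[HierarchyLabel]):
    levels = np.array([lab.levels for lab in labels], dtype=object)
    wild = np.array([lab.wildcard for lab in labels], dtype=bool)
    return levels, wild


def _depth_matrix(
    annotations: AnnotationTable,
    query_ids: Sequence[str],
    lookup_ids: Sequence[str],
    wildcard_matches: bool,
) -> np.ndarray:
    """(n_query, n_lookup) min-over-label-pairs mismatch depth; 5 = unannotated."""
    lookup_anns = [annotations.get(l) for l in lookup_ids]
    flat_labels: list = []
    owners: list = []
    for j, ann in enumerate(lookup_anns):
        if ann is None:
            continue
        for lab in ann:
            flat_labels.append(lab)
            owners.append(j)
    n_q, n_l = len(query_ids), len(lookup_ids)
    out = np.full((n_q, n_l), _N_LEVELS + 1, dtype=int)
    if not flat_labels:
        return out
    l_levels, l_wild = _label_arrays(flat_labels)  # (m, 4)
    owners_arr = np.array(owners)
    for i, qid in enumerate(query_ids):
        q_ann = annotations.get(qid)
        if q_ann is None:
            continue
        best = np.full(len(flat_labels), _N_LEVELS, dtype=int)
        for qlab in q_ann:
            q_levels = np.array(qlab.levels, dtype=object)
            q_wild = np.array(qlab.wildcard, dtype=bool)
            if wildcard_matches:
                agree = (l_levels == q_levels) | l_wild | q_wild
            else:
                agree = (l_levels == q_levels) & ~l_wild & ~q_wild
            # leading run of agreement per row
            lead = np.cumprod(agree, axis=1).sum(axis=1)
            best = np.minimum(best, _N_LEVELS - lead)
        np.minimum.at(out[i], owners_arr, best)
    return out


def cost_matrix(
    annotations: AnnotationTable,
    query_ids: Sequence[str],
    lookup_ids: Sequence[str],
    cost_vector: CostVector,
    wildcard_matches: bool = True,
) -> np.ndarray:
    """(n_query, n_lookup) per-item hierarchical cost (min over label pairs).

    Unannotated items cost the full bound B.
    """
    depth = _depth_matrix(annotations, query_ids, lookup_ids, wildcard_matches)
    table = np.array(list(cost_vector.costs) + [cost_vector.bound])
    return table[depth]
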