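"""Seeded generators for exchangeable score/label instances.

Three presets mirror the statistical structure the calibration experiments
assume, so every code path is testable without any external data:

* :func:`gen_flat_instance` — query x lookup similarity scores drawn from a
  match / non-match mixture (match scores stochastically larger), with
  Pfam-style multi-label annotations and an optional monotone squash that
  piles scores up near the top of the range.
* :func:`gen_hierarchy_instance` — query-to-class-centroid *distances* whose
  mean grows with the tree distance between the query's true leaf and the
  centroid's leaf, plus optional non-member queries far from everything.
* :func:`gen_prefilter_instance` — joint similarity / structural-Z draws
  with a monotone link, noise, and the "Z below 2 is reported as 0"
  convention.

All randomness flows through ``numpy.random.default_rng(seed)``; the same
spec and seed reproduce the instance bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_types import (
    AnnotationTable,
    Scheme,
    ScoreKind,
    ScoreMatrix,
    parse_hierarchy_label,
)

__all__ = [
    "ScoreModel",
    "FlatSpec",
    "HierarchySpec",
    "PrefilterSpec",
    "gen_flat_instance",
    "gen_hierarchy_instance",
    "gen_prefilter_instance",
]


@dataclass(frozen=True)
class ScoreModel:
    """Bounded-range beta mixture for match and non-match scores.

    The match component must stochastically dominate the non-match one.
    ``compression > 1`` applies the monotone squash ``s -> s**(1/c)``,
    pushing mass toward the top of the range (the near-1 pileup regime that
    stresses isotonic calibration).
    """

    match_a: float = 8.0
    match_b: float = 2.0
    nonmatch_a: float = 2.0
    nonmatch_b: float = 6.0
    low: float = 0.0
    high: float = 1.0
    compression: float = 1.0

    def __post_init__(self) -> None:
        if self.high <= self.low:
            raise ValueError("score range is empty")
        if self.compression < 1.0:
            raise ValueError("compression must be >= 1")

    def draw(self, rng: np.random.Generator, match_mask: np.ndarray) -> np.ndarray:
        shape = match_mask.shape
        s = np.where(
            match_mask,
            rng.beta(self.match_a, self.match_b, size=shape),
            rng.beta(self.nonmatch_a, self.nonmatch_b, size=shape),
        )
        if self.compression > 1.0:
            s = s ** (1.0 / self.compression)
        return self.low + (self.high - self.low) * s


@dataclass(frozen=True)
class FlatSpec:
    """Spec for the flat (Pfam-style) instance.

    With ``match_probability`` set, per-pair match labels are i.i.d.
    Bernoulli draws and the annotations encode them for the *partial* match
    predicate.  Otherwise every protein draws accessions from a vocabulary
    (``labels_per_protein[k]`` = probability of k+1 labels) and the truth
    mask is exact set equality.
    """

    seed: int = 0
    n_query: int = 100
    n_lookup: int = 500
    match_probability: Optional[float] = None
    vocab_size: int = 50
    labels_per_protein: tuple = (0.8, 0.2)
    score_model: ScoreModel = field(default_factory=ScoreModel)

    def __post_init__(self) -> None:
        if self.n_query <= 0 or self.n_lookup <= 0:
            raise ValueError("n_query and n_lookup must be positive")
        if self.match_probability is not None and not (
            0.0 <= self.match_probability <= 1.0
        ):
            raise ValueError("match_probability must lie in [0, 1]")
        if abs(sum(self.labels_per_protein) - 1.0) > 1e-9:
            raise ValueError("labels_per_protein must sum to 1")


def _draw_pfam_sets(rng, n: int, vocab_size: int, size_probs) -> list:
    vocab = [f"PF{v:05d}" for v in range(vocab_size)]
    counts = rng.choice(len(size_probs), size=n, p=list(size_probs)) + 1
    return [
        frozenset(rng.choice(vocab, size=c, replace=False)) for c in counts
    ]


def gen_flat_instance(spec: FlatSpec):
    """Return ``(ScoreMatrix, AnnotationTable, true-match mask)``."""
    rng = np.random.default_rng(spec.seed)
    n_q, n_l = spec.n_query, spec.n_lookup
    query_ids = [f"Q{i:05d}" for i in range(n_q)]
    lookup_ids = [f"L{j:05d}" for j in range(n_l)]

    if spec.match_probability is not None:
        mask = rng.random((n_q, n_l)) < spec.match_probability
        # encode the mask so that the *partial* predicate reproduces it:
        # each query owns one accession; a lookup carries the accessions of
        # the queries it matches (or a private filler so sets are non-empty).
        q_acc = [f"PF{10000 + i:05d}" for i in range(n_q)]
        entries: dict = {qid: frozenset([acc]) for qid, acc in zip(query_ids, q_acc)}
        for j, lid in enumerate(lookup_ids):
            accs = {q_acc[i] for i in np.flatnonzero(mask[:, j])}
            entries[lid] = frozenset(accs) if accs else frozenset([f"PF{900000 + j}"])
    else:
        q_sets = _draw_pfam_sets(rng, n_q, spec.vocab_size, spec.labels_per_protein)
        l_sets = _draw_pfam_sets(rng, n_l, spec.vocab_size, spec.labels_per_protein)
        codes: dict = {}
        q_codes = np.array([codes.setdefault(s, len(codes)) for s in q_sets])
        l_codes = np.array([codes.setdefault(s, len(codes)) for s in l_sets])
        mask = q_codes[:, None] == l_codes[None, :]
        entries = dict(zip(query_ids, q_sets))
        entries.update(zip(lookup_ids, l_sets))

    scores = spec.score_model.draw(rng, mask)
    matrix = ScoreMatrix(query_ids, lookup_ids, scores, ScoreKind.SIMILARITY)
    return matrix, AnnotationTable(entries=entries), mask


@dataclass(frozen=True)
class HierarchySpec:
    """Spec for the hierarchy (EC/SCOPe-style distogram) instance.

    Classes are the leaves of a 4-level tree with the given branching
    factors.  A member query's distance to a centroid is
    ``base_distance + level_increment * mismatch_depth + noise``; non-member
    queries sit ``nonmember_offset`` beyond the deepest mismatch.
    """

    seed: int = 0
    n_query: int = 200
    branching: tuple = (4, 3, 3, 3)
    base_distance: float = 0.3
    level_increment: float = 0.35
    noise_scale: float = 0.05
    nonmember_fraction: float = 0.0
    nonmember_offset: float = 2.0
    scheme: Scheme = Scheme.EC

    def __post_init__(self) -> None:
        if len(self.branching) != 4 or any(b < 1 for b in self.branching):
            raise ValueError("branching needs 4 positive factors")
        if self.n_query <= 0:
            raise ValueError("n_query must be positive")
        if not (0.0 <= self.nonmember_fraction <= 1.0):
            raise ValueError("nonmember_fraction must lie in [0, 1]")


def _leaf_labels(spec: HierarchySpec) -> list:
    ranges = [range(1, b + 1) for b in spec.branching]
    return [
        parse_hierarchy_label(".".join(str(p) for p in combo), spec.scheme)
        for combo in itertools.product(*ranges)
    ]


def gen_hierarchy_instance(spec: HierarchySpec):
    """Return ``(distance ScoreMatrix, AnnotationTable, class catalog)``.

    The catalog maps each centroid (lookup) id to its leaf label; member
    queries carry their true leaf label, non-member queries are listed as
    explicitly unannotated.
    """
    rng = np.random.default_rng(spec.seed)
    leaves = _leaf_labels(spec)
    n_c = len(leaves)
    lookup_ids = [f"EC:{lab}" for lab in leaves]
    query_ids = [f"Q{i:05d}" for i in range(spec.n_query)]

    # pairwise mismatch depth between leaves, via their level index vectors
    coords = np.array([[int(l) for l in lab.levels] for lab in leaves])
    agree = coords[:, None, :] == coords[None, :, :]
    leaf_depth = 4 - np.cumprod(agree, axis=2).sum(axis=2)  # (n_c, n_c)

    true_leaf = rng.integers(0, n_c, size=spec.n_query)
    member = rng.random(spec.n_query) >= spec.nonmember_fraction
    noise = rng.normal(0.0, spec.noise_scale, size=(spec.n_query, n_c))
    depth = leaf_depth[true_leaf]  # (n_query, n_c)
    dist = spec.base_distance + spec.level_increment * depth + noise
    far = (
        spec.base_distance
        + spec.level_increment * 4
        + spec.nonmember_offset
        + noise
    )
    dist = np.where(member[:, None], dist, far)
    dist = np.maximum(dist, 1e-3)

    entries: dict = {lid: (lab,) for lid, lab in zip(lookup_ids, leaves)}
    unannotated = set()
    for i, qid in enumerate(query_ids):
        if member[i]:
            entries[qid] = (leaves[true_leaf[i]],)
        else:
            unannotated.add(qid)
    matrix = ScoreMatrix(query_ids, lookup_ids, dist, ScoreKind.DISTANCE)
    catalog = dict(zip(lookup_ids, leaves))
    return matrix, AnnotationTable(entries=entries, unannotated=unannotated), catalog


@dataclass(frozen=True)
class PrefilterSpec:
    """Spec for the joint similarity / structural-Z instance.

    Homologous pairs get ``Z = z_scale * s**z_power + noise`` (monotone link
    in the similarity ``s``); non-homologous pairs get Z = 0; any Z below
    ``z_report_floor`` is reported as 0, matching aligner output behavior.
    """

    seed: int = 0
    n_query: int = 50
    n_lookup: int = 500
    homolog_probability: float = 0.05
    score_model: ScoreModel = field(default_factory=ScoreModel)
    z_scale: float = 12.0
    z_power: float = 2.0
    z_noise: float = 0.5
    z_report_floor: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.homolog_probability <= 1.0):
            raise ValueError("homolog_probability must lie in [0, 1]")
        if self.z_scale <= 0:
            raise ValueError("z_scale must be positive")


def gen_prefilter_instance(spec: PrefilterSpec):
    """Return ``(ScoreMatrix, Z DataFrame, homolog mask)``.

    The Z table is indexed by query id with lookup ids as columns, aligned
    with the score matrix.
    """
    rng = np.random.default_rng(spec.seed)
    n_q, n_l = spec.n_query, spec.n_lookup
    mask = rng.random((n_q, n_l)) < spec.homolog_probability
    scores = spec.score_model.draw(rng, mask)
    z_raw = spec.z_scale * scores**spec.z_power + rng.normal(
        0.0, spec.z_noise, size=(n_q, n_l)
    )
    z_raw = np.clip(z_raw, 0.0, None)
    z = np.where(mask, z_raw, 0.0)
    z = np.where(z < spec.z_report_floor, 0.0, z)
    query_ids = [f"Q{i:05d}" for i in range(n_q)]
    lookup_ids = [f"L{j:05d}" for j in range(n_l)]
    matrix = ScoreMatrix(query_ids, lookup_ids, scores, ScoreKind.SIMILARITY)
    z_table = pd.DataFrame(z, index=query_ids, columns=lookup_ids)
    return matrix, z_table, mask


def spec_manifest(spec) -> dict:
    """Reconstructible record of a generator spec (written by the CLI)."""
    d = asdict(spec)
    d["generator"] = type(spec).__name__
    d["rng"] = "numpy.random.default_rng(PCG64)"
    return d
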