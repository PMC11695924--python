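"""Domain types, parsing, and validation shared by every other module.

The toolkit is score-model agnostic: all it sees is a query x lookup matrix
of real-valued search scores with a declared orientation (similarity: larger
means closer; distance: smaller means closer), plus annotation tables mapping
identifiers to Pfam accession sets or four-level hierarchy labels.

Internally every calibration routine works in a single *canonical*
orientation in which retrieval sets are nested nondecreasing as the
threshold grows ("permissiveness").  Similarity scores map into canonical
space by negation, distances map directly.  This keeps sign conventions out
of the calibration code entirely.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np


class ScoreKind(str, enum.Enum):
    """Orientation of a score matrix."""

    SIMILARITY = "similarity"  # larger score = closer
    DISTANCE = "distance"      # smaller score = closer


class Scheme(str, enum.Enum):
    """Annotation scheme of a four-level hierarchy label."""

    EC = "EC"
    SCOPE = "SCOPe"
    GENERIC = "generic"


_N_LEVELS = 4
WILDCARD = "*"


class ParseError(ValueError):
    """Raised when a label or file fails to parse; message names the token."""


@dataclass(frozen=True)
class HierarchyLabel:
    """A four-level classification label (EC or SCOPe style).

    ``levels`` always has exactly four entries; a level that was printed as
    ``*`` (or omitted) is a wildcard.  Wildcards may only appear as a suffix:
    once a level is unspecified, everything below it is too.
    """

    scheme: Scheme
    levels: tuple[str, str, str, str]
    wildcard: tuple[bool, bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.levels) != _N_LEVELS or len(self.wildcard) != _N_LEVELS:
            raise ParseError("hierarchy labels have exactly four levels")
        seen_wild = False
        for lev, wild in zip(self.levels, self.wildcard):
            if seen_wild and not wild:
                raise ParseError(
                    f"concrete level {lev!r} follows a wildcard in {self.levels}"
                )
            if wild:
                seen_wild = True
            elif not lev:
                raise ParseError("empty level string in hierarchy label")

    @property
    def depth(self) -> int:
        """Number of concrete (non-wildcard) levels."""
        return sum(not w for w in self.wildcard)

    def __str__(self) -> str:
        return ".".join(
            WILDCARD if w else lev for lev, w in zip(self.levels, self.wildcard)
        )


def parse_hierarchy_label(
    text: str, scheme: Union[Scheme, str] = Scheme.EC
) -> HierarchyLabel:
    """Parse a dot-separated label such as ``2.1.1.13`` or ``2.3.1.*``.

    Missing trailing components become wildcards, so ``2.3`` parses the same
    as ``2.3.*.*``.  A wildcard followed by a concrete level, more than four
    components, or an empty component is a :class:`ParseError`.
    """
    scheme = Scheme(scheme)
    parts = [p.strip() for p in str(text).strip().split(".")]
    if len(parts) > _N_LEVELS:
        raise ParseError(f"label {text!r} has more than {_N_LEVELS} components")
    for p in parts:
        if p == "":
            raise ParseError(f"label {text!r} contains an empty component")
    while len(parts) < _N_LEVELS:
        parts.append(WILDCARD)
    wildcard = tuple(p == WILDCARD for p in parts)
    return HierarchyLabel(scheme=scheme, levels=tuple(parts), wildcard=wildcard)


def format_hierarchy_label(label: HierarchyLabel) -> str:
    """Canonical string form; ``parse -> format -> parse`` is the identity."""
    return str(label)


#: Annotation payload: a Pfam accession set or a non-empty tuple of labels.
Annotation = Union[frozenset, tuple]


@dataclass
class AnnotationTable:
    """Mapping from identifier to its annotation payload.

    A payload is either a ``frozenset`` of Pfam accessions or a non-empty
    tuple of :class:`HierarchyLabel` (multiple valid assignments allowed).
    Identifiers known to carry no annotation are listed in ``unannotated``
    so downstream code can distinguish "no label" from "forgot to load".
    """

    entries: dict = field(default_factory=dict)
    unannotated: set = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, payload in self.entries.items():
            if isinstance(payload, (set, frozenset)):
                self.entries[key] = frozenset(payload)
            elif isinstance(payload, (list, tuple)):
                if len(payload) == 0:
                    raise ValueError(f"empty label list for id {key!r}")
                self.entries[key] = tuple(payload)
            else:
                raise TypeError(
                    f"annotation for {key!r} must be a Pfam set or label list"
                )

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def get(self, key: str):
        """Payload for ``key``, or ``None`` if it is (explicitly) unannotated."""
        if key in self.entries:
            return self.entries[key]
        if key in self.unannotated:
            return None
        raise KeyError(f"id {key!r} has no annotation entry")

    def require_all(self, ids: Iterable[str]) -> None:
        missing = [i for i in ids if i not in self.entries and i not in self.unannotated]
        if missing:
            raise KeyError(f"ids without annotation entries: {missing[:5]}...")


_PFAM_PREFIX = "PF"


def load_annotations(path, scheme: str = "pfam") -> AnnotationTable:
    """Read a TSV ``id<TAB>annotation[;annotation...]`` file.

    ``scheme='pfam'`` stores accession sets; any :class:`Scheme` value parses
    dot-notation hierarchy labels.  A row with an empty annotation field
    marks the id as explicitly unannotated.
    """
    entries: dict = {}
    unannotated: set = set()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 1:
                continue
            ident = fields[0].strip()
            payload = fields[1].strip() if len(fields) > 1 else ""
            if not payload:
                unannotated.add(ident)
                continue
            tokens = [t.strip() for t in payload.split(";") if t.strip()]
            if scheme == "pfam":
                entries[ident] = frozenset(tokens)
            else:
                try:
                    entries[ident] = tuple(
                        parse_hierarchy_label(t, scheme) for t in tokens
                    )
                except ParseError as err:
                    raise ParseError(f"{path}:{lineno}: {err}") from err
    return AnnotationTable(entries=entries, unannotated=unannotated)


class InclusionRule(str, enum.Enum):
    GEQ = "geq"
    GT = "gt"
    LEQ = "leq"
    LT = "lt"


@dataclass(frozen=True)
class RetrievalSet:
    """The lookup ids retrieved for one query at a given threshold."""

    query_id: str
    members: tuple
    threshold: float
    rule: InclusionRule

    def __len__(self) -> int:
        return len(self.members)

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)


@dataclass
class ScoreMatrix:
    """Dense query x lookup score matrix with a declared orientation.

    Row ``i`` holds the scores of query ``query_ids[i]`` against every
    lookup id, in column order.  Identifiers are opaque strings.
    """

    query_ids: list
    lookup_ids: list
    scores: np.ndarray
    score_kind: ScoreKind

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.score_kind = ScoreKind(self.score_kind)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D array")
        if self.scores.shape != (len(self.query_ids), len(self.lookup_ids)):
            raise ValueError(
                f"score shape {self.scores.shape} does not match id lists "
                f"({len(self.query_ids)} x {len(self.lookup_ids)})"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")
        if len(set(self.query_ids)) != len(self.query_ids):
            raise ValueError("duplicate query ids")
        if len(set(self.lookup_ids)) != len(self.lookup_ids):
            raise ValueError("duplicate lookup ids")

    @property
    def n_query(self) -> int:
        return len(self.query_ids)

    @property
    def n_lookup(self) -> int:
        return len(self.lookup_ids)

    # -- canonical ("permissiveness") orientation -------------------------
    #
    # canonical score c = -s for similarity, c = s for distance.  A lookup
    # item is retrieved iff c <= t (inclusive rule), so the retrieval set is
    # nested nondecreasing in the canonical threshold t.

    def canonical_scores(self) -> np.ndarray:
        if self.score_kind is ScoreKind.SIMILARITY:
            return -self.scores
        return self.scores

    def to_canonical_threshold(self, lam: float) -> float:
        return -lam if self.score_kind is ScoreKind.SIMILARITY else lam

    def from_canonical_threshold(self, t: float) -> float:
        return -t if self.score_kind is ScoreKind.SIMILARITY else t

    def default_rule(self, strict: bool = False) -> InclusionRule:
        """Boundary rule: >= for similarity, <= for distance (strict variants
        behind the flag; the source material is inconsistent on this point)."""
        if self.score_kind is ScoreKind.SIMILARITY:
            return InclusionRule.GT if strict else InclusionRule.GEQ
        return InclusionRule.LT if strict else InclusionRule.LEQ

    def row(self, query_id: str) -> np.ndarray:
        return self.scores[self.query_ids.index(query_id)]

    def subset_queries(self, indices: Sequence[int]) -> "ScoreMatrix":
        idx = list(indices)
        return ScoreMatrix(
            query_ids=[self.query_ids[i] for i in idx],
            lookup_ids=list(self.lookup_ids),
            scores=self.scores[idx, :],
            score_kind=self.score_kind,
        )


class LoadError(ValueError):
    """Raised on malformed score files; message carries the line number."""


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise LoadError(f"{path}:{lineno}: non-numeric score {token!r}") from None


def _load_triples(path, score_kind: ScoreKind) -> ScoreMatrix:
    query_ids: list = []
    lookup_ids: list = []
    q_index: dict = {}
    l_index: dict = {}
    values: dict = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise LoadError(f"{path}:{lineno}: expected 3 tab-separated fields")
            qid, lid, tok = (f.strip() for f in fields)
            if lineno == 1:
                # optional header row: third field not numeric
                try:
                    float(tok)
                except ValueError:
                    continue
            score = _parse_float(tok, path, lineno)
            if qid not in q_index:
                q_index[qid] = len(query_ids)
                query_ids.append(qid)
            if lid not in l_index:
                l_index[lid] = len(lookup_ids)
                lookup_ids.append(lid)
            key = (q_index[qid], l_index[lid])
            if key in values:
                raise LoadError(f"{path}:{lineno}: duplicate pair ({qid}, {lid})")
            values[key] = score
    if not values:
        raise LoadError(f"{path}: no score rows found")
    n_q, n_l = len(query_ids), len(lookup_ids)
    if len(values) != n_q * n_l:
        raise LoadError(
            f"{path}: triples do not cover the full {n_q} x {n_l} grid "
            f"({len(values)} pairs present)"
        )
    scores = np.empty((n_q, n_l), dtype=float)
    for (i, j), v in values.items():
        scores[i, j] = v
    return ScoreMatrix(query_ids, lookup_ids, scores, score_kind)


def _load_dense(path, score_kind: ScoreKind) -> ScoreMatrix:
    query_ids: list = []
    rows: list = []
    lookup_ids: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not lookup_ids:
                lookup_ids = [f.strip() for f in fields[1:]]
                if not lookup_ids:
                    raise LoadError(f"{path}:{lineno}: header row has no lookup ids")
                continue
            if len(fields) != len(lookup_ids) + 1:
                raise LoadError(
                    f"{path}:{lineno}: ragged row ({len(fields) - 1} values, "
                    f"expected {len(lookup_ids)})"
                )
            query_ids.append(fields[0].strip())
            rows.append([_parse_float(t, path, lineno) for t in fields[1:]])
    if not rows:
        raise LoadError(f"{path}: no data rows found")
    return ScoreMatrix(query_ids, lookup_ids, np.array(rows), score_kind)


def load_score_matrix(
    path,
    format: str = "triples",
    score_kind: Union[ScoreKind, str] = ScoreKind.SIMILARITY,
) -> ScoreMatrix:
    """Load a score matrix from a TSV file.

    ``format='triples'`` expects ``query_id<TAB>lookup_id<TAB>score`` rows
    (header optional, full cross product required, duplicates rejected);
    ``format='dense'`` expects lookup ids as header row and query ids in the
    first column.  Ids keep first-appearance order.
    """
    kind = ScoreKind(score_kind)
    path = Path(path)
    if format == "triples":
        return _load_triples(path, kind)
    if format == "dense":
        return _load_dense(path, kind)
    raise ValueError(f"unknown score file format {format!r}")


def write_score_matrix_triples(matrix: ScoreMatrix, path) -> None:
    """Write a matrix back out as a header-less triples TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, qid in enumerate(matrix.query_ids):
            for j, lid in enumerate(matrix.lookup_ids):
                fh.write(f"{qid}\t{lid}\t{float(matrix.scores[i, j])!r}\n")
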