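import numpy as np
import pytest

from confret import (
    AnnotationTable,
    FlatSpec,
    MatchSpec,
    Scheme,
    ScoreKind,
    ScoreMatrix,
    parse_hierarchy_label,
)


@pytest.fixture
def ec(request):
    return lambda text: parse_hierarchy_label(text, Scheme.EC)


@pytest.fixture
def tiny_similarity_matrix():
    """2 queries x 3 lookups, similarity orientation."""
    return ScoreMatrix(
        query_ids=["q1", "q2"],
        lookup_ids=["v1", "v2", "v3"],
        scores=np.array([[0.9, 0.4, 0.1], [0.2, 0.8, 0.5]]),
        score_kind=ScoreKind.SIMILARITY,
    )


@pytest.fixture
def pfam_annotations():
    return AnnotationTable(
        entries={
            "q1": {"PF00001"},
            "q2": {"PF00002", "PF00003"},
            "v1": {"PF00001"},
            "v2": {"PF00002"},
            "v3": {"PF00009"},
        }
    )


@pytest.fixture
def exact_spec():
    return MatchSpec(mode="pfam_exact")


@pytest.fixture
def flat_instance():
    from confret import gen_flat_instance

    return gen_flat_instance(FlatSpec(seed=7, n_query=50, n_lookup=400))
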