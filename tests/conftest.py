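"""Shared fixture builders for hand-constructed sentences and pairs."""

from __future__ import annotations

import pytest

from befree.preprocess import DEFAULT_PREPROCESSOR
from befree.synthetic import GeneratorConfig, generate_corpus
from befree.text_model import (
    AnnotatedSentence, CandidateInstance, DependencyGraph, EntityMention,
    PairLabel, Token,
)


def build_sentence(
    surfaces: list[str],
    mentions: list[tuple[str, str, int, int, set[str]]] = (),
    edges: list[tuple[int, int, str]] | None = None,
    root: int = 0,
    sid: str = "s1",
    doc_id: str = "100",
) -> AnnotatedSentence:
    """Sentence from raw surfaces; mentions are (id, type, first, last, ids)."""
    tokens = []
    offset = 0
    for i, surf in enumerate(surfaces):
        pos, lemma, stem = DEFAULT_PREPROCESSOR.analyze(surf)
        tokens.append(Token(i, surf, lemma, stem, pos, (offset, offset + len(surf))))
        offset += len(surf) + 1
    ms = tuple(
        EntityMention(id=mid, semantic_type=typ, token_span=(first, last),
                      concept_ids=frozenset(ids),
                      surface=" ".join(surfaces[first:last + 1]))
        for mid, typ, first, last, ids in mentions
    )
    graph = None
    if edges is not None:
        graph = DependencyGraph(
            nodes=frozenset(range(len(surfaces))), edges=tuple(edges), root=root
        )
    sent = AnnotatedSentence(
        id=sid, doc_id=doc_id, text=" ".join(surfaces),
        tokens=tuple(tokens), mentions=ms, graph=graph,
    )
    sent.validate()
    return sent


def make_pair(
    sent: AnnotatedSentence, id1: str, id2: str, fine: str | None = None
) -> CandidateInstance:
    label = PairLabel.from_fine(fine) if fine else None
    return CandidateInstance(sent, sent.mention_by_id(id1), sent.mention_by_id(id2), label)


@pytest.fixture(scope="session")
def fig_sentence() -> AnnotatedSentence:
    """'EHD3 is associated with MDD' with a gene, a disease and a second gene
    mention, plus a basic-dependency tree rooted at 'associated'."""
    return build_sentence(
        ["EHD3", "and", "FREM3", "are", "associated", "with", "MDD"],
        mentions=[
            ("g1", "GENE", 0, 0, {"30845"}),
            ("g2", "GENE", 2, 2, {"166752"}),
            ("d1", "DISEASE", 6, 6, {"C1269683"}),
        ],
        edges=[
            (4, 0, "nsubjpass"), (0, 1, "cc"), (0, 2, "conj"),
            (4, 3, "auxpass"), (4, 5, "prep"), (5, 6, "pobj"),
        ],
        root=4,
    )


@pytest.fixture(scope="session")
def synthetic_50():
    """50 deterministic template instances (shared across kernel tests)."""
    return generate_corpus(GeneratorConfig(n_sentences=50, seed=7))[1]
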