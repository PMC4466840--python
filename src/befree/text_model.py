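"""Domain model for annotated sentences, entity pairs and corpus I/O.

The unit of work is an :class:`AnnotatedSentence` — tokens enriched with POS,
lemma and stem, entity mentions normalized to Entrez Gene IDs or UMLS CUIs,
and an optional dependency graph. A :class:`CandidateInstance` is an ordered
pair of mentions in one sentence, optionally carrying a gold label. Certainty
labels follow the four-way scheme positive / negative / speculative / false
association (PA/NA/SA/FA), collapsed onto a binary TRUE/FALSE axis for the
standard relation-classification task.

Corpora are interchanged as line-delimited JSON (one sentence per line, 0-based
half-open character offsets). Readers are provided for a configurable
relation-annotation CSV dialect and for CoNLL-U / CoNLL-X dependency files.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .preprocess import DEFAULT_PREPROCESSOR, Preprocessor, tokenize_with_spans

__all__ = [
    "Token", "EntityMention", "DependencyGraph", "AnnotatedSentence",
    "CandidateInstance", "PairLabel", "CorpusReadResult",
    "FINE_TO_BINARY", "sentence_from_text", "blind_entities",
    "read_jsonl_corpus", "write_jsonl_corpus", "read_euadr_corpus",
    "read_conll_dependencies", "attach_dependencies",
]

GENE = "GENE"
DISEASE = "DISEASE"
DRUG = "DRUG"

#: Default mapping from four-way certainty labels onto the binary task.
#: Speculative associations count as TRUE; only explicit false associations
#: (entity co-occurrence without a semantic relation) are FALSE.
FINE_TO_BINARY = {"PA": "TRUE", "NA": "TRUE", "SA": "TRUE", "FA": "FALSE"}


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    stem: str
    pos: str
    char_span: tuple[int, int]


@dataclass(frozen=True)
class EntityMention:
    id: str
    semantic_type: str            # GENE | DISEASE | DRUG
    token_span: tuple[int, int]   # inclusive token indices
    concept_ids: frozenset[str] = frozenset()
    surface: str = ""


@dataclass(frozen=True)
class DependencyGraph:
    """Directed dependency edges (governor, dependent, relation) over tokens."""

    nodes: frozenset[int]
    edges: tuple[tuple[int, int, str], ...]
    root: int

    def governors(self, dep: int) -> list[tuple[int, str]]:
        return [(g, rel) for g, d, rel in self.edges if d == dep]

    def undirected_adjacency(self) -> dict[int, list[tuple[int, str, bool]]]:
        """Adjacency over the undirected view.

        Each neighbour entry is ``(other, relation, toward_governor)`` where
        ``toward_governor`` is True when moving from the key node to ``other``
        ascends the tree (dependent -> governor).
        """
        adj: dict[int, list[tuple[int, str, bool]]] = {n: [] for n in self.nodes}
        for gov, dep, rel in self.edges:
            adj[gov].append((dep, rel, False))
            adj[dep].append((gov, rel, True))
        return adj

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        adj = self.undirected_adjacency()
        seen = {self.root}
        stack = [self.root]
        while stack:
            for other, _, _ in adj[stack.pop()]:
                if other not in seen:
                    seen.add(other)
                    stack.append(other)
        return seen == set(self.nodes)


@dataclass
class AnnotatedSentence:
    id: str
    doc_id: str
    text: str
    tokens: tuple[Token, ...]
    mentions: tuple[EntityMention, ...] = ()
    graph: DependencyGraph | None = None

    def mention_by_id(self, mid: str) -> EntityMention:
        for m in self.mentions:
            if m.id == mid:
                return m
        raise KeyError(mid)

    def validate(self) -> None:
        n = len(self.tokens)
        for m in self.mentions:
            first, last = m.token_span
            if not (0 <= first <= last < n):
                raise ValueError(
                    f"mention {m.id} span {m.token_span} outside sentence {self.id}"
                )
        if self.graph is not None and set(self.graph.nodes) != set(range(n)):
            raise ValueError(f"graph nodes do not cover tokens of sentence {self.id}")


@dataclass(frozen=True)
class PairLabel:
    binary: str                 # TRUE | FALSE
    fine: str | None = None     # PA | NA | SA | FA

    @classmethod
    def from_fine(cls, fine: str, mapping: dict[str, str] | None = None) -> "PairLabel":
        mapping = mapping or FINE_TO_BINARY
        return cls(binary=mapping[fine], fine=fine)


@dataclass
class CandidateInstance:
    """An ordered pair of entity mentions in one sentence.

    The first mention must strictly precede the second in token order;
    overlapping or nested pairs are rejected at construction.
    """

    sentence: AnnotatedSentence
    entity1: EntityMention
    entity2: EntityMention
    label: PairLabel | None = None

    def __post_init__(self) -> None:
        if self.entity1.token_span[1] >= self.entity2.token_span[0]:
            raise ValueError(
                "candidate mentions overlap or are out of order: "
                f"{self.entity1.token_span} vs {self.entity2.token_span}"
            )

    @property
    def uid(self) -> str:
        return f"{self.sentence.id}:{self.entity1.id}:{self.entity2.id}"


def sentence_from_text(
    sid: str,
    text: str,
    doc_id: str = "",
    preprocessor: Preprocessor = DEFAULT_PREPROCESSOR,
) -> AnnotatedSentence:
    """Tokenize raw text and enrich each token via the pre-processing contract."""
    tokens = []
    for i, (surface, start, end) in enumerate(tokenize_with_spans(text)):
        pos, lemma, stem = preprocessor.analyze(surface)
        tokens.append(Token(i, surface, lemma, stem, pos, (start, end)))
    return AnnotatedSentence(id=sid, doc_id=doc_id, text=text, tokens=tuple(tokens))


# ---------------------------------------------------------------------------
# Entity blinding
# ---------------------------------------------------------------------------

CANDIDATE1 = "CANDIDATE1"
CANDIDATE2 = "CANDIDATE2"
ENTITY_OTHER = "ENTITY_OTHER"


def blind_entities(instance: CandidateInstance) -> tuple[list[Token], int, int]:
    """Generalize a sentence for kernel feature extraction.

    The two candidate mentions collapse to single CANDIDATE1/CANDIDATE2
    placeholder tokens; any other mention sharing a semantic type with either
    candidate collapses to ENTITY_OTHER. Placeholders carry POS ``NN`` and
    their own text as lemma and stem. Returns the blinded token sequence plus
    the positions of the two candidate placeholders within it.
    """
    sent = instance.sentence
    cand_types = {instance.entity1.semantic_type, instance.entity2.semantic_type}
    replacements: dict[tuple[int, int], str] = {
        instance.entity1.token_span: CANDIDATE1,
        instance.entity2.token_span: CANDIDATE2,
    }
    for m in sent.mentions:
        if m.token_span in replacements:
            continue
        if m.semantic_type in cand_types:
            # Overlap with a candidate span keeps the candidate placeholder.
            if any(
                m.token_span[0] <= cspan[1] and cspan[0] <= m.token_span[1]
                for cspan in (instance.entity1.token_span, instance.entity2.token_span)
            ):
                continue
            replacements.setdefault(m.token_span, ENTITY_OTHER)

    starts = {span[0]: (span, text) for span, text in replacements.items()}
    covered = {
        i for span in replacements for i in range(span[0], span[1] + 1)
    }
    out: list[Token] = []
    pos1 = pos2 = -1
    i = 0
    while i < len(sent.tokens):
        if i in starts:
            span, text = starts[i]
            first_tok = sent.tokens[span[0]]
            last_tok = sent.tokens[span[1]]
            tok = Token(
                index=len(out), surface=text, lemma=text, stem=text, pos="NN",
                char_span=(first_tok.char_span[0], last_tok.char_span[1]),
            )
            if text == CANDIDATE1:
                pos1 = len(out)
            elif text == CANDIDATE2:
                pos2 = len(out)
            out.append(tok)
            i = span[1] + 1
        elif i in covered:  # token inside a multi-token replaced span
            i += 1
        else:
            t = sent.tokens[i]
            out.append(Token(len(out), t.surface, t.lemma, t.stem, t.pos, t.char_span))
            i += 1
    return out, pos1, pos2


# ---------------------------------------------------------------------------
# JSONL interchange
# ---------------------------------------------------------------------------

def _sentence_to_dict(sent: AnnotatedSentence, pairs: Sequence[CandidateInstance]) -> dict:
    d: dict = {
        "id": sent.id,
        "doc_id": sent.doc_id,
        "text": sent.text,
        "tokens": [
            {
                "surface": t.surface, "lemma": t.lemma, "stem": t.stem,
                "pos": t.pos, "start": t.char_span[0], "end": t.char_span[1],
            }
            for t in sent.tokens
        ],
        "mentions": [
            {
                "id": m.id, "type": m.semantic_type,
                "first": m.token_span[0], "last": m.token_span[1],
                "concept_ids": sorted(m.concept_ids), "surface": m.surface,
            }
            for m in sent.mentions
        ],
        "pairs": [
            {
                "e1": p.entity1.id, "e2": p.entity2.id,
                "binary": p.label.binary if p.label else None,
                "fine": p.label.fine if p.label else None,
            }
            for p in pairs
        ],
    }
    if sent.graph is not None:
        d["graph"] = {
            "root": sent.graph.root,
            "edges": [[g, dep, rel] for g, dep, rel in sent.graph.edges],
        }
    return d


def _sentence_from_dict(d: dict) -> tuple[AnnotatedSentence, list[CandidateInstance]]:
    tokens = tuple(
        Token(i, t["surface"], t["lemma"], t["stem"], t["pos"], (t["start"], t["end"]))
        for i, t in enumerate(d["tokens"])
    )
    mentions = tuple(
        EntityMention(
            id=m["id"], semantic_type=m["type"], token_span=(m["first"], m["last"]),
            concept_ids=frozenset(m["concept_ids"]), surface=m["surface"],
        )
        for m in d["mentions"]
    )
    graph = None
    if "graph" in d:
        edges = tuple((g, dep, rel) for g, dep, rel in d["graph"]["edges"])
        graph = DependencyGraph(
            nodes=frozenset(range(len(tokens))), edges=edges, root=d["graph"]["root"]
        )
    sent = AnnotatedSentence(
        id=d["id"], doc_id=d["doc_id"], text=d["text"],
        tokens=tokens, mentions=mentions, graph=graph,
    )
    pairs = []
    for p in d.get("pairs", []):
        label = None
        if p.get("fine"):
            label = PairLabel(binary=p["binary"], fine=p["fine"])
        elif p.get("binary"):
            label = PairLabel(binary=p["binary"])
        pairs.append(
            CandidateInstance(sent, sent.mention_by_id(p["e1"]),
                              sent.mention_by_id(p["e2"]), label)
        )
    return sent, pairs


@dataclass
class CorpusReadResult:
    sentences: list[AnnotatedSentence] = field(default_factory=list)
    instances: list[CandidateInstance] = field(default_factory=list)
    skipped_spans: int = 0
    rejected_overlaps: int = 0


def write_jsonl_corpus(
    path: str | Path,
    sentences: Iterable[AnnotatedSentence],
    instances: Iterable[CandidateInstance],
) -> None:
    by_sentence: dict[str, list[CandidateInstance]] = {}
    for inst in instances:
        by_sentence.setdefault(inst.sentence.id, []).append(inst)
    with open(path, "w") as fh:
        for sent in sentences:
            fh.write(json.dumps(_sentence_to_dict(sent, by_sentence.get(sent.id, [])),
                                sort_keys=True))
            fh.write("\n")


def read_jsonl_corpus(path: str | Path) -> CorpusReadResult:
    result = CorpusReadResult()
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            sent, pairs = _sentence_from_dict(json.loads(line))
            sent.validate()
            result.sentences.append(sent)
            result.instances.extend(pairs)
    return result


# ---------------------------------------------------------------------------
# Relation-annotation CSV dialect
# ---------------------------------------------------------------------------

#: Default column mapping for the flat CSV relation dialect. Character offsets
#: are 0-based half-open into the sentence text. The layout of the published
#: distribution is configurable through this mapping.
EUADR_DEFAULT_COLUMNS = {
    "doc_id": "pmid",
    "sentence_id": "sentence_id",
    "text": "sentence",
    "e1_start": "e1_start", "e1_end": "e1_end", "e1_type": "e1_type",
    "e1_ids": "e1_ids",
    "e2_start": "e2_start", "e2_end": "e2_end", "e2_type": "e2_type",
    "e2_ids": "e2_ids",
    "label": "label",            # PA | NA | SA | FA
    "consensus": "consensus",    # truthy => consensus of two annotators
}

_RELATION_TYPES = {
    "gene-disease": {GENE, DISEASE},
    "drug-disease": {DRUG, DISEASE},
    "drug-target": {DRUG, GENE},
}


def _chars_to_token_span(sent: AnnotatedSentence, start: int, end: int) -> tuple[int, int] | None:
    hit = [t.index for t in sent.tokens
           if t.char_span[0] < end and start < t.char_span[1]]
    if not hit:
        return None
    return hit[0], hit[-1]


def read_euadr_corpus(
    path: str | Path,
    relation_set: str = "gene-disease",
    columns: dict[str, str] | None = None,
    fine_to_binary: dict[str, str] | None = None,
    preprocessor: Preprocessor = DEFAULT_PREPROCESSOR,
) -> CorpusReadResult:
    """Read a relation-annotation CSV into sentences and labelled pairs.

    Only rows flagged as annotator-consensus are retained; each retained row
    becomes one :class:`CandidateInstance` with its four-way certainty label
    and the derived binary label. Rows with spans outside the sentence are
    skipped and counted; overlapping candidate pairs are rejected and counted.
    """
    if relation_set not in _RELATION_TYPES:
        raise ValueError(f"unknown relation set {relation_set!r}")
    cols = columns or EUADR_DEFAULT_COLUMNS
    wanted_types = _RELATION_TYPES[relation_set]
    mapping = fine_to_binary or FINE_TO_BINARY
    result = CorpusReadResult()
    sentences: dict[str, AnnotatedSentence] = {}

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                sid = row[cols["sentence_id"]]
                text = row[cols["text"]]
                fine = row[cols["label"]].strip().upper()
                consensus = row[cols["consensus"]].strip().lower()
                spans = [
                    (int(row[cols["e1_start"]]), int(row[cols["e1_end"]]),
                     row[cols["e1_type"]].strip().upper(), row[cols["e1_ids"]]),
                    (int(row[cols["e2_start"]]), int(row[cols["e2_end"]]),
                     row[cols["e2_type"]].strip().upper(), row[cols["e2_ids"]]),
                ]
            except (KeyError, ValueError) as exc:
                raise ValueError(f"malformed row {rownum} in {path}: {exc}") from exc

            if consensus not in {"1", "true", "yes", "y"}:
                continue
            if {s[2] for s in spans} != wanted_types:
                continue
            if fine not in mapping:
                raise ValueError(f"row {rownum}: unknown certainty label {fine!r}")

            if sid not in sentences:
                sent = sentence_from_text(
                    sid, text, doc_id=row[cols["doc_id"]], preprocessor=preprocessor
                )
                sentences[sid] = sent
                result.sentences.append(sent)
            sent = sentences[sid]

            mentions = []
            bad_span = False
            for k, (start, end, etype, ids) in enumerate(spans, start=1):
                if end > len(sent.text) or start < 0 or start >= end:
                    bad_span = True
                    break
                tspan = _chars_to_token_span(sent, start, end)
                if tspan is None:
                    bad_span = True
                    break
                mentions.append(EntityMention(
                    id=f"{sid}.r{rownum}.e{k}", semantic_type=etype, token_span=tspan,
                    concept_ids=frozenset(x for x in ids.split(";") if x),
                    surface=sent.text[start:end],
                ))
            if bad_span:
                result.skipped_spans += 1
                continue

            mentions.sort(key=lambda m: m.token_span)
            sent.mentions = tuple(sorted(
                set(sent.mentions) | set(mentions), key=lambda m: m.token_span
            ))
            try:
                inst = CandidateInstance(
                    sent, mentions[0], mentions[1],
                    PairLabel.from_fine(fine, mapping),
                )
            except ValueError:
                result.rejected_overlaps += 1
                continue
            result.instances.append(inst)
    return result


# ---------------------------------------------------------------------------
# CoNLL dependency files
# ---------------------------------------------------------------------------

def read_conll_dependencies(path: str | Path) -> list[DependencyGraph]:
    """Parse CoNLL-U or CoNLL-X dependency annotations, one graph per sentence.

    Both dialects keep token id, surface, head and relation in columns
    1, 2, 7 and 8, so a single reader covers both. Multiword-token ranges and
    empty nodes (CoNLL-U) are skipped. If a sentence declares several roots the
    first is kept and the rest re-attached to it.
    """
    graphs: list[DependencyGraph] = []
    rows: list[tuple[int, int, str]] = []

    def flush() -> None:
        nonlocal rows
        if not rows:
            return
        edges = []
        root_candidates = []
        for dep, head, rel in rows:
            if head == 0:
                root_candidates.append(dep)
            else:
                edges.append((head - 1, dep - 1, rel))
        if not root_candidates:
            raise ValueError("sentence without a root in CoNLL input")
        root = root_candidates[0]
        for extra in root_candidates[1:]:
            edges.append((root - 1, extra - 1, "dep"))
        n = len(rows)
        graphs.append(DependencyGraph(
            nodes=frozenset(range(n)), edges=tuple(edges), root=root - 1
        ))
        rows = []

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue
            rows.append((int(tid), int(cols[6]), cols[7]))
    flush()
    return graphs


def attach_dependencies(
    sentences: Sequence[AnnotatedSentence], graphs: Sequence[DependencyGraph]
) -> None:
    """Attach parses to sentences by order, checking token counts match."""
    if len(sentences) != len(graphs):
        raise ValueError(
            f"parse count ({len(graphs)}) != sentence count ({len(sentences)})"
        )
    for sent, graph in zip(sentences, graphs):
        if len(graph.nodes) != len(sent.tokens):
            raise ValueError(
                f"alignment error for sentence {sent.id}: "
                f"{len(graph.nodes)} parse tokens vs {len(sent.tokens)} sentence tokens"
            )
        sent.graph = graph
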