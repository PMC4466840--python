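"""Entity-ambiguity resolution over pluggable dictionary matches.

Dictionary-based gene/disease recognition is a contract here: any component
that produces :class:`DictionaryMatch` objects (span, surface, candidate
concept entries) plugs in, and a toy gazetteer ships for tests. This module
implements the two disambiguation layers applied on top of such matches:

* **intra-type (acronym) resolution** — when an acronym follows its defining
  long form, the candidate concept-id sets of the two mentions are
  intersected; residual ambiguity is ranked by synonym similarity to the long
  form and, as a last resort, by gene-literature links (gene2pubmed).
* **cross-type resolution** — a symbol like "APC" can name a gene
  (adenomatous polyposis coli) or a disease (atrial premature complex);
  nearby trigger keywords decide the semantic type, and failing that the
  abstract's MeSH disease annotations are soft-matched against the mention's
  disease candidate terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .text_model import AnnotatedSentence

__all__ = [
    "ConceptEntry", "DictionaryMatch", "KeywordLists", "ToyGazetteer",
    "detect_abbreviations", "resolve_acronym", "resolve_cross_type",
    "AcronymResolution",
]


@dataclass(frozen=True)
class ConceptEntry:
    concept_id: str
    semantic_type: str               # GENE | DISEASE
    synonyms: tuple[str, ...] = ()


@dataclass(frozen=True)
class DictionaryMatch:
    char_span: tuple[int, int]
    surface: str
    entries: tuple[ConceptEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a dictionary match needs at least one candidate entry")

    @property
    def concept_ids(self) -> frozenset[str]:
        return frozenset(e.concept_id for e in self.entries)

    @property
    def semantic_types(self) -> frozenset[str]:
        return frozenset(e.semantic_type for e in self.entries)


@dataclass(frozen=True)
class KeywordLists:
    gene_context: frozenset[str] = frozenset(
        {"gene", "genes", "protein", "proteins", "factor", "target",
         "biomarker", "transcript", "allele", "polymorphism"}
    )
    disease_context: frozenset[str] = frozenset(
        {"disease", "diseases", "disorder", "disorders", "condition",
         "syndrome", "cancer", "deficiency"}
    )

    def __post_init__(self) -> None:
        if self.gene_context & self.disease_context:
            raise ValueError("gene and disease keyword lists must be disjoint")


# ---------------------------------------------------------------------------
# Abbreviation detection (long form "(" short form ")")
# ---------------------------------------------------------------------------

_PAREN_RE = re.compile(r"\(([^()]{1,40})\)")


def _chars_align(short: str, long: str) -> bool:
    """Schwartz–Hearst-style alignment: match short-form characters right to
    left inside the long form; the first character must start a long-form
    token."""
    s = short.lower()
    l = long.lower()
    si = len(s) - 1
    li = len(l) - 1
    while si >= 0:
        ch = s[si]
        if not ch.isalnum():
            si -= 1
            continue
        while li >= 0 and (l[li] != ch or (si == 0 and li > 0 and l[li - 1].isalnum())):
            li -= 1
        if li < 0:
            return False
        si -= 1
        li -= 1
    return True


def detect_abbreviations(text: str) -> list[tuple[str, str]]:
    """Find (short form, long form) pairs of the pattern ``LONG ( SHORT )``.

    A short form qualifies when it is 2-10 characters, at most two words,
    starts with an alphanumeric character matching the long form, and every
    one of its characters can be aligned in order within the long form.
    The candidate long form spans at most ``min(|short|+5, 2*|short|)`` words
    immediately before the parenthesis. Only innermost parentheses are
    considered.
    """
    pairs = []
    for m in _PAREN_RE.finditer(text):
        short = m.group(1).strip()
        if not (2 <= len(short) <= 10) or len(short.split()) > 2:
            continue
        if not short[0].isalnum() or not any(c.isalpha() for c in short):
            continue
        prefix = text[: m.start()].rstrip()
        cut = max(prefix.rfind("("), prefix.rfind(")"))
        if cut >= 0:                 # long form never crosses a parenthesis
            prefix = prefix[cut + 1:]
        words = re.findall(r"\S+", prefix)
        if not words:
            continue
        max_words = min(len(short) + 5, 2 * len(short))
        for k in range(min(max_words, len(words)), 0, -1):
            long_form = " ".join(words[-k:])
            if not long_form[0].isalnum():
                continue
            if long_form.lower().startswith(short[0].lower()) and _chars_align(short, long_form):
                pairs.append((short, long_form))
                break
    return pairs


# ---------------------------------------------------------------------------
# Acronym (intra-type) resolution
# ---------------------------------------------------------------------------

@dataclass
class AcronymResolution:
    concept_ids: frozenset[str]
    resolved: bool
    route: str    # "intersection" | "similarity" | "gene2pubmed" | "unresolved"


def _token_jaccard(a: str, b: str) -> float:
    ta = set(re.findall(r"\w+", a.lower()))
    tb = set(re.findall(r"\w+", b.lower()))
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / len(ta | tb)


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a.lower(), b.lower())["editDistance"]


def resolve_acronym(
    short: DictionaryMatch,
    long: DictionaryMatch,
    pmid: str | None = None,
    gene2pubmed: dict[str, frozenset[str]] | None = None,
) -> AcronymResolution:
    """Resolve an acronym against its defining long form.

    The candidate concept-id sets of both mentions are intersected. A single
    survivor wins outright. Several survivors are ranked by token-Jaccard
    similarity between each concept's synonym terms and the long-form surface
    (ties broken by minimum edit distance, then by gene2pubmed linkage to the
    citing publication). An empty intersection leaves both mentions
    unresolved. Never invents an identifier outside the candidate sets.
    """
    common = short.concept_ids & long.concept_ids
    if not common:
        return AcronymResolution(frozenset(), resolved=False, route="unresolved")
    if len(common) == 1:
        return AcronymResolution(common, resolved=True, route="intersection")

    entries = {e.concept_id: e for e in (*short.entries, *long.entries)
               if e.concept_id in common}

    def similarity(cid: str) -> float:
        syns = entries[cid].synonyms or (cid,)
        return max(_token_jaccard(s, long.surface) for s in syns)

    def distance(cid: str) -> int:
        syns = entries[cid].synonyms or (cid,)
        return min(_edit_distance(s, long.surface) for s in syns)

    ranked = sorted(common, key=lambda cid: (-similarity(cid), distance(cid), cid))
    best = ranked[0]
    tied = [cid for cid in ranked
            if similarity(cid) == similarity(best) and distance(cid) == distance(best)]
    if len(tied) == 1:
        return AcronymResolution(frozenset({best}), resolved=True, route="similarity")
    if gene2pubmed is not None and pmid is not None:
        linked = [cid for cid in tied if pmid in gene2pubmed.get(cid, frozenset())]
        if len(linked) == 1:
            return AcronymResolution(frozenset(linked), resolved=True, route="gene2pubmed")
    return AcronymResolution(frozenset(tied), resolved=False, route="unresolved")


# ---------------------------------------------------------------------------
# Cross-type (gene vs disease) resolution
# ---------------------------------------------------------------------------

def _soft_match(terms_a: set[str], terms_b: set[str]) -> float:
    """Lowercase token-set overlap normalized by the smaller set."""
    if not terms_a or not terms_b:
        return 0.0
    return len(terms_a & terms_b) / min(len(terms_a), len(terms_b))


def resolve_cross_type(
    match: DictionaryMatch,
    sentence: AnnotatedSentence,
    mesh_terms: frozenset[str] = frozenset(),
    keywords: KeywordLists | None = None,
    window: int = 5,
    mesh_threshold: float = 0.5,
) -> str:
    """Decide GENE vs DISEASE for a match ambiguous across semantic types.

    Trigger keywords within ``window`` tokens of the mention decide first,
    the nearest keyword winning and exact distance ties staying UNRESOLVED.
    Without any keyword, the mention's disease candidate synonyms are
    soft-matched (token overlap / smaller set) against the abstract's MeSH
    disease terms; a score >= ``mesh_threshold`` labels the mention DISEASE.
    """
    keywords = keywords or KeywordLists()
    start, end = match.char_span
    mention_tokens = [t.index for t in sentence.tokens
                      if t.char_span[0] < end and start < t.char_span[1]]
    if not mention_tokens:
        return "UNRESOLVED"
    first, last = mention_tokens[0], mention_tokens[-1]

    best_gene = best_disease = None
    for t in sentence.tokens:
        if first <= t.index <= last:
            continue
        dist = first - t.index if t.index < first else t.index - last
        if dist > window:
            continue
        low = t.surface.lower()
        if low in keywords.gene_context and (best_gene is None or dist < best_gene):
            best_gene = dist
        if low in keywords.disease_context and (best_disease is None or dist < best_disease):
            best_disease = dist
    if best_gene is not None or best_disease is not None:
        if best_disease is None:
            return "GENE"
        if best_gene is None:
            return "DISEASE"
        if best_gene < best_disease:
            return "GENE"
        if best_disease < best_gene:
            return "DISEASE"
        return "UNRESOLVED"

    disease_terms: set[str] = set()
    for e in match.entries:
        if e.semantic_type == "DISEASE":
            for syn in (*e.synonyms, match.surface):
                disease_terms.update(re.findall(r"\w+", syn.lower()))
    mesh_tokens: set[str] = set()
    for term in mesh_terms:
        mesh_tokens.update(re.findall(r"\w+", term.lower()))
    if _soft_match(disease_terms, mesh_tokens) >= mesh_threshold:
        return "DISEASE"
    return "UNRESOLVED"


# ---------------------------------------------------------------------------
# Toy gazetteer (test NER fulfilling the dictionary contract)
# ---------------------------------------------------------------------------

@dataclass
class ToyGazetteer:
    """Longest-match dictionary NER over a small term -> entries lexicon."""

    lexicon: dict[str, tuple[ConceptEntry, ...]] = field(default_factory=dict)

    def add(self, term: str, *entries: ConceptEntry) -> None:
        self.lexicon[term.lower()] = tuple(entries)

    def find(self, text: str) -> list[DictionaryMatch]:
        matches: list[DictionaryMatch] = []
        terms = sorted(self.lexicon, key=len, reverse=True)
        taken: list[tuple[int, int]] = []
        for term in terms:
            for m in re.finditer(rf"(?<!\w){re.escape(term)}(?!\w)", text, re.IGNORECASE):
                span = (m.start(), m.end())
                if any(span[0] < e and s < span[1] for s, e in taken):
                    continue
                taken.append(span)
                matches.append(DictionaryMatch(
                    char_span=span, surface=m.group(0),
                    entries=self.lexicon[term],
                ))
        return sorted(matches, key=lambda d: d.char_span)
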