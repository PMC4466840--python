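"""Shallow Linguistic Kernel: K_SL = K_GC + K_LC.

The global-context kernel K_GC assumes that a relation between two candidate
entities is most often expressed in one of three token patterns around the
pair — *fore-between* (everything before the first candidate plus the tokens
between), *between* (strictly between the candidates), and *between-after*
(the between tokens plus everything after the second candidate). Each pattern
is represented as a bag of contiguous n-grams (orders 1..3 by default) over
the blinded, lowercased token sequence, augmented with sparse bigrams —
ordered token pairs separated by 1..`max_gap` intervening tokens, down-weighted
by ``decay ** gap``. K_GC is the sum over the three patterns of the
cosine-normalized dot products.

The local-context kernel K_LC looks at a fixed window (±2 by default) around
each candidate mention and emits, per position, the token's orthographic class,
POS tag, lemma and stem as indicator features; positions beyond the sentence
boundary carry a sentinel value so vector arity is constant. K_LC is the
cosine of the two indicator vectors.

Candidate tokens themselves never enter the global patterns: after blinding
they are constants and would only add shared mass to every pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .text_model import CandidateInstance, Token, blind_entities

__all__ = [
    "SLConfig", "PatternVector", "LocalContextVector",
    "extract_global_context", "extract_local_context",
    "k_gc", "k_lc", "k_sl", "orthographic_class",
]

PATTERNS = ("fore_between", "between", "between_after")
SENTINEL = "∅"  # padding value for window slots beyond the sentence


@dataclass(frozen=True)
class SLConfig:
    ngram_max: int = 3
    sparse_bigram_max_gap: int = 2
    sparse_bigram_decay: float = 0.5
    window: int = 2
    normalize: bool = True
    gc_weight: float = 1.0
    lc_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.ngram_max < 1 or self.window < 1:
            raise ValueError("ngram_max and window must be >= 1")
        if not (0 < self.sparse_bigram_decay <= 1):
            raise ValueError("sparse bigram decay must lie in (0, 1]")


@dataclass
class PatternVector:
    """Sparse n-gram weights for the three global-context patterns."""

    fore_between: dict[tuple[str, ...], float] = field(default_factory=dict)
    between: dict[tuple[str, ...], float] = field(default_factory=dict)
    between_after: dict[tuple[str, ...], float] = field(default_factory=dict)

    def pattern(self, name: str) -> dict[tuple[str, ...], float]:
        return getattr(self, name)


@dataclass
class LocalContextVector:
    """Indicator features keyed by (candidate slot, offset, kind, value)."""

    features: frozenset[tuple[int, int, str, str]] = frozenset()


def _ngram_weights(words: list[str], cfg: SLConfig) -> dict[tuple[str, ...], float]:
    out: dict[tuple[str, ...], float] = {}
    n = len(words)
    for order in range(1, cfg.ngram_max + 1):
        for i in range(n - order + 1):
            key = tuple(words[i:i + order])
            out[key] = out.get(key, 0.0) + 1.0
    for gap in range(1, cfg.sparse_bigram_max_gap + 1):
        w = cfg.sparse_bigram_decay ** gap
        for i in range(n - gap - 1):
            key = ("<sb>", words[i], words[i + gap + 1])
            out[key] = out.get(key, 0.0) + w
    return out


def extract_global_context(instance: CandidateInstance, cfg: SLConfig) -> PatternVector:
    tokens, p1, p2 = blind_entities(instance)
    words = [t.surface.lower() for t in tokens]
    fore = words[:p1]
    between = words[p1 + 1:p2]
    after = words[p2 + 1:]
    return PatternVector(
        fore_between=_ngram_weights(fore + between, cfg),
        between=_ngram_weights(between, cfg),
        between_after=_ngram_weights(between + after, cfg),
    )


_ORTH_KINDS = ("ORTH", "POS", "LEMMA", "STEM")


def orthographic_class(surface: str) -> str:
    if not any(c.isalnum() for c in surface):
        return "PUNCT"
    if any(c.isdigit() for c in surface):
        return "HASDIGIT"
    if surface.isupper():
        return "ALLCAPS"
    if surface.islower():
        return "ALLLOWER"
    if surface[0].isupper() and surface[1:].islower():
        return "INITCAP"
    return "MIXED"


def extract_local_context(instance: CandidateInstance, cfg: SLConfig) -> LocalContextVector:
    tokens, p1, p2 = blind_entities(instance)
    feats: set[tuple[int, int, str, str]] = set()
    for slot, pos in ((1, p1), (2, p2)):
        for offset in [*range(-cfg.window, 0), *range(1, cfg.window + 1)]:
            j = pos + offset
            if 0 <= j < len(tokens):
                t: Token = tokens[j]
                feats.add((slot, offset, "ORTH", orthographic_class(t.surface)))
                feats.add((slot, offset, "POS", t.pos))
                feats.add((slot, offset, "LEMMA", t.lemma.lower()))
                feats.add((slot, offset, "STEM", t.stem.lower()))
            else:
                for kind in _ORTH_KINDS:
                    feats.add((slot, offset, kind, SENTINEL))
    return LocalContextVector(features=frozenset(feats))


def _cosine(a: dict, b: dict) -> float:
    if not a or not b:
        return 0.0
    dot = sum(w * b[k] for k, w in a.items() if k in b)
    na = math.sqrt(sum(w * w for w in a.values()))
    nb = math.sqrt(sum(w * w for w in b.values()))
    return dot / (na * nb)


def k_gc(a: PatternVector, b: PatternVector, cfg: SLConfig | None = None) -> float:
    cfg = cfg or SLConfig()
    total = 0.0
    for name in PATTERNS:
        pa, pb = a.pattern(name), b.pattern(name)
        if cfg.normalize:
            total += _cosine(pa, pb)
        else:
            total += sum(w * pb[k] for k, w in pa.items() if k in pb)
    return total


def k_lc(a: LocalContextVector, b: LocalContextVector) -> float:
    shared = len(a.features & b.features)
    if not a.features or not b.features:
        return 0.0
    return shared / math.sqrt(len(a.features) * len(b.features))


def k_sl(x: CandidateInstance, y: CandidateInstance, cfg: SLConfig | None = None) -> float:
    """Shallow Linguistic Kernel between two candidate pairs."""
    cfg = cfg or SLConfig()
    gc = k_gc(extract_global_context(x, cfg), extract_global_context(y, cfg), cfg)
    lc = k_lc(extract_local_context(x, cfg), extract_local_context(y, cfg))
    return cfg.gc_weight * gc + cfg.lc_weight * lc
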