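"""Deterministic sentence pre-processing.

Relation-extraction kernels consume tokens enriched with POS tag, lemma and
stem. In a production pipeline these come from external NLP tooling; here the
pipeline is a pluggable contract (:class:`Preprocessor`) and the package ships
a self-contained fallback so that every test and simulation is reproducible on
any machine with no model downloads:

* a regex tokenizer that records exact character offsets,
* the Porter suffix-stripping stemmer,
* a small lexicon lemmatizer falling back to the lowercased surface,
* a rule-based POS tagger (closed-class lexicon plus suffix heuristics)
  emitting Penn-Treebank-style tags.

The tagger is intentionally crude: kernels only need *consistent* tags, not
linguistically perfect ones, and the synthetic corpus is generated through
this same pipeline.
"""

from __future__ import annotations

import re
from typing import Protocol

__all__ = ["Preprocessor", "FallbackPreprocessor", "porter_stem", "tokenize_with_spans"]

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize_with_spans(text: str) -> list[tuple[str, int, int]]:
    """Split *text* into word/punctuation tokens with half-open char spans."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences (the m of the algorithm)."""
    forms = "".join("c" if _is_consonant(stem, i) else "v" for i in range(len(stem)))
    return len(re.findall("vc", forms))


def _has_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    return (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
        and word[-1] not in "wxy"
    )


def _replace(word: str, suffix: str, repl: str, m_min: int) -> str | None:
    if not word.endswith(suffix):
        return None
    stem = word[: len(word) - len(suffix)]
    if _measure(stem) > m_min:
        return stem + repl
    return word


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]
_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]
_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Porter's suffix-stripping stemmer over a lowercased alphabetic word."""
    w = word.lower()
    if len(w) <= 2 or not w.isalpha():
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif not w.endswith("ss") and w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w, flag = w[:-2], True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w, flag = w[:-3], True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_consonant(w) and w[-1] not in "lsz":
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    for suffix, repl in _STEP2:
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break
    for suffix, repl in _STEP3:
        out = _replace(w, suffix, repl, 0)
        if out is not None:
            w = out
            break
    for suffix in _STEP4:
        if w.endswith(suffix):
            stem = w[: len(w) - len(suffix)]
            if suffix == "ion" and (not stem or stem[-1] not in "st"):
                continue
            if _measure(stem) > 1:
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem
    # step 5b
    if _ends_double_consonant(w) and w[-1] == "l" and _measure(w) > 1:
        w = w[:-1]
    return w


# ---------------------------------------------------------------------------
# Lemmatizer and POS tagger
# ---------------------------------------------------------------------------

_LEMMA_LEXICON = {
    "is": "be", "are": "be", "was": "be", "were": "be", "been": "be", "be": "be",
    "has": "have", "have": "have", "had": "have",
    "does": "do", "did": "do", "done": "do",
    "associated": "associate", "associations": "association",
    "found": "find", "shown": "show", "showed": "show",
    "increased": "increase", "increases": "increase", "decreased": "decrease",
    "observed": "observe", "reported": "report", "linked": "link",
    "caused": "cause", "causes": "cause", "carried": "carry",
    "mutations": "mutation", "patients": "patient", "genes": "gene",
    "diseases": "disease", "levels": "level", "studies": "study",
    "measured": "measure", "genotyped": "genotype", "detected": "detect",
    "conferred": "confer", "confers": "confer", "identified": "identify",
}

_CLOSED_CLASS_POS = {
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "no": "DT",
    "of": "IN", "in": "IN", "with": "IN", "between": "IN", "for": "IN",
    "to": "TO", "by": "IN", "on": "IN", "from": "IN", "among": "IN",
    "and": "CC", "or": "CC", "but": "CC",
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "has": "VBZ", "have": "VBP", "had": "VBD",
    "not": "RB", "also": "RB", "however": "RB", "significantly": "RB",
    "we": "PRP", "it": "PRP", "that": "IN", "which": "WDT",
}


def _rule_pos(surface: str) -> str:
    low = surface.lower()
    if low in _CLOSED_CLASS_POS:
        return _CLOSED_CLASS_POS[low]
    if not any(c.isalnum() for c in surface):
        return "."
    if surface[0].isdigit():
        return "CD"
    if low.endswith("ly"):
        return "RB"
    if low.endswith(("ed", "en")):
        return "VBN"
    if low.endswith("ing"):
        return "VBG"
    if low.endswith(("ous", "ive", "al", "ic", "able")):
        return "JJ"
    if low.endswith("s") and not low.endswith("ss"):
        return "NNS"
    if surface[0].isupper() and low != surface:
        return "NNP"
    return "NN"


class Preprocessor(Protocol):
    """Contract for enriching raw token surfaces with POS, lemma and stem."""

    def analyze(self, surface: str) -> tuple[str, str, str]:
        """Return ``(pos, lemma, stem)`` for one token surface."""
        ...


class FallbackPreprocessor:
    """Deterministic lexicon/rule pipeline; no external models or downloads."""

    def analyze(self, surface: str) -> tuple[str, str, str]:
        low = surface.lower()
        lemma = _LEMMA_LEXICON.get(low, low)
        stem = porter_stem(low) if low.isalpha() else low
        return _rule_pos(surface), lemma, stem


DEFAULT_PREPROCESSOR = FallbackPreprocessor()
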