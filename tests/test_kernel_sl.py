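"""Shallow linguistic kernel: pattern extraction oracles and kernel laws."""

import itertools
import math

import numpy as np
import pytest

from befree.kernel_sl import (
    SLConfig, SENTINEL, extract_global_context, extract_local_context,
    k_gc, k_lc, k_sl, orthographic_class,
)
from conftest import build_sentence, make_pair


def brute_force_ngrams(words, ngram_max=3, max_gap=2, decay=0.5):
    """Independent enumeration of contiguous n-grams and sparse bigrams."""
    expected = {}
    for order in range(1, ngram_max + 1):
        for i in range(len(words) - order + 1):
            key = tuple(words[i:i + order])
            expected[key] = expected.get(key, 0.0) + 1.0
    for i, j in itertools.combinations(range(len(words)), 2):
        gap = j - i - 1
        if 1 <= gap <= max_gap:
            key = ("<sb>", words[i], words[j])
            expected[key] = expected.get(key, 0.0) + decay ** gap
    return expected


def simple_pair(words, g_idx, d_idx, mentions_extra=()):
    mentions = [("g", "GENE", g_idx, g_idx, {"1"}),
                ("d", "DISEASE", d_idx, d_idx, {"C1"}), *mentions_extra]
    sent = build_sentence(words, mentions=mentions)
    return make_pair(sent, "g", "d")


class TestGlobalContext:
    def test_between_pattern_matches_bruteforce_oracle(self):
        inst = simple_pair(["EHD3", "is", "associated", "with", "MDD"], 0, 4)
        pv = extract_global_context(inst, SLConfig())
        expected = brute_force_ngrams(["is", "associated", "with"])
        assert pv.between == expected
        assert ("is",) in pv.between and ("is", "associated", "with") in pv.between
        assert pv.between[("<sb>", "is", "with")] == pytest.approx(0.5)

    def test_adjacent_candidates_leave_between_empty(self):
        inst = simple_pair(["EHD3", "MDD", "levels", "were", "high"], 0, 1)
        pv = extract_global_context(inst, SLConfig())
        assert pv.between == {}

    def test_fore_between_contains_between_as_key_multiset(self, fig_sentence):
        inst = make_pair(fig_sentence, "g1", "d1")
        pv = extract_global_context(inst, SLConfig())
        assert pv.between
        for key, weight in pv.between.items():
            assert pv.fore_between.get(key, 0.0) >= weight

    def test_candidate_placeholders_excluded_from_patterns(self):
        inst = simple_pair(["EHD3", "is", "associated", "with", "MDD"], 0, 4)
        pv = extract_global_context(inst, SLConfig())
        for pattern in ("fore_between", "between", "between_after"):
            for key in pv.pattern(pattern):
                assert "candidate1" not in key and "candidate2" not in key


class TestOrthographicClass:
    # exhaustive truth table over the class definitions
    @pytest.mark.parametrize("surface,expected", [
        ("EHD3", "HASDIGIT"), ("p53", "HASDIGIT"), ("123", "HASDIGIT"),
        ("BRCA", "ALLCAPS"), ("gene", "ALLLOWER"), ("Disease", "INITCAP"),
        ("mRNA", "MIXED"), ("McDonald", "MIXED"),
        (",", "PUNCT"), ("(", "PUNCT"),
    ])
    def test_truth_table(self, surface, expected):
        assert orthographic_class(surface) == expected


class TestLocalContext:
    def test_sentence_start_padded_with_sentinel(self):
        inst = simple_pair(["EHD3", "is", "associated", "with", "MDD"], 0, 4)
        lv = extract_local_context(inst, SLConfig())
        for kind in ("ORTH", "POS", "LEMMA", "STEM"):
            assert (1, -2, kind, SENTINEL) in lv.features
            assert (1, -1, kind, SENTINEL) in lv.features
            assert (2, 1, kind, SENTINEL) in lv.features

    def test_digit_token_contributes_hasdigit_feature(self):
        inst = simple_pair(["MDD", "affects", "EHD3", "strongly", "today"], 0, 4,
                           mentions_extra=())
        # EHD3 sits at offset -2 of candidate 2 (token 4)
        lv = extract_local_context(inst, SLConfig())
        assert (2, -2, "ORTH", "HASDIGIT") in lv.features

    def test_fixed_arity(self):
        cfg = SLConfig(window=2)
        inst = simple_pair(["a", "EHD3", "b", "MDD", "c"], 1, 3)
        lv = extract_local_context(inst, cfg)
        assert len(lv.features) == 2 * (2 * cfg.window) * 4

    def test_determinism(self):
        inst = simple_pair(["EHD3", "is", "associated", "with", "MDD"], 0, 4)
        assert extract_local_context(inst, SLConfig()) == \
            extract_local_context(inst, SLConfig())


def dense_dot(a: dict, b: dict) -> float:
    vocab = sorted(set(a) | set(b))
    va = np.array([a.get(k, 0.0) for k in vocab])
    vb = np.array([b.get(k, 0.0) for k in vocab])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


class TestKernels:
    def test_k_gc_self_similarity_is_three(self):
        inst = simple_pair(["the", "gene", "EHD3", "is", "linked", "to", "MDD",
                            "in", "adults"], 2, 6)
        pv = extract_global_context(inst, SLConfig())
        assert k_gc(pv, pv) == pytest.approx(3.0, abs=1e-12)

    def test_k_gc_disjoint_vocabulary_is_zero(self):
        a = extract_global_context(
            simple_pair(["x1", "alpha", "beta", "gamma", "x2"], 0, 4), SLConfig())
        b = extract_global_context(
            simple_pair(["y1", "delta", "epsilon", "zeta", "y2"], 0, 4), SLConfig())
        assert k_gc(a, b) == 0.0

    def test_k_gc_equals_dense_oracle(self):
        a = extract_global_context(
            simple_pair(["g", "is", "associated", "with", "d", "here"], 0, 4), SLConfig())
        b = extract_global_context(
            simple_pair(["g", "is", "linked", "with", "d", "here"], 0, 4), SLConfig())
        expected = sum(dense_dot(a.pattern(p), b.pattern(p))
                       for p in ("fore_between", "between", "between_after"))
        assert k_gc(a, b) == pytest.approx(expected, abs=1e-12)

    def test_k_lc_self_is_one_and_disjoint_is_zero(self):
        cfg = SLConfig()
        # long sentences: no sentinel features shared between the two
        a = extract_local_context(
            simple_pair(["alpha", "beta", "G1", "gamma", "delta", "D1",
                         "epsilon", "zeta"], 2, 5), cfg)
        b = extract_local_context(
            simple_pair(["ONE", "TWO", "g2", "THREE", "FOUR", "d2",
                         "FIVE", "SIX"], 2, 5), cfg)
        assert k_lc(a, a) == pytest.approx(1.0, abs=1e-12)
        assert k_lc(a, b) == 0.0

    def test_k_lc_half_overlap_matches_count_oracle(self):
        cfg = SLConfig()
        a = extract_local_context(
            simple_pair(["alpha", "beta", "G1", "gamma", "delta", "D1",
                         "epsilon", "zeta"], 2, 5), cfg)
        c = extract_local_context(
            simple_pair(["alpha", "beta", "G1", "gamma", "delta", "D1",
                         "other", "words"], 2, 5), cfg)
        shared = len(a.features & c.features)
        assert k_lc(a, c) == pytest.approx(
            shared / math.sqrt(len(a.features) * len(c.features)), abs=1e-12)

    def test_k_sl_self_is_four_with_defaults(self):
        inst = simple_pair(["the", "gene", "EHD3", "is", "linked", "to", "MDD",
                            "in", "adults"], 2, 6)
        assert k_sl(inst, inst) == pytest.approx(4.0, abs=1e-12)

    def test_weight_zero_gc_reduces_to_lc(self):
        cfg = SLConfig(gc_weight=0.0, lc_weight=1.0)
        x = simple_pair(["a", "EHD3", "b", "MDD", "c"], 1, 3)
        y = simple_pair(["a", "TP53", "b", "asthma", "c"], 1, 3)
        expected = k_lc(extract_local_context(x, cfg), extract_local_context(y, cfg))
        assert k_sl(x, y, cfg) == pytest.approx(expected, abs=1e-12)


class TestProperties:
    def test_symmetry_over_synthetic_instances(self, synthetic_50):
        for x, y in itertools.islice(itertools.combinations(synthetic_50, 2), 100):
            assert abs(k_sl(x, y) - k_sl(y, x)) < 1e-12

    def test_gram_is_positive_semidefinite(self, synthetic_50):
        from befree.classifier import compute_gram
        gram = compute_gram(synthetic_50, kernel="sl")
        assert np.abs(gram - gram.T).max() < 1e-12
        assert np.linalg.eigvalsh(gram).min() >= -1e-8

    def test_adding_shared_between_token_never_decreases_k_gc(self):
        cfg = SLConfig()
        base_a = ["g", "is", "associated", "with", "d"]
        base_b = ["g", "is", "linked", "with", "d"]
        before = k_gc(
            extract_global_context(simple_pair(base_a, 0, 4), cfg),
            extract_global_context(simple_pair(base_b, 0, 4), cfg), cfg)
        grown_a = ["g", "is", "strongly", "associated", "with", "d"]
        grown_b = ["g", "is", "strongly", "linked", "with", "d"]
        after = k_gc(
            extract_global_context(simple_pair(grown_a, 0, 5), cfg),
            extract_global_context(simple_pair(grown_b, 0, 5), cfg), cfg)
        assert after >= before - 1e-12
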