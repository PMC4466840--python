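"""Dependency kernel: path/LCS oracles, walk features, kernel laws."""

import itertools

import networkx as nx
import numpy as np
import pytest

from befree.kernel_dep import (
    DepConfig, UP, DOWN, extract_walk_features, head_token, k_combined,
    k_dep, k_dep_instances, shortest_path,
)
from befree.kernel_sl import k_sl
from befree.text_model import DependencyGraph, EntityMention
from conftest import build_sentence, make_pair


def tree_sentence():
    """'EHD3 is associated with MDD': C1 <-nsubjpass- associated -prep/pobj-> C2."""
    return build_sentence(
        ["EHD3", "is", "associated", "with", "MDD"],
        mentions=[("g", "GENE", 0, 0, {"30845"}),
                  ("d", "DISEASE", 4, 4, {"C1269683"})],
        edges=[(2, 0, "nsubjpass"), (2, 1, "auxpass"), (2, 3, "prep"), (3, 4, "pobj")],
        root=2,
    )


class TestHeadToken:
    def test_single_token_mention(self):
        sent = tree_sentence()
        assert head_token(sent.mention_by_id("g"), sent.graph) == 0

    def test_multi_token_span_head_is_externally_governed_token(self):
        # "major depressive disorder": internal modifiers governed by "disorder"
        sent = build_sentence(
            ["EHD3", "causes", "major", "depressive", "disorder"],
            mentions=[("g", "GENE", 0, 0, {"1"}),
                      ("d", "DISEASE", 2, 4, {"C1"})],
            edges=[(1, 0, "nsubj"), (1, 4, "dobj"), (4, 2, "amod"), (4, 3, "amod")],
            root=1,
        )
        graph = sent.graph
        mention = sent.mention_by_id("d")
        assert head_token(mention, graph) == 4
        # exhaustive governor scan oracle: tokens with all governors inside span
        span = set(range(2, 5))
        external = [i for i in span
                    if any(g not in span for g, _ in graph.governors(i))]
        assert external == [4]

    def test_all_external_governors_falls_back_to_last(self):
        sent = build_sentence(
            ["alpha", "beta", "gamma"],
            mentions=[("m", "DISEASE", 0, 1, {"C1"})],
            edges=[(2, 0, "dep"), (2, 1, "dep")],
            root=2,
        )
        assert head_token(sent.mention_by_id("m"), sent.graph) == 1


class TestShortestPath:
    def test_lcs_is_common_governor(self):
        sent = tree_sentence()
        path = shortest_path(sent.graph, 0, 4)
        assert path.nodes == (0, 2, 3, 4)
        assert path.nodes[path.lcs_index] == 2  # "associated"
        assert path.edges[0] == ("nsubjpass", UP)
        assert path.edges[-1] == ("pobj", DOWN)

    def test_direct_dependent_lcs_is_endpoint(self):
        graph = DependencyGraph(
            nodes=frozenset({0, 1}), edges=((0, 1, "dobj"),), root=0)
        path = shortest_path(graph, 0, 1)
        assert len(path.edges) == 1
        assert path.lcs_index == 0

    def test_disconnected_components_give_empty_path(self):
        graph = DependencyGraph(
            nodes=frozenset({0, 1, 2, 3}),
            edges=((0, 1, "a"), (2, 3, "b")), root=0)
        assert shortest_path(graph, 0, 3).empty

    def test_random_trees_match_dijkstra_and_ancestor_oracles(self):
        rng = np.random.RandomState(1234)
        for _ in range(200):
            n = 12
            # random rooted tree: each node attaches to a random predecessor
            parents = [None] + [int(rng.randint(0, i)) for i in range(1, n)]
            edges = tuple((parents[i], i, f"rel{rng.randint(4)}")
                          for i in range(1, n))
            graph = DependencyGraph(nodes=frozenset(range(n)), edges=edges, root=0)
            h1, h2 = rng.choice(n, size=2, replace=False)
            path = shortest_path(graph, int(h1), int(h2))

            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from((u, v) for u, v, _ in edges)
            expected_len = nx.dijkstra_path_length(g, int(h1), int(h2))
            assert len(path.edges) == expected_len

            # LCS == lowest common ancestor by ancestor-set intersection
            def ancestors(x):
                out = [x]
                while parents[x] is not None:
                    x = parents[x]
                    out.append(x)
                return out
            a1, a2 = ancestors(int(h1)), ancestors(int(h2))
            lca = next(a for a in a1 if a in set(a2))
            assert path.nodes[path.lcs_index] == lca


class TestWalkFeatures:
    def test_one_vwalk_per_edge_one_ewalk_per_internal_node(self):
        sent = tree_sentence()
        inst = make_pair(sent, "g", "d")
        path = shortest_path(sent.graph, 0, 4)
        walks = extract_walk_features(path, inst, DepConfig())
        assert sum(1 for k in walks.counts if k[0] == "v") == 3
        assert sum(1 for k in walks.counts if k[0] == "e") == 2

    def test_stem_vwalk_uses_stemmer_output(self):
        sent = tree_sentence()
        inst = make_pair(sent, "g", "d")
        path = shortest_path(sent.graph, 0, 4)
        walks = extract_walk_features(
            path, inst, DepConfig(vwalk_feature="STEM", include_ewalks=False))
        assert ("v", "CANDIDATE1", "nsubjpass↑", "associ") in walks.counts

    def test_role_ewalk(self):
        sent = build_sentence(
            ["EHD3", "influences", "MDD"],
            mentions=[("g", "GENE", 0, 0, {"1"}), ("d", "DISEASE", 2, 2, {"C1"})],
            edges=[(1, 0, "nsubj"), (1, 2, "dobj")],
            root=1,
        )
        inst = make_pair(sent, "g", "d")
        path = shortest_path(sent.graph, 0, 2)
        walks = extract_walk_features(
            path, inst, DepConfig(ewalk_feature="ROLE", include_vwalks=False))
        assert ("e", "nsubj↑", "OTHER", "dobj↓") in walks.counts

    def test_empty_path_yields_empty_vector(self):
        sent = tree_sentence()
        inst = make_pair(sent, "g", "d")
        from befree.kernel_dep import EMPTY_PATH
        assert not extract_walk_features(EMPTY_PATH, inst, DepConfig())


class TestKernel:
    def _walks(self, cfg=None):
        sent = tree_sentence()
        inst = make_pair(sent, "g", "d")
        path = shortest_path(sent.graph, 0, 4)
        return extract_walk_features(path, inst, cfg or DepConfig())

    def test_self_similarity_is_one(self):
        w = self._walks()
        assert k_dep(w, w) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_walks_are_orthogonal(self):
        a = self._walks(DepConfig(vwalk_feature="LEMMA", include_ewalks=False))
        sent = build_sentence(
            ["TP53", "regulates", "apoptosis"],
            mentions=[("g", "GENE", 0, 0, {"1"}), ("d", "DISEASE", 2, 2, {"C1"})],
            edges=[(1, 0, "nsubj"), (1, 2, "dobj")],
            root=1,
        )
        inst = make_pair(sent, "g", "d")
        b = extract_walk_features(
            shortest_path(sent.graph, 0, 2), inst,
            DepConfig(vwalk_feature="LEMMA", include_ewalks=False))
        assert k_dep(a, b) == 0.0

    def test_matches_dense_oracle(self):
        a, b = self._walks(), self._walks(DepConfig(vwalk_feature="POS"))
        vocab = sorted(set(a.counts) | set(b.counts), key=repr)
        va = np.array([a.counts.get(k, 0) for k in vocab], dtype=float)
        vb = np.array([b.counts.get(k, 0) for k in vocab], dtype=float)
        expected = va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))
        assert k_dep(a, b) == pytest.approx(float(expected), abs=1e-12)

    def test_path_reversal_symmetry(self, synthetic_50):
        for x, y in itertools.islice(itertools.combinations(synthetic_50, 2), 50):
            assert abs(k_dep_instances(x, y) - k_dep_instances(y, x)) < 1e-12


class TestCombined:
    def test_weight_degeneracy(self, synthetic_50):
        x, y = synthetic_50[0], synthetic_50[1]
        assert k_combined(x, y, [("sl", 1.0), ("dep", 0.0)]) == \
            pytest.approx(k_sl(x, y), abs=1e-12)

    def test_additivity_on_self(self, synthetic_50):
        x = synthetic_50[0]
        assert k_combined(x, x, [("sl", 1.0), ("dep", 1.0)]) == \
            pytest.approx(k_sl(x, x) + 1.0, abs=1e-12)

    def test_unknown_kernel_id_rejected(self, synthetic_50):
        with pytest.raises(ValueError, match="unknown kernel"):
            k_combined(synthetic_50[0], synthetic_50[1], [("bogus", 1.0)])

    @pytest.mark.parametrize("kernel", ["dep", "sl+dep"])
    def test_gram_psd(self, synthetic_50, kernel):
        from befree.classifier import compute_gram
        gram = compute_gram(synthetic_50, kernel=kernel)
        assert np.abs(gram - gram.T).max() < 1e-12
        assert np.linalg.eigvalsh(gram).min() >= -1e-8

    @pytest.mark.parametrize("vwalk,ewalk", [
        ("TOKEN", "POS"), ("STEM", "ROLE"), ("LEMMA", "LEMMA"), ("POS", "TOKEN"),
    ])
    def test_gram_psd_across_dep_configs(self, synthetic_50, vwalk, ewalk):
        from befree.classifier import compute_gram
        cfg = DepConfig(vwalk_feature=vwalk, ewalk_feature=ewalk)
        gram = compute_gram(synthetic_50, kernel="dep", dep_config=cfg)
        assert np.linalg.eigvalsh(gram).min() >= -1e-8
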