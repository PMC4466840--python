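"""Dependency Kernel: walk features along the shortest dependency path.

The shortest path between the two candidate entities is extracted from the
sentence's dependency graph (breadth-first search over the undirected view).
Each traversed edge records its relation label and direction — UP when moving
from a dependent to its governor, DOWN when descending. The Least Common
Subsumer (LCS) is the common governor of both candidates: the node where the
traversal flips from UP to DOWN, or an endpoint when the path is monotone.

Two walk feature families are read off the path:

* **v-walk** per edge: ``(node_i, edge_{i,i+1}, node_{i+1})``
* **e-walk** per internal node: ``(edge_{i-1,i}, node_i, edge_{i,i+1})``

Node features are configurable (surface token, stem, lemma, POS, or the
candidate/other role); candidate nodes' lexical features are blinded to
placeholders by default. The kernel is the cosine-normalized dot product of
walk-count vectors; candidates in disconnected parse components contribute
zero kernel mass rather than being excluded.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
import math

from .kernel_sl import SLConfig, k_sl
from .text_model import CandidateInstance, DependencyGraph, EntityMention

__all__ = [
    "DepConfig", "PathRepresentation", "WalkFeatureVector",
    "head_token", "shortest_path", "extract_walk_features",
    "k_dep", "k_dep_instances", "k_combined",
    "CANDIDATE1_NODE", "CANDIDATE2_NODE",
]

UP = "UP"
DOWN = "DOWN"
NODE_FEATURES = ("TOKEN", "STEM", "LEMMA", "POS", "ROLE")
CANDIDATE1_NODE = "CANDIDATE1"
CANDIDATE2_NODE = "CANDIDATE2"


@dataclass(frozen=True)
class DepConfig:
    vwalk_feature: str = "LEMMA"
    ewalk_feature: str = "ROLE"
    include_vwalks: bool = True
    include_ewalks: bool = True
    blind_candidates: bool = True
    include_direction: bool = True

    def __post_init__(self) -> None:
        for feat in (self.vwalk_feature, self.ewalk_feature):
            if feat not in NODE_FEATURES:
                raise ValueError(f"unknown node feature {feat!r}")
        if not (self.include_vwalks or self.include_ewalks):
            raise ValueError("at least one of v-walks/e-walks must be enabled")


@dataclass(frozen=True)
class PathRepresentation:
    nodes: tuple[int, ...]                    # token indices, candidate1 -> candidate2
    edges: tuple[tuple[str, str], ...]        # (relation label, UP|DOWN)
    lcs_index: int

    @property
    def empty(self) -> bool:
        return not self.nodes


EMPTY_PATH = PathRepresentation(nodes=(), edges=(), lcs_index=-1)


@dataclass
class WalkFeatureVector:
    counts: dict[tuple, int]

    def __bool__(self) -> bool:
        return bool(self.counts)


def head_token(mention: EntityMention, graph: DependencyGraph) -> int:
    """Syntactic head of a mention span: the token governed from outside.

    Falls back to the last span token when zero or several such tokens exist.
    """
    first, last = mention.token_span
    span = set(range(first, last + 1))
    external = [
        i for i in span
        if any(g not in span for g, _ in graph.governors(i))
        or (not graph.governors(i) and i == graph.root)
    ]
    if len(external) == 1:
        return external[0]
    return last


def shortest_path(graph: DependencyGraph, h1: int, h2: int) -> PathRepresentation:
    """BFS shortest path between two tokens over the undirected parse view."""
    if h1 == h2:
        raise ValueError("path endpoints must differ")
    if h1 not in graph.nodes or h2 not in graph.nodes:
        raise ValueError("path endpoint not in graph")
    adj = graph.undirected_adjacency()
    prev: dict[int, tuple[int, str, bool]] = {}
    seen = {h1}
    queue = deque([h1])
    while queue:
        u = queue.popleft()
        if u == h2:
            break
        for v, rel, toward_gov in adj[u]:
            if v not in seen:
                seen.add(v)
                prev[v] = (u, rel, toward_gov)
                queue.append(v)
    if h2 not in seen:
        return EMPTY_PATH

    nodes: list[int] = [h2]
    edges: list[tuple[str, str]] = []
    cur = h2
    while cur != h1:
        u, rel, toward_gov = prev[cur]
        # stored step was u -> cur; direction relative to the forward traversal
        edges.append((rel, UP if toward_gov else DOWN))
        nodes.append(u)
        cur = u
    nodes.reverse()
    edges.reverse()

    lcs = 0
    for i, (_, direction) in enumerate(edges):
        if direction == UP:
            lcs = i + 1
        else:
            break
    return PathRepresentation(nodes=tuple(nodes), edges=tuple(edges), lcs_index=lcs)


def _node_feature(
    instance: CandidateInstance, idx: int, feature: str, cfg: DepConfig,
    h1: int, h2: int,
) -> str:
    if feature == "ROLE":
        return "CANDIDATE" if idx in (h1, h2) else "OTHER"
    if cfg.blind_candidates and idx == h1:
        return CANDIDATE1_NODE
    if cfg.blind_candidates and idx == h2:
        return CANDIDATE2_NODE
    tok = instance.sentence.tokens[idx]
    if feature == "TOKEN":
        return tok.surface.lower()
    if feature == "STEM":
        return tok.stem
    if feature == "LEMMA":
        return tok.lemma
    return tok.pos  # POS


def _edge_key(edge: tuple[str, str], cfg: DepConfig) -> str:
    rel, direction = edge
    return f"{rel}{'↑' if direction == UP else '↓'}" if cfg.include_direction else rel


def extract_walk_features(
    path: PathRepresentation,
    instance: CandidateInstance,
    cfg: DepConfig | None = None,
) -> WalkFeatureVector:
    cfg = cfg or DepConfig()
    counts: dict[tuple, int] = {}
    if path.empty:
        return WalkFeatureVector(counts)
    h1, h2 = path.nodes[0], path.nodes[-1]
    if cfg.include_vwalks:
        for i, edge in enumerate(path.edges):
            key = (
                "v",
                _node_feature(instance, path.nodes[i], cfg.vwalk_feature, cfg, h1, h2),
                _edge_key(edge, cfg),
                _node_feature(instance, path.nodes[i + 1], cfg.vwalk_feature, cfg, h1, h2),
            )
            counts[key] = counts.get(key, 0) + 1
    if cfg.include_ewalks:
        for i in range(1, len(path.nodes) - 1):
            key = (
                "e",
                _edge_key(path.edges[i - 1], cfg),
                _node_feature(instance, path.nodes[i], cfg.ewalk_feature, cfg, h1, h2),
                _edge_key(path.edges[i], cfg),
            )
            counts[key] = counts.get(key, 0) + 1
    return WalkFeatureVector(counts)


def k_dep(a: WalkFeatureVector, b: WalkFeatureVector) -> float:
    """Cosine-normalized dot product over walk counts; empty vectors give 0."""
    if not a or not b:
        return 0.0
    dot = sum(c * b.counts[k] for k, c in a.counts.items() if k in b.counts)
    na = math.sqrt(sum(c * c for c in a.counts.values()))
    nb = math.sqrt(sum(c * c for c in b.counts.values()))
    return dot / (na * nb)


def _instance_walks(instance: CandidateInstance, cfg: DepConfig) -> WalkFeatureVector:
    graph = instance.sentence.graph
    if graph is None:
        return WalkFeatureVector({})
    h1 = head_token(instance.entity1, graph)
    h2 = head_token(instance.entity2, graph)
    path = shortest_path(graph, h1, h2)
    return extract_walk_features(path, instance, cfg)


def k_dep_instances(
    x: CandidateInstance, y: CandidateInstance, cfg: DepConfig | None = None
) -> float:
    cfg = cfg or DepConfig()
    return k_dep(_instance_walks(x, cfg), _instance_walks(y, cfg))


KERNEL_IDS = ("sl", "dep")


def k_combined(
    x: CandidateInstance,
    y: CandidateInstance,
    spec: list[tuple[str, float]] | None = None,
    sl_config: SLConfig | None = None,
    dep_config: DepConfig | None = None,
) -> float:
    """Weighted sum of kernels, default ``[(sl, 1), (dep, 1)]``."""
    spec = spec or [("sl", 1.0), ("dep", 1.0)]
    total = 0.0
    for kid, weight in spec:
        if weight < 0:
            raise ValueError("kernel weights must be non-negative")
        if kid == "sl":
            total += weight * k_sl(x, y, sl_config)
        elif kid == "dep":
            total += weight * k_dep_instances(x, y, dep_config)
        else:
            raise ValueError(f"unknown kernel id {kid!r}")
    return total
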