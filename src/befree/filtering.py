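"""Prioritization filters for large-scale text-mined association sets.

Two quality concerns drive the workflow. Abstracts that yield a very large
number of distinct associations are usually long coordination-heavy sentences
that are error-prone to mine, so all pairs from abstracts reporting more than
``max_assoc_per_abstract`` associations (default 20) are removed outright.
Associations supported by a single publication are then triaged by a decision
tree: keep a record if it has at least ``min_pmids`` supporting publications,
or appears in the curated reference, or its lone publication appeared in a
journal whose impact factor reaches ``if_threshold``. A missing impact factor
is explicit (``None``) and distinct from zero.

Each filter returns a subset of its input; with neutral thresholds
(``min_pmids=0``) the decision-tree filter is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

from .scoring import AssociationRecord

__all__ = [
    "JournalInfo", "FilterConfig", "drop_dense_abstracts",
    "decision_tree_filter", "stratify_singletons", "FilterAudit",
]

#: pmid -> (journal name, impact factor or None, publication year)
JournalInfo = dict[str, tuple[str, float | None, int]]

DEFAULT_IF_BIN_EDGES = (0.0, 2.5, 5.0, 10.0)


@dataclass(frozen=True)
class FilterConfig:
    max_assoc_per_abstract: int = 20
    min_pmids: int = 2
    if_threshold: float = 2.5
    keep_if_in_reference: bool = True

    def __post_init__(self) -> None:
        if self.max_assoc_per_abstract < 0 or self.min_pmids < 0 or self.if_threshold < 0:
            raise ValueError("filter thresholds must be non-negative")


@dataclass
class FilterAudit:
    kept_by_support: int = 0
    kept_by_reference: int = 0
    kept_by_impact: int = 0
    dropped: int = 0


def drop_dense_abstracts(
    records: Sequence[AssociationRecord], cfg: FilterConfig | None = None
) -> list[AssociationRecord]:
    """Remove all evidence coming from abstracts reporting too many associations.

    An abstract is *dense* when strictly more than ``max_assoc_per_abstract``
    distinct associations cite it; records supported only by dense abstracts
    are dropped, and dense PMIDs are stripped from the support of the rest.
    """
    cfg = cfg or FilterConfig()
    per_abstract: dict[str, int] = {}
    for r in records:
        for pmid in r.pmids:
            per_abstract[pmid] = per_abstract.get(pmid, 0) + 1
    dense = {p for p, n in per_abstract.items() if n > cfg.max_assoc_per_abstract}
    out = []
    for r in records:
        remaining = r.pmids - dense
        if not remaining:
            continue
        if remaining == r.pmids:
            out.append(r)
        else:
            out.append(replace(
                r, pmids=frozenset(remaining),
                evidence=tuple(e for e in r.evidence if e[0] not in dense),
            ))
    return out


def drop_dense_abstract_pairs(instances, cfg: FilterConfig | None = None) -> list:
    """Sentence-pair variant: drop every candidate pair from dense abstracts.

    An abstract's association count is the number of distinct normalized
    (gene, disease) identifier pairs among its candidate instances.
    """
    cfg = cfg or FilterConfig()
    assoc_of_doc: dict[str, set] = {}
    for inst in instances:
        key = (tuple(sorted(inst.entity1.concept_ids)),
               tuple(sorted(inst.entity2.concept_ids)))
        assoc_of_doc.setdefault(inst.sentence.doc_id, set()).add(key)
    dense = {d for d, s in assoc_of_doc.items() if len(s) > cfg.max_assoc_per_abstract}
    return [inst for inst in instances if inst.sentence.doc_id not in dense]


def _singleton_if(record: AssociationRecord, journals: JournalInfo) -> float | None:
    (pmid,) = record.pmids
    info = journals.get(pmid)
    return info[1] if info is not None else None


DecisionRule = Callable[[int, bool, "float | None"], bool]


def default_rule(cfg: FilterConfig) -> DecisionRule:
    def rule(n_pmids: int, in_reference: bool, impact: float | None) -> bool:
        if n_pmids >= cfg.min_pmids:
            return True
        if cfg.keep_if_in_reference and in_reference:
            return True
        return n_pmids == 1 and impact is not None and impact >= cfg.if_threshold
    return rule


def decision_tree_filter(
    records: Sequence[AssociationRecord],
    reference: Iterable[tuple[str, str]],
    journals: JournalInfo,
    cfg: FilterConfig | None = None,
    rule: DecisionRule | None = None,
) -> tuple[list[AssociationRecord], FilterAudit]:
    """Triage records by support count, reference membership and journal IF.

    The rule is a configurable boolean expression over
    ``(n_pmids, in_reference, impact_factor_of_singleton)``; the default
    realizes keep-if ``n >= min_pmids OR in_reference OR
    (singleton AND IF >= if_threshold)``. Multi-publication records never
    consult the IF branch.
    """
    cfg = cfg or FilterConfig()
    rule = rule or default_rule(cfg)
    ref = set(reference)
    audit = FilterAudit()
    kept: list[AssociationRecord] = []
    for r in records:
        n = len(r.pmids)
        in_ref = r.key in ref
        impact = _singleton_if(r, journals) if n == 1 else None
        if rule(n, in_ref, impact):
            kept.append(r)
            if n >= cfg.min_pmids:
                audit.kept_by_support += 1
            elif cfg.keep_if_in_reference and in_ref:
                audit.kept_by_reference += 1
            else:
                audit.kept_by_impact += 1
        else:
            audit.dropped += 1
    return kept, audit


def stratify_singletons(
    records: Sequence[AssociationRecord],
    journals: JournalInfo,
    reference: Iterable[tuple[str, str]] = (),
    if_bin_edges: Sequence[float] = DEFAULT_IF_BIN_EDGES,
) -> dict[str, dict]:
    """Tables over singleton-publication records: by year and by IF bin.

    Each cell carries ``(total, in_reference)`` so curated-coverage overlays
    can be drawn directly. IF bins are half-open on the left —
    ``(0, 2.5], (2.5, 5], (5, 10], > 10`` by default — with an explicit
    ``no IF`` bin for publications without an impact factor.
    """
    ref = set(reference)
    by_year: dict[int, list[int]] = {}
    edges = list(if_bin_edges)
    labels = ["no IF"] + [
        f"({edges[i]}, {edges[i + 1]}]" for i in range(len(edges) - 1)
    ] + [f"> {edges[-1]}"]
    by_if: dict[str, list[int]] = {lab: [0, 0] for lab in labels}

    for r in records:
        if len(r.pmids) != 1:
            continue
        (pmid,) = r.pmids
        info = journals.get(pmid)
        in_ref = int(r.key in ref)
        year = info[2] if info else 0
        cell = by_year.setdefault(year, [0, 0])
        cell[0] += 1
        cell[1] += in_ref
        impact = info[1] if info else None
        if impact is None:
            label = "no IF"
        else:
            label = f"> {edges[-1]}"
            for i in range(len(edges) - 1):
                if edges[i] < impact <= edges[i + 1]:
                    label = f"({edges[i]}, {edges[i + 1]}]"
                    break
        by_if[label][0] += 1
        by_if[label][1] += in_ref
    return {
        "by_year": {y: tuple(v) for y, v in sorted(by_year.items())},
        "by_impact_factor": {k: tuple(v) for k, v in by_if.items()},
    }
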