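"""Aggregation of sentence-level predictions into scored associations.

TRUE-classified candidate pairs are grouped by normalized identifiers
(Entrez Gene ID, UMLS CUI) into :class:`AssociationRecord` objects carrying
their supporting PMIDs and evidence sentences. Records are scored with the
DisGeNET evidence score

    S = S_CURATED + S_PREDICTED + S_LITERATURE

where curated sources (UniProt, CTD human) contribute fixed weights 0.3 each,
animal-model sources (RGD/CTD rat, MGD/CTD mouse) 0.1 each, and each
literature-mining source j contributes min(cap_j, n_j * 100 / N_j) — n_j the
publications supporting the association in source j, N_j the total
publications in that source, capped at 0.08 (GAD) or 0.06 (LHGDN, text
mining). S lies in [0, 1] and is monotone in both sources and support.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .text_model import CandidateInstance

__all__ = [
    "AssociationRecord", "ScoreWeights", "aggregate", "disgenet_score",
    "compare_with_reference", "summarize_distributions",
    "CURATED_SOURCES", "PREDICTED_SOURCES", "LITERATURE_SOURCES",
]

CURATED_SOURCES = ("UNIPROT", "CTD_HUMAN")
PREDICTED_SOURCES = ("RGD", "CTD_RAT", "MGD", "CTD_MOUSE")
LITERATURE_SOURCES = ("GAD", "LHGDN", "BEFREE")
ALL_SOURCES = CURATED_SOURCES + PREDICTED_SOURCES + LITERATURE_SOURCES


@dataclass(frozen=True)
class AssociationRecord:
    gene_id: str
    disease_id: str
    pmids: frozenset[str] = frozenset()
    sources: frozenset[str] = frozenset()
    #: supporting-publication counts per literature source; BEFREE falls back
    #: to ``len(pmids)`` when absent.
    literature_support: Mapping[str, int] = field(default_factory=dict)
    evidence: tuple[tuple[str, str], ...] = ()   # (pmid, sentence text)

    def __post_init__(self) -> None:
        unknown = self.sources - set(ALL_SOURCES)
        if unknown:
            raise ValueError(f"unknown sources {sorted(unknown)}")
        if "BEFREE" in self.sources and not self.pmids:
            raise ValueError("text-mined records require at least one PMID")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_id, self.disease_id)

    def support(self, source: str) -> int:
        if source in self.literature_support:
            return self.literature_support[source]
        if source == "BEFREE":
            return len(self.pmids)
        return 0


@dataclass(frozen=True)
class ScoreWeights:
    w_uniprot: float = 0.3
    w_ctd_human: float = 0.3
    w_rat: float = 0.1
    w_mouse: float = 0.1
    max_gad: float = 0.08
    max_lhgdn: float = 0.06
    max_befree: float = 0.06
    #: total publications per literature source. The text-mining default is
    #: the publication count of the large-scale run this score parametrizes;
    #: it is dataset-dependent and always overridable.
    n_literature: Mapping[str, int] = field(
        default_factory=lambda: {"BEFREE": 355_976, "GAD": 135_000, "LHGDN": 100_000}
    )

    def cap(self, source: str) -> float:
        return {"GAD": self.max_gad, "LHGDN": self.max_lhgdn,
                "BEFREE": self.max_befree}[source]


def disgenet_score(record: AssociationRecord, weights: ScoreWeights | None = None) -> float:
    """DisGeNET evidence score in [0, 1] for one association record."""
    w = weights or ScoreWeights()
    s = 0.0
    if "UNIPROT" in record.sources:
        s += w.w_uniprot
    if "CTD_HUMAN" in record.sources:
        s += w.w_ctd_human
    if record.sources & {"RGD", "CTD_RAT"}:
        s += w.w_rat
    if record.sources & {"MGD", "CTD_MOUSE"}:
        s += w.w_mouse
    for source in LITERATURE_SOURCES:
        if source not in record.sources:
            continue
        total = w.n_literature.get(source)
        if not total or total <= 0:
            raise ValueError(
                f"literature source {source} present but no publication total configured"
            )
        n = record.support(source)
        s += min(w.cap(source), n * 100.0 / total)
    return s


def aggregate(
    predicted: Sequence[CandidateInstance],
    source: str = "BEFREE",
) -> tuple[list[AssociationRecord], int]:
    """Group TRUE-classified pairs by (gene id, disease CUI).

    Pairs whose mentions lack normalized concept identifiers are excluded and
    counted. Returns records sorted by key plus the excluded-pair count.
    """
    grouped: dict[tuple[str, str], dict] = {}
    excluded = 0
    for inst in predicted:
        g_ids = sorted(inst.entity1.concept_ids) if inst.entity1.semantic_type == "GENE" \
            else sorted(inst.entity2.concept_ids)
        d_ids = sorted(inst.entity2.concept_ids) if inst.entity2.semantic_type == "DISEASE" \
            else sorted(inst.entity1.concept_ids)
        if not g_ids or not d_ids:
            excluded += 1
            continue
        key = (g_ids[0], d_ids[0])
        slot = grouped.setdefault(key, {"pmids": set(), "evidence": []})
        slot["pmids"].add(inst.sentence.doc_id)
        slot["evidence"].append((inst.sentence.doc_id, inst.sentence.text))
    records = [
        AssociationRecord(
            gene_id=g, disease_id=d,
            pmids=frozenset(v["pmids"]),
            sources=frozenset({source}),
            evidence=tuple(sorted(set(v["evidence"]))),
        )
        for (g, d), v in sorted(grouped.items())
    ]
    return records, excluded


def compare_with_reference(
    records: Iterable[AssociationRecord],
    reference: Iterable[tuple[str, str]],
) -> dict[str, int]:
    """Overlap of mined associations with a curated reference list."""
    mined = {r.key for r in records}
    ref = set(reference)
    return {
        "befree_only": len(mined - ref),
        "reference_only": len(ref - mined),
        "shared": len(mined & ref),
    }


def summarize_distributions(records: Sequence[AssociationRecord]) -> dict:
    """Support/coverage histograms for a set of association records."""
    if not records:
        return {
            "pmids_per_association": {}, "associations_per_abstract": {},
            "genes_per_disease": {}, "diseases_per_gene": {},
            "mean_pmids_per_association": 0.0, "mean_associations_per_abstract": 0.0,
        }
    pmid_hist: dict[int, int] = {}
    per_abstract: dict[str, int] = {}
    genes_of: dict[str, set[str]] = {}
    diseases_of: dict[str, set[str]] = {}
    for r in records:
        k = len(r.pmids)
        pmid_hist[k] = pmid_hist.get(k, 0) + 1
        for pmid in r.pmids:
            per_abstract[pmid] = per_abstract.get(pmid, 0) + 1
        genes_of.setdefault(r.disease_id, set()).add(r.gene_id)
        diseases_of.setdefault(r.gene_id, set()).add(r.disease_id)

    def spectrum(sets: dict[str, set[str]]) -> dict[int, int]:
        out: dict[int, int] = {}
        for v in sets.values():
            out[len(v)] = out.get(len(v), 0) + 1
        return out

    abstract_hist: dict[int, int] = {}
    for count in per_abstract.values():
        abstract_hist[count] = abstract_hist.get(count, 0) + 1
    total_pmids = sum(k * v for k, v in pmid_hist.items())
    return {
        "pmids_per_association": pmid_hist,
        "associations_per_abstract": abstract_hist,
        "genes_per_disease": spectrum(genes_of),
        "diseases_per_gene": spectrum(diseases_of),
        "mean_pmids_per_association": total_pmids / len(records),
        "mean_associations_per_abstract":
            sum(per_abstract.values()) / len(per_abstract) if per_abstract else 0.0,
    }


def with_source(record: AssociationRecord, source: str,
                support: int | None = None) -> AssociationRecord:
    """Copy of *record* with an extra source (and optional support count)."""
    lit = dict(record.literature_support)
    if support is not None:
        lit[source] = support
    return replace(record, sources=record.sources | {source}, literature_support=lit)
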