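"""Semi-automatic gene-disease corpus construction from curated records.

Genetic-association archives record, per study, a gene, a disease phrase, a
positive/negative curator verdict and the sentence stating the claim — but
not where in the sentence the entities sit. This module turns such flat
records into a labelled relation corpus: a pluggable NER locates and
normalizes gene and disease mentions in the record's sentence, the curated
pair becomes a TRUE instance (fine label PA for positive, NA for negative
verdicts), and any other gene-disease co-occurrence in the same sentence that
no curator annotated becomes a FALSE instance.

Usable records must (i) carry a positive or negative association verdict,
(ii) state the association in a single sentence, and (iii) provide the Entrez
Gene identifier. Records failing (i) are kept separately as FALSE-candidate
material; records failing (ii) or (iii) are dropped.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .text_model import (
    AnnotatedSentence, CandidateInstance, EntityMention, PairLabel,
    sentence_from_text, GENE, DISEASE,
)

__all__ = [
    "GADRecord", "FilteredRecords", "CorpusBuildResult",
    "read_gad_tsv", "filter_records", "label_pairs", "build_corpus",
]

#: NER contract: sentence text -> AnnotatedSentence with normalized mentions.
NERFunction = Callable[[str, str], AnnotatedSentence]

_SENTENCE_SPLIT_RE = re.compile(r"[.!?](?=\s+[A-Z])")


@dataclass(frozen=True)
class GADRecord:
    record_id: str
    gene_symbol: str
    entrez_id: str | None
    disease_phrase: str
    association: str              # positive | negative | unannotated
    sentence: str
    pmid: str


GAD_DEFAULT_COLUMNS = {
    "record_id": "id", "gene_symbol": "gene", "entrez_id": "entrez_id",
    "disease_phrase": "disease", "association": "association",
    "sentence": "sentence", "pmid": "pmid",
}


def read_gad_tsv(path: str | Path, columns: dict[str, str] | None = None) -> list[GADRecord]:
    cols = columns or GAD_DEFAULT_COLUMNS
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            assoc = row[cols["association"]].strip().lower()
            records.append(GADRecord(
                record_id=row[cols["record_id"]],
                gene_symbol=row[cols["gene_symbol"]].strip(),
                entrez_id=row[cols["entrez_id"]].strip() or None,
                disease_phrase=row[cols["disease_phrase"]].strip(),
                association=assoc if assoc in {"positive", "negative"} else "unannotated",
                sentence=row[cols["sentence"]].strip(),
                pmid=row[cols["pmid"]].strip(),
            ))
    return records


def _is_single_sentence(text: str) -> bool:
    return bool(text) and not _SENTENCE_SPLIT_RE.search(text)


@dataclass
class FilteredRecords:
    usable: list[GADRecord] = field(default_factory=list)
    false_candidates: list[GADRecord] = field(default_factory=list)
    dropped: int = 0


def filter_records(records: Iterable[GADRecord]) -> FilteredRecords:
    """Apply the usability criteria for TRUE-candidate records.

    Retained iff the curator verdict is positive or negative, the statement is
    one sentence, and an Entrez identifier is present. Records with a usable
    sentence but no verdict are kept apart as FALSE-candidate material.
    """
    out = FilteredRecords()
    for r in records:
        if not _is_single_sentence(r.sentence):
            out.dropped += 1
            continue
        if r.association in {"positive", "negative"}:
            if r.entrez_id is None:
                out.dropped += 1
            else:
                out.usable.append(r)
        else:
            out.false_candidates.append(r)
    return out


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", re.sub(r"[^\w\s]", " ", text.lower())).strip()


def _disease_matches(mention: EntityMention, record: GADRecord) -> bool:
    """Containment either way on normalized strings, or a shared CUI when the
    record's disease phrase is itself a CUI."""
    phrase = _normalize(record.disease_phrase)
    surface = _normalize(mention.surface)
    if phrase and surface and (phrase in surface or surface in phrase):
        return True
    return record.disease_phrase.strip().upper() in mention.concept_ids


@dataclass
class LabelResult:
    instances: list[CandidateInstance] = field(default_factory=list)
    skipped: bool = False


def label_pairs(
    sentence: AnnotatedSentence,
    record: GADRecord,
    curated_siblings: Sequence[GADRecord] = (),
) -> LabelResult:
    """Label gene-disease mention pairs in a NER-annotated record sentence.

    The leftmost gene mention matching the record's Entrez id, paired with the
    leftmost disease mention matching the record's disease phrase, becomes the
    TRUE instance (PA for positive, NA for negative verdicts). Every other
    gene-disease co-occurrence becomes FALSE — unless another curated record
    for the same publication (``curated_siblings``) claims that pair, which
    keeps TRUE and FALSE sets disjoint by construction. If NER finds no
    curated gene or disease, the record is skipped (it contributes to neither
    class).
    """
    genes = [m for m in sentence.mentions if m.semantic_type == GENE]
    diseases = [m for m in sentence.mentions if m.semantic_type == DISEASE]
    anchor_gene = next(
        (m for m in genes if record.entrez_id and record.entrez_id in m.concept_ids),
        None,
    )
    anchor_disease = next((m for m in diseases if _disease_matches(m, record)), None)

    result = LabelResult()
    curated = record.association in {"positive", "negative"}
    if curated and (anchor_gene is None or anchor_disease is None):
        result.skipped = True
        return result

    def curated_elsewhere(g: EntityMention, d: EntityMention) -> bool:
        for sib in curated_siblings:
            if sib is record or sib.pmid != record.pmid:
                continue
            if (sib.entrez_id and sib.entrez_id in g.concept_ids
                    and _disease_matches(d, sib)):
                return True
        return False

    fine = "PA" if record.association == "positive" else "NA"
    for g in genes:
        for d in diseases:
            e1, e2 = (g, d) if g.token_span < d.token_span else (d, g)
            try:
                if curated and g is anchor_gene and d is anchor_disease:
                    inst = CandidateInstance(sentence, e1, e2, PairLabel.from_fine(fine))
                elif curated_elsewhere(g, d):
                    continue
                else:
                    inst = CandidateInstance(sentence, e1, e2,
                                             PairLabel(binary="FALSE", fine="FA"))
            except ValueError:      # overlapping/nested mention pair
                continue
            result.instances.append(inst)
    return result


@dataclass
class CorpusBuildResult:
    sentences: list[AnnotatedSentence] = field(default_factory=list)
    instances: list[CandidateInstance] = field(default_factory=list)
    stats: dict[str, int] = field(default_factory=dict)


def build_corpus(records: Sequence[GADRecord], ner: NERFunction) -> CorpusBuildResult:
    """Run the full semi-automatic pipeline: filter, NER, pair labelling.

    Deterministic given records and NER; duplicate records collapse on
    (pmid, sentence, gene, disease). The stats table reports TRUE/FALSE/PA/NA
    counts plus skip counters.
    """
    filtered = filter_records(records)
    result = CorpusBuildResult()
    stats = {"TRUE": 0, "FALSE": 0, "PA": 0, "NA": 0,
             "skipped_ner": 0, "dropped_usability": filtered.dropped,
             "duplicates": 0}
    seen_records: set[tuple[str, str, str, str]] = set()
    seen_instances: set[str] = set()

    for r in [*filtered.usable, *filtered.false_candidates]:
        dedup_key = (r.pmid, r.sentence, r.gene_symbol, r.disease_phrase)
        if dedup_key in seen_records:
            stats["duplicates"] += 1
            continue
        seen_records.add(dedup_key)
        sentence = ner(r.sentence, r.pmid)
        labelled = label_pairs(sentence, r, curated_siblings=filtered.usable)
        if labelled.skipped:
            stats["skipped_ner"] += 1
            continue
        new = [i for i in labelled.instances if i.uid not in seen_instances]
        if not new:
            continue
        if sentence.id not in {s.id for s in result.sentences}:
            result.sentences.append(sentence)
        for inst in new:
            seen_instances.add(inst.uid)
            assert inst.label is not None
            stats[inst.label.binary] += 1
            if inst.label.fine in ("PA", "NA"):
                stats[inst.label.fine] += 1
        result.instances.extend(new)
    result.stats = stats
    return result
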