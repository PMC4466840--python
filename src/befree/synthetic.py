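"""Deterministic generators for annotated sentences and association tables.

Every module of the package is testable offline through two generators:

``generate_corpus``
    Template sentences over gene/disease slots with gold PA/NA/FA labels and
    dependency skeletons, run through the deterministic fallback
    pre-processor. Positive templates assert an association, negative
    templates deny one, and false-association templates merely co-occur the
    entities — so classes are linguistically separable by construction, which
    is what parameter-recovery tests need. Label counts follow the template
    mix exactly (largest-remainder apportionment), not sampling.

``generate_association_table``
    Gene-disease association records whose publications-per-association
    counts follow a truncated power law calibrated so the singleton fraction
    matches the configured value (default 0.685, the share observed in
    large-scale literature mining), plus journal impact factors drawn from a
    categorical distribution over IF bins (including an explicit no-IF mass)
    and a Bernoulli reference-membership flag.

The generators emulate the *structure* of literature-mined data — label
schemes, parse trees, long-tailed support distributions — not the lexical
richness of MEDLINE: template vocabulary is tiny and sentence syntax is
fixed per template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .filtering import JournalInfo
from .scoring import AssociationRecord
from .text_model import (
    AnnotatedSentence, CandidateInstance, DependencyGraph, EntityMention,
    PairLabel, Token, GENE, DISEASE,
)
from .preprocess import DEFAULT_PREPROCESSOR

__all__ = [
    "SentenceTemplate", "GeneratorConfig", "AssociationTableConfig",
    "generate_corpus", "generate_association_table",
    "expected_retained_fraction", "TEMPLATES",
]


@dataclass(frozen=True)
class SentenceTemplate:
    """Token pattern with GENE/DISEASE slots, gold label and parse skeleton.

    ``heads`` gives the 0-based governor per token (-1 for the root) and
    ``relations`` the dependency label per token; the skeleton must be a tree.
    """

    tokens: tuple[str, ...]
    label: str                        # PA | NA | FA
    heads: tuple[int, ...]
    relations: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.tokens.count("GENE") == 1 and self.tokens.count("DISEASE") == 1
        assert len(self.heads) == len(self.tokens) == len(self.relations)
        assert self.heads.count(-1) == 1


# Parse skeletons are hand-built basic-dependency trees.
TEMPLATES: tuple[SentenceTemplate, ...] = (
    SentenceTemplate(
        tokens=("GENE", "is", "associated", "with", "DISEASE"),
        label="PA",
        heads=(2, 2, -1, 2, 3),
        relations=("nsubjpass", "auxpass", "root", "prep", "pobj"),
    ),
    SentenceTemplate(
        tokens=("mutations", "in", "GENE", "increase", "the", "risk", "of", "DISEASE"),
        label="PA",
        heads=(3, 0, 1, -1, 5, 3, 5, 6),
        relations=("nsubj", "prep", "pobj", "root", "det", "dobj", "prep", "pobj"),
    ),
    SentenceTemplate(
        tokens=("GENE", "variants", "confer", "susceptibility", "to", "DISEASE"),
        label="PA",
        heads=(1, 2, -1, 2, 3, 4),
        relations=("nn", "nsubj", "root", "dobj", "prep", "pobj"),
    ),
    SentenceTemplate(
        tokens=("GENE", "is", "not", "associated", "with", "DISEASE"),
        label="NA",
        heads=(3, 3, 3, -1, 3, 4),
        relations=("nsubjpass", "auxpass", "neg", "root", "prep", "pobj"),
    ),
    SentenceTemplate(
        tokens=("no", "association", "was", "found", "between", "GENE", "and", "DISEASE"),
        label="NA",
        heads=(1, 3, 3, -1, 3, 4, 5, 6),
        relations=("det", "nsubjpass", "auxpass", "root", "prep", "pobj", "cc", "conj"),
    ),
    SentenceTemplate(
        tokens=("GENE", "expression", "was", "measured", "in", "patients", "with", "DISEASE"),
        label="FA",
        heads=(1, 3, 3, -1, 3, 4, 5, 6),
        relations=("nn", "nsubjpass", "auxpass", "root", "prep", "pobj", "prep", "pobj"),
    ),
    SentenceTemplate(
        tokens=("patients", "with", "DISEASE", "were", "genotyped", "for", "GENE"),
        label="FA",
        heads=(4, 0, 1, 4, -1, 4, 5),
        relations=("nsubjpass", "prep", "pobj", "auxpass", "root", "prep", "pobj"),
    ),
)

_GENE_NAMES = (
    "BRCA1", "TP53", "EHD3", "FREM3", "CFTR", "APP", "ESR1", "ERBB2",
    "IL6", "TNF", "VEGFA", "COMT", "APOE", "MTHFR", "SLC6A4", "BDNF",
)
_DISEASE_NAMES = (
    "asthma", "schizophrenia", "depression", "diabetes", "melanoma",
    "hypertension", "obesity", "epilepsy", "psoriasis", "glaucoma",
    "leukemia", "migraine",
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_sentences: int = 200
    seed: int = 42
    #: proportions over (PA, NA, FA); must sum to 1
    mix: tuple[float, float, float] = (0.35, 0.25, 0.40)
    n_genes: int = len(_GENE_NAMES)
    n_diseases: int = len(_DISEASE_NAMES)

    def __post_init__(self) -> None:
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("template mix proportions must sum to 1")


def _apportion(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over proportions."""
    raw = [p * n for p in proportions]
    base = [int(x) for x in raw]
    rem = n - sum(base)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return base


def _instantiate(template: SentenceTemplate, gene: str, disease: str,
                 sid: str, pmid: str) -> tuple[AnnotatedSentence, CandidateInstance]:
    surfaces = [gene if t == "GENE" else disease if t == "DISEASE" else t
                for t in template.tokens]
    text = " ".join(surfaces)
    tokens = []
    offset = 0
    for i, surf in enumerate(surfaces):
        pos, lemma, stem = DEFAULT_PREPROCESSOR.analyze(surf)
        tokens.append(Token(i, surf, lemma, stem, pos, (offset, offset + len(surf))))
        offset += len(surf) + 1
    edges = tuple(
        (h, d, rel)
        for d, (h, rel) in enumerate(zip(template.heads, template.relations))
        if h != -1
    )
    graph = DependencyGraph(
        nodes=frozenset(range(len(tokens))),
        edges=edges,
        root=template.heads.index(-1),
    )
    gi = template.tokens.index("GENE")
    di = template.tokens.index("DISEASE")
    gene_mention = EntityMention(
        id=f"{sid}.g", semantic_type=GENE, token_span=(gi, gi),
        concept_ids=frozenset({str(1000 + _GENE_NAMES.index(gene) if gene in _GENE_NAMES else 9999)}),
        surface=gene,
    )
    disease_mention = EntityMention(
        id=f"{sid}.d", semantic_type=DISEASE, token_span=(di, di),
        concept_ids=frozenset({f"C{_DISEASE_NAMES.index(disease):07d}" if disease in _DISEASE_NAMES else "C9999999"}),
        surface=disease,
    )
    mentions = tuple(sorted((gene_mention, disease_mention), key=lambda m: m.token_span))
    sent = AnnotatedSentence(
        id=sid, doc_id=pmid, text=text, tokens=tuple(tokens),
        mentions=mentions, graph=graph,
    )
    e1, e2 = mentions
    inst = CandidateInstance(sent, e1, e2, PairLabel.from_fine(template.label))
    return sent, inst


def generate_corpus(
    cfg: GeneratorConfig | None = None,
) -> tuple[list[AnnotatedSentence], list[CandidateInstance]]:
    """Deterministic template corpus with gold labels and parse trees."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.RandomState(cfg.seed)
    by_label: dict[str, list[SentenceTemplate]] = {}
    for t in TEMPLATES:
        by_label.setdefault(t.label, []).append(t)
    counts = _apportion(cfg.n_sentences, cfg.mix)
    genes = _GENE_NAMES[: cfg.n_genes]
    diseases = _DISEASE_NAMES[: cfg.n_diseases]

    sentences: list[AnnotatedSentence] = []
    instances: list[CandidateInstance] = []
    idx = 0
    for label, n_label in zip(("PA", "NA", "FA"), counts):
        pool = by_label[label]
        for j in range(n_label):
            template = pool[j % len(pool)]
            gene = genes[rng.randint(len(genes))]
            disease = diseases[rng.randint(len(diseases))]
            sid = f"s{idx:05d}"
            pmid = str(10_000_000 + idx)
            sent, inst = _instantiate(template, gene, disease, sid, pmid)
            sentences.append(sent)
            instances.append(inst)
            idx += 1
    # interleave deterministically so folds do not align with label blocks
    order = rng.permutation(len(sentences))
    sentences = [sentences[i] for i in order]
    instances = [instances[i] for i in order]
    return sentences, instances


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

#: IF-bin categorical: (upper-edge label, probability). ``None`` = no IF.
DEFAULT_IF_BINS: tuple[tuple[str, float], ...] = (
    ("none", 0.35),
    ("0-2.5", 0.16),
    ("2.5-5", 0.33),
    ("5-10", 0.10),
    (">10", 0.06),
)

_IF_RANGES = {"0-2.5": (0.1, 2.5), "2.5-5": (2.5, 5.0), "5-10": (5.0, 10.0), ">10": (10.0, 30.0)}


@dataclass(frozen=True)
class AssociationTableConfig:
    n_records: int = 10_000
    seed: int = 1
    n_genes: int = 2_000
    n_diseases: int = 1_500
    singleton_fraction: float = 0.685
    max_pmids: int = 200
    reference_probability: float = 0.02
    if_bins: tuple[tuple[str, float], ...] = DEFAULT_IF_BINS
    year_range: tuple[int, int] = (1990, 2014)

    def __post_init__(self) -> None:
        if not (0 < self.singleton_fraction < 1):
            raise ValueError("singleton fraction must lie in (0, 1)")
        if abs(sum(p for _, p in self.if_bins) - 1.0) > 1e-9:
            raise ValueError("IF bin probabilities must sum to 1")


def _powerlaw_exponent(singleton_fraction: float, kmax: int) -> float:
    """Exponent of a truncated power law P(k) ∝ k^-a with P(1) as given."""
    ks = np.arange(1, kmax + 1, dtype=float)

    def p1(a: float) -> float:
        return 1.0 / np.sum(ks ** -a) - singleton_fraction

    return float(brentq(p1, 0.01, 10.0))


@dataclass
class AssociationTable:
    records: list[AssociationRecord] = field(default_factory=list)
    journals: JournalInfo = field(default_factory=dict)
    reference: set[tuple[str, str]] = field(default_factory=set)
    config: AssociationTableConfig | None = None


def generate_association_table(cfg: AssociationTableConfig | None = None) -> AssociationTable:
    """Association records with long-tailed support and journal metadata."""
    cfg = cfg or AssociationTableConfig()
    rng = np.random.RandomState(cfg.seed)
    alpha = _powerlaw_exponent(cfg.singleton_fraction, cfg.max_pmids)
    ks = np.arange(1, cfg.max_pmids + 1, dtype=float)
    probs = ks ** -alpha
    probs /= probs.sum()

    table = AssociationTable(config=cfg)
    pmid_counter = 20_000_000
    seen_pairs: set[tuple[str, str]] = set()
    bin_labels = [b for b, _ in cfg.if_bins]
    bin_probs = np.array([p for _, p in cfg.if_bins])

    while len(table.records) < cfg.n_records:
        gene = str(rng.randint(1, cfg.n_genes + 1))
        disease = f"C{rng.randint(1, cfg.n_diseases + 1):07d}"
        if (gene, disease) in seen_pairs:
            continue
        seen_pairs.add((gene, disease))
        n_pmids = int(rng.choice(len(ks), p=probs)) + 1
        pmids = set()
        for _ in range(n_pmids):
            pmid = str(pmid_counter)
            pmid_counter += 1
            pmids.add(pmid)
            bin_label = bin_labels[rng.choice(len(bin_labels), p=bin_probs)]
            if bin_label == "none":
                impact = None
            else:
                lo, hi = _IF_RANGES[bin_label]
                impact = float(np.round(rng.uniform(lo, hi), 3))
            year = int(rng.randint(cfg.year_range[0], cfg.year_range[1] + 1))
            table.journals[pmid] = (f"J{rng.randint(1, 500):03d}", impact, year)
        record = AssociationRecord(
            gene_id=gene, disease_id=disease,
            pmids=frozenset(pmids), sources=frozenset({"BEFREE"}),
        )
        table.records.append(record)
        if rng.rand() < cfg.reference_probability:
            table.reference.add((gene, disease))
    return table


def expected_retained_fraction(
    cfg: AssociationTableConfig, min_pmids: int = 2, if_threshold: float = 2.5
) -> float:
    """Analytic retained fraction under the default decision-tree rule.

    keep iff  n_pmids >= min_pmids  OR  in reference
              OR (singleton AND journal IF >= threshold).
    Assumes reference membership and IF are independent of support count,
    which is how the generator draws them.
    """
    alpha = _powerlaw_exponent(cfg.singleton_fraction, cfg.max_pmids)
    ks = np.arange(1, cfg.max_pmids + 1, dtype=float)
    probs = ks ** -alpha
    probs /= probs.sum()
    p_multi = float(probs[min_pmids - 1:].sum()) if min_pmids > 1 else 1.0
    p_single = 1.0 - p_multi
    p_if_ok = sum(
        p for label, p in cfg.if_bins
        if label != "none" and _IF_RANGES[label][0] >= if_threshold
    )
    p_ref = cfg.reference_probability
    return p_multi + p_single * (p_ref + (1 - p_ref) * p_if_ok)
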