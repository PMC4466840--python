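# Methods

## Problem and pipeline

Given sentences in which a gene and a disease are both mentioned, the package
decides whether the sentence asserts an association between them
(relation extraction), aggregates the accepted sentence-level pairs into
gene–disease association records keyed by normalized identifiers, scores each
record by the breadth and curation level of its evidence, and filters the
resulting set for delivery. Supporting components construct labelled corpora
from curated association records and resolve entity ambiguity before pairing.

## Sentence representation

Tokens carry surface, POS tag, lemma, stem and exact character offsets.
Pre-processing is a pluggable contract (`befree.preprocess.Preprocessor`);
the shipped fallback uses a regex tokenizer, the Porter stemmer (implemented
in-package and tested against the algorithm's canonical vocabulary), a small
lexicon lemmatizer and a rule-based Penn-Treebank-style tagger. The fallback
is deliberately crude linguistically: kernels need *consistent* annotations,
not perfect ones, and a deterministic in-process pipeline makes every test
and simulation reproducible with no model downloads. Production deployments
should plug in a real tagger/lemmatizer through the same contract.

Before feature extraction the candidate pair is blinded: each candidate
mention collapses to a `CANDIDATE1`/`CANDIDATE2` placeholder token and any
other mention of the same semantic types to `ENTITY_OTHER`. This keeps
kernels from keying on specific entity names.

## Shallow Linguistic Kernel

`K_SL = w_GC·K_GC + w_LC·K_LC` (unit weights by default).

**Global context.** Three token spans around the pair — fore-between,
between, between-after; the candidate placeholders themselves are excluded,
since after blinding they are constants shared by every instance. Each span
becomes a sparse bag of lowercased contiguous n-grams of order 1..`ngram_max`
(default 3) plus *sparse bigrams*: ordered token pairs with 1..`max_gap`
(default 2) intervening tokens, weighted `decay^gap` with `decay = 0.5`.
The decay and gap are package defaults (configurable); the pattern scheme
itself follows the established shallow-linguistic design. `K_GC` is the sum
of the three per-pattern cosine similarities, so it lies in [0, 3]; an empty
pattern contributes 0. Per-pattern cosine normalization (rather than one
global normalization or raw counts) prevents long sentences from dominating;
a `normalize` flag restores raw dot products.

**Local context.** For each candidate and each offset in −w..−1, +1..+w
(default window w = 2, measured from the mention boundary in the blinded
sequence), four indicator features are emitted: orthographic class
(ALLCAPS / INITCAP / ALLLOWER / HASDIGIT / MIXED / PUNCT, with digit
presence taking precedence over case), POS, lemma, stem. Positions beyond
the sentence boundary carry an explicit sentinel value instead of being
truncated, keeping vector arity fixed (16w features) and making
self-similarity exactly 1. `K_LC` is the cosine of the indicator vectors.

## Dependency Kernel

The syntactic head of each candidate mention is the span token governed from
outside the span (falling back to the last token when zero or several
qualify). The shortest path between the two heads is found by BFS over the
undirected view of the parse; each traversed edge records its relation label
and traversal direction (UP toward the governor, DOWN toward the dependent).
The Least Common Subsumer is the node where the traversal flips UP→DOWN, or
an endpoint for monotone paths — verified in tests against a brute-force
ancestor-set-intersection oracle on random trees.

From the path, one v-walk `(node_i, edge_{i,i+1}, node_{i+1})` per edge and
one e-walk `(edge_{i-1,i}, node_i, edge_{i,i+1})` per internal node are
extracted. Node features are configurable among TOKEN / STEM / LEMMA / POS /
ROLE (candidate vs other); candidate nodes' lexical features are blinded by
default. Edge features include traversal direction by default (a flag drops
it, leaving the bare relation type). `K_DEP` is the cosine-normalized dot
product over walk counts. The kernel is a plain linear kernel over walk-count
vectors, not a gap-weighted subsequence kernel over the path: the walk
features are the documented contract here, and a subsequence variant would
be a separate kernel, not a configuration of this one. Candidates in
disconnected parse components yield an empty walk vector and hence zero
kernel mass — the instance stays in the dataset (stable fold sizes) but
cannot support classification.

Weighted combinations `Σ w_i·K_i` over {SL, DEP} are exposed; sums of
positively weighted cosine-normalized linear kernels are positive
semidefinite, which the test suite checks on Gram matrices (minimum
eigenvalue ≥ −1e−8 across kernel configurations).

## Classification and evaluation

`KernelRelationClassifier` is a scikit-learn estimator (`fit`/`predict`/
`get_params`) over candidate-instance samples; it precomputes the Gram matrix
and trains `sklearn.svm.SVC(kernel="precomputed")` with C = 1.0 by default.
Multi-class problems (positive vs negative vs false association) are decided
one-vs-one; vote ties are broken by summed decision values rather than class
order. Class weights are unbalanced by default with an inverse-frequency
option for corpora dominated by negative sentences.

Cross-validation partitions *sentences*, never splitting one sentence's
candidate pairs across folds, stratified by binary label with a seeded
shuffle (default fold seed 42). Metrics are P/R/F over TRUE (binary) or over
PA and NA separately (three-class), reported both macro-averaged across folds
and recomputed from the pooled confusion matrix — the two averaging modes
genuinely differ and both are emitted. Gram matrices are computed once per
CV run and sliced per fold; symmetric Grams are additionally memoized by
instance-uid set and configuration.

## Corpus construction and entity disambiguation

The curated-record corpus builder retains records whose association verdict
is positive or negative, whose statement is a single sentence, and whose gene
carries an Entrez identifier. The curated (gene, disease) pair — leftmost
matching mentions — is labelled TRUE with fine label PA/NA; all other
gene–disease co-occurrences in the sentence become FALSE unless another
curated record for the same publication claims them, which keeps the TRUE
and FALSE sets disjoint by construction. Disease phrases match NER mentions
by case-insensitive normalized containment in either direction, or by shared
concept identifier; records whose curated entities the NER misses are
excluded from both classes rather than silently labelled FALSE.

Acronym resolution intersects the candidate concept-id sets of an acronym
and its defining long form (validated by right-to-left character alignment
within the long form, long forms never crossing a parenthesis). Residual
ambiguity is ranked by token-Jaccard similarity between concept synonyms and
the long-form surface, then minimum edit distance, then gene-literature
linkage (gene2pubmed). Cross-type ambiguity (gene vs disease symbol) is
decided by trigger keywords within ±5 tokens (nearest wins; exact ties stay
unresolved), falling back to soft matching of the mention's disease synonyms
against the abstract's MeSH disease terms — lowercase token overlap divided
by the smaller set, threshold 0.5. Window, keyword lists and threshold are
configurable; the values are package defaults chosen once.

## Evidence score

`S = S_CURATED + S_PREDICTED + S_LITERATURE` with UniProt and CTD-human
membership worth 0.3 each, rat (RGD or CTD-rat) and mouse (MGD or CTD-mouse)
membership 0.1 each, and each literature source j contributing
`min(cap_j, n_j·100/N_j)` where `n_j` is the number of publications
supporting the association in source j, `N_j` the source's total publication
count, and caps are 0.08 (GAD) and 0.06 (LHGDN and text mining). `n_j` is
read as "publications supporting *this* association in source j". The
text-mining `N` defaults to 355,976 — the publication count of the
large-scale literature run this score parametrizes — but is always
configurable because it is dataset-dependent. S is monotone in sources and
support and lies in [0, 1] (the weights and caps sum to 1).

## Filtering workflow

Dense-abstract removal drops all evidence from abstracts reporting more than
20 distinct associations (strictly greater: exactly 20 is kept); association
records left without support disappear, others lose the dense PMIDs. The
decision-tree triage keeps a record iff
`n_pmids ≥ min_pmids (2) OR in curated reference OR (singleton AND journal
IF ≥ 2.5)`; the rule is a configurable boolean over those three quantities,
missing impact factors are explicit `None` (distinct from 0), and
multi-publication records never consult the IF branch. The exact branch
topology of the original workflow is not recoverable, so the default rule
realizes the three stated criteria directly and the retained percentage is a
property of the data, not a correctness target.

## Synthetic data

`generate_corpus` renders hand-built templates — affirmative
("GENE is associated with DISEASE"-style), negated ("no association was
found between…") and co-occurrence-only constructions — with gene/disease
fillers drawn per seed, dependency skeletons instantiated from per-template
trees, and annotations produced by the fallback pre-processor. Label counts
follow the configured mix exactly via largest-remainder apportionment
(default 35% PA / 25% NA / 40% FA, echoing corpora where false
co-occurrences are the largest class). Because the three classes use
disjoint cue vocabulary, the corpus is separable: parameter-recovery tests
legitimately expect F ≥ 0.95, and passing them demonstrates that the
kernels, Gram plumbing and CV protocol recover a recoverable signal — not
that comparable accuracy would be reached on real abstracts, whose lexical
variety, parse errors and annotation noise the generator does not emulate.

`generate_association_table` draws publications-per-association from a
truncated power law `P(k) ∝ k^(−α)`, k = 1..200, with α solved by bisection
so that P(1) equals the configured singleton fraction (default 0.685, the
share observed in large-scale literature mining; the implied mean ≈ 2.5
publications per association). Journal impact factors follow a categorical
over bins — 35% no IF, 16% (0, 2.5], 33% (2.5, 5], 10% (5, 10], 6% > 10 —
matching the reported no-IF and low-IF shares, with the remainder placed
mostly in (2.5, 5]. Reference membership is Bernoulli(0.02), the reported
curated-overlap share, drawn independently of support count; that
independence is what makes the filter's retained fraction analytically
computable (`expected_retained_fraction`) and testable within binomial
error.

## Numerical and degenerate-input choices

- Cosine of an empty vector against anything is 0; self-similarity of
  non-empty vectors is exactly 1 (3 for the three-pattern global kernel,
  4 for `K_SL` with unit weights).
- Kernel symmetry is exact (identical code path both directions); PSD is
  asserted at −1e−8 to absorb eigensolver round-off.
- Candidate pairs must be in token order and non-overlapping; overlapping or
  nested pairs are rejected and counted, never silently kept.
- Sentences without a parse, or with candidates in disconnected parse
  components, contribute zero dependency-kernel mass instead of being
  dropped.
- Multiple roots in a CoNLL sentence: the first root is kept and the others
  re-attached to it; token-count mismatches between parse and sentence raise
  an alignment error naming the sentence.
- Fold assignment, template instantiation and table generation are driven by
  seeded `RandomState` instances only; rebuilding any artifact with the same
  seed is byte-identical.

## Problem sizes

Default test and reproduction sizes — 50 instances for kernel Gram
diagnostics, 200 sentences for cross-validation, 200 random trees for path
oracles, 10,000 records for distribution calibration — are chosen so the
whole suite runs in seconds while keeping binomial error on calibrated
fractions under the 2% tolerance the tests assert.

## Known limitations

- The fallback POS tagger and lemmatizer are rule/lexicon stubs; real-corpus
  use requires plugging production NLP tools into the pre-processing
  contract.
- The dictionary NER itself is a contract, not an implementation; only the
  disambiguation layers on top of it are provided.
- Template-generated text cannot measure real-world extraction accuracy;
  published benchmark figures on manually annotated corpora are out of scope
  here because the corpora must be obtained separately.
- The walk-feature kernel does not implement gap-weighted subsequences over
  the dependency path; see the Dependency Kernel section for the rationale.
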