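"""SVM relation classification over precomputed kernel matrices.

The central object is :class:`KernelRelationClassifier`, a scikit-learn
estimator whose samples are :class:`~befree.text_model.CandidateInstance`
objects. The Gram matrix between instances is computed by the configured
kernel (shallow-linguistic, dependency, or a weighted combination) and handed
to a soft-margin SVM with a precomputed kernel. Multi-class problems
(positive vs negative vs false association) are decided one-vs-one with vote
ties broken by summed decision values.

Evaluation follows the sentence-level protocol: folds partition *sentences*,
never splitting the candidate pairs of one sentence across folds, stratified
by binary label where possible. Precision, recall and F-score are reported
over the TRUE class in binary mode and over PA and NA separately in
three-class mode, both macro-averaged across folds and recomputed from the
pooled confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .kernel_dep import DepConfig, _instance_walks, k_dep
from .kernel_sl import (
    SLConfig, extract_global_context, extract_local_context, k_gc, k_lc,
)
from .text_model import CandidateInstance

__all__ = [
    "KernelRelationClassifier", "EvaluationReport", "FoldMetrics",
    "compute_gram", "train", "predict", "cross_validate",
    "sentence_level_folds", "prf_from_confusion",
]


def _parse_kernel_spec(kernel: str | list[tuple[str, float]]) -> list[tuple[str, float]]:
    if isinstance(kernel, str):
        parts = [p.strip() for p in kernel.split("+")]
        return [(p, 1.0) for p in parts]
    return list(kernel)


def _featurize(
    instances: Sequence[CandidateInstance],
    spec: list[tuple[str, float]],
    sl_config: SLConfig | None,
    dep_config: DepConfig | None,
) -> dict[str, list]:
    """Extract the per-instance feature vectors each kernel in *spec* needs."""
    sl_cfg = sl_config or SLConfig()
    dep_cfg = dep_config or DepConfig()
    feats: dict[str, list] = {}
    kids = {kid for kid, _ in spec}
    if "sl" in kids:
        feats["sl"] = [
            (extract_global_context(i, sl_cfg), extract_local_context(i, sl_cfg))
            for i in instances
        ]
    if "dep" in kids:
        feats["dep"] = [_instance_walks(i, dep_cfg) for i in instances]
    unknown = kids - {"sl", "dep"}
    if unknown:
        raise ValueError(f"unknown kernel id(s) {sorted(unknown)}")
    return feats


#: Gram cache keyed by (instance uids, kernel/config repr); bounded FIFO.
_GRAM_CACHE: dict[tuple, np.ndarray] = {}
_GRAM_CACHE_MAX = 8


def compute_gram(
    x_instances: Sequence[CandidateInstance],
    y_instances: Sequence[CandidateInstance] | None = None,
    kernel: str | list[tuple[str, float]] = "sl",
    sl_config: SLConfig | None = None,
    dep_config: DepConfig | None = None,
) -> np.ndarray:
    """Kernel matrix between two instance collections (symmetric if one).

    Features are extracted once per instance; symmetric Gram matrices over
    the same instance set and configuration are memoized.
    """
    spec = _parse_kernel_spec(kernel)
    symmetric = y_instances is None
    cfg_key = (tuple(spec), repr(sl_config or SLConfig()), repr(dep_config or DepConfig()))
    if symmetric:
        cache_key = (tuple(i.uid for i in x_instances), cfg_key)
        hit = _GRAM_CACHE.get(cache_key)
        if hit is not None:
            return hit
    ys = x_instances if symmetric else y_instances
    weights = dict(spec)
    for w in weights.values():
        if w < 0:
            raise ValueError("kernel weights must be non-negative")
    fx = _featurize(x_instances, spec, sl_config, dep_config)
    fy = fx if symmetric else _featurize(ys, spec, sl_config, dep_config)
    sl_cfg = sl_config or SLConfig()

    gram = np.zeros((len(x_instances), len(ys)))
    for i in range(len(x_instances)):
        start = i if symmetric else 0
        for j in range(start, len(ys)):
            val = 0.0
            if "sl" in fx:
                pv_a, lv_a = fx["sl"][i]
                pv_b, lv_b = fy["sl"][j]
                val += weights["sl"] * (
                    sl_cfg.gc_weight * k_gc(pv_a, pv_b, sl_cfg)
                    + sl_cfg.lc_weight * k_lc(lv_a, lv_b)
                )
            if "dep" in fx:
                val += weights["dep"] * k_dep(fx["dep"][i], fy["dep"][j])
            gram[i, j] = val
            if symmetric:
                gram[j, i] = val
    if not np.isfinite(gram).all():
        bad = np.argwhere(~np.isfinite(gram))[0]
        raise FloatingPointError(
            f"non-finite kernel value between instances {bad[0]} and {bad[1]}"
        )
    if symmetric:
        if len(_GRAM_CACHE) >= _GRAM_CACHE_MAX:
            _GRAM_CACHE.pop(next(iter(_GRAM_CACHE)))
        _GRAM_CACHE[cache_key] = gram
    return gram


def _labels_from_decision(classes: np.ndarray, dec: np.ndarray) -> np.ndarray:
    """Decode SVM decision values; one-vs-one votes with ties broken by
    summed decision values in the multi-class case."""
    if len(classes) == 2:
        return np.where(dec > 0, classes[1], classes[0])
    n = len(classes)
    m = dec.shape[0]
    votes = np.zeros((m, n))
    sums = np.zeros((m, n))
    col = 0
    for i in range(n):
        for j in range(i + 1, n):
            d = dec[:, col]
            votes[:, i] += d > 0
            votes[:, j] += d <= 0
            sums[:, i] += d
            sums[:, j] -= d
            col += 1
    best = np.argmax(votes, axis=1)
    for r in range(m):
        top = np.flatnonzero(votes[r] == votes[r, best[r]])
        if len(top) > 1:
            best[r] = top[np.argmax(sums[r, top])]
    return classes[best]


class KernelRelationClassifier(ClassifierMixin, BaseEstimator):
    """SVM over sentence-pair kernels, in scikit-learn estimator form.

    Parameters
    ----------
    kernel:
        ``"sl"``, ``"dep"``, ``"sl+dep"`` or an explicit weighted list such
        as ``[("sl", 1.0), ("dep", 0.5)]``.
    C:
        Soft-margin penalty of the SVM.
    sl_config, dep_config:
        Kernel hyper-parameters; defaults follow the standard configuration
        (trigrams, sparse bigrams with decay 0.5 and gap 2, window 2).
    class_weight:
        ``None`` or ``"balanced"`` (inverse-frequency weighting, useful for
        corpora with a large fraction of negative sentences).
    """

    def __init__(
        self,
        kernel: str | list[tuple[str, float]] = "sl+dep",
        C: float = 1.0,
        sl_config: SLConfig | None = None,
        dep_config: DepConfig | None = None,
        class_weight: str | None = None,
    ) -> None:
        self.kernel = kernel
        self.C = C
        self.sl_config = sl_config
        self.dep_config = dep_config
        self.class_weight = class_weight

    # -- scikit-learn API ---------------------------------------------------

    def fit(self, X: Sequence[CandidateInstance], y: Sequence[str]):
        y = np.asarray(y, dtype=object)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty instance list")
        if len(set(y)) < 2:
            raise ValueError("training data must contain at least two classes")
        self.train_instances_ = list(X)
        gram = compute_gram(
            self.train_instances_, None, self.kernel, self.sl_config, self.dep_config
        )
        self.svc_ = SVC(
            kernel="precomputed",
            C=self.C,
            class_weight=self.class_weight,
            decision_function_shape="ovo",
        )
        self.svc_.fit(gram, y)
        self.classes_ = self.svc_.classes_
        self.dual_coef_ = self.svc_.dual_coef_
        self.intercept_ = self.svc_.intercept_
        return self

    def decision_function(self, X: Sequence[CandidateInstance]) -> np.ndarray:
        gram = compute_gram(
            X, self.train_instances_, self.kernel, self.sl_config, self.dep_config
        )
        return self.svc_.decision_function(gram)

    def predict(self, X: Sequence[CandidateInstance]) -> np.ndarray:
        if len(X) == 0:
            return np.array([], dtype=object)
        return _labels_from_decision(self.classes_, self.decision_function(X))


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def train(
    instances: Sequence[CandidateInstance],
    labels: Sequence[str],
    kernel: str | list[tuple[str, float]] = "sl+dep",
    C: float = 1.0,
    **kwargs,
) -> KernelRelationClassifier:
    return KernelRelationClassifier(kernel=kernel, C=C, **kwargs).fit(instances, labels)


def predict(model: KernelRelationClassifier, instances: Sequence[CandidateInstance]):
    labels = model.predict(instances)
    dec = model.decision_function(instances) if len(instances) else np.array([])
    return labels, dec


# ---------------------------------------------------------------------------
# Evaluation protocol
# ---------------------------------------------------------------------------

@dataclass
class FoldMetrics:
    fold: int
    per_class: dict[str, tuple[float, float, float]]   # class -> (P, R, F)
    confusion: dict[tuple[str, str], int]              # (gold, predicted) -> count
    n_test: int


@dataclass
class EvaluationReport:
    mode: str
    folds: list[FoldMetrics] = field(default_factory=list)
    macro: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    pooled: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    confusion: dict[tuple[str, str], int] = field(default_factory=dict)

    def f_true(self) -> float:
        key = "TRUE" if self.mode == "binary" else "PA"
        return self.macro[key][2]


def prf_from_confusion(
    confusion: dict[tuple[str, str], int], cls: str
) -> tuple[float, float, float]:
    tp = confusion.get((cls, cls), 0)
    fp = sum(c for (g, p), c in confusion.items() if p == cls and g != cls)
    fn = sum(c for (g, p), c in confusion.items() if g == cls and p != cls)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


def sentence_level_folds(
    instances: Sequence[CandidateInstance], k: int, seed: int
) -> list[int]:
    """Assign a fold index to each instance, partitioning by sentence.

    Sentences are stratified by their majority binary label and dealt
    round-robin to folds after a seeded shuffle, so all candidate pairs of a
    sentence share a fold and fold label balance is as even as the grouping
    allows.
    """
    groups: dict[str, list[int]] = {}
    for i, inst in enumerate(instances):
        groups.setdefault(inst.sentence.id, []).append(i)
    if k > len(groups):
        raise ValueError(f"k={k} exceeds number of sentences ({len(groups)})")

    def majority_label(idx: list[int]) -> str:
        labels = [instances[i].label.binary if instances[i].label else "?" for i in idx]
        return max(sorted(set(labels)), key=labels.count)

    strata: dict[str, list[str]] = {}
    for sid, idx in groups.items():
        strata.setdefault(majority_label(idx), []).append(sid)

    rng = np.random.RandomState(seed)
    fold_of_sentence: dict[str, int] = {}
    next_fold = 0
    for label in sorted(strata):
        sids = sorted(strata[label])
        rng.shuffle(sids)
        for sid in sids:
            fold_of_sentence[sid] = next_fold % k
            next_fold += 1
    return [fold_of_sentence[inst.sentence.id] for inst in instances]


def cross_validate(
    instances: Sequence[CandidateInstance],
    kernel: str | list[tuple[str, float]] = "sl+dep",
    C: float = 1.0,
    k: int = 10,
    seed: int = 42,
    mode: str = "binary",
    sl_config: SLConfig | None = None,
    dep_config: DepConfig | None = None,
    class_weight: str | None = None,
) -> EvaluationReport:
    """Sentence-level k-fold cross-validation.

    ``mode="binary"`` scores TRUE vs FALSE; ``mode="three_class"`` scores
    PA vs NA vs FALSE using the fine labels (PA/NA for TRUE instances).
    """
    if mode not in {"binary", "three_class"}:
        raise ValueError(f"unknown mode {mode!r}")

    def gold(inst: CandidateInstance) -> str:
        assert inst.label is not None
        if mode == "binary":
            return inst.label.binary
        if inst.label.binary == "FALSE":
            return "FALSE"
        return inst.label.fine or "PA"

    fold_ids = sentence_level_folds(instances, k, seed)
    report = EvaluationReport(mode=mode)
    classes_of_interest = ["TRUE"] if mode == "binary" else ["PA", "NA"]
    pooled: dict[tuple[str, str], int] = {}
    # one full Gram; every fold slices it
    gram = compute_gram(instances, None, kernel, sl_config, dep_config)
    labels = np.array([gold(i) for i in instances], dtype=object)

    for fold in range(k):
        train_idx = np.array([i for i, f in enumerate(fold_ids) if f != fold])
        test_idx = np.array([i for i, f in enumerate(fold_ids) if f == fold])
        if len(test_idx) == 0:
            continue
        svc = SVC(kernel="precomputed", C=C, class_weight=class_weight,
                  decision_function_shape="ovo")
        svc.fit(gram[np.ix_(train_idx, train_idx)], labels[train_idx])
        dec = svc.decision_function(gram[np.ix_(test_idx, train_idx)])
        pred = _labels_from_decision(svc.classes_, dec)
        confusion: dict[tuple[str, str], int] = {}
        for i, p in zip(test_idx, pred):
            key = (gold(instances[i]), str(p))
            confusion[key] = confusion.get(key, 0) + 1
            pooled[key] = pooled.get(key, 0) + 1
        per_class = {c: prf_from_confusion(confusion, c) for c in classes_of_interest}
        report.folds.append(FoldMetrics(
            fold=fold, per_class=per_class, confusion=confusion, n_test=len(test_idx)
        ))

    for c in classes_of_interest:
        triples = [fm.per_class[c] for fm in report.folds]
        report.macro[c] = tuple(float(np.mean([t[i] for t in triples]))
                                for i in range(3))
        report.pooled[c] = prf_from_confusion(pooled, c)
    report.confusion = pooled
    return report
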