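"""Classification metrics, ROC/AUC, cross-validation and negative sampling.

Metrics are the standard confusion-table statistics — accuracy,
precision, sensitivity, specificity and the Matthews correlation
coefficient — reported per fold and as mean +/- sample SD over a
five-fold cross-validation.  The ROC curve is built by sweeping every
distinct score threshold and the AUC by trapezoidal integration, which
coincides with the rank statistic P(score+ > score-) + 0.5 P(tie).

Negative (non-interacting) pairs are drawn uniformly without
replacement from the complement of the known interactions in the
bipartite all-pairs space: with p proteins the ordered candidate space
has p^2 pairs (e.g. 7,437 proteins give 55,308,969 candidates, of which
55,280,859 remain after removing 28,110 known interactions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .io_formats import InteractionPair
from .model import BaselineModel, DNNConfig, predict, train_baseline, train_dnn
from .reduction import fit_projector, pair_descriptor, project

__all__ = [
    "Confusion",
    "Metrics",
    "CVReport",
    "confusion",
    "metrics",
    "roc_auc",
    "kfold_split",
    "candidate_pair_count",
    "negative_candidate_count",
    "sample_negatives",
    "run_cv",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    acc: float
    pr: float
    sens: float
    spec: float
    mcc: float
    auc: float = float("nan")


@dataclass
class CVReport:
    """Per-fold metrics plus mean and sample SD (n-1 denominator)."""

    folds: list[Metrics]
    roc: list[list[tuple[float, float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.folds) < 2:
            raise ValueError("a cross-validation report needs at least 2 folds")

    def _agg(self, fn) -> dict[str, float]:
        keys = ("acc", "pr", "sens", "spec", "mcc", "auc")
        return {k: float(fn([getattr(m, k) for m in self.folds])) for k in keys}

    @property
    def mean(self) -> dict[str, float]:
        return self._agg(np.mean)

    @property
    def sd(self) -> dict[str, float]:
        return self._agg(lambda v: np.std(v, ddof=1))


def confusion(
    y: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> Confusion:
    """Tally the confusion table; scores >= threshold predict positive."""
    y = np.asarray(y, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty input")
    if y.size != scores.size:
        raise ValueError("labels and scores must have equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores contain non-finite values")
    pred = scores >= threshold
    pos = y == 1
    return Confusion(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} has a 0/0 denominator; reporting 0")
        return 0.0
    return num / den


def metrics(c: Confusion) -> Metrics:
    """Accuracy, precision, sensitivity, specificity and MCC from counts.

    Degenerate 0/0 denominators yield 0 with a warning; the MCC
    denominator uses the usual square root of the four marginal
    products.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    total = c.total
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    pr = _safe_div(tp, tp + fp, "precision")
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, fp + tn, "specificity")
    denom = float(tp + fp) * (tp + fn) * (tn + fn) * (tn + fp)
    if denom == 0:
        warnings.warn("MCC denominator is 0; reporting 0")
        mcc = 0.0
    else:
        mcc = (tn * tp - fp * fn) / np.sqrt(denom)
    return Metrics(acc=acc, pr=pr, sens=sens, spec=spec, mcc=mcc)


def roc_auc(
    y: Sequence[int], scores: Sequence[float]
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC points (fpr, tpr, threshold) by sweeping all distinct score
    thresholds, and the trapezoidal AUC."""
    y = np.asarray(y, dtype=int).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    points: list[tuple[float, float, float]] = [(0.0, 0.0, np.inf)]
    tp = fp = 0
    i = 0
    n = y.size
    while i < n:
        thr = s_sorted[i]
        while i < n and s_sorted[i] == thr:
            if y_sorted[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos, float(thr)))
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def kfold_split(
    pairs: Sequence[InteractionPair],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> list[np.ndarray]:
    """Split pair indices into k disjoint folds (returned as index arrays).

    With stratification the per-fold class ratio differs from the global
    ratio by at most one sample.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(pairs)
    if n < k:
        raise ValueError(f"cannot split {n} pairs into {k} folds")
    labels = np.array([p.label for p in pairs])
    if stratified and len(np.unique(labels)) > 1:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    return [test_idx for _, test_idx in splits]


def candidate_pair_count(n_proteins: int, ordered: bool = True) -> int:
    """Size of the bipartite all-pairs candidate space.

    Ordered pairs including self-pairs (p^2) by default; the unordered
    option counts each i<j pair once, excluding self-pairs.
    """
    if ordered:
        return n_proteins * n_proteins
    return n_proteins * (n_proteins - 1) // 2


def negative_candidate_count(
    n_proteins: int, n_positives: int, ordered: bool = True
) -> int:
    """Number of candidate pairs left after removing known interactions."""
    return candidate_pair_count(n_proteins, ordered=ordered) - n_positives


def sample_negatives(
    proteins: Sequence[str],
    positives: Iterable[tuple[str, str]],
    n: int,
    seed: int = 0,
    ordered: bool = True,
) -> list[InteractionPair]:
    """Draw n presumed non-interacting pairs uniformly without replacement
    from the candidate space minus the known positive pairs."""
    ids = list(proteins)
    p = len(ids)
    index = {pid: i for i, pid in enumerate(ids)}
    if ordered:
        pos_codes = {index[a] * p + index[b] for a, b in positives}
        space = p * p

        def decode(code: int) -> tuple[str, str]:
            return ids[code // p], ids[code % p]

    else:
        pos_codes = set()
        for a, b in positives:
            i, j = sorted((index[a], index[b]))
            if i != j:
                pos_codes.add(i * p + j)
        space = p * (p - 1) // 2
        codes_list = [i * p + j for i in range(p) for j in range(i + 1, p)]

        def decode(code: int) -> tuple[str, str]:
            return ids[code // p], ids[code % p]

    available = space - len(pos_codes)
    if n > available:
        raise ValueError(
            f"requested {n} negatives but only {available} candidate pairs "
            "remain outside the positive set"
        )
    rng = np.random.default_rng(seed)
    if ordered and space > 5_000_000 and n <= available // 10:
        # large candidate space, sparse draw: rejection sampling
        chosen_set: set[int] = set()
        chosen = []
        while len(chosen) < n:
            code = int(rng.integers(0, p)) * p + int(rng.integers(0, p))
            if code in pos_codes or code in chosen_set:
                continue
            chosen_set.add(code)
            chosen.append(code)
    else:
        if ordered:
            exclude = (
                np.fromiter(pos_codes, dtype=np.int64, count=len(pos_codes))
                if pos_codes
                else np.array([], dtype=np.int64)
            )
            keep = np.setdiff1d(np.arange(space, dtype=np.int64), exclude)
        else:
            keep = np.array([c for c in codes_list if c not in pos_codes], dtype=np.int64)
        chosen = rng.choice(keep, size=n, replace=False)
    return [InteractionPair(*decode(int(c)), 0) for c in chosen]


def _pair_matrix(
    pairs: Sequence[InteractionPair],
    reduced: Mapping[str, np.ndarray],
    symmetrize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    rows = [pair_descriptor(reduced[p.id_a], reduced[p.id_b]).values for p in pairs]
    labels = [p.label for p in pairs]
    if symmetrize:
        rows += [pair_descriptor(reduced[p.id_b], reduced[p.id_a]).values for p in pairs]
        labels += [p.label for p in pairs]
    return np.array(rows), np.array(labels)


def run_cv(
    features: Mapping[str, np.ndarray],
    pairs: Sequence[InteractionPair],
    *,
    classifier: str = "dnn",
    svd_k: int = 300,
    folds: int = 5,
    seed: int = 0,
    stratified: bool = True,
    paper_mode: bool = False,
    symmetrize: bool = False,
    dnn: DNNConfig | None = None,
    baseline_params: dict | None = None,
    threshold: float = 0.5,
) -> CVReport:
    """Five-fold cross-validation of the full reduce-pair-classify chain.

    Per fold the SVD projector is fitted on the descriptors of proteins
    appearing in the training pairs only (``paper_mode=True`` fits once
    on all proteins instead), the classifier is trained on the training
    pairs, and the held-out fold is scored.  Everything is driven by
    ``seed``.
    """
    missing = sorted(
        {pid for p in pairs for pid in (p.id_a, p.id_b) if pid not in features}
    )
    if missing:
        raise ValueError(f"no descriptor for pair proteins: {missing}")
    pairs = list(pairs)
    fold_indices = kfold_split(pairs, k=folds, seed=seed, stratified=stratified)
    all_idx = np.arange(len(pairs))

    global_projector = None
    if paper_mode:
        X_all = np.array([features[pid] for pid in sorted(features)])
        global_projector = fit_projector(X_all, k=svd_k)

    fold_metrics: list[Metrics] = []
    fold_rocs: list[list[tuple[float, float, float]]] = []
    for f, test_idx in enumerate(fold_indices):
        test_mask = np.zeros(len(pairs), dtype=bool)
        test_mask[test_idx] = True
        train_pairs = [pairs[i] for i in all_idx[~test_mask]]
        test_pairs = [pairs[i] for i in all_idx[test_mask]]

        if global_projector is not None:
            projector = global_projector
        else:
            train_ids = sorted({pid for p in train_pairs for pid in (p.id_a, p.id_b)})
            projector = fit_projector(
                np.array([features[pid] for pid in train_ids]), k=svd_k
            )
        reduced = {pid: project(projector, vec) for pid, vec in features.items()}

        X_train, y_train = _pair_matrix(train_pairs, reduced, symmetrize)
        X_test, y_test = _pair_matrix(test_pairs, reduced, symmetrize=False)

        fold_seed = int(
            np.random.SeedSequence([seed, f]).generate_state(1)[0] % (2**31)
        )
        if classifier == "dnn":
            cfg = dnn or DNNConfig()
            cfg = DNNConfig(**{**cfg.__dict__, "seed": fold_seed})
            state = train_dnn(X_train, y_train, cfg)
            scores = predict(state, X_test)
        elif classifier in ("knn", "rf"):
            params = dict(baseline_params or {})
            params.setdefault("seed", fold_seed)
            model: BaselineModel = train_baseline(classifier, X_train, y_train, params)
            scores = model.predict(X_test)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")

        m = metrics(confusion(y_test, scores, threshold=threshold))
        points, auc = roc_auc(y_test, scores)
        m.auc = auc
        fold_metrics.append(m)
        fold_rocs.append(points)
    return CVReport(folds=fold_metrics, roc=fold_rocs)
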