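"""Repeated k-fold cross-validation, confusion matrices and ROC/AUC.

The headline protocol of the package is: for each k in {5..9}, randomly
partition the samples into k folds (stratified by default, so small
classes stay represented in every fold), hold each fold out once, and
repeat the whole process over many seeds; accuracies are averaged with
their standard deviation.  ROC curves come with the Hanley-McNeil
standard error and a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import bayesnet
from .data import DiscretizedMatrix

__all__ = [
    "CVReport",
    "RocCurve",
    "ClassifierConfig",
    "kfold_partition",
    "cross_validate",
    "confusion_matrix",
    "roc_curve",
]


@dataclass
class ClassifierConfig:
    """How to (re)fit the Bayesian-network classifier inside each fold."""

    max_parents: int = 1
    smoothing: float = bayesnet.DEFAULT_SMOOTHING
    order: Sequence[str] | None = None  # structure-search gene ordering


@dataclass
class CVReport:
    """Repeated k-fold accuracies plus pooled confusion statistics."""

    accuracies: dict  # (k, seed) -> accuracy
    class_set: list
    confusion: np.ndarray  # pooled true x predicted counts over all runs
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self):
        vals = np.array(list(self.accuracies.values()), dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("accuracies must lie in [0, 1]")
        self.mean = float(vals.mean())
        self.std = float(vals.std(ddof=0))

    @property
    def n_runs(self) -> int:
        return len(self.accuracies)

    def per_k(self) -> dict:
        """Mean accuracy per fold count k."""
        out: dict = {}
        for (k, _), a in self.accuracies.items():
            out.setdefault(k, []).append(a)
        return {k: float(np.mean(v)) for k, v in sorted(out.items())}

    def per_class_metrics(self) -> dict:
        """Pooled sensitivity and specificity per class (one-vs-rest)."""
        cm = self.confusion.astype(float)
        total = cm.sum()
        out = {}
        for i, cls in enumerate(self.class_set):
            tp = cm[i, i]
            fn = cm[i].sum() - tp
            fp = cm[:, i].sum() - tp
            tn = total - tp - fn - fp
            sens = tp / (tp + fn) if tp + fn > 0 else float("nan")
            spec = tn / (tn + fp) if tn + fp > 0 else float("nan")
            out[cls] = {"sensitivity": float(sens), "specificity": float(spec)}
        return out

    def plot(self, ax=None):
        """Mean accuracy per fold count with across-run SD error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        per_k: dict = {}
        for (k, _), a in self.accuracies.items():
            per_k.setdefault(k, []).append(a)
        ks = sorted(per_k)
        means = [np.mean(per_k[k]) for k in ks]
        sds = [np.std(per_k[k]) for k in ks]
        ax.errorbar(ks, means, yerr=sds, marker="o", capsize=3)
        ax.set_xlabel("folds (k)")
        ax.set_ylabel("cross-validation accuracy")
        ax.set_ylim(0, 1.02)
        return ax

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean,
            "std_accuracy": self.std,
            "per_k_mean": self.per_k(),
            "accuracies": {f"k={k},seed={s}": a
                           for (k, s), a in sorted(self.accuracies.items())},
            "class_set": list(self.class_set),
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class_metrics(),
        }


def kfold_partition(
    sample_ids: Sequence,
    labels: Sequence[str],
    k: int,
    seed: int,
    stratified: bool = True,
) -> list:
    """Random k-fold split of sample indices, deterministic given seed.

    Fold sizes differ by at most one.  In stratified mode each class's
    shuffled samples are dealt onto the folds by one global round-robin
    pointer, so per-fold class counts also differ by at most one; a class
    smaller than k simply lands in a subset of the folds (with a warning).
    """
    n = len(sample_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} samples")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list = [[] for _ in range(k)]
    if not stratified:
        perm = rng.permutation(n)
        for p, idx in enumerate(perm):
            folds[p % k].append(int(idx))
    else:
        labels = list(labels)
        classes = list(dict.fromkeys(labels))
        pointer = int(rng.integers(k))
        for cls in classes:
            idx = np.array([i for i, l in enumerate(labels) if l == cls])
            if idx.size < k:
                warnings.warn(
                    f"class {cls!r} has {idx.size} samples < k={k}; "
                    "it cannot appear in every fold", stacklevel=2)
            idx = idx[rng.permutation(idx.size)]
            for i in idx:
                folds[pointer % k].append(int(i))
                pointer += 1
    return [np.array(sorted(f), dtype=np.intp) for f in folds]


def _refit_discretization(matrix, subset, sub, train_idx, fold, seed):
    """Strict-mode helper: refit per-gene discretization on the training
    fold and push the held-out samples through the training boundaries."""
    from . import discretize as _dz
    from .data import ExpressionMatrix

    gidx = [matrix.gene_ids.index(g) for g in subset]
    train_matrix = ExpressionMatrix(
        subset, [matrix.sample_ids[i] for i in train_idx],
        matrix.values[np.ix_(gidx, train_idx)],
        [matrix.labels[i] for i in train_idx], list(matrix.class_set))
    train = _dz.discretize_matrix(train_matrix, seed=seed)
    test_codes = np.empty((len(subset), fold.size), dtype=np.intp)
    for r, g in enumerate(subset):
        codes = _dz.apply_boundaries(matrix.values[gidx[r], fold],
                                     train.boundaries_per_gene[r])
        test_codes[r] = np.minimum(codes, train.ranges_per_gene[r] - 1)
    return train, test_codes


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_set: Sequence[str],
) -> np.ndarray:
    """Counts of (true class i, predicted class j); the diagonal sum over
    the total is the accuracy."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    if len(true_labels) == 0:
        raise ValueError("empty input")
    lut = {c: i for i, c in enumerate(class_set)}
    cm = np.zeros((len(class_set), len(class_set)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lut or p not in lut:
            raise ValueError(f"label outside class_set: {t!r} / {p!r}")
        cm[lut[t], lut[p]] += 1
    return cm


def cross_validate(
    disc: DiscretizedMatrix,
    subset: Sequence[str],
    k_values: Iterable[int] = (5, 6, 7, 8, 9),
    n_seeds: int = 50,
    classifier_config: ClassifierConfig | None = None,
    stratified: bool = True,
    base_seed: int = 0,
    matrix=None,
    strict: bool = False,
) -> CVReport:
    """Repeated k-fold CV of the Bayesian-net classifier on a gene subset.

    For every (k, seed) pair the samples are re-partitioned, the network is
    re-learned on each training split (structure and CPTs — the test fold
    never influences the model) and each sample is tested exactly once.
    Per-run accuracy is correct/total over the whole run; the report also
    pools a confusion matrix across runs.  Seeds are 1..n_seeds offset by
    ``base_seed``.

    By default the discretization in ``disc`` (fitted once on the full
    matrix, mirroring a preparation step that precedes evaluation) is
    reused in every fold.  With ``strict=True`` and the continuous
    ``matrix`` supplied, the per-gene discretization is refitted on each
    training fold only and test samples are mapped through the training
    boundaries, removing that (mild) information leak.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if strict and matrix is None:
        raise ValueError("strict mode needs the continuous matrix")
    cfg = classifier_config or ClassifierConfig()
    sub = disc.restrict(subset)
    # the configured ordering may cover a larger candidate pool
    order = ([g for g in cfg.order if g in set(subset)]
             if cfg.order is not None else None)
    if order is not None and len(order) != len(subset):
        raise ValueError("classifier order does not cover the subset")
    accuracies: dict = {}
    cm = np.zeros((len(disc.class_set), len(disc.class_set)), dtype=np.int64)
    for k in k_values:
        for rep in range(1, n_seeds + 1):
            seed = base_seed + rep
            folds = kfold_partition(sub.sample_ids, sub.labels, k, seed,
                                    stratified)
            correct = 0
            run_true: list = []
            run_pred: list = []
            for fold in folds:
                mask = np.ones(sub.n_samples, dtype=bool)
                mask[fold] = False
                train_idx = np.flatnonzero(mask)
                if strict:
                    train, test_codes = _refit_discretization(
                        matrix, subset, sub, train_idx, fold, seed)
                else:
                    train = sub.restrict_samples(train_idx)
                    test_codes = sub.codes[:, fold]
                model = bayesnet.learn_structure(
                    train, order=order, max_parents=cfg.max_parents,
                    smoothing=cfg.smoothing)
                pred = bayesnet.predict_codes(model, test_codes)
                truth = [sub.labels[i] for i in fold]
                correct += sum(p == t for p, t in zip(pred, truth))
                run_true.extend(truth)
                run_pred.extend(pred)
            accuracies[(k, seed)] = correct / sub.n_samples
            cm += confusion_matrix(run_true, run_pred, sub.class_set)
    return CVReport(accuracies, list(sub.class_set), cm)


@dataclass
class RocCurve:
    """Empirical ROC with trapezoid AUC, Hanley-McNeil SE and 95% CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float
    ci: tuple

    def __post_init__(self):
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC operating points must be monotone")
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC out of [0, 1]")

    def plot(self, ax=None, label=None):
        """The ROC curve with its AUC, SE and 95% CI in the legend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        text = (f"AUC {self.auc:.3f} (SE {self.se:.4f}, "
                f"CI {self.ci[0]:.3f}-{self.ci[1]:.3f})")
        if label:
            text = f"{label}: {text}"
        ax.plot(self.fpr, self.tpr, label=text)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("false-positive rate")
        ax.set_ylabel("true-positive rate")
        ax.legend(loc="lower right", fontsize=8)
        return ax


def roc_curve(scores: Sequence[float], binary_labels: Sequence[int]) -> RocCurve:
    """Empirical ROC of a score for a binary label (1 = positive).

    Tied scores collapse to a single operating point; the trapezoid AUC
    then equals the Mann-Whitney probability P(score+ > score-) + tie/2.
    The standard error is Hanley & McNeil's binormal-free formula and the
    95% CI is auc +/- 1.96*SE clipped to [0, 1].
    """
    y = np.asarray(binary_labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    fpr, tpr, _ = _sk_roc_curve(y, s)
    a = float(_trapezoid_auc(fpr, tpr))
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    lo = max(0.0, a - 1.96 * se)
    hi = min(1.0, a + 1.96 * se)
    return RocCurve(fpr, tpr, a, se, (lo, hi))
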