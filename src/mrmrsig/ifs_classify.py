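"""Incremental feature selection with a leave-one-out cross-validated SVM.

The classifier contract mirrors the historical e1071::svm defaults: RBF
kernel, cost 1, gamma = 1/n_features, features scaled to zero mean / unit
variance.  Scaling is fitted inside each LOOCV fold on the held-in samples
only, so no information leaks from the held-out sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .datamodel_io import DatasetPair, ExpressionMatrix
from .mrmr import RankedGeneList


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM configuration. gamma may be the string "auto" (= 1/n_features) or a float."""

    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | str = "auto"
    feature_scaling: bool = True

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError("cost must be positive")

    def make_svc(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.cost, gamma=self.gamma)


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FN/FP/TN counts with the POSITIVE class as 'positive'."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn}


@dataclass(frozen=True)
class Metrics:
    acc: float
    sn: float
    sp: float

    def rounded(self, ndigits: int = 3) -> "Metrics":
        return Metrics(round(self.acc, ndigits), round(self.sn, ndigits), round(self.sp, ndigits))


@dataclass
class IFSCurve:
    """LOOCV accuracy for each nested top-k candidate gene set, k = 1..k_max."""

    points: list[tuple[int, float]]

    def __post_init__(self) -> None:
        ks = [k for k, _ in self.points]
        if ks != list(range(1, len(ks) + 1)):
            raise ValueError("curve k values must be consecutive from 1")

    @property
    def k_max(self) -> int:
        return len(self.points)

    def accuracies(self) -> np.ndarray:
        return np.array([a for _, a in self.points])


@dataclass(frozen=True)
class SignatureSelection:
    chosen_k: int
    argmax_k: int
    chosen_accuracy: float
    max_accuracy: float
    floor_unmet: bool = False


def metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy, sensitivity and specificity from a confusion matrix.

    ACC = (TP+TN)/(TP+TN+FP+FN); Sn = TP/(TP+FN); Sp = TN/(TN+FP).
    """
    if cm.tp + cm.fn == 0:
        raise ZeroDivisionError("no actual-positive samples: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise ZeroDivisionError("no actual-negative samples: specificity undefined")
    acc = (cm.tp + cm.tn) / cm.total
    sn = cm.tp / (cm.tp + cm.fn)
    sp = cm.tn / (cm.tn + cm.fp)
    return Metrics(acc=acc, sn=sn, sp=sp)


def _scale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant features pass through centered
    return mu, sd


def _design(m: ExpressionMatrix, genes) -> tuple[np.ndarray, np.ndarray]:
    idx = m.gene_index(list(genes))
    X = m.values[idx, :].T  # samples x features
    y = m.label_vector()
    return X, y


def loocv_accuracy(
    m: ExpressionMatrix, genes, spec: ClassifierSpec | None = None
) -> tuple[float, ConfusionMatrix]:
    """Pooled leave-one-out confusion matrix and accuracy for one gene subset.

    Samples are canonicalized to lexicographic id order first, so the result
    is independent of input column order.
    """
    if spec is None:
        spec = ClassifierSpec()
    X, y = _design(m, genes)
    order = np.argsort(np.asarray(m.sample_ids, dtype=object))
    X, y = X[order, :], y[order]
    n = len(y)
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each class needs >= 2 samples for LOOCV (got {n_pos} positive, {n_neg} negative)"
        )
    pred = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        Xte = X[i : i + 1]
        if spec.feature_scaling:
            mu, sd = _scale_fit(Xtr)
            Xtr = (Xtr - mu) / sd
            Xte = (Xte - mu) / sd
        clf = spec.make_svc()
        clf.fit(Xtr, ytr)
        pred[i] = clf.predict(Xte)[0]
        mask[i] = True
    cm = _confusion(y, pred)
    return (cm.tp + cm.tn) / n, cm


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionMatrix:
    return ConfusionMatrix(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
    )


def run_ifs(
    m: ExpressionMatrix,
    ranked: RankedGeneList,
    k_max: int = 500,
    spec: ClassifierSpec | None = None,
) -> IFSCurve:
    """LOOCV accuracy of the top-k ranked genes for every k up to k_max."""
    if k_max > len(ranked):
        raise ValueError(f"k_max={k_max} exceeds ranked list length {len(ranked)}")
    points = []
    for k in range(1, k_max + 1):
        acc, _ = loocv_accuracy(m, ranked.top(k), spec)
        points.append((k, acc))
    return IFSCurve(points=points)


def select_signature_size(
    curve: IFSCurve, delta: float = 0.01, acc_floor: float = 0.90
) -> SignatureSelection:
    """Smallest k within delta of the curve maximum and above the accuracy floor.

    If no k reaches the floor, the argmax k is returned with floor_unmet set.
    """
    if delta < 0 or not 0 <= acc_floor <= 1:
        raise ValueError("delta must be >= 0 and acc_floor in [0, 1]")
    accs = curve.accuracies()
    max_acc = float(accs.max())
    argmax_k = int(np.argmax(accs)) + 1
    # "within delta" is strict (a gap of exactly delta is not a plateau), but the
    # maximum itself always qualifies so delta = 0 degenerates to the argmax
    within = (max_acc - accs < delta) | (accs == max_acc)
    ok = within & (accs >= acc_floor)
    if ok.any():
        k = int(np.argmax(ok)) + 1
        return SignatureSelection(k, argmax_k, float(accs[k - 1]), max_acc)
    return SignatureSelection(argmax_k, argmax_k, max_acc, max_acc, floor_unmet=True)


def train_final_and_test(
    pair: DatasetPair, genes, spec: ClassifierSpec | None = None
) -> ConfusionMatrix:
    """Fit once on the full training set, evaluate on the independent test set.

    Scaling parameters are fitted on training data only.
    """
    if spec is None:
        spec = ClassifierSpec()
    Xtr, ytr = _design(pair.train, genes)
    Xte, yte = _design(pair.test, genes)
    if spec.feature_scaling:
        mu, sd = _scale_fit(Xtr)
        Xtr = (Xtr - mu) / sd
        Xte = (Xte - mu) / sd
    clf = spec.make_svc()
    clf.fit(Xtr, ytr)
    return _confusion(yte, clf.predict(Xte))


def write_curve(curve: IFSCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("k\taccuracy\n")
        for k, a in curve.points:
            fh.write(f"{k}\t{a!r}\n")


def read_curve(path) -> IFSCurve:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return IFSCurve(points=[(int(k), float(a)) for k, a in zip(df["k"], df["accuracy"])])
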