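"""Kernel-SVM two-class classification with leave-one-out cross-validation.

The classifier is a soft-margin support vector machine evaluated through
its kernel expansion

    f(x) = sum_i c_i K(x_i, x) + b,

with the polynomial kernel K(a, b) = (1 + a.b)^d; ``linear`` is the plain
inner product and ``quadratic`` is the degree-2 polynomial.  The quadratic
program behind the fit is delegated to scikit-learn's SVC on a precomputed
kernel matrix, but the coefficients c_i and offset b are exposed and the
decision function is evaluated by this module's own kernel code.

Accuracy is reported by leave-one-out cross-validation: each of the P
frames is predicted once by a model trained on the remaining P - 1, and

    accuracy = 100 * N_t / (N_A + N_B)

counts the correctly classified frames.  Features are z-scored inside each
fold using statistics of the training rows only -- correlations live in
[-1, 1] while entropies reach several bits, and kernel machines need the
scales commensurate; computing the statistics per fold avoids leaking the
held-out frame into training.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: linear, quadratic (= polynomial degree 2), polynomial.

    The polynomial degree defaults to 3 when unspecified; ``coef0`` is the
    additive constant inside the power.
    """

    name: str = "polynomial"
    degree: int | None = None
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in ("linear", "quadratic", "polynomial"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.degree is not None and self.degree < 1:
            raise ValueError("degree must be >= 1")

    @property
    def effective_degree(self) -> int:
        if self.name == "linear":
            return 1
        if self.name == "quadratic":
            return 2
        return self.degree if self.degree is not None else 3


def kernel_matrix(X: np.ndarray, Y: np.ndarray | None = None,
                  kspec: KernelSpec = KernelSpec()) -> np.ndarray:
    """Gram matrix K[i, j] = K(X_i, Y_j); symmetric PSD when Y is X."""
    X = np.atleast_2d(np.asarray(X, float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    G = X @ Y.T
    if kspec.name == "linear":
        return G
    return (kspec.coef0 + G) ** kspec.effective_degree


@dataclasses.dataclass
class SvmModel:
    """Fitted kernel SVM in explicit expansion form."""

    X_train: np.ndarray
    coefficients: np.ndarray  # c_i over all P training rows (0 off-support)
    b: float
    kspec: KernelSpec
    classes: tuple = (-1, 1)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """f(x) = sum_i c_i K(x_i, x) + b, via this module's kernel."""
        K = kernel_matrix(np.atleast_2d(np.asarray(X, float)),
                          self.X_train, self.kspec)
        return K @ self.coefficients + self.b

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Sign of the decision function; f(x) = 0 resolves to +1."""
        f = self.decision_function(X)
        return np.where(f >= 0, self.classes[1], self.classes[0])


@dataclasses.dataclass
class CvResult:
    """Leave-one-out outcome: per-frame predictions and the accuracy (%)."""

    predictions: np.ndarray
    true_labels: np.ndarray
    margins: np.ndarray

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.predictions == self.true_labels))

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / len(self.true_labels)


def train(X: np.ndarray, y: np.ndarray,
          kspec: KernelSpec = KernelSpec(),
          c_penalty: float = 1.0) -> SvmModel:
    """Fit the soft-margin SVM; labels must be two classes coded +1/-1."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    if set(classes) != {-1, 1}:
        raise ValueError("labels must be coded as +1 / -1")
    K = kernel_matrix(X, X, kspec)
    svc = SVC(kernel="precomputed", C=c_penalty)
    svc.fit(K, y)
    coef = np.zeros(len(y))
    coef[svc.support_] = svc.dual_coef_[0]
    return SvmModel(
        X_train=X,
        coefficients=coef,
        b=float(svc.intercept_[0]),
        kspec=kspec,
    )


def _fold_standardizer(X_train: np.ndarray):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return lambda X: (X - mean) / sd


def loocv(X: np.ndarray, y: np.ndarray,
          kspec: KernelSpec = KernelSpec(),
          c_penalty: float = 1.0,
          standardize: bool = True) -> CvResult:
    """Leave-one-out cross-validation: exactly P train/predict cycles.

    Standardization statistics are recomputed from the P - 1 training rows
    of each fold; the held-out frame never contributes.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y)
    P = len(y)
    for cls in np.unique(y):
        if np.sum(y == cls) < 2:
            raise ValueError(f"class {cls} has fewer than 2 frames")
    preds = np.empty(P, dtype=y.dtype)
    margins = np.empty(P, dtype=float)
    for k in range(P):
        mask = np.ones(P, dtype=bool)
        mask[k] = False
        X_tr, y_tr = X[mask], y[mask]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {k}: training set is single-class")
        if standardize:
            scale = _fold_standardizer(X_tr)
            X_tr = scale(X_tr)
            X_te = scale(X[k:k + 1])
        else:
            X_te = X[k:k + 1]
        model = train(X_tr, y_tr, kspec, c_penalty)
        margins[k] = model.decision_function(X_te)[0]
        preds[k] = model.predict(X_te)[0]
    return CvResult(predictions=preds, true_labels=y.copy(), margins=margins)


def _encode_pair(labels: np.ndarray, pair: tuple[str, str]) -> np.ndarray:
    """First label of the sorted pair -> +1, the other -> -1."""
    pos = sorted(pair)[0]
    return np.where(labels == pos, 1, -1)


def task_pair_experiment(
    feature_sets: Mapping[str, "object"],
    kernels: Sequence[KernelSpec] = (KernelSpec(),),
    c_penalty: float = 1.0,
) -> pd.DataFrame:
    """LOOCV accuracy for every task pair under every (extractor, kernel).

    ``feature_sets`` maps a method name to a FeatureMatrix-like object with
    ``values`` and ``labels``.  The output table has one row per unordered
    task-label pair plus ``Avg`` and ``Std dev`` summary rows (sample
    standard deviation), one column per method/kernel combination.
    """
    first = next(iter(feature_sets.values()))
    all_labels = sorted(set(first.labels))
    if len(all_labels) < 2:
        raise ValueError("need at least 2 task labels")
    pairs = list(itertools.combinations(all_labels, 2))
    columns: dict[str, list[float]] = {}
    for method, fm in feature_sets.items():
        labels = np.asarray(fm.labels)
        for kspec in kernels:
            col = (f"{method}:{kspec.name}" if len(kernels) > 1 else method)
            accs = []
            for pair in pairs:
                mask = np.isin(labels, pair)
                y = _encode_pair(labels[mask], pair)
                res = loocv(fm.values[mask], y, kspec, c_penalty)
                accs.append(res.accuracy)
            columns[col] = accs
    index = [f"{a}{b}" for a, b in pairs]
    table = pd.DataFrame(columns, index=index)
    table.loc["Avg"] = table.loc[index].mean()
    table.loc["Std dev"] = table.loc[index].std(ddof=1)
    return table
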