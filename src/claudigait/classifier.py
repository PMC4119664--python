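"""SVM-based differentiation of the four gait classes.

The presented method trains four one-vs-rest soft-margin RBF-SVM binary
classifiers, one per class, each restricted to its own feature subset
(the "+" columns of the feature-selection table), with its own z-score
normalization and its own grid-searched (C, gamma).  A test subject is
assigned to ``argmax_i f_i(x)`` over the four raw decision values.

Four reference classifiers consume the full nine-feature z-scored
vector: linear discriminant analysis, a decision tree, a one-vs-one SVM
(6 pairwise classifiers, majority vote) and a plain one-vs-rest SVM,
the latter two with one shared grid-searched (C, gamma).

Binary SVM solving is delegated to libsvm via scikit-learn; the decision
function is f(x) = w.phi(x) + b with the positive class mapped to +1, so
``sign(f)`` is the binary decision.  Grid-search model selection uses
scikit-learn's low-level libsvm binding directly (verified in the test
suite to produce decision values identical to ``sklearn.svm.SVC``) to
keep leave-one-out evaluation with per-fold grid search fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
import sklearn.svm._libsvm as _libsvm

from .features import FEATURE_NAMES

_libsvm.set_verbosity_wrap(0)

#: Fixed class order; argmax and vote ties resolve to the earliest entry.
CLASS_ORDER = ("normal", "PAD", "L5", "L4")

#: Exponentially increasing hyperparameter grids, C = 2^-5, 2^-3, ..., 2^15
#: and gamma = 2^-15, 2^-13, ..., 2^3.
DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))

#: Per-class feature subsets ("+" rows of the selection table), as boolean
#: masks over FEATURE_NAMES.
_MASK_TABLE = {
    "normal": ("mean_ankle_angle", "femur_amplitude", "gastroc_max_contracted",
               "gastroc_rom", "quad_max_relaxed"),
    "PAD": ("mean_ankle_angle", "gastroc_max_relaxed", "gastroc_max_contracted",
            "quad_rom"),
    "L5": ("mean_ankle_angle", "gastroc_max_relaxed", "gastroc_max_contracted",
           "quad_rom"),
    "L4": ("mean_ankle_angle", "knee_angle_at_stance_start", "gastroc_max_relaxed",
           "gastroc_max_contracted", "quad_max_contracted", "quad_rom"),
}
DEFAULT_FEATURE_MASKS = {
    label: np.array([name in selected for name in FEATURE_NAMES])
    for label, selected in _MASK_TABLE.items()
}

BASELINE_METHODS = ("lda", "tree", "ovo_svm", "ovr_svm")


# --------------------------------------------------------------------------
# normalization

@dataclass(frozen=True)
class NormStats:
    """Per-feature z-score statistics fitted on training data only.

    Scale is the population standard deviation (ddof = 0); a feature that
    is constant in training maps to 0 everywhere.
    """

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def normalize_fit(X: np.ndarray) -> NormStats:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("need a non-empty 2-D training matrix")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    return NormStats(mean=mean, scale=scale)


def normalize_apply(stats: NormStats, X: np.ndarray) -> np.ndarray:
    return stats.apply(X)


# --------------------------------------------------------------------------
# kernels and binary SVM

@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.  ``gamma`` applies to rbf, polynomial
    and sigmoid kernels; ``coef0``/``degree`` to polynomial and sigmoid;
    parameters unused by a kind are ignored.  The main pipeline uses rbf
    only."""

    kind: str = "rbf"
    gamma: float = 1.0
    coef0: float = 0.0
    degree: int = 3

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "polynomial", "rbf", "sigmoid"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind in ("rbf", "polynomial", "sigmoid") and self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def svc_kwargs(self) -> dict:
        name = {"polynomial": "poly"}.get(self.kind, self.kind)
        kw = {"kernel": name}
        if self.kind != "linear":
            kw["gamma"] = self.gamma
        if self.kind in ("polynomial", "sigmoid"):
            kw["coef0"] = self.coef0
        if self.kind == "polynomial":
            kw["degree"] = self.degree
        return kw


def train_binary_svm(X: np.ndarray, y: np.ndarray, C: float,
                     kernel: KernelSpec | None = None) -> SVC:
    """Fit one soft-margin binary SVM with labels in {-1, +1}.

    The returned model's ``decision_function`` is positive on the +1 side,
    so ``sign(f(x))`` is the binary decision.
    """
    if kernel is None:
        kernel = KernelSpec("rbf")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    uniq = set(np.unique(y).tolist())
    if uniq != {-1, 1}:
        raise ValueError("labels must contain both -1 and +1")
    if C <= 0:
        raise ValueError("C must be > 0")
    return SVC(C=C, **kernel.svc_kwargs()).fit(X, y)


def _fast_rbf_decision(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                       C: float, gamma: float) -> np.ndarray:
    """Binary RBF-SVM decision values on ``Xte`` via the low-level libsvm
    binding, in the same sign convention as ``SVC.decision_function``
    (positive = larger label).  Used only inside grid-search scoring."""
    out = _libsvm.fit(
        np.ascontiguousarray(Xtr, dtype=np.float64),
        np.ascontiguousarray(ytr, dtype=np.float64),
        svm_type=0, kernel="rbf", C=float(C), gamma=float(gamma),
    )
    df = _libsvm.decision_function(
        np.ascontiguousarray(Xte, dtype=np.float64),
        out[0], out[1], out[2], out[3], out[4], out[5], out[6],
        kernel="rbf", gamma=float(gamma),
    )
    return -df.ravel()


# --------------------------------------------------------------------------
# grid search

def _cv_folds(y: np.ndarray, seed: int):
    """Stratified folds for internal model selection: 5 folds, reduced to
    3 when the smallest class has fewer than 5 members and to
    leave-one-out when it has fewer than 3."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    m = int(counts.min())
    if m >= 5:
        k = 5
    elif m >= 3:
        k = 3
    else:
        return [(np.delete(np.arange(y.size), i), np.array([i])) for i in range(y.size)]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(y.size), y))


def _binary_scheme(Xtr, ytr, Xte, C, gamma):
    return np.where(_fast_rbf_decision(Xtr, ytr, Xte, C, gamma) >= 0, 1, -1)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    seed: int = 0,
    scheme=None,
    folds=None,
) -> tuple[float, float]:
    """Exhaustive (C, gamma) search maximizing internal cross-validated
    accuracy; ties break to the smallest C, then the smallest gamma.

    ``scheme(Xtr, ytr, Xte, C, gamma) -> predicted labels`` defines what
    is being tuned; the default is a single binary RBF-SVM.  Deterministic
    given ``seed`` (which shuffles the stratified folds).
    """
    C_grid = sorted(float(c) for c in C_grid)
    gamma_grid = sorted(float(g) for g in gamma_grid)
    if not C_grid or not gamma_grid:
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if scheme is None:
        scheme = _binary_scheme
    if folds is None:
        folds = _cv_folds(y, seed)
    # a training split holding a single class cannot be fitted; score over
    # the remaining splits (degenerate when none survive)
    splits = [
        (X[tr], y[tr], X[te], y[te])
        for tr, te in folds
        if np.unique(y[tr]).size >= 2
    ]
    if not splits:
        raise ValueError("degenerate folds: no split contains both labels")
    best = None
    best_correct = -1
    for C in C_grid:
        for gamma in gamma_grid:
            correct = 0
            for Xtr, ytr, Xte, yte in splits:
                pred = scheme(Xtr, ytr, Xte, C, gamma)
                correct += int(np.sum(pred == yte))
            if correct > best_correct:
                best_correct = correct
                best = (C, gamma)
    return best


# --------------------------------------------------------------------------
# the presented per-class-subset one-vs-rest model

@dataclass
class _ClassUnit:
    """One trained one-vs-rest binary classifier with its feature mask,
    normalization statistics and hyperparameters."""

    label: str
    mask: np.ndarray
    stats: NormStats
    C: float
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = self.stats.apply(np.asarray(X, dtype=float)[:, self.mask])
        sq = (
            np.sum(Z * Z, axis=1)[:, None]
            + np.sum(self.support_vectors * self.support_vectors, axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * sq)
        return K @ self.dual_coef + self.intercept


@dataclass
class SubsetOVRModel:
    """Four one-vs-rest binary RBF-SVMs, each with its own feature subset,
    normalization and (C, gamma); the overall decision is the argmax of
    the four raw decision values, ties resolving to class order."""

    units: dict = field(default_factory=dict)
    classes: tuple = CLASS_ORDER

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"expected {len(FEATURE_NAMES)} features")
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        return np.column_stack([self.units[c].decision(X) for c in self.classes])

    def predict(self, X: np.ndarray) -> np.ndarray:
        f = self.decision_values(X)
        return np.asarray(self.classes, dtype=object)[np.argmax(f, axis=1)]

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "feature_names": list(FEATURE_NAMES),
            "units": {
                c: {
                    "mask": u.mask.astype(int).tolist(),
                    "mean": u.stats.mean.tolist(),
                    "scale": u.stats.scale.tolist(),
                    "C": u.C,
                    "gamma": u.gamma,
                    "support_vectors": u.support_vectors.tolist(),
                    "dual_coef": u.dual_coef.tolist(),
                    "intercept": u.intercept,
                }
                for c, u in self.units.items()
            },
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "SubsetOVRModel":
        units = {}
        for c, u in d["units"].items():
            units[c] = _ClassUnit(
                label=c,
                mask=np.asarray(u["mask"], dtype=bool),
                stats=NormStats(np.asarray(u["mean"]), np.asarray(u["scale"])),
                C=u["C"],
                gamma=u["gamma"],
                support_vectors=np.asarray(u["support_vectors"], dtype=float),
                dual_coef=np.asarray(u["dual_coef"], dtype=float),
                intercept=float(u["intercept"]),
            )
        return cls(units=units, classes=tuple(d["classes"]))

    @classmethod
    def load(cls, path) -> "SubsetOVRModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_presented(
    X: np.ndarray,
    y,
    masks: dict | None = None,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> SubsetOVRModel:
    """Train the presented per-class-subset one-vs-rest model.

    For each class: restrict features to that class's mask, fit z-score
    normalization on the training data, grid-search (C, gamma) separately
    and train the binary SVM with the class as +1 and the rest as -1.
    """
    if masks is None:
        masks = DEFAULT_FEATURE_MASKS
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    present = set(np.unique(y).tolist())
    model = SubsetOVRModel()
    for label in model.classes:
        if label not in present:
            raise ValueError(f"class {label!r} absent from training data")
        mask = np.asarray(masks[label], dtype=bool)
        if not mask.any():
            raise ValueError(f"feature mask for {label!r} selects no features")
        Xi = X[:, mask]
        stats = normalize_fit(Xi)
        Z = stats.apply(Xi)
        ybin = np.where(y == label, 1, -1)
        C, gamma = grid_search(Z, ybin, C_grid, gamma_grid, seed=seed)
        svc = train_binary_svm(Z, ybin, C, KernelSpec("rbf", gamma=gamma))
        model.units[label] = _ClassUnit(
            label=label,
            mask=mask,
            stats=stats,
            C=C,
            gamma=gamma,
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_.ravel().copy(),
            intercept=float(svc.intercept_[0]),
        )
    return model


def predict_presented(model: SubsetOVRModel, X: np.ndarray):
    """Class labels (and per-class decision values) for test features."""
    return model.predict(X), model.decision_values(X)


# --------------------------------------------------------------------------
# reference classifiers (full nine-feature z-scored input, no masks)

@dataclass
class BaselineModel:
    method: str
    stats: NormStats
    classes: tuple
    impl: object = None           # sklearn estimator for lda / tree
    C: float | None = None
    gamma: float | None = None
    binaries: dict = field(default_factory=dict)   # svm schemes

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Z = self.stats.apply(X)
        if self.method in ("lda", "tree"):
            return self.impl.predict(Z).astype(object)
        if self.method == "ovr_svm":
            f = np.column_stack(
                [self.binaries[c].decision_function(Z) for c in self.classes]
            )
            return np.asarray(self.classes, dtype=object)[np.argmax(f, axis=1)]
        # ovo_svm: majority vote; ties by summed decision values, then order
        votes = np.zeros((Z.shape[0], len(self.classes)))
        sums = np.zeros_like(votes)
        for (i, j), svc in self.binaries.items():
            f = svc.decision_function(Z)      # positive = class i (+1)
            votes[:, i] += f > 0
            votes[:, j] += f <= 0
            sums[:, i] += f
            sums[:, j] -= f
        out = np.empty(Z.shape[0], dtype=object)
        for r in range(Z.shape[0]):
            top = np.nonzero(votes[r] == votes[r].max())[0]
            if top.size > 1:
                top = top[sums[r, top] == sums[r, top].max()]
            out[r] = self.classes[top[0]]
        return out


def _ovr_scheme(classes):
    arr = np.asarray(classes, dtype=object)

    def scheme(Xtr, ytr, Xte, C, gamma):
        f = np.column_stack(
            [_fast_rbf_decision(Xtr, np.where(ytr == c, 1, -1), Xte, C, gamma) for c in classes]
        )
        return arr[np.argmax(f, axis=1)]

    return scheme


def _ovo_scheme(classes):
    arr = np.asarray(classes, dtype=object)
    pairs = list(combinations(range(len(classes)), 2))

    def scheme(Xtr, ytr, Xte, C, gamma):
        votes = np.zeros((Xte.shape[0], len(classes)))
        sums = np.zeros_like(votes)
        for i, j in pairs:
            sel = (ytr == classes[i]) | (ytr == classes[j])
            f = _fast_rbf_decision(
                Xtr[sel], np.where(ytr[sel] == classes[i], 1, -1), Xte, C, gamma
            )
            votes[:, i] += f > 0
            votes[:, j] += f <= 0
            sums[:, i] += f
            sums[:, j] -= f
        out = np.empty(Xte.shape[0], dtype=object)
        for r in range(Xte.shape[0]):
            top = np.nonzero(votes[r] == votes[r].max())[0]
            if top.size > 1:
                top = top[sums[r, top] == sums[r, top].max()]
            out[r] = arr[top[0]]
        return out

    return scheme


def train_baseline(
    X: np.ndarray,
    y,
    method: str,
    seed: int = 0,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
) -> BaselineModel:
    """Train one reference classifier on the full z-scored feature vector.

    ``ovo_svm`` trains k(k-1)/2 = 6 pairwise binary classifiers combined
    by majority vote; ``ovr_svm`` trains 4 one-vs-rest classifiers
    combined by argmax.  Both use one shared (C, gamma) grid-searched on
    the accuracy of the full multiclass scheme.  ``lda`` and ``tree`` use
    the library defaults (tree seeded for determinism).
    """
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {BASELINE_METHODS}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    classes = tuple(c for c in CLASS_ORDER if c in set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    stats = normalize_fit(X)
    Z = stats.apply(X)
    model = BaselineModel(method=method, stats=stats, classes=classes)

    if method == "lda":
        model.impl = LinearDiscriminantAnalysis().fit(Z, y.astype(str))
    elif method == "tree":
        model.impl = DecisionTreeClassifier(random_state=seed).fit(Z, y.astype(str))
    elif method == "ovr_svm":
        scheme = _ovr_scheme(classes)
        C, gamma = grid_search(Z, y, C_grid, gamma_grid, seed=seed, scheme=scheme)
        model.C, model.gamma = C, gamma
        for c in classes:
            model.binaries[c] = train_binary_svm(
                Z, np.where(y == c, 1, -1), C, KernelSpec("rbf", gamma=gamma)
            )
    else:  # ovo_svm
        scheme = _ovo_scheme(classes)
        C, gamma = grid_search(Z, y, C_grid, gamma_grid, seed=seed, scheme=scheme)
        model.C, model.gamma = C, gamma
        for i, j in combinations(range(len(classes)), 2):
            sel = (y == classes[i]) | (y == classes[j])
            model.binaries[(i, j)] = train_binary_svm(
                Z[sel], np.where(y[sel] == classes[i], 1, -1), C,
                KernelSpec("rbf", gamma=gamma),
            )
    return model
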