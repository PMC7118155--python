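"""Classifiers and evaluation protocols for burn-group feature vectors.

Pairwise separation uses a soft-margin support vector machine with a radial
basis function kernel; samples of the null-hypothesis group carry label +1
and the rest -1, so the sign of the decision value (the signed distance to
the separating hyperplane) gives the predicted group.  Multiclass
classification uses kernel Fisher discriminant analysis (KFDA): the Fisher
criterion -- projected between-class over within-class scatter -- is solved
in the RBF feature space through the kernel-matrix generalized eigenproblem,
yielding at most C-1 discriminant scores; a sample is assigned to the class
whose training-score centroid is nearest.

Both protocols are assessed with leave-one-out cross-validation (LOOCV):
the min-max normalization statistics and the classifier are refit on every
fold from the remaining samples only, so the held-out observation never
influences its own prediction.  A stratified Monte-Carlo split evaluation
and the minimum-sample-size formula for a diagnostic test with given
sensitivity, specificity, prevalence and marginal error complete the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import LinAlgError, eigh
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.svm import SVC

from .features import FeatureMatrix, MinMaxStats, apply_normalization

__all__ = [
    "BinaryConfusion",
    "MulticlassConfusion",
    "PerformanceMeasures",
    "SampleSizeSpec",
    "SvmModel",
    "KfdaModel",
    "train_svm",
    "svm_score",
    "loocv_binary",
    "kfda_fit",
    "kfda_transform",
    "kfda_classify",
    "loocv_multiclass",
    "monte_carlo_eval",
    "compute_measures",
    "min_sample_size",
]


# ---------------------------------------------------------------------------
# confusion matrices and measures

@dataclass(frozen=True)
class BinaryConfusion:
    """2x2 confusion counts; the positive class is the null-hypothesis group."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive_label: str = "+1"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class PerformanceMeasures:
    accuracy: float
    sensitivity: float
    specificity: float

    def rounded(self, ndigits: int = 2) -> "PerformanceMeasures":
        """Half-up rounding for report display; raw ratios stay available."""
        def r(x: float) -> float:
            return math.floor(x * 10**ndigits + 0.5) / 10**ndigits

        return PerformanceMeasures(r(self.accuracy), r(self.sensitivity), r(self.specificity))


def compute_measures(cm: BinaryConfusion) -> PerformanceMeasures:
    """Accuracy, sensitivity and specificity of a binary confusion matrix."""
    pos, neg = cm.tp + cm.fn, cm.tn + cm.fp
    if pos == 0 or neg == 0:
        raise ValueError("both classes must have at least one evaluated sample")
    return PerformanceMeasures(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=cm.tp / pos,
        specificity=cm.tn / neg,
    )


@dataclass(frozen=True)
class MulticlassConfusion:
    """C x C counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        C = len(self.class_labels)
        if c.shape != (C, C):
            raise ValueError(f"counts must be {C}x{C}, got {c.shape}")
        if c.min() < 0:
            raise ValueError("confusion counts must be non-negative")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_labels", tuple(self.class_labels))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Row-normalized diagonal: recall of each true class."""
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            acc = np.where(row > 0, np.diag(self.counts) / row, np.nan)
        return acc


# ---------------------------------------------------------------------------
# RBF-SVM pairwise classification

def _resolve_gamma(gamma, X: np.ndarray) -> float:
    if gamma == "scale" or gamma is None:
        var = X.var()
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(gamma)


@dataclass(frozen=True)
class SvmModel:
    """A fitted RBF-SVM for one class pair, with its normalization statistics."""

    svc: SVC
    positive_label: str
    negative_label: str
    feature_names: tuple[str, ...]
    stats: MinMaxStats | None = None
    gamma: float = 0.0
    C: float = 1.0


def train_svm(
    matrix: FeatureMatrix,
    positive_label: str,
    gamma="scale",
    C: float = 1.0,
    stats: MinMaxStats | None = None,
) -> SvmModel:
    """Fit a soft-margin RBF-SVM separating ``positive_label`` from the rest.

    ``matrix`` must hold exactly two classes, already normalized (pass the
    training-fold :class:`MinMaxStats` via ``stats`` so held-out samples can
    be transformed consistently).  The positive (+1) class is the
    null-hypothesis group.
    """
    classes = matrix.classes
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not among classes {classes}")
    if len(classes) != 2:
        raise ValueError(f"pairwise training requires exactly 2 classes, got {classes}")
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values in training data")
    y = np.where(np.asarray(matrix.labels) == positive_label, 1, -1)
    if (y == 1).sum() < 2 or (y == -1).sum() < 2:
        raise ValueError("each class needs at least 2 training samples")
    g = _resolve_gamma(gamma, X)
    svc = SVC(kernel="rbf", C=C, gamma=g)
    svc.fit(X, y)
    negative = next(c for c in classes if c != positive_label)
    return SvmModel(
        svc=svc,
        positive_label=positive_label,
        negative_label=negative,
        feature_names=matrix.feature_names,
        stats=stats,
        gamma=g,
        C=C,
    )


def svm_score(model: SvmModel, sample: np.ndarray) -> float:
    """Signed decision value for one feature vector; positive => H0 group.

    The score is the (kernel-space) signed distance surrogate to the decision
    boundary: its magnitude grows with distance from the margin and its sign
    selects the predicted burn group.
    """
    x = np.asarray(sample, dtype=float).reshape(1, -1)
    if x.shape[1] != len(model.feature_names):
        raise ValueError(
            f"sample has {x.shape[1]} features, model expects {len(model.feature_names)}"
        )
    return float(model.svc.decision_function(x)[0])


def _minmax_stats(X: np.ndarray, names: tuple[str, ...]) -> MinMaxStats:
    return MinMaxStats(mins=X.min(axis=0), maxs=X.max(axis=0), feature_names=names)


def loocv_binary(
    matrix: FeatureMatrix,
    positive_label: str,
    gamma="scale",
    C: float = 1.0,
) -> tuple[BinaryConfusion, PerformanceMeasures, np.ndarray]:
    """Leave-one-out assessment of the pairwise RBF-SVM.

    Every fold refits the min-max normalization and the SVM on the remaining
    samples, then scores the held-out one; the confusion matrix aggregates
    all folds and the measures are computed from the aggregate.  Returns the
    per-sample decision scores in the row order of ``matrix``.
    """
    classes = matrix.classes
    if len(classes) != 2:
        raise ValueError(f"binary LOOCV requires exactly 2 classes, got {classes}")
    labels = np.asarray(matrix.labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples for LOOCV")
    n = matrix.n_samples
    scores = np.empty(n)
    tp = fn = fp = tn = 0
    X = matrix.values
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr = X[keep]
        stats = _minmax_stats(Xtr, matrix.feature_names)
        train = FeatureMatrix(
            apply_normalization(Xtr, stats),
            matrix.feature_names,
            tuple(labels[keep]),
            tuple(np.asarray(matrix.sample_ids)[keep]),
        )
        model = train_svm(train, positive_label, gamma=gamma, C=C, stats=stats)
        s = svm_score(model, apply_normalization(X[i], stats))
        scores[i] = s
        truth_pos = labels[i] == positive_label
        pred_pos = s > 0
        tp += truth_pos and pred_pos
        fn += truth_pos and not pred_pos
        fp += (not truth_pos) and pred_pos
        tn += (not truth_pos) and not pred_pos
    cm = BinaryConfusion(tp=tp, fn=fn, fp=fp, tn=tn, positive_label=positive_label)
    return cm, compute_measures(cm), scores


# ---------------------------------------------------------------------------
# kernel Fisher discriminant analysis

@dataclass(frozen=True)
class KfdaModel:
    """Fitted kernel Fisher discriminant: projection + class centroids."""

    X: np.ndarray
    alphas: np.ndarray                 # (n_train, n_discriminants)
    eigenvalues: np.ndarray
    gamma: float
    regularization: float
    class_labels: tuple[str, ...]
    centroids: np.ndarray              # (C, n_discriminants)
    train_scores: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    train_labels: tuple[str, ...] = ()
    stats: MinMaxStats | None = None


def kfda_fit(
    matrix: FeatureMatrix,
    gamma="scale",
    regularization: float | None = None,
    stats: MinMaxStats | None = None,
) -> KfdaModel:
    """Solve the kernel Fisher criterion for up to C-1 discriminants.

    Maximizes projected between-class over within-class scatter in the RBF
    feature space via the generalized eigenproblem ``M a = lambda N a`` on
    the n x n kernel matrix, with a ridge ``eps * I`` added to the
    within-class term ``N`` (which is rank-deficient by construction).  By
    default ``eps = 1e-3 * trace(N) / n``.  Discriminant directions are
    ordered by decreasing eigenvalue and sign-fixed deterministically.
    """
    classes = matrix.classes
    if len(classes) < 2:
        raise ValueError(f"KFDA needs at least 2 classes, got {classes}")
    labels = np.asarray(matrix.labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    g = _resolve_gamma(gamma, X)
    n = X.shape[0]
    K = rbf_kernel(X, X, gamma=g)
    m_star = K.mean(axis=1)
    M = np.zeros((n, n))
    N = np.zeros((n, n))
    for c in classes:
        idx = np.flatnonzero(labels == c)
        Kc = K[:, idx]
        mc = Kc.mean(axis=1)
        dc = mc - m_star
        M += len(idx) * np.outer(dc, dc)
        N += Kc @ Kc.T - len(idx) * np.outer(mc, mc)
    if regularization is None:
        regularization = 1e-3 * max(np.trace(N), 1e-12) / n
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    N += regularization * np.eye(n)
    try:
        w, v = eigh(M, N)
    except LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"KFDA generalized eigenproblem is singular ({exc}); "
            "increase the regularization"
        ) from exc
    n_disc = min(len(classes) - 1, n - 1)
    order = np.argsort(w)[::-1][:n_disc]
    alphas = v[:, order]
    eigenvalues = w[order]
    # deterministic sign: the largest-magnitude coefficient is positive
    for j in range(alphas.shape[1]):
        k = np.argmax(np.abs(alphas[:, j]))
        if alphas[k, j] < 0:
            alphas[:, j] = -alphas[:, j]
    train_scores = K @ alphas
    centroids = np.stack([train_scores[labels == c].mean(axis=0) for c in classes])
    return KfdaModel(
        X=X.copy(),
        alphas=alphas,
        eigenvalues=eigenvalues,
        gamma=g,
        regularization=float(regularization),
        class_labels=classes,
        centroids=centroids,
        train_scores=train_scores,
        train_labels=tuple(labels),
        stats=stats,
    )


def kfda_transform(model: KfdaModel, samples: np.ndarray) -> np.ndarray:
    """Project samples onto the discriminant scores (s1 ... s_{C-1})."""
    S = np.atleast_2d(np.asarray(samples, dtype=float))
    if S.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"samples have {S.shape[1]} features, model expects {model.X.shape[1]}"
        )
    Kn = rbf_kernel(S, model.X, gamma=model.gamma)
    return Kn @ model.alphas


def kfda_classify(model: KfdaModel, sample: np.ndarray) -> str:
    """Assign the label of the nearest class centroid in score space.

    Distance is Euclidean over the discriminant scores; exact ties go to the
    class that appears first in the model's class order.
    """
    score = kfda_transform(model, np.asarray(sample, dtype=float).reshape(1, -1))[0]
    dists = np.linalg.norm(model.centroids - score, axis=1)
    return model.class_labels[int(np.argmin(dists))]


def loocv_multiclass(
    matrix: FeatureMatrix,
    gamma="scale",
    regularization: float | None = None,
) -> tuple[MulticlassConfusion, np.ndarray, float]:
    """Leave-one-out KFDA over all classes.

    Returns the aggregated C x C confusion matrix, the per-class (recall)
    accuracies, and the overall accuracy (trace / total).
    """
    classes = matrix.classes
    labels = np.asarray(matrix.labels)
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples for LOOCV")
    n = matrix.n_samples
    C = len(classes)
    counts = np.zeros((C, C), dtype=np.int64)
    cindex = {c: k for k, c in enumerate(classes)}
    X = matrix.values
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        stats = _minmax_stats(X[keep], matrix.feature_names)
        train = FeatureMatrix(
            apply_normalization(X[keep], stats),
            matrix.feature_names,
            tuple(labels[keep]),
            tuple(np.asarray(matrix.sample_ids)[keep]),
        )
        model = kfda_fit(train, gamma=gamma, regularization=regularization, stats=stats)
        pred = kfda_classify(model, apply_normalization(X[i], stats))
        counts[cindex[labels[i]], cindex[pred]] += 1
    cm = MulticlassConfusion(counts, classes)
    return cm, cm.per_class_accuracy, cm.overall_accuracy


def monte_carlo_eval(
    matrix: FeatureMatrix,
    train_fraction: float = 0.9,
    repetitions: int = 100,
    seed: int = 0,
    gamma="scale",
    regularization: float | None = None,
) -> tuple[float, np.ndarray]:
    """Repeated stratified random-split evaluation of the KFDA classifier.

    Each repetition draws a mutually exclusive train/test split with
    ``train_fraction`` of every class assigned to training (stratification
    keeps small classes represented), fits KFDA on the training part with
    training-only normalization, and measures test accuracy.  Returns the
    mean accuracy and the per-repetition accuracies.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    labels = np.asarray(matrix.labels)
    classes = matrix.classes
    class_idx = {c: np.flatnonzero(labels == c) for c in classes}
    for c, idx in class_idx.items():
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 2), len(idx) - 1)
        if n_tr < 2 or len(idx) - n_tr < 1:
            raise ValueError(
                f"class {c!r} with {len(idx)} samples cannot be split at "
                f"train_fraction={train_fraction}"
            )
    rng = np.random.default_rng(seed)
    X = matrix.values
    accs = np.empty(repetitions)
    for r in range(repetitions):
        train_mask = np.zeros(matrix.n_samples, dtype=bool)
        for c, idx in class_idx.items():
            n_tr = int(round(train_fraction * len(idx)))
            n_tr = min(max(n_tr, 2), len(idx) - 1)
            perm = rng.permutation(idx)
            train_mask[perm[:n_tr]] = True
        stats = _minmax_stats(X[train_mask], matrix.feature_names)
        train = FeatureMatrix(
            apply_normalization(X[train_mask], stats),
            matrix.feature_names,
            tuple(labels[train_mask]),
            tuple(np.asarray(matrix.sample_ids)[train_mask]),
        )
        model = kfda_fit(train, gamma=gamma, regularization=regularization, stats=stats)
        test_idx = np.flatnonzero(~train_mask)
        preds = [
            kfda_classify(model, apply_normalization(X[i], stats)) for i in test_idx
        ]
        accs[r] = np.mean([p == labels[i] for p, i in zip(preds, test_idx)])
    return float(accs.mean()), accs


# ---------------------------------------------------------------------------
# minimum sample size for a diagnostic test

@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs of the diagnostic-test minimum-sample-size formula.

    ``sensitivity``/``specificity`` are the anticipated test performance,
    ``prevalence`` the fraction of positive samples, ``margin`` the maximum
    marginal error ``d`` on the estimated proportions, and ``z`` the standard
    normal critical value ``z_{1 - alpha/2}`` of the chosen confidence level
    (1.96 for alpha = 0.05).
    """

    sensitivity: float
    specificity: float
    prevalence: float
    margin: float
    z: float = 1.96

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in (0, 1]")
        if not 0.0 < self.specificity <= 1.0:
            raise ValueError("specificity must be in (0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be strictly inside (0, 1)")
        if self.margin <= 0.0:
            raise ValueError("margin must be positive")
        if self.z <= 0.0:
            raise ValueError("z must be positive")

    @classmethod
    def from_alpha(cls, sensitivity, specificity, prevalence, margin, alpha=0.05):
        from scipy.stats import norm

        return cls(sensitivity, specificity, prevalence, margin, z=float(norm.ppf(1 - alpha / 2)))


def min_sample_size(spec: SampleSizeSpec) -> int:
    """Minimum sample size for the target sensitivity and specificity.

    Evaluates ``n = max(z^2 s_n (1 - s_n) / (d^2 P),
    z^2 s_p (1 - s_p) / (d^2 (1 - P)))`` and returns the ceiling: the larger
    of the sample sizes needed to estimate sensitivity (among the prevalent
    fraction P) and specificity (among 1 - P) to within the margin d.
    """
    z2 = spec.z**2
    n_sens = z2 * spec.sensitivity * (1.0 - spec.sensitivity) / (spec.margin**2 * spec.prevalence)
    n_spec = z2 * spec.specificity * (1.0 - spec.specificity) / (
        spec.margin**2 * (1.0 - spec.prevalence)
    )
    return math.ceil(max(n_sens, n_spec) - 1e-9)
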