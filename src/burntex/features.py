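"""Second-order (Haralick-family) texture features of a GLCM.

Nineteen features are active by default.  Indices ``i, j`` run over
``0 .. L-1``; ``p`` is the joint co-occurrence probability, ``p_sum`` and
``p_diff`` the distributions of ``i + j`` and ``|i - j|``; ``mu, sigma`` are
marginal means and standard deviations.  Definitions:

====================================  =============================================
energy                                sum p^2
contrast                              sum (i - j)^2 p
correlation                           sum (i - mu_x)(j - mu_y) p / (sigma_x sigma_y)
homogeneity                           sum p / (1 + (i - j)^2)
inverse difference                    sum p / (1 + |i - j|)
dissimilarity                         sum |i - j| p
maximum probability                   max p
entropy                               -sum p log p
autocorrelation                       sum i j p
cluster shade                         sum (i + j - mu_x - mu_y)^3 p
cluster prominence                    sum (i + j - mu_x - mu_y)^4 p
sum average                           sum s p_sum(s)
sum entropy                           -sum p_sum log p_sum
sum variance                          sum (s - sum average)^2 p_sum(s)
difference entropy                    -sum p_diff log p_diff
difference variance                   Var of p_diff
IMC-I                                 (HXY - HXY1) / max(HX, HY)
IMC-II                                sqrt(1 - exp(-2 (HXY2 - HXY)))
inverse difference normalized         sum p / (1 + |i - j| / L)
inverse difference moment normalized  sum p / (1 + (i - j)^2 / L^2)
====================================  =============================================

Difference variance is the variance of the ``|i - j|`` distribution (one of
two definitions in circulation; fixed globally here).  The min-max column
normalization maps each feature across a dataset to [0, 1]; inside
cross-validation the (min, max) statistics come from the training fold only
and the held-out sample is transformed without clipping, so the left-out
observation never influences its own scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import spearmanr

from .glcm import GLCMProbability, compute_glcm, normalize_glcm
from .io import GreyImage

__all__ = [
    "FEATURE_CATALOG",
    "DEFAULT_FEATURES",
    "SELECTED_FEATURES",
    "TextureFeatureVector",
    "FeatureMatrix",
    "MinMaxStats",
    "compute_features",
    "extract_feature_matrix",
    "normalize_features",
    "apply_normalization",
    "feature_trend_report",
]

#: Full catalog of implemented features, in the fixed tie-break order.
FEATURE_CATALOG: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "information_measure_of_correlation_1",
    "information_measure_of_correlation_2",
    "inverse_difference",
    "inverse_difference_moment_normalized",
    "inverse_difference_normalized",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
)

#: The 19 features active by default (the catalog minus the plain-normalized
#: inverse difference, which duplicates the moment-normalized variant's role).
DEFAULT_FEATURES: tuple[str, ...] = tuple(
    f for f in FEATURE_CATALOG if f != "inverse_difference_normalized"
)

#: The eight features retained by backward selection on the burn data:
#: the set whose severity trends the discussion analyses.
SELECTED_FEATURES: tuple[str, ...] = (
    "contrast",
    "correlation",
    "difference_variance",
    "homogeneity",
    "information_measure_of_correlation_2",
    "inverse_difference",
    "maximum_probability",
    "sum_entropy",
)

#: Trend direction of each selected feature with increasing burn severity.
TREND_DIRECTIONS: dict[str, int] = {
    "contrast": +1,
    "correlation": -1,
    "difference_variance": +1,
    "homogeneity": -1,
    "information_measure_of_correlation_2": +1,
    "inverse_difference": -1,
    "maximum_probability": -1,
    "sum_entropy": +1,
}


@dataclass(frozen=True)
class TextureFeatureVector:
    """Named feature values for one image, plus degeneracy warnings."""

    values: dict[str, float]
    source_id: str = ""
    warnings: tuple[str, ...] = ()

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.values)


def compute_features(
    p: GLCMProbability, feature_set: Sequence[str] | None = None
) -> TextureFeatureVector:
    """Evaluate the requested texture features of one GLCM probability.

    ``feature_set`` defaults to the 19 active features; unknown names raise
    with the catalog listed.  A constant image (``sigma_x`` or ``sigma_y``
    zero) makes correlation undefined; it is returned as 0.0 with a warning
    recorded on the vector rather than aborting batch extraction.
    """
    if feature_set is None:
        feature_set = DEFAULT_FEATURES
    if not feature_set:
        raise ValueError("feature_set must not be empty")
    unknown = [f for f in feature_set if f not in FEATURE_CATALOG]
    if unknown:
        raise ValueError(
            f"unknown feature name(s) {unknown}; available features: {list(FEATURE_CATALOG)}"
        )
    L = p.levels
    i = np.arange(L, dtype=float)
    d = np.arange(L, dtype=float)          # |i - j| support
    s = np.arange(2 * L - 1, dtype=float)  # i + j support
    warnings: list[str] = []

    vals: dict[str, float] = {}

    def correlation() -> float:
        if p.sigma_x == 0.0 or p.sigma_y == 0.0:
            warnings.append("correlation undefined for constant image; returned 0")
            return 0.0
        acor = float(i @ p.p @ i)
        return (acor - p.mu_x * p.mu_y) / (p.sigma_x * p.sigma_y)

    sum_average = float(s @ p.p_sum)
    mu_diff = float(d @ p.p_diff)
    cluster_arg = s - p.mu_x - p.mu_y

    formulas = {
        "autocorrelation": lambda: float(i @ p.p @ i),
        "cluster_prominence": lambda: float(cluster_arg**4 @ p.p_sum),
        "cluster_shade": lambda: float(cluster_arg**3 @ p.p_sum),
        "contrast": lambda: float(d**2 @ p.p_diff),
        "correlation": correlation,
        "difference_entropy": lambda: float(-xlogy(p.p_diff, p.p_diff).sum()),
        "difference_variance": lambda: float(d**2 @ p.p_diff - mu_diff**2),
        "dissimilarity": lambda: mu_diff,
        "energy": lambda: float((p.p**2).sum()),
        "entropy": lambda: p.hxy,
        "homogeneity": lambda: float(p.p_diff @ (1.0 / (1.0 + d**2))),
        "information_measure_of_correlation_1": lambda: (
            (p.hxy - p.hxy1) / max(p.hx, p.hy) if max(p.hx, p.hy) > 0 else 0.0
        ),
        "information_measure_of_correlation_2": lambda: float(
            np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (p.hxy2 - p.hxy))))
        ),
        "inverse_difference": lambda: float(p.p_diff @ (1.0 / (1.0 + d))),
        "inverse_difference_moment_normalized": lambda: float(
            p.p_diff @ (1.0 / (1.0 + d**2 / L**2))
        ),
        "inverse_difference_normalized": lambda: float(p.p_diff @ (1.0 / (1.0 + d / L))),
        "maximum_probability": lambda: float(p.p.max()),
        "sum_average": lambda: sum_average,
        "sum_entropy": lambda: float(-xlogy(p.p_sum, p.p_sum).sum()),
        "sum_variance": lambda: float((s - sum_average) ** 2 @ p.p_sum),
    }
    for name in feature_set:
        vals[name] = formulas[name]()
    return TextureFeatureVector(values=vals, warnings=tuple(warnings))


@dataclass(frozen=True)
class FeatureMatrix:
    """Feature values for a dataset: one row per image, one column per feature."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    labels: tuple[str, ...]
    sample_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (samples x features)")
        if v.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match the number of columns")
        if v.shape[0] != len(self.labels):
            raise ValueError("labels length must match the number of rows")
        ids = self.sample_ids or tuple(f"sample_{k}" for k in range(v.shape[0]))
        if len(ids) != v.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        object.__setattr__(self, "sample_ids", tuple(ids))

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def classes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return tuple(seen)

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(self.values[:, idx], tuple(names), self.labels, self.sample_ids)

    def restrict_labels(self, keep: Sequence[str]) -> "FeatureMatrix":
        mask = [lab in keep for lab in self.labels]
        return FeatureMatrix(
            self.values[mask],
            self.feature_names,
            tuple(l for l in self.labels if l in keep),
            tuple(s for s, m in zip(self.sample_ids, mask) if m),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        if not {"sample_id", "label"} <= set(df.columns):
            raise ValueError(f"feature table {path} must have sample_id and label columns")
        names = tuple(c for c in df.columns if c not in ("sample_id", "label"))
        return cls(
            df[list(names)].to_numpy(float),
            names,
            tuple(df["label"].astype(str)),
            tuple(df["sample_id"].astype(str)),
        )


def extract_feature_matrix(
    images: Iterable[GreyImage],
    labels: Sequence[str],
    offset: tuple[int, int] = (0, 1),
    feature_set: Sequence[str] | None = None,
    symmetric: bool = False,
) -> FeatureMatrix:
    """GLCM + feature extraction for a labelled collection of images."""
    if feature_set is None:
        feature_set = DEFAULT_FEATURES
    rows, ids = [], []
    for img in images:
        prob = normalize_glcm(compute_glcm(img, offset=offset, symmetric=symmetric))
        vec = compute_features(prob, feature_set)
        rows.append([vec[f] for f in feature_set])
        ids.append(img.source_id or f"sample_{len(ids)}")
    if len(rows) != len(labels):
        raise ValueError("number of images and labels must match")
    # de-duplicate blank/clashing ids deterministically
    if len(set(ids)) != len(ids):
        ids = [f"{s}#{k}" for k, s in enumerate(ids)]
    return FeatureMatrix(np.asarray(rows, float), tuple(feature_set), tuple(labels), tuple(ids))


@dataclass(frozen=True)
class MinMaxStats:
    """Per-feature (min, max) of a training set, for leak-free reuse."""

    mins: np.ndarray
    maxs: np.ndarray
    feature_names: tuple[str, ...]


def apply_normalization(values: np.ndarray, stats: MinMaxStats) -> np.ndarray:
    """Map columns through (x - min) / (max - min) using frozen statistics.

    Constant columns (max == min) map to zero.  Values outside the training
    range land outside [0, 1]; they are deliberately not clipped.
    """
    rng = stats.maxs - stats.mins
    out = np.zeros_like(np.asarray(values, float))
    nz = rng > 0
    out[..., nz] = (values[..., nz] - stats.mins[nz]) / rng[nz]
    return out


def normalize_features(matrix: FeatureMatrix) -> tuple[FeatureMatrix, MinMaxStats]:
    """Min-max normalize each feature column to [0, 1] across the dataset."""
    if matrix.n_samples < 2:
        raise ValueError("min-max normalization needs at least 2 samples")
    mins = matrix.values.min(axis=0)
    maxs = matrix.values.max(axis=0)
    stats = MinMaxStats(mins=mins, maxs=maxs, feature_names=matrix.feature_names)
    return (
        FeatureMatrix(
            apply_normalization(matrix.values, stats),
            matrix.feature_names,
            matrix.labels,
            matrix.sample_ids,
        ),
        stats,
    )


def feature_trend_report(
    matrix: FeatureMatrix, class_order: Sequence[str]
) -> pd.DataFrame:
    """Per-class means of min-max-normalized features plus the trend sign.

    ``class_order`` lists the classes from least to most severe.  The trend
    column is the sign of the Spearman rank correlation between severity rank
    and per-class mean, used to check the qualitative feature-evolution
    directions (contrast-like features rise with severity, homogeneity-like
    features fall).
    """
    unknown = set(class_order) - set(matrix.labels)
    if unknown:
        raise ValueError(f"classes {sorted(unknown)} not present in the data")
    if len(class_order) < 2:
        raise ValueError("trend report needs at least 2 classes")
    norm, _ = normalize_features(matrix)
    lab = np.asarray(norm.labels)
    means = {
        cls: norm.values[lab == cls].mean(axis=0) for cls in class_order
    }
    df = pd.DataFrame(means, index=list(matrix.feature_names))
    trends = []
    ranks = np.arange(len(class_order), dtype=float)
    for f in matrix.feature_names:
        row = df.loc[f].to_numpy()
        if np.allclose(row, row[0]):
            trends.append(0)
        else:
            rho = spearmanr(ranks, row).statistic
            trends.append(int(np.sign(rho)) if not np.isnan(rho) else 0)
    df["trend"] = trends
    return df
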