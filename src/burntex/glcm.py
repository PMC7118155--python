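"""Grey-level co-occurrence matrices and their probability form.

The co-occurrence matrix chi(i, j) for an offset ``(k, l)`` counts ordered
pixel pairs ``I(m, n) = i`` and ``I(m + k, n + l) = j`` over all positions
where the offset partner lies inside the image; boundary pixels without a
partner are skipped (no wraparound or padding).  The matrix is *not*
symmetrized by default: one direction is counted, and the transpose
corresponds to the negated offset.

All entropy-family quantities use the natural logarithm with the convention
``0 * log 0 = 0``.  The base is a single global choice: it rescales the
entropy features uniformly and cancels inside the information measures of
correlation when used consistently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import xlogy

from .io import GreyImage

__all__ = [
    "CooccurrenceMatrix",
    "GLCMProbability",
    "compute_glcm",
    "normalize_glcm",
    "average_glcm",
    "save_glcm_csv",
    "load_glcm_csv",
]


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """L x L grey-level pair counts for a single offset."""

    counts: np.ndarray
    offset: tuple[int, int]
    levels: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.levels, self.levels):
            raise ValueError(f"counts must be {self.levels}x{self.levels}, got {c.shape}")
        if c.min() < 0:
            raise ValueError("counts must be non-negative")
        c = c.copy()
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "offset", (int(self.offset[0]), int(self.offset[1])))

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class GLCMProbability:
    """Normalized joint distribution p(i, j) plus the derived quantities the
    texture features consume.

    Attributes
    ----------
    p
        L x L joint probability, sums to 1.
    px, py
        Row / column marginals.
    p_sum
        Distribution of ``i + j`` over ``0 .. 2(L-1)``.
    p_diff
        Distribution of ``|i - j|`` over ``0 .. L-1``.
    hx, hy, hxy, hxy1, hxy2
        Marginal entropies, joint entropy, and the two cross entropies
        against the product of marginals (natural log).  ``hxy2 - hxy`` is
        the mutual-information-like quantity used by the second information
        measure of correlation.
    mu_x, mu_y, sigma_x, sigma_y
        Mean and standard deviation of the marginals.
    """

    p: np.ndarray
    px: np.ndarray
    py: np.ndarray
    p_sum: np.ndarray
    p_diff: np.ndarray
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    levels: int
    offset: tuple[int, int]

    @classmethod
    def from_probability(
        cls, p: np.ndarray, offset: tuple[int, int] = (0, 1)
    ) -> "GLCMProbability":
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError(f"p must be square, got shape {p.shape}")
        if p.min() < 0:
            raise ValueError("probabilities must be non-negative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {total}")
        L = p.shape[0]
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        i = np.arange(L, dtype=float)
        mu_x = float(i @ px)
        mu_y = float(i @ py)
        sigma_x = float(np.sqrt(max((i - mu_x) ** 2 @ px, 0.0)))
        sigma_y = float(np.sqrt(max((i - mu_y) ** 2 @ py, 0.0)))
        isum = np.add.outer(np.arange(L), np.arange(L))
        idiff = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        p_sum = np.bincount(isum.ravel(), weights=p.ravel(), minlength=2 * L - 1)
        p_diff = np.bincount(idiff.ravel(), weights=p.ravel(), minlength=L)
        hx = float(-xlogy(px, px).sum())
        hy = float(-xlogy(py, py).sum())
        hxy = float(-xlogy(p, p).sum())
        prod = np.outer(px, py)
        mask = p > 0  # p(i,j) > 0 implies px(i) > 0 and py(j) > 0
        hxy1 = float(-(p[mask] * np.log(prod[mask])).sum())
        hxy2 = float(-xlogy(prod, prod).sum())
        for arr in (p, px, py, p_sum, p_diff):
            arr.setflags(write=False)
        return cls(
            p=p, px=px, py=py, p_sum=p_sum, p_diff=p_diff,
            hx=hx, hy=hy, hxy=hxy, hxy1=hxy1, hxy2=hxy2,
            mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y,
            levels=L, offset=(int(offset[0]), int(offset[1])),
        )


def compute_glcm(
    image: GreyImage, offset: tuple[int, int] = (0, 1), symmetric: bool = False
) -> CooccurrenceMatrix:
    """Count ordered grey-level pairs at the given ``(row, column)`` offset.

    The default offset ``(0, 1)`` pairs each pixel with its right-hand
    (horizontally adjacent) neighbour.  With ``symmetric=True`` the transposed
    counts are added, which is equivalent to also counting the negated offset.
    Cost is O(M * N).
    """
    k, l = int(offset[0]), int(offset[1])
    if (k, l) == (0, 0):
        raise ValueError("offset (0, 0) is not a valid co-occurrence offset")
    M, N = image.shape
    r0, r1 = max(0, -k), M - max(0, k)
    c0, c1 = max(0, -l), N - max(0, l)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"image of shape {M}x{N} has no pixel pairs at offset {(k, l)}")
    L = image.levels
    a = image.pixels[r0:r1, c0:c1]
    b = image.pixels[r0 + k : r1 + k, c0 + l : c1 + l]
    idx = a.astype(np.int64) * L + b
    counts = np.bincount(idx.ravel(), minlength=L * L).reshape(L, L)
    if symmetric:
        counts = counts + counts.T
    return CooccurrenceMatrix(counts, offset=(k, l), levels=L)


def normalize_glcm(glcm: CooccurrenceMatrix) -> GLCMProbability:
    """Normalize counts to the joint probability p(i, j) = chi(i, j) / total."""
    total = glcm.total_pairs
    if total == 0:
        raise ValueError("cannot normalize a co-occurrence matrix with zero pairs")
    return GLCMProbability.from_probability(glcm.counts / total, offset=glcm.offset)


def average_glcm(glcms: Sequence[CooccurrenceMatrix]) -> GLCMProbability:
    """Arithmetic mean of the normalized probability matrices of several images.

    All inputs must share the grey-level count and offset.  Used to
    visualise how the co-occurrence mass of a class of images migrates, e.g.
    the growth of low-intensity speckle pairs with burn severity.
    """
    if not glcms:
        raise ValueError("average_glcm requires at least one matrix")
    L, off = glcms[0].levels, glcms[0].offset
    for g in glcms[1:]:
        if g.levels != L:
            raise ValueError(f"mismatched grey-level counts: {g.levels} != {L}")
        if g.offset != off:
            raise ValueError(f"mismatched offsets: {g.offset} != {off}")
    mean_p = np.mean([normalize_glcm(g).p for g in glcms], axis=0)
    mean_p /= mean_p.sum()  # guard against rounding drift
    return GLCMProbability.from_probability(mean_p, offset=off)


def save_glcm_csv(glcm: CooccurrenceMatrix, path) -> None:
    """Write the L x L count matrix as CSV with a one-line metadata header."""
    header = f"offset={glcm.offset[0]},{glcm.offset[1]} levels={glcm.levels}"
    np.savetxt(path, glcm.counts, fmt="%d", delimiter=",", header=header)


def load_glcm_csv(path) -> CooccurrenceMatrix:
    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(item.split("=") for item in header.split())
    k, l = (int(v) for v in meta["offset"].split(","))
    counts = np.loadtxt(path, delimiter=",", skiprows=1, dtype=np.int64)
    return CooccurrenceMatrix(counts, offset=(k, l), levels=int(meta["levels"]))
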