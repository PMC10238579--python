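"""Generalized Discrimination Value (GDV), a label-aware cluster-separability statistic.

The GDV measures how well labeled points cluster in a ``D``-dimensional space.
Each dimension is first z-scored (population convention) and multiplied by 1/2,
making the statistic invariant under global shift/scale of the raw data.  On the
rescaled points the GDV is

    GDV = (1/sqrt(D)) * [ (1/L) * sum_l  d(C_l)
                          - (2/(L(L-1))) * sum_{l<m} d(C_l, C_m) ],

where ``d(C_l)`` is the mean Euclidean distance over all unordered within-class
pairs of class ``l`` and ``d(C_l, C_m)`` the mean distance over all cross-pairs
of classes ``l`` and ``m``.  A value of 0 indicates no clustering; more negative
values indicate better separation (-1 is already a very strong separation).
The 1/sqrt(D) prefactor makes values comparable across dimensionalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "LabeledPointSet",
    "ScaledPointSet",
    "GaussianClusterConfig",
    "zscore_columns",
    "mean_intra_class_distance",
    "mean_inter_class_distance",
    "gdv",
    "gdv_dimension_profile",
    "simulate_two_class_gaussians",
]


class DegenerateDimensionError(ValueError):
    """A data column has zero variance, so z-scoring is undefined."""


class DegenerateClassError(ValueError):
    """A class has too few members for the requested distance statistic."""


@dataclass
class LabeledPointSet:
    """``N`` points in ``D`` dimensions with a class label per point."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2:
            raise ValueError("points must be a 2-D array (N x D)")
        if len(self.labels) != self.points.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.points.shape[0]} points"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def restrict_dims(self, dims: Sequence[int]) -> "LabeledPointSet":
        return LabeledPointSet(self.points[:, list(dims)], self.labels)


@dataclass
class ScaledPointSet:
    """Per-dimension z-scored (x 1/2) coordinates with the scaling parameters."""

    points: np.ndarray
    column_means: np.ndarray
    column_sds: np.ndarray


@dataclass
class GaussianClusterConfig:
    """Two-class Gaussian test-bed: class 0 at the origin, class 1 shifted.

    ``separations[i]`` is the mean difference along dimension ``i``; both
    classes have unit variance in every dimension and dimensions are mutually
    independent.
    """

    n_per_class: int
    separations: np.ndarray = field(default_factory=lambda: np.ones(1))
    seed: int = 0

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.separations.ndim != 1 or not np.all(np.isfinite(self.separations)):
            raise ValueError("separations must be a finite 1-D vector")


def zscore_columns(points: np.ndarray) -> ScaledPointSet:
    """Z-score each column (population sd, divisor N) and multiply by 1/2.

    Output columns have mean 0 and standard deviation 1/2, which fixes the
    scale on which GDV values are comparable.

    Raises
    ------
    DegenerateDimensionError
        If any column is constant (zero variance).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    mu = points.mean(axis=0)
    sd = points.std(axis=0)  # population convention (ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateDimensionError(
            f"zero-variance column(s) {bad.tolist()}: z-scoring undefined"
        )
    return ScaledPointSet(0.5 * (points - mu) / sd, mu, sd)


def _class_rows(labels: np.ndarray, class_id) -> np.ndarray:
    return np.flatnonzero(np.asarray(labels) == class_id)


def mean_intra_class_distance(scaled: ScaledPointSet, labels, class_id) -> float:
    """Mean Euclidean distance over all unordered within-class pairs."""
    rows = _class_rows(labels, class_id)
    if rows.size < 2:
        raise DegenerateClassError(
            f"class {class_id!r} has {rows.size} member(s); need >= 2"
        )
    return float(pdist(scaled.points[rows]).mean())


def mean_inter_class_distance(scaled: ScaledPointSet, labels, class_a, class_b) -> float:
    """Mean Euclidean distance over all cross-pairs of two distinct classes."""
    if class_a == class_b:
        raise ValueError("class_a and class_b must differ")
    rows_a = _class_rows(labels, class_a)
    rows_b = _class_rows(labels, class_b)
    if rows_a.size == 0 or rows_b.size == 0:
        raise DegenerateClassError("both classes must be nonempty")
    return float(cdist(scaled.points[rows_a], scaled.points[rows_b]).mean())


def gdv(data: LabeledPointSet) -> float:
    """The Generalized Discrimination Value of a labeled point set.

    0 means no clustering; more negative means better class separation.
    Invariant under global affine rescaling of the raw data and under
    permutation of the dimensions.
    """
    classes = data.classes
    if len(classes) < 2:
        raise ValueError("GDV needs at least two classes")
    scaled = zscore_columns(data.points)
    L = len(classes)
    intra = sum(mean_intra_class_distance(scaled, data.labels, c) for c in classes)
    inter = 0.0
    for i in range(L - 1):
        for j in range(i + 1, L):
            inter += mean_inter_class_distance(
                scaled, data.labels, classes[i], classes[j]
            )
    D = data.n_dims
    return float((intra / L - 2.0 * inter / (L * (L - 1))) / np.sqrt(D))


def gdv_dimension_profile(
    data: LabeledPointSet, dim_order: Sequence[int] | None = None
) -> np.ndarray:
    """GDV as a function of the number of leading dimensions included.

    Entry ``j`` (0-based) is the GDV of the sub-point-set restricted to the
    first ``j+1`` dimensions of ``dim_order`` (default: natural order).
    Separating dimensions drive the profile down; appending non-separating
    dimensions drags it back toward zero.
    """
    if dim_order is None:
        dim_order = list(range(data.n_dims))
    dim_order = list(dim_order)
    if sorted(dim_order) != list(range(data.n_dims)):
        raise ValueError("dim_order must be a permutation of 0..D-1")
    return np.array(
        [gdv(data.restrict_dims(dim_order[: j + 1])) for j in range(len(dim_order))]
    )


def simulate_two_class_gaussians(cfg: GaussianClusterConfig) -> LabeledPointSet:
    """Two unit-variance Gaussian classes with per-dimension mean offsets.

    Class 0 is centred at the origin, class 1 at ``cfg.separations``.
    Dimensions are mutually independent; reproducible under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_per_class, len(cfg.separations)
    class0 = rng.standard_normal((n, d))
    class1 = rng.standard_normal((n, d)) + cfg.separations
    points = np.vstack([class0, class1])
    labels = np.repeat([0, 1], n)
    return LabeledPointSet(points, labels)
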