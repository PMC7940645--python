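"""Group-level metabolic connectivity: Pearson correlation across
subjects and the ``1 - |r|`` dissimilarity that seeds the filtration.

The absolute value makes strong anticorrelation count as proximity,
exactly as the distance is defined for this analysis; ``absolute=False``
(``d = 1 - r``, range [0, 2]) is available for sensitivity analyses.
Note ``d`` is not guaranteed to satisfy the triangle inequality —
downstream code must not assume a metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import SubjectMatrix

__all__ = ["CorrelationMatrix", "DistanceMatrix", "pearson_matrix", "to_distance"]


@dataclass
class CorrelationMatrix:
    """Symmetric ROI x ROI Pearson correlation with unit diagonal."""

    r: np.ndarray
    roi_names: list[str]
    n_subjects: int

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or n != len(self.roi_names):
            raise ValueError("correlation matrix / ROI-name shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix is not symmetric")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("correlation entries outside [-1, 1]")


@dataclass
class DistanceMatrix:
    """Symmetric ROI x ROI dissimilarity with zero diagonal."""

    d: np.ndarray
    roi_names: list[str]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = self.d.shape[0]
        if self.d.shape != (n, n) or n != len(self.roi_names):
            raise ValueError("distance matrix / ROI-name shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance diagonal must be exactly 0")
        if np.any(self.d < 0):
            raise ValueError("negative distances")

    @property
    def n_rois(self) -> int:
        return self.d.shape[0]


def pearson_matrix(matrix: SubjectMatrix) -> CorrelationMatrix:
    """Pearson correlation of every ROI pair across subjects.

    Zero-variance columns are a hard error naming the ROI; the result is
    symmetrised, clipped to [-1, 1] and given an exact unit diagonal.
    """
    x = matrix.values
    sd = x.std(axis=0)
    dead = [matrix.roi_names[j] for j in np.flatnonzero(sd == 0)]
    if dead:
        raise ValueError(
            f"zero-variance ROI column(s) {dead}: correlation undefined"
        )
    r = np.corrcoef(x, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, roi_names=list(matrix.roi_names), n_subjects=matrix.n_subjects)


def to_distance(corr: CorrelationMatrix, absolute: bool = True) -> DistanceMatrix:
    """Dissimilarity ``d = 1 - |r|`` (default) or ``1 - r``."""
    d = 1.0 - (np.abs(corr.r) if absolute else corr.r)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, roi_names=list(corr.roi_names))
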