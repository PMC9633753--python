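"""Sexual shape dimorphism (SShD) scores and their allometric decomposition.

An individual aligned face F_i is scored by scalar projection onto the
male-minus-female mean-shape axis:

    SShD(F_i) = ((F_i - midpoint) . (M - F)) / |M - F|^2

where M, F are the male and female reference mean shapes and the
midpoint (M + F)/2 is the projection origin, so the two reference means
score +0.5 and -0.5.  Scores below -1 are conventionally called
hyperfeminine and above +1 hypermasculine.

The score decomposes into a size-driven (allometric) and a
size-independent (non-allometric) part via multivariate regression of
the shape vectors on centroid size: the allometric score is the
projection of the size-predicted shape deviation, the non-allometric
score is the projection of what remains, and the two add up to the total
exactly by linearity of the projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DimorphismAxis",
    "SShDResult",
    "SShDDecomposer",
    "compute_sshd",
    "decompose_sshd",
]


@dataclass
class DimorphismAxis:
    """Male/female reference mean shapes and their difference axis."""

    male_mean: np.ndarray
    female_mean: np.ndarray

    def __post_init__(self) -> None:
        self.male_mean = np.asarray(self.male_mean, dtype=float).ravel()
        self.female_mean = np.asarray(self.female_mean, dtype=float).ravel()
        if self.male_mean.shape != self.female_mean.shape:
            raise ValueError("male and female means must have equal length")
        if self.axis_norm <= 0:
            raise ValueError("zero-norm dimorphism axis (male mean == female mean)")

    @property
    def axis(self) -> np.ndarray:
        return self.male_mean - self.female_mean

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.male_mean + self.female_mean)

    @property
    def axis_norm(self) -> float:
        return float(np.linalg.norm(self.male_mean - self.female_mean))


def compute_sshd(face: np.ndarray, axis: DimorphismAxis) -> float:
    """Project one aligned shape vector onto the dimorphism axis.

    The face must live in the same shape space *and orientation frame*
    as the axis: pose-normalize configurations into the canonical
    anatomical frame before Procrustes alignment so the consensus frame
    matches the frame the reference means are expressed in.
    """
    face = np.asarray(face, dtype=float).ravel()
    if face.shape != axis.axis.shape:
        raise ValueError(
            f"face dimension {face.shape[0]} does not match axis "
            f"dimension {axis.axis.shape[0]}"
        )
    a = axis.axis
    return float((face - axis.midpoint) @ a / (a @ a))


@dataclass
class SShDResult:
    """Per-subject total, allometric and non-allometric SShD scores."""

    subject_id: str
    sshd_total: float
    sshd_allometric: float
    sshd_nonallometric: float
    centroid_size: float


class SShDDecomposer(BaseEstimator):
    """Regress aligned shapes on centroid size and split SShD scores.

    Fitted attributes
    -----------------
    slope_ : (3p,) per-mm multivariate regression slope of shape on CS
    mean_size_ : mean centroid size of the fitting sample
    axis_slope_ : projection of ``slope_`` on the dimorphism axis
        (SShD units per mm of centroid size)
    """

    def __init__(self, axis: DimorphismAxis):
        self.axis = axis

    def fit(self, X, sizes):
        X = np.asarray(X, dtype=float)
        cs = np.asarray(sizes, dtype=float)
        if X.ndim != 2 or X.shape[0] != cs.shape[0]:
            raise ValueError("shapes and sizes must have matching lengths")
        d = cs - cs.mean()
        ss = float(d @ d)
        if ss <= 0:
            raise ValueError("centroid size is constant across subjects")
        self.slope_ = (d @ (X - X.mean(axis=0))) / ss
        self.mean_size_ = float(cs.mean())
        a = self.axis.axis
        self.axis_slope_ = float(self.slope_ @ a / (a @ a))
        return self

    def transform(self, X, sizes, subject_ids=None) -> list[SShDResult]:
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        cs = np.asarray(sizes, dtype=float)
        if subject_ids is None:
            subject_ids = [str(i) for i in range(X.shape[0])]
        out = []
        for i in range(X.shape[0]):
            total = compute_sshd(X[i], self.axis)
            allo = self.axis_slope_ * (cs[i] - self.mean_size_)
            out.append(
                SShDResult(subject_ids[i], total, allo, total - allo, float(cs[i]))
            )
        return out


def decompose_sshd(
    shapes: np.ndarray,
    sizes: np.ndarray,
    axis: DimorphismAxis,
    subject_ids: list[str] | None = None,
) -> list[SShDResult]:
    """Fit the size regression on the cohort and score every subject."""
    dec = SShDDecomposer(axis).fit(shapes, sizes)
    return dec.transform(shapes, sizes, subject_ids)


def results_to_frame(results: list[SShDResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "sshd_total": [r.sshd_total for r in results],
            "sshd_allometric": [r.sshd_allometric for r in results],
            "sshd_nonallometric": [r.sshd_nonallometric for r in results],
            "centroid_size": [r.centroid_size for r in results],
        }
    )
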