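"""Geometric morphometrics for dense 3D facial landmark configurations.

This module covers the shape side of the analysis: anatomical pose
normalization (nasion origin, canthion-defined sagittal plane,
exocanthion/porion/subnasale axial plane), centroid size, generalized
Procrustes analysis (GPA), principal-component shape spaces with a
Kaiser-plus-90%-cumulative retention rule, a normalized inter-landmark
distance panel, and accentuated group-mean shapes for visualization.

Landmark configurations are named point sets in millimetres.  GPA removes
position, orientation and scale (full Procrustes: every configuration is
scaled to unit centroid size), leaving shape coordinates on which PCA
defines the facial morphospace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.linalg import norm
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LandmarkConfiguration",
    "ShapeCoordinates",
    "ShapeSpacePCA",
    "ShapeSpace",
    "retained_components",
    "GeneralizedProcrustesAnalysis",
    "pose_normalize",
    "centroid_size",
    "gpa",
    "fit_shape_space",
    "interlandmark_panel",
    "PANEL_VARIABLES",
    "accentuate_mean",
    "export_obj",
    "export_ply",
]


# ---------------------------------------------------------------------------
# landmark configurations
# ---------------------------------------------------------------------------

#: anatomical anchors required for pose normalization
POSE_ANCHORS = (
    "nasion",
    "exocanthion_r",
    "exocanthion_l",
    "endocanthion_r",
    "endocanthion_l",
    "porion_r",
    "porion_l",
    "subnasale",
)


@dataclass
class LandmarkConfiguration:
    """One subject's named 3D landmark configuration (coordinates in mm)."""

    subject_id: str
    labels: list[str]
    coords: np.ndarray  # (p, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (p, 3)")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels and coords length mismatch")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicated landmark labels: {dupes}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    def get(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"landmark {label!r} not present") from None
        return self.coords[i]

    def has(self, label: str) -> bool:
        return label in self.labels

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coords, columns=["x", "y", "z"]).assign(
            label=self.labels, subject_id=self.subject_id
        )[["subject_id", "label", "x", "y", "z"]]

    def with_coords(self, coords: np.ndarray) -> "LandmarkConfiguration":
        return LandmarkConfiguration(self.subject_id, list(self.labels), coords)


@dataclass
class ShapeCoordinates:
    """Procrustes-aligned shape of one subject.

    ``vector`` is the flattened (3p,) unit-centroid-size aligned
    configuration; ``centroid_size`` retains the original size in mm.
    """

    subject_id: str
    vector: np.ndarray
    centroid_size: float


def centroid_size(config: LandmarkConfiguration | np.ndarray) -> float:
    """Centroid size: sqrt of summed squared distances to the centroid."""
    X = config.coords if isinstance(config, LandmarkConfiguration) else np.asarray(config, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("centroid size requires at least 2 points")
    return float(norm(X - X.mean(axis=0)))


# ---------------------------------------------------------------------------
# pose normalization
# ---------------------------------------------------------------------------

def pose_normalize(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Map a configuration into the canonical anatomical frame.

    The nasion is placed at the origin.  The sagittal (x = 0) plane is the
    least-squares symmetry plane of the exo- and endocanthions; the axial
    (z = 0) plane is the least-squares plane through the exocanthions,
    porions and subnasale.  The frame is right-handed with +x toward the
    subject's right, +z superior (nasion above subnasale) and +y anterior.
    """
    missing = [l for l in POSE_ANCHORS if not config.has(l)]
    if missing:
        raise ValueError(f"missing pose anchor landmarks: {missing}")

    nas = config.get("nasion")
    ex_r, ex_l = config.get("exocanthion_r"), config.get("exocanthion_l")
    en_r, en_l = config.get("endocanthion_r"), config.get("endocanthion_l")
    po_r, po_l = config.get("porion_r"), config.get("porion_l")
    sn = config.get("subnasale")

    d_ex, d_en = ex_r - ex_l, en_r - en_l
    if norm(d_ex) < 1e-9 or norm(d_en) < 1e-9:
        raise ValueError("degenerate canthion anchors (coincident left/right)")
    # symmetry direction: average of the two left-right unit vectors
    x_ax = d_ex / norm(d_ex) + d_en / norm(d_en)
    if norm(x_ax) < 1e-9:
        raise ValueError("degenerate canthion anchors (anti-parallel pairs)")
    x_ax /= norm(x_ax)

    axial_pts = np.vstack([ex_r, ex_l, po_r, po_l, sn])
    centered = axial_pts - axial_pts.mean(axis=0)
    # plane normal = direction of least variance
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9:
        raise ValueError("degenerate axial-plane anchors (collinear)")
    z_ax = vt[2]
    z_ax = z_ax - (z_ax @ x_ax) * x_ax
    if norm(z_ax) < 1e-9:
        raise ValueError("axial plane normal parallel to symmetry axis")
    z_ax /= norm(z_ax)
    if z_ax @ (nas - sn) < 0:  # superior direction: nasion above subnasale
        z_ax = -z_ax
    y_ax = np.cross(z_ax, x_ax)

    R = np.vstack([x_ax, y_ax, z_ax])
    return config.with_coords((config.coords - nas) @ R.T)


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

def _center_unit(X: np.ndarray) -> tuple[np.ndarray, float]:
    Xc = X - X.mean(axis=0)
    cs = norm(Xc)
    if cs <= 0:
        raise ValueError("degenerate configuration with zero centroid size")
    return Xc / cs, float(cs)


def _rotation_to(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, bool]:
    """Proper rotation R minimizing ||A @ R - B||; reports if a reflection
    would have fit strictly better (reflections are never applied).  For
    planar configurations the smallest singular value vanishes and the
    sign flip is fit-neutral, so no reflection is reported."""
    U, s, Vt = np.linalg.svd(A.T @ B)
    improper = bool(np.linalg.det(U) * np.linalg.det(Vt) < 0)
    if improper:
        U = U.copy()
        U[:, -1] *= -1
    matters = improper and s[-1] > 1e-12 * max(s[0], 1.0)
    return U @ Vt, matters


class GeneralizedProcrustesAnalysis(TransformerMixin, BaseEstimator):
    """Iterative full-Procrustes superimposition.

    Each configuration is centered, scaled to unit centroid size, and
    rotated to the current consensus; the consensus is re-estimated until
    its RMS change drops below ``tol``.  Reflections are disallowed in the
    rotation solver (anatomical data must not be mirrored); a configuration
    for which a reflection would have been optimal triggers a warning.

    Fitted attributes
    -----------------
    mean_shape_ : (p, 3) converged consensus, unit centroid size
    n_iter_ : iterations used
    converged_ : whether the tolerance was reached
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _as_array(configs) -> np.ndarray:
        if isinstance(configs, np.ndarray):
            X = configs.astype(float)
            if X.ndim != 3 or X.shape[2] != 3:
                raise ValueError("expected array of shape (n, p, 3)")
            return X
        labels0 = None
        stack = []
        for c in configs:
            if labels0 is None:
                labels0 = c.labels
            elif c.labels != labels0:
                raise ValueError(
                    f"mismatched landmark sets (subject {c.subject_id!r})"
                )
            stack.append(c.coords)
        if not stack:
            raise ValueError("need at least one configuration")
        return np.stack(stack)

    def fit(self, X, y=None):
        A = self._as_array(X)
        n = A.shape[0]
        aligned = np.empty_like(A)
        for i in range(n):
            aligned[i], _ = _center_unit(A[i])
        mean = aligned[0].copy()
        n_reflections = 0
        self.converged_ = False
        it = 0
        for it in range(1, self.max_iter + 1):
            for i in range(n):
                R, refl = _rotation_to(aligned[i], mean)
                n_reflections += refl
                aligned[i] = aligned[i] @ R
            new_mean = aligned.mean(axis=0)
            new_mean -= new_mean.mean(axis=0)
            new_mean /= norm(new_mean)
            delta = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
            mean = new_mean
            if delta < self.tol:
                self.converged_ = True
                break
        if n_reflections:
            warnings.warn(
                f"optimal superimposition required a reflection for "
                f"{n_reflections} rotation(s); proper rotations were used instead",
                stacklevel=2,
            )
        self.mean_shape_ = mean
        self.n_iter_ = it
        self.n_landmarks_ = A.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Align configurations to the fitted consensus; returns (n, 3p)."""
        check_is_fitted(self, "mean_shape_")
        A = self._as_array(X)
        out = np.empty((A.shape[0], A.shape[1] * 3))
        for i in range(A.shape[0]):
            Z, _ = _center_unit(A[i])
            R, _ = _rotation_to(Z, self.mean_shape_)
            out[i] = (Z @ R).ravel()
        return out


def gpa(configs: list[LandmarkConfiguration]) -> tuple[list[ShapeCoordinates], np.ndarray]:
    """Run GPA; returns per-subject shape coordinates and the flattened mean."""
    model = GeneralizedProcrustesAnalysis().fit(configs)
    aligned = model.transform(configs)
    shapes = [
        ShapeCoordinates(c.subject_id, aligned[i], centroid_size(c))
        for i, c in enumerate(configs)
    ]
    return shapes, model.mean_shape_.ravel()


# ---------------------------------------------------------------------------
# principal-component shape spaces
# ---------------------------------------------------------------------------

def retained_components(
    eigenvalues: np.ndarray, mode: str = "correlation", var_threshold: float = 0.90
) -> int:
    """Apply the Kaiser-plus-cumulative retention rule to an eigen-spectrum.

    Returns ``min(kaiser, k_cut)``: the Kaiser count (eigenvalues above 1
    in correlation mode, above the mean eigenvalue in covariance mode) is
    trimmed back to the cumulative-share cutoff whenever the Kaiser set
    already explains more than the threshold.
    """
    evals = np.asarray(eigenvalues, dtype=float)
    if evals.ndim != 1 or evals.size == 0 or (evals < 0).any():
        raise ValueError("eigenvalues must be a non-empty 1D non-negative array")
    if np.any(np.diff(evals) > 1e-12):
        raise ValueError("eigenvalues must be non-increasing")
    total = evals.sum()
    if total <= 0:
        raise ValueError("eigenvalues sum to zero")
    kaiser_thresh = 1.0 if mode == "correlation" else evals.mean()
    kaiser = max(int(np.sum(evals > kaiser_thresh)), 1)
    cum = np.cumsum(evals / total)
    k_cut = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    return min(kaiser, min(k_cut, evals.size))


class ShapeSpacePCA(TransformerMixin, BaseEstimator):
    """PCA with the Kaiser-plus-90%-cumulative component retention rule.

    The number of retained components is ``min(kaiser, k90)`` where
    ``kaiser`` counts eigenvalues above the Kaiser threshold (literally
    > 1 in correlation mode; > mean eigenvalue in covariance mode, the
    scale-free analogue) and ``k90`` is the smallest k whose cumulative
    variance share reaches ``var_threshold``.  Equivalently: retain the
    Kaiser set, but cut it back to the 90% point whenever the Kaiser set
    already explains more than 90%.

    Parameters
    ----------
    mode : {"covariance", "correlation"}
        Matrix decomposed.  Procrustes coordinates use covariance mode
        (their common scale is meaningful); nutrient matrices use
        correlation mode (heterogeneous units).
    var_threshold : float
        Cumulative-share cutoff, default 0.90.
    """

    def __init__(self, mode: str = "covariance", var_threshold: float = 0.90):
        self.mode = mode
        self.var_threshold = var_threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2D matrix with at least 2 rows")
        if self.mode not in ("covariance", "correlation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0 < self.var_threshold <= 1):
            raise ValueError("var_threshold must be in (0, 1]")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if self.mode == "correlation":
            sd = Xc.std(axis=0, ddof=1)
            const = np.flatnonzero(sd <= 0)
            if const.size:
                raise ValueError(
                    f"constant columns in correlation mode: {const.tolist()}"
                )
            self.scale_ = sd
            Xc = Xc / sd
        else:
            self.scale_ = np.ones(X.shape[1])
        C = (Xc.T @ Xc) / (X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        self.eigenvalues_ = evals
        self.components_ = evecs
        total = evals.sum()
        self.explained_variance_ratio_ = evals / total if total > 0 else evals
        kaiser_thresh = 1.0 if self.mode == "correlation" else evals.mean()
        self.kaiser_count_ = max(int(np.sum(evals > kaiser_thresh)), 1)
        self.n_retained_ = retained_components(evals, self.mode, self.var_threshold)
        return self

    def transform(self, X) -> np.ndarray:
        """Scores on the retained components, (n, k)."""
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        Z = (X - self.mean_) / self.scale_
        return Z @ self.components_[:, : self.n_retained_]

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct observations from retained-component scores."""
        check_is_fitted(self, "components_")
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        Z = scores @ self.components_[:, : self.n_retained_].T
        return Z * self.scale_ + self.mean_


#: the spec-level ShapeSpace container is the fitted estimator itself
ShapeSpace = ShapeSpacePCA


def fit_shape_space(matrix: np.ndarray, mode: str = "covariance") -> ShapeSpacePCA:
    """Fit a principal-component space with the retention rule applied."""
    return ShapeSpacePCA(mode=mode).fit(matrix)


# ---------------------------------------------------------------------------
# inter-landmark distance panel
# ---------------------------------------------------------------------------

def _d(a: np.ndarray, b: np.ndarray) -> float:
    return float(norm(a - b))


#: the 16 unique panel variables (12 exocanthion-normalized distances + 4 ratios)
PANEL_VARIABLES = (
    "ac_ac", "zy_zy", "ch_ch", "go_go",
    "n_en", "n_sn", "n_zy", "n_prn", "n_ls",
    "sto_gn", "ls_li", "ps_pi",
    "go_go/zy_zy", "gla_sn/sn_gn", "n_gn/zy_zy", "gla_ls/zy_zy",
)

_PANEL_REQUIRED = (
    "exocanthion_r", "exocanthion_l", "alar_curvature_r", "alar_curvature_l",
    "zygion_r", "zygion_l", "cheilion_r", "cheilion_l", "gonion_r", "gonion_l",
    "endocanthion_r", "endocanthion_l", "palpebrale_superius_r",
    "palpebrale_superius_l", "palpebrale_inferius_r", "palpebrale_inferius_l",
    "nasion", "subnasale", "pronasale", "labiale_superius", "labiale_inferius",
    "stomion", "gnathion", "glabella",
)


def interlandmark_panel(config: LandmarkConfiguration) -> pd.Series:
    """Normalized anthropometric panel of 16 inter-landmark variables.

    Linear distances are divided by the exocanthion-to-exocanthion
    distance, removing individual facial size; the four ratio variables
    are dimensionless already.  Bilateral midline-to-side distances
    (nasion-endocanthion, nasion-zygion, eye height) are averaged over
    the two sides.
    """
    missing = [l for l in _PANEL_REQUIRED if not config.has(l)]
    if missing:
        raise ValueError(f"missing panel landmarks: {missing}")
    g = config.get
    ex = _d(g("exocanthion_r"), g("exocanthion_l"))
    if ex <= 0:
        raise ValueError("zero exocanthion distance")
    n, sn, gn, gla = g("nasion"), g("subnasale"), g("gnathion"), g("glabella")
    ls = g("labiale_superius")
    zy = _d(g("zygion_r"), g("zygion_l"))
    go = _d(g("gonion_r"), g("gonion_l"))
    vals = {
        "ac_ac": _d(g("alar_curvature_r"), g("alar_curvature_l")) / ex,
        "zy_zy": zy / ex,
        "ch_ch": _d(g("cheilion_r"), g("cheilion_l")) / ex,
        "go_go": go / ex,
        "n_en": 0.5 * (_d(n, g("endocanthion_r")) + _d(n, g("endocanthion_l"))) / ex,
        "n_sn": _d(n, sn) / ex,
        "n_zy": 0.5 * (_d(n, g("zygion_r")) + _d(n, g("zygion_l"))) / ex,
        "n_prn": _d(n, g("pronasale")) / ex,
        "n_ls": _d(n, ls) / ex,
        "sto_gn": _d(g("stomion"), gn) / ex,
        "ls_li": _d(ls, g("labiale_inferius")) / ex,
        "ps_pi": 0.5 * (
            _d(g("palpebrale_superius_r"), g("palpebrale_inferius_r"))
            + _d(g("palpebrale_superius_l"), g("palpebrale_inferius_l"))
        ) / ex,
        "go_go/zy_zy": go / zy,
        "gla_sn/sn_gn": _d(gla, sn) / _d(sn, gn),
        "n_gn/zy_zy": _d(n, gn) / zy,
        "gla_ls/zy_zy": _d(gla, ls) / zy,
    }
    return pd.Series(vals, name=config.subject_id)[list(PANEL_VARIABLES)]


# ---------------------------------------------------------------------------
# accentuated group means
# ---------------------------------------------------------------------------

def accentuate_mean(
    group_mean: np.ndarray, grand_mean: np.ndarray, weight: float = 5.0
) -> np.ndarray:
    """Exaggerate a group mean away from the grand mean.

    Returns ``grand_mean + weight * (group_mean - grand_mean)``; weight 5
    is the conventional accentuation for visual comparison of group faces.
    """
    group_mean = np.asarray(group_mean, dtype=float)
    grand_mean = np.asarray(grand_mean, dtype=float)
    if group_mean.shape != grand_mean.shape:
        raise ValueError("shape vectors must have the same length")
    return grand_mean + weight * (group_mean - grand_mean)


# ---------------------------------------------------------------------------
# mesh/point export
# ---------------------------------------------------------------------------

def export_obj(coords: np.ndarray, path) -> None:
    """Write a (p, 3) point set as an OBJ vertex cloud."""
    V = np.asarray(coords, float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# facediet landmark export\n")
        for x, y, z in V:
            fh.write(f"v {x:.6f} {y:.6f} {z:.6f}\n")


def export_ply(coords: np.ndarray, path) -> None:
    """Write a (p, 3) point set as an ASCII PLY vertex cloud."""
    V = np.asarray(coords, float).reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\n"
            f"element vertex {len(V)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            "end_header\n"
        )
        for x, y, z in V:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
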