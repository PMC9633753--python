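"""Synthetic average-face landmark template.

A deterministic stand-in for a dense facial semi-landmark template: 26
named anatomical points with plausible adult-female coordinates (mm, in
the canonical frame — nasion origin, +x subject-right, +y anterior,
+z superior) plus a configurable number of filler surface semi-landmarks
laid out on an ellipsoidal face patch by a golden-angle spiral.

Also constructs the fixed "masculinization" direction used to plant
sexual shape dimorphism and allometry: a geometric morph (wider jaw and
zygomata, longer lower face, prominent brow) orthogonalized against the
similarity group (translations, rotations, uniform scaling) at the
template, so planting a displacement along it survives Procrustes
superimposition to first order.
"""

from __future__ import annotations

import numpy as np

from .morpho import LandmarkConfiguration

# named anatomical landmarks, mm, canonical frame
NAMED_LANDMARKS: dict[str, tuple[float, float, float]] = {
    "nasion": (0.0, 0.0, 0.0),
    "glabella": (0.0, 3.0, 12.0),
    "exocanthion_r": (44.0, -8.0, -2.0),
    "exocanthion_l": (-44.0, -8.0, -2.0),
    "endocanthion_r": (16.0, -5.0, -1.0),
    "endocanthion_l": (-16.0, -5.0, -1.0),
    "palpebrale_superius_r": (30.0, -2.0, 2.0),
    "palpebrale_superius_l": (-30.0, -2.0, 2.0),
    "palpebrale_inferius_r": (30.0, -3.0, -5.0),
    "palpebrale_inferius_l": (-30.0, -3.0, -5.0),
    "zygion_r": (65.0, -28.0, -18.0),
    "zygion_l": (-65.0, -28.0, -18.0),
    "porion_r": (72.0, -75.0, -10.0),
    "porion_l": (-72.0, -75.0, -10.0),
    "subnasale": (0.0, 18.0, -50.0),
    "pronasale": (0.0, 30.0, -42.0),
    "alar_curvature_r": (17.0, 15.0, -48.0),
    "alar_curvature_l": (-17.0, 15.0, -48.0),
    "labiale_superius": (0.0, 22.0, -68.0),
    "stomion": (0.0, 20.0, -75.0),
    "labiale_inferius": (0.0, 21.0, -82.0),
    "cheilion_r": (25.0, 12.0, -75.0),
    "cheilion_l": (-25.0, 12.0, -75.0),
    "gnathion": (0.0, 12.0, -115.0),
    "gonion_r": (52.0, -40.0, -85.0),
    "gonion_l": (-52.0, -40.0, -85.0),
}

N_NAMED = len(NAMED_LANDMARKS)

# per-landmark displacement (mm) defining the raw masculinization morph
_MORPH: dict[str, tuple[float, float, float]] = {
    "gonion_r": (5.0, 0.0, -3.0),
    "gonion_l": (-5.0, 0.0, -3.0),
    "gnathion": (0.0, 3.0, -6.0),
    "glabella": (0.0, 5.0, 1.0),
    "zygion_r": (2.5, 0.0, 0.0),
    "zygion_l": (-2.5, 0.0, 0.0),
    "pronasale": (0.0, 3.0, -2.0),
    "subnasale": (0.0, 1.0, -2.0),
    "palpebrale_superius_r": (0.0, 0.0, -1.5),
    "palpebrale_superius_l": (0.0, 0.0, -1.5),
    "labiale_superius": (0.0, -1.0, -1.0),
}


def _filler_points(n: int) -> np.ndarray:
    """Deterministic surface semi-landmarks on an ellipsoidal face patch."""
    if n <= 0:
        return np.empty((0, 3))
    k = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    # frontal patch of an ellipsoid centred behind the nasion
    u = 0.15 + 0.7 * (k + 0.5) / n          # polar fraction
    theta = golden * k                       # azimuth
    a, b, c = 72.0, 62.0, 88.0               # semi-axes mm (width, depth, height)
    phi = np.pi * u
    x = a * np.sin(phi) * np.cos(theta)
    y = b * np.abs(np.sin(phi) * np.sin(theta))  # keep points on the anterior side
    z = c * np.cos(phi)
    centre = np.array([0.0, -25.0, -45.0])
    return np.column_stack([x, y, z]) + centre


def template_labels(n_landmarks: int = 60) -> list[str]:
    if n_landmarks < N_NAMED:
        raise ValueError(
            f"n_landmarks must be >= {N_NAMED} (the named anatomical set)"
        )
    extra = [f"surface_{i:04d}" for i in range(n_landmarks - N_NAMED)]
    return list(NAMED_LANDMARKS) + extra


def template_coords(n_landmarks: int = 60) -> np.ndarray:
    """(p, 3) template coordinates in mm."""
    named = np.array(list(NAMED_LANDMARKS.values()))
    return np.vstack([named, _filler_points(n_landmarks - N_NAMED)])


def template_configuration(n_landmarks: int = 60, subject_id: str = "template") -> LandmarkConfiguration:
    return LandmarkConfiguration(
        subject_id, template_labels(n_landmarks), template_coords(n_landmarks)
    )


def _similarity_tangent_basis(T_hat: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the similarity-group tangent at a
    centered unit-size configuration: 3 translations, 3 rotations, 1 scaling."""
    p = T_hat.shape[0]
    gens = []
    for ax in range(3):
        t = np.zeros((p, 3))
        t[:, ax] = 1.0
        gens.append(t.ravel())
    for A in (
        np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], float),
        np.array([[0, 0, -1], [0, 0, 0], [1, 0, 0]], float),
        np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], float),
    ):
        gens.append((T_hat @ A.T).ravel())
    gens.append(T_hat.ravel())
    G = np.array(gens)
    # orthonormalize (rows)
    Q, _ = np.linalg.qr(G.T)
    return Q.T


def unit_template_and_axis(n_landmarks: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Centered unit-centroid-size template and the unit masculinization axis.

    The axis is the geometric morph projected off the similarity-group
    tangent space, flattened to (3p,) and normalized; displacements along
    it are therefore pure shape changes.
    """
    T = template_coords(n_landmarks)
    Tc = T - T.mean(axis=0)
    cs = np.linalg.norm(Tc)
    T_hat = Tc / cs
    labels = template_labels(n_landmarks)
    D = np.zeros_like(T)
    for name, d in _MORPH.items():
        D[labels.index(name)] = d
    d = D.ravel() / cs
    basis = _similarity_tangent_basis(T_hat)
    d = d - basis.T @ (basis @ d)
    nrm = np.linalg.norm(d)
    if nrm <= 0:
        raise RuntimeError("degenerate masculinization axis")
    return T_hat, d / nrm


def shape_modes(n_landmarks: int = 60, n_modes: int = 8) -> np.ndarray:
    """(n_modes, 3p) orthonormal population shape-variation modes.

    Deterministic pseudo-random directions orthogonalized against the
    similarity-group tangent, the masculinization axis and each other, so
    planted inter-individual variation is pure shape change uncorrelated
    with the dimorphism axis.
    """
    T_hat, axis = unit_template_and_axis(n_landmarks)
    d = T_hat.size
    rng = np.random.default_rng(777)  # fixed: the modes are constants
    raw = rng.standard_normal((n_modes, d))
    basis = np.vstack([_similarity_tangent_basis(T_hat), axis])
    modes = []
    for v in raw:
        v = v - basis.T @ (basis @ v)
        for m in modes:
            v = v - (m @ v) * m
        nrm = np.linalg.norm(v)
        if nrm < 1e-12:
            raise RuntimeError("degenerate shape mode")
        modes.append(v / nrm)
    return np.array(modes)


def template_centroid_size(n_landmarks: int = 60) -> float:
    T = template_coords(n_landmarks)
    return float(np.linalg.norm(T - T.mean(axis=0)))
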