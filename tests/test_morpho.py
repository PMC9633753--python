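"""Pose normalization, GPA, shape PCA retention, panel, accentuation."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.linalg import orthogonal_procrustes

from facediet._template import template_configuration
from facediet.morpho import (
    GeneralizedProcrustesAnalysis,
    LandmarkConfiguration,
    ShapeSpacePCA,
    accentuate_mean,
    centroid_size,
    fit_shape_space,
    gpa,
    interlandmark_panel,
    pose_normalize,
    retained_components,
)


def _rigid(coords, rng, scale=False):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-30, 30, size=3)
    s = rng.uniform(0.5, 2.0) if scale else 1.0
    return s * coords @ R.T + t


class TestLandmarkConfiguration:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            LandmarkConfiguration("s", ["a", "a"], np.zeros((2, 3)))

    def test_nonfinite_rejected(self):
        coords = np.zeros((2, 3))
        coords[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            LandmarkConfiguration("s", ["a", "b"], coords)


class TestCentroidSize:
    def test_unit_square(self):
        square = LandmarkConfiguration(
            "s", list("abcd"),
            np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float),
        )
        assert centroid_size(square) == pytest.approx(np.sqrt(2.0))

    def test_translation_invariant_and_homogeneous(self, rng):
        cfg = template_configuration(40)
        cs = centroid_size(cfg)
        assert centroid_size(cfg.with_coords(cfg.coords + [5, -3, 11])) == pytest.approx(cs)
        assert centroid_size(cfg.with_coords(2 * cfg.coords)) == pytest.approx(2 * cs)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            centroid_size(np.zeros((1, 3)))


class TestPoseNormalize:
    def test_nasion_at_origin(self, rng):
        cfg = template_configuration(40)
        moved = cfg.with_coords(_rigid(cfg.coords, rng))
        out = pose_normalize(moved)
        np.testing.assert_allclose(out.get("nasion"), 0.0, atol=1e-10)

    def test_idempotent(self, rng):
        cfg = template_configuration(40)
        once = pose_normalize(cfg.with_coords(_rigid(cfg.coords, rng)))
        twice = pose_normalize(once)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-8)

    def test_rigid_invariance(self, rng):
        cfg = template_configuration(40)
        base = pose_normalize(cfg)
        for _ in range(3):
            moved = cfg.with_coords(_rigid(cfg.coords, rng))
            np.testing.assert_allclose(
                pose_normalize(moved).coords, base.coords, atol=1e-8
            )

    def test_anatomical_orientation(self):
        out = pose_normalize(template_configuration(40))
        assert out.get("exocanthion_r")[0] > 0          # +x subject-right
        assert out.get("pronasale")[1] > 0              # +y anterior
        assert out.get("subnasale")[2] < 0              # nasion above subnasale

    def test_missing_anchor_rejected(self):
        cfg = template_configuration(40)
        idx = cfg.labels.index("porion_l")
        labels = cfg.labels[:idx] + cfg.labels[idx + 1:]
        coords = np.delete(cfg.coords, idx, axis=0)
        with pytest.raises(ValueError, match="porion_l"):
            pose_normalize(LandmarkConfiguration("s", labels, coords))


class TestGPA:
    def test_single_configuration(self):
        cfg = template_configuration(30)
        shapes, mean = gpa([cfg])
        centered = cfg.coords - cfg.coords.mean(axis=0)
        expected = (centered / np.linalg.norm(centered)).ravel()
        # a global rotation is unidentifiable; the single shape is its own mean
        np.testing.assert_allclose(shapes[0].vector, mean, atol=1e-12)
        assert np.linalg.norm(shapes[0].vector) == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(shapes[0].vector @ expected), 1.0, atol=1e-12)

    def test_similarity_invariance_pair(self, rng):
        cfg = template_configuration(30)
        other = cfg.with_coords(_rigid(cfg.coords, rng, scale=True))
        shapes, _ = gpa([cfg, other])
        d = np.linalg.norm(shapes[0].vector - shapes[1].vector)
        assert d < 1e-10

    def test_rigid_and_scale_invariance_of_output(self, rng):
        """Random similarity transforms of the inputs leave GPA output
        unchanged within 1e-8."""
        cohort = [
            template_configuration(30, f"s{i}").with_coords(
                template_configuration(30).coords + rng.normal(0, 2.0, (30, 3))
            )
            for i in range(6)
        ]
        ref_aligned, ref_mean = gpa(cohort)
        moved = [c.with_coords(_rigid(c.coords, rng, scale=True)) for c in cohort]
        new_aligned, new_mean = gpa(moved)
        # align the two consensus frames before comparing
        R, _ = orthogonal_procrustes(
            new_mean.reshape(-1, 3), ref_mean.reshape(-1, 3)
        )
        for a, b in zip(new_aligned, ref_aligned):
            np.testing.assert_allclose(
                a.vector.reshape(-1, 3) @ R, b.vector.reshape(-1, 3), atol=1e-8
            )

    def test_mean_matches_brute_force_oracle(self):
        """GPA consensus of three toy triangles equals the mean found by
        direct numerical minimization of the Procrustes objective."""
        tris = [
            np.array([[0.0, 0, 0], [1.1, 0, 0], [0.4, 0.9, 0.1]]),
            np.array([[0.0, 0.1, 0], [1.0, -0.1, 0], [0.55, 1.0, -0.1]]),
            np.array([[-0.1, 0, 0.05], [1.0, 0.05, 0], [0.5, 0.8, 0.0]]),
        ]
        configs = [LandmarkConfiguration(f"t{i}", list("abc"), t) for i, t in enumerate(tris)]
        _, mean = gpa(configs)

        Z = []
        for t in tris:
            c = t - t.mean(axis=0)
            Z.append(c / np.linalg.norm(c))

        def objective(params):
            aligned = [
                Z[i] @ Rotation.from_rotvec(params[3 * i: 3 * i + 3]).as_matrix().T
                for i in range(3)
            ]
            m = np.mean(aligned, axis=0)
            m = m / np.linalg.norm(m)
            return sum(np.sum((a - m) ** 2) for a in aligned)

        best = None
        for s in range(4):
            x0 = np.random.default_rng(s).normal(0, 0.5, 9)
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
            if best is None or res.fun < best.fun:
                best = res
        aligned = [
            Z[i] @ Rotation.from_rotvec(best.x[3 * i: 3 * i + 3]).as_matrix().T
            for i in range(3)
        ]
        m = np.mean(aligned, axis=0)
        m /= np.linalg.norm(m)
        R, _ = orthogonal_procrustes(m, mean.reshape(-1, 3))
        np.testing.assert_allclose(m @ R, mean.reshape(-1, 3), atol=1e-8)

    def test_mismatched_landmark_sets_rejected(self):
        a = template_configuration(30, "a")
        b = template_configuration(31, "b")
        with pytest.raises(ValueError, match="mismatched"):
            gpa([a, b])


class TestShapeSpace:
    def test_exact_rank_two(self, rng):
        basis = rng.standard_normal((2, 6))
        X = rng.standard_normal((20, 2)) @ basis + rng.standard_normal(6)
        space = fit_shape_space(X, mode="covariance")
        assert np.sum(space.eigenvalues_ > 1e-10) == 2
        scores = space.transform(X)
        recon = space.inverse_transform(scores[:, : space.n_retained_])
        if space.n_retained_ >= 2:
            np.testing.assert_allclose(recon, X, atol=1e-8)

    @pytest.mark.parametrize(
        "evals,expected",
        [
            # Kaiser keeps 4 but cumulative share at 4 is 87% < 90% -> 4
            ([4.0, 2.0, 1.5, 1.2, 0.6, 0.4, 0.3], 4),
            # Kaiser keeps 3 and already passes 90% at 3 -> 3
            ([6.0, 2.0, 1.1, 0.5, 0.4], 3),
            ([1.0, 1.0, 1.0], 1),  # nothing above 1: floor of one component
        ],
    )
    def test_retention_rule_hand_examples(self, evals, expected):
        assert retained_components(np.array(evals), mode="correlation") == expected

    def test_retention_rule_properties(self, rng):
        """k never exceeds the Kaiser count, and reaches the 90% share
        whenever the Kaiser set itself does."""
        for _ in range(50):
            evals = np.sort(rng.gamma(1.0, 1.0, size=rng.integers(3, 25)))[::-1]
            k = retained_components(evals, mode="covariance")
            kaiser = max(int(np.sum(evals > evals.mean())), 1)
            assert 1 <= k <= kaiser
            shares = np.cumsum(evals) / evals.sum()
            if shares[kaiser - 1] >= 0.9:
                assert shares[k - 1] >= 0.9 - 1e-12

    def test_trace_conservation(self, rng):
        X = rng.standard_normal((40, 7)) * rng.uniform(0.5, 3, size=7)
        space = fit_shape_space(X, mode="covariance")
        total_var = np.sum(np.var(X, axis=0, ddof=1))
        assert space.eigenvalues_.sum() == pytest.approx(total_var, abs=1e-8)
        # eigenvector orthonormality
        V = space.components_
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)

    def test_constant_column_rejected_in_correlation_mode(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="constant"):
            fit_shape_space(X, mode="correlation")


class TestPanel:
    def test_scale_invariance(self):
        cfg = template_configuration(40)
        p1 = interlandmark_panel(cfg)
        p2 = interlandmark_panel(cfg.with_coords(2.0 * cfg.coords))
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)

    def test_zygomatic_width_hand_value(self):
        cfg = template_configuration(40)
        coords = cfg.coords.copy()
        coords[cfg.labels.index("zygion_r")] = [60.0, 0.0, 0.0]
        coords[cfg.labels.index("zygion_l")] = [-60.0, 0.0, 0.0]
        panel = interlandmark_panel(cfg.with_coords(coords))
        ex = np.linalg.norm(
            cfg.get("exocanthion_r") - cfg.get("exocanthion_l")
        )
        assert panel["zy_zy"] * ex == pytest.approx(120.0)

    def test_mirror_symmetry(self):
        cfg = template_configuration(40)
        mirrored = cfg.coords.copy()
        mirrored[:, 0] *= -1
        # swap left/right labels so the mirrored face is a valid configuration
        swap = {}
        for i, lab in enumerate(cfg.labels):
            if lab.endswith("_r"):
                swap[i] = cfg.labels.index(lab[:-2] + "_l")
            elif lab.endswith("_l"):
                swap[i] = cfg.labels.index(lab[:-2] + "_r")
            else:
                swap[i] = i
        reordered = mirrored[[swap[i] for i in range(len(cfg.labels))]]
        p1 = interlandmark_panel(cfg)
        p2 = interlandmark_panel(cfg.with_coords(reordered))
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)

    def test_missing_panel_landmark(self):
        cfg = template_configuration(40)
        idx = cfg.labels.index("gnathion")
        with pytest.raises(ValueError, match="gnathion"):
            interlandmark_panel(
                LandmarkConfiguration(
                    "s",
                    cfg.labels[:idx] + cfg.labels[idx + 1:],
                    np.delete(cfg.coords, idx, axis=0),
                )
            )


class TestAccentuate:
    def test_weights(self, rng):
        grand = rng.standard_normal(12)
        group = grand + rng.standard_normal(12) * 0.1
        np.testing.assert_allclose(accentuate_mean(group, grand, 0.0), grand)
        np.testing.assert_allclose(accentuate_mean(group, grand, 1.0), group)
        d = group - grand
        np.testing.assert_allclose(accentuate_mean(group, grand, 5.0), grand + 5 * d)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accentuate_mean(np.zeros(3), np.zeros(4), 2.0)
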