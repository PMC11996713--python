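"""Procrustes Surface Metric, prototype handling and the alignment loop."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from gpsa import (
    GPSAParams,
    ICPParams,
    SimilarityTransform,
    TriangleMesh,
    compute_psm,
    compute_psm_squared,
    mean_surface_of,
    nearest_neighbors,
    run_gpsa,
    select_prototype,
    symmetric_icp,
    update_prototype,
)
from gpsa.core import merge_close_points
from gpsa.synthetic import CohortSpec, generate_cohort
from conftest import random_rotation


def brute_force_psm(A, B):
    d = cdist(A, B)
    return np.sqrt(
        np.sum(d.min(axis=1) ** 2) / (2 * len(A))
        + np.sum(d.min(axis=0) ** 2) / (2 * len(B))
    )


class TestPSM:
    def test_identical_sets_zero(self, rng):
        pts = rng.normal(size=(30, 3))
        assert compute_psm(pts, pts) == 0.0

    def test_single_pair_hand_value(self):
        A = np.array([[0.0, 0.0, 0.0]])
        B = np.array([[3.0, 4.0, 0.0]])
        # both directions see distance 5: sqrt(25/2 + 25/2) = 5
        assert compute_psm(A, B) == pytest.approx(5.0, abs=1e-14)

    def test_asymmetric_counts_hand_value(self):
        A = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        B = np.array([[0.0, 0.0, 0.0]])
        # A->B: 0 and 2; B->A: 0 => sqrt((0+4)/4 + 0/2) = 1
        assert compute_psm(A, B) == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("n_a,n_b", [(17, 23), (100, 60)])
    def test_matches_brute_force(self, rng, n_a, n_b):
        A = rng.normal(size=(n_a, 3))
        B = rng.normal(size=(n_b, 3))
        assert compute_psm(A, B) == pytest.approx(
            brute_force_psm(A, B), rel=1e-12
        )

    def test_symmetry_exact(self, rng):
        A = rng.normal(size=(40, 3))
        B = rng.normal(size=(25, 3))
        assert compute_psm(A, B) == compute_psm(B, A)

    def test_rigid_motion_invariance(self, rng):
        A = rng.normal(size=(30, 3))
        B = rng.normal(size=(30, 3))
        d0 = compute_psm(A, B)
        R = random_rotation(rng, 120.0)
        t = rng.normal(size=3)
        assert compute_psm(A @ R.T + t, B @ R.T + t) == pytest.approx(
            d0, rel=1e-9
        )

    def test_equals_procrustes_distance_over_sqrt_m(self, rng):
        """With equal counts and mutual NN pairing the identity, D = P/sqrt(m)."""
        m = 40
        A = rng.uniform(0, 100, size=(m, 3))  # well separated w.h.p.
        B = A + 0.01 * rng.normal(size=(m, 3))  # tiny displacements keep NN identity
        corr = nearest_neighbors(A, B)
        assert (corr.pairs_ab == np.arange(m)).all()
        P = np.sqrt(np.sum((A - B) ** 2))
        assert compute_psm(A, B) == pytest.approx(P / np.sqrt(m), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_psm(np.zeros((0, 3)), np.zeros((3, 3)))

    def test_squared_consistent(self, rng):
        A = rng.normal(size=(20, 3))
        B = rng.normal(size=(22, 3))
        assert compute_psm(A, B) ** 2 == pytest.approx(
            compute_psm_squared(A, B), rel=1e-14
        )


class TestSelectPrototype:
    def test_identical_cohort_tie_breaks_low(self, icosphere):
        mesh = icosphere(1)
        idx = select_prototype([mesh, mesh, mesh])
        assert idx == 0

    def test_scaled_spheres_equivalent_after_superimposition(self, icosphere):
        meshes = [icosphere(1, radii=(r, r, r)) for r in (1.0, 1.0, 2.0)]
        assert select_prototype(meshes) == 0

    def test_medoid_of_deformed_cohort(self, icosphere, rng):
        a = icosphere(1, radii=(1.2, 1.0, 0.8))
        b = icosphere(1, radii=(1.2, 1.0, 0.8))
        warped = a.vertices.copy()
        warped[:, 0] *= 1.6  # strong deformation
        c = TriangleMesh(warped, a.faces, "warped")
        meshes = [c, a, b]
        idx = select_prototype(meshes)
        assert idx in (1, 2)
        # exhaustive check: summed pairwise PSM is minimal at the choice
        n = len(meshes)
        totals = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.sqrt(symmetric_icp(meshes[i], meshes[j]).final_cost)
                totals[i] += d
                totals[j] += d
        assert idx == totals.argmin()

    def test_single_mesh_warns(self, icosphere):
        with pytest.warns(UserWarning):
            assert select_prototype([icosphere(1)]) == 0


class TestUpdatePrototype:
    def test_mean_of_inbound_pairs(self):
        proto = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        s1 = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        s2 = np.array([[2.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        pairings = [nearest_neighbors(s, proto) for s in (s1, s2)]
        out = update_prototype(proto, [s1, s2], pairings)
        np.testing.assert_allclose(out[0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(out[1], [10.0, 0.0, 0.0])

    def test_identical_cohort_fixed_point(self, icosphere):
        proto = icosphere(1).vertices
        sup = [proto.copy(), proto.copy()]
        pairings = [nearest_neighbors(s, proto) for s in sup]
        out = update_prototype(proto, sup, pairings)
        np.testing.assert_allclose(out, proto, atol=1e-12)

    def test_unpaired_point_uses_outbound_fallback(self):
        proto = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [10.0, 0.0, 0.0]])
        spec = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        corr = nearest_neighbors(spec, proto)
        out = update_prototype(proto, [spec], [corr])
        # proto[1] attracts no specimen vertex; falls back to its own NN
        np.testing.assert_allclose(out[1], [0.0, 0.0, 0.0])


class TestMergeClosePoints:
    def test_zero_radius_keeps_count(self, rng):
        pts = rng.normal(size=(20, 3))
        out, _f, _m = merge_close_points(pts, np.zeros((0, 3), int), 0.0)
        assert len(out) == 20

    def test_close_pair_merges_to_centroid(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], [5.0, 0.0, 0.0]])
        faces = np.array([[0, 1, 2]])
        out, f, mapping = merge_close_points(pts, faces, 0.2)
        assert len(out) == 2
        np.testing.assert_allclose(out[0], [0.05, 0.0, 0.0])
        assert len(f) == 0  # face collapsed by the merge
        assert mapping[0] == mapping[1]


class TestRunGPSA:
    def test_identical_cohort(self, icosphere):
        mesh = icosphere(2)
        result = run_gpsa([mesh, mesh, mesh], "auto", GPSAParams())
        assert result.psm_to_mean.max() < 1e-10
        assert result.pairwise_psm.shape == (3, 3)
        np.testing.assert_allclose(result.pairwise_psm, result.pairwise_psm.T)
        assert np.diag(result.pairwise_psm).max() == 0.0

    def test_similarity_transforms_fully_removed(self):
        """Alignment removes exactly the non-shape degrees of freedom."""
        spec = CohortSpec(
            n_specimens=10, seed=3, base_shape="ellipsoid", noise_sigma=0.0,
            vertex_count_jitter=False, max_rotation_deg=25.0,
        )
        meshes, truth = generate_cohort(spec)
        result = run_gpsa(meshes, "auto", GPSAParams())
        diam = truth.base_diameter
        assert result.psm_to_mean.max() < 1e-6 * diam
        assert result.pairwise_psm.max() < 1e-6 * diam

    def test_jitter_increases_distance_monotonically(self, icosphere, rng):
        base = icosphere(2, radii=(1.2, 1.0, 0.8))
        diam = base.diameter()
        psms = []
        jitter = 0.01 * diam * rng.normal(size=base.vertices.shape)
        for sigma_frac in (0.001, 0.01, 0.1):
            noisy = TriangleMesh(
                base.vertices + sigma_frac / 0.01 * jitter, base.faces, "noisy"
            )
            result = run_gpsa([base, base, noisy], base, GPSAParams(
                prototype_update=False, outer_iterations=1))
            psms.append(result.psm_to_mean[2])
        assert psms[0] < psms[1] < psms[2]

    def test_two_mesh_cohort_shape(self, icosphere):
        a = icosphere(1)
        b = icosphere(1, radii=(1.1, 1.0, 0.9))
        result = run_gpsa([a, b], "auto", GPSAParams())
        assert result.pairwise_psm.shape == (2, 2)
        assert result.pairwise_psm[0, 1] == result.pairwise_psm[1, 0]

    def test_fewer_than_two_rejected(self, icosphere):
        with pytest.raises(ValueError):
            run_gpsa([icosphere(1)], "auto")


class TestMeanSurface:
    def test_identical_cohort_mean_equals_input(self, icosphere):
        mesh = icosphere(2)
        result = run_gpsa([mesh, mesh], mesh, GPSAParams())
        mean = mean_surface_of(result)
        res = symmetric_icp(mean, mesh)
        aligned = res.transform.apply(mean.vertices)
        assert np.abs(aligned - mesh.vertices).max() < 1e-9

    def test_displaced_vertex_averaged(self, icosphere):
        base = icosphere(3, radii=(10.0, 10.0, 10.0))
        moved = base.vertices.copy()
        vid = int(np.argmax(moved[:, 0]))  # vertex nearest +x pole
        moved[vid, 0] += 2.0
        other = TriangleMesh(moved, base.faces, "b")
        params = GPSAParams(outer_iterations=1, duplicate_merge_radius=0.0)
        result = run_gpsa([base, other], base, params)
        mean = mean_surface_of(result)
        expected = base.vertices[vid] + [1.0, 0.0, 0.0]
        assert np.linalg.norm(mean.vertices[vid] - expected) < 0.1

    def test_reusing_exported_mean_is_deterministic(self, icosphere, tmp_path):
        from gpsa import read_ply, write_ply

        a = icosphere(1, radii=(1.2, 1.0, 0.8))
        b = icosphere(1, radii=(1.0, 1.1, 0.9))
        result = run_gpsa([a, b], "auto", GPSAParams())
        mean = mean_surface_of(result)
        path = tmp_path / "mean.ply"
        write_ply(mean, path, dialect="binary")
        reloaded = read_ply(path)
        r1 = run_gpsa([a, b], reloaded, GPSAParams())
        r2 = run_gpsa([a, b], reloaded, GPSAParams())
        np.testing.assert_array_equal(r1.psm_to_mean, r2.psm_to_mean)
        np.testing.assert_array_equal(r1.pairwise_psm, r2.pairwise_psm)
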