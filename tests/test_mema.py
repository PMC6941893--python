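"""Surface maps: vertex assignment, geodesic smoothing, the random-effects
fit, cluster inference, and coverage."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gammamap import mema, synth
from gammamap.mesh import cluster_sizes, geodesic_distances, label_clusters


class TestNearestNode:
    def test_exact_vertex_maps_to_itself(self, mesh_small):
        assert mema.nearest_node(mesh_small.vertices[17], mesh_small) == 17

    def test_matches_exhaustive_scan(self, mesh_small, rng):
        for _ in range(50):
            p = rng.uniform(-45, 45, 3)
            best = min(
                range(mesh_small.n_vertices),
                key=lambda i: np.sum((mesh_small.vertices[i] - p) ** 2),
            )
            assert mema.nearest_node(p, mesh_small) == best

    def test_tie_breaks_to_lowest_index(self, mesh_small):
        # midpoint of an edge is equidistant from both endpoints
        i, j = mesh_small.faces[0][:2]
        mid = (mesh_small.vertices[i] + mesh_small.vertices[j]) / 2
        assert mema.nearest_node(mid, mesh_small) == min(i, j)

    def test_nonfinite_coordinate_rejected(self, mesh_small):
        with pytest.raises(ValueError):
            mema.nearest_node(np.array([np.nan, 0, 0]), mesh_small)


class TestGeodesicSmoothing:
    def test_constant_field_is_fixed_point(self, mesh_fine):
        out = mema.geodesic_gaussian_smooth(np.full(mesh_fine.n_vertices, 3.0), mesh_fine, 3.0)
        assert np.allclose(out, 3.0, atol=1e-12)

    def test_impulse_response_matches_direct_kernel(self, mesh_fine):
        src = 123
        field = np.zeros(mesh_fine.n_vertices)
        field[src] = 1.0
        out = mema.geodesic_gaussian_smooth(field, mesh_fine, fwhm := 6.0)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        cutoff = mema.KERNEL_CUTOFF_SIGMAS * sigma
        d_all = geodesic_distances(mesh_fine, np.arange(mesh_fine.n_vertices), limit=cutoff)
        for tgt in np.flatnonzero(out > 0)[:20]:
            drow = d_all[tgt]
            w = np.where(np.isfinite(drow), np.exp(-(drow**2) / (2 * sigma**2)), 0.0)
            assert out[tgt] == pytest.approx(w[src] / w.sum(), rel=1e-9)

    def test_tiny_fwhm_is_identity(self, mesh_fine, rng):
        field = rng.standard_normal(mesh_fine.n_vertices)
        out = mema.geodesic_gaussian_smooth(field, mesh_fine, 0.1)
        assert np.allclose(out, field)

    def test_global_mean_approximately_preserved(self, mesh_fine, rng):
        # row normalization is not exactly symmetric, but on a near-uniform
        # closed mesh the global mean moves only marginally
        field = rng.standard_normal(mesh_fine.n_vertices)
        out = mema.geodesic_gaussian_smooth(field, mesh_fine, 3.0)
        assert abs(out.mean() - field.mean()) < 0.01 * field.std()


class TestMemaFit:
    def test_reduces_to_one_sample_t_with_zero_variances(self, rng):
        y = rng.normal(20, 5, 10)
        est = pd.DataFrame({"subject": range(10), "vertex": 0, "estimate": y, "variance": 0.0})
        fit = mema.mema_fit(est, 1)
        t_ref, p_ref = stats.ttest_1samp(y, 0.0)
        assert fit.t[0] == pytest.approx(t_ref, abs=1e-6)
        assert fit.p[0] == pytest.approx(p_ref, rel=1e-6)
        assert fit.effect[0] == pytest.approx(y.mean(), abs=1e-9)

    def test_single_subject_estimate_without_test(self):
        est = pd.DataFrame({"subject": ["A"], "vertex": [0], "estimate": [42.0], "variance": [1.0]})
        fit = mema.mema_fit(est, 1)
        assert fit.effect[0] == 42.0
        assert np.isnan(fit.p[0])
        assert fit.n_subjects[0] == 1

    def test_zero_variances_unequal_estimates_no_crash(self):
        est = pd.DataFrame(
            {"subject": range(4), "vertex": 0, "estimate": [1.0, 2.0, 3.0, 4.0], "variance": 0.0}
        )
        fit = mema.mema_fit(est, 1)
        assert np.isfinite(fit.t[0])
        assert fit.tau2[0] > 0  # dispersion absorbed by tau^2

    def test_inverse_variance_weighting_with_fixed_effects(self):
        # tau^2 = 0 (consistent estimates) -> weights 1/v_i
        est = pd.DataFrame(
            {
                "subject": range(3),
                "vertex": 0,
                "estimate": [10.0, 10.0, 10.0],
                "variance": [1.0, 2.0, 4.0],
            }
        )
        fit = mema.mema_fit(est, 1)
        assert fit.effect[0] == pytest.approx(10.0)
        assert fit.tau2[0] == pytest.approx(0.0, abs=1e-4)


class TestClusterInference:
    def test_label_clusters_matches_flood_fill(self, mesh_small, rng):
        adjacency = [[] for _ in range(mesh_small.n_vertices)]
        for a, b, c in mesh_small.faces:
            for i, j in ((a, b), (b, c), (c, a)):
                adjacency[i].append(j)
                adjacency[j].append(i)
        for _ in range(20):
            mask = rng.uniform(size=mesh_small.n_vertices) < 0.3
            ids = label_clusters(mesh_small, mask)
            # brute-force flood fill
            seen = np.full(mesh_small.n_vertices, -1)
            next_id = 0
            for start in range(mesh_small.n_vertices):
                if not mask[start] or seen[start] >= 0:
                    continue
                stack = [start]
                seen[start] = next_id
                while stack:
                    v = stack.pop()
                    for nb in adjacency[v]:
                        if mask[nb] and seen[nb] < 0:
                            seen[nb] = next_id
                            stack.append(nb)
                next_id += 1
            assert np.array_equal(ids, seen)

    def test_extent_threshold_monotone_in_fwer_alpha(self, mesh_fine):
        k5 = mema.cluster_extent_threshold(mesh_fine, 3.0, 0.01, 0.05, n_iter=200, seed=0)
        k1 = mema.cluster_extent_threshold(mesh_fine, 3.0, 0.01, 0.01, n_iter=200, seed=0)
        assert k1 >= k5

    def test_extent_threshold_grows_with_smoothness(self, mesh_fine):
        k3 = mema.cluster_extent_threshold(mesh_fine, 3.0, 0.01, 0.05, n_iter=200, seed=0)
        k6 = mema.cluster_extent_threshold(mesh_fine, 6.0, 0.01, 0.05, n_iter=200, seed=0)
        assert k6 > k3

    def test_too_few_iterations_rejected(self, mesh_fine):
        with pytest.raises(ValueError):
            mema.cluster_extent_threshold(mesh_fine, 3.0, 0.01, 0.05, n_iter=50, seed=0)


class TestCoverage:
    def test_no_electrodes_empty_mask(self, mesh_small):
        counts, mask = mema.coverage_mask(pd.DataFrame(columns=["patient", "x", "y", "z"]),
                                          mesh_small)
        assert counts.sum() == 0
        assert not mask.any()

    def test_three_patients_at_one_vertex(self, mesh_small):
        v = mesh_small.vertices[5]
        el = pd.DataFrame(
            {"patient": ["P1", "P2", "P3"], "x": v[0], "y": v[1], "z": v[2]}
        )
        counts, mask = mema.coverage_mask(el, mesh_small, radius_mm=10.0, min_patients=3)
        assert counts[5] == 3
        assert mask[5]

    def test_counts_match_brute_force_distance_scan(self, mesh_small, rng):
        el = synth.place_electrodes(mesh_small, 3, 2, 4, 3.5, seed=5)
        radius = 12.0
        counts, _ = mema.coverage_mask(el, mesh_small, radius_mm=radius, min_patients=3)
        vtx = mema.assign_electrodes(el, mesh_small)
        expected = np.zeros(mesh_small.n_vertices, dtype=int)
        for v in range(mesh_small.n_vertices):
            n = 0
            for patient, rows in el.assign(vtx=vtx).groupby("patient"):
                d = geodesic_distances(mesh_small, rows["vtx"].unique())
                if (d[:, v] <= radius).any():
                    n += 1
            expected[v] = n
        assert np.array_equal(counts, expected)


class TestMovieWindows:
    def test_frame_count_formula(self):
        wins = mema.movie_windows((-500.0, 600.0), width_ms=150.0, step_ms=10.0)
        assert len(wins) == int(np.floor((1100 - 150) / 10)) + 1 == 96
        assert wins[0] == (-500.0, -350.0)
        assert wins[-1][1] <= 600.0

    def test_epoch_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            mema.movie_windows((0.0, 100.0), width_ms=150.0)
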