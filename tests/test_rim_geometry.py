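"""Rim geometry: volumes, diameter, surfaces, distance sets, G_H."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliomark import (
    LabeledVolume,
    ShellSpec,
    compute_volumes,
    extract_rim_surfaces,
    geometric_features,
    geometric_heterogeneity,
    make_shell_phantom,
    max_diameter_3d,
    rim_distance_set,
    spherical_rim_width,
)
from gliomark.rim_geometry import (
    DegenerateRimError,
    NoEnhancementError,
    PREFACTOR,
    RimDistanceSet,
    rim_quartiles,
)
from gliomark.volume import BACKGROUND, CE, INNER

from _oracles import brute_max_diameter, brute_min_distances


def _volume_from_labels(labels, spacing=(1.0, 1.0, 1.0)):
    return LabeledVolume(np.zeros(labels.shape), labels, spacing)


class TestVolumes:
    def test_counting(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels.flat[:100] = CE
        labels.flat[100:150] = INNER
        v_ce, v_i, v = compute_volumes(_volume_from_labels(labels))
        assert (v_ce, v_i) == (0.100, 0.050)
        assert v == pytest.approx(0.150)

    def test_spacing_scales_volumes(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels.flat[:100] = CE
        labels.flat[100:150] = INNER
        v1 = compute_volumes(_volume_from_labels(labels))
        v8 = compute_volumes(_volume_from_labels(labels, spacing=(2, 2, 2)))
        assert v8 == tuple(8 * x for x in v1)

    def test_shell_volume_analytic(self):
        spec = ShellSpec(inner_radius=10, outer_radius_base=20, spacing=(0.5,) * 3)
        _, _, v = compute_volumes(make_shell_phantom(spec))
        assert v == pytest.approx(4 / 3 * np.pi * 8.0, rel=0.02)  # 33.51 cm^3

    def test_no_enhancement_raises(self):
        labels = np.zeros((4, 4, 4), dtype=np.uint8)
        labels[0, 0, 0] = INNER
        with pytest.raises(NoEnhancementError):
            compute_volumes(_volume_from_labels(labels))

    @given(
        n_ce=st.integers(1, 60),
        n_inner=st.integers(0, 60),
        s=st.floats(0.3, 3.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_additivity_exact(self, n_ce, n_inner, s):
        """V = V_CE + V_I holds exactly on every input."""
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels.flat[:n_ce] = CE
        labels.flat[n_ce:n_ce + n_inner] = INNER
        v_ce, v_i, v = compute_volumes(_volume_from_labels(labels, spacing=(s, s, s)))
        assert v == v_ce + v_i


class TestSphericalRimWidth:
    def test_collapses_to_shell_thickness(self):
        # spherical shell R = 2 cm, r = 1 cm
        v = 4 / 3 * np.pi * 8.0
        v_i = 4 / 3 * np.pi
        assert spherical_rim_width(v, v_i) == pytest.approx(1.0)

    def test_empty_rim(self):
        assert spherical_rim_width(3.7, 3.7) == 0.0

    def test_prefactor_rounds_to_062(self):
        assert round(PREFACTOR, 2) == 0.62

    def test_inverted_volumes_rejected(self):
        with pytest.raises(ValueError):
            spherical_rim_width(1.0, 2.0)

    def test_voxelized_shell_width(self, uniform_shell):
        _, v_i, v = compute_volumes(uniform_shell)
        assert spherical_rim_width(v, v_i) * 10 == pytest.approx(10.0, rel=0.05)


class TestMaxDiameter:
    def test_three_four_five(self):
        labels = np.zeros((31, 41, 3), dtype=np.uint8)
        labels[0, 0, 0] = CE
        labels[30, 40, 0] = CE
        assert max_diameter_3d(_volume_from_labels(labels)) == pytest.approx(5.0)

    def test_single_voxel(self):
        labels = np.zeros((3, 3, 3), dtype=np.uint8)
        labels[1, 1, 1] = CE
        assert max_diameter_3d(_volume_from_labels(labels)) == 0.0

    def test_anisotropic_spacing(self):
        labels = np.zeros((2, 1, 1), dtype=np.uint8)
        labels[:, 0, 0] = CE
        d = max_diameter_3d(_volume_from_labels(labels, spacing=(3.0, 1.0, 1.0)))
        assert d == pytest.approx(0.3)

    def test_matches_bruteforce_on_random_blobs(self, rng):
        """Convex-hull shortcut equals the all-pairs maximum."""
        for _ in range(5):
            labels = np.zeros((20, 20, 20), dtype=np.uint8)
            idx = rng.integers(0, 20, size=(200, 3))
            labels[idx[:, 0], idx[:, 1], idx[:, 2]] = CE
            vol = _volume_from_labels(labels, spacing=(0.9, 1.1, 1.4))
            pts = np.argwhere(vol.tumor_mask) * np.array([0.9, 1.1, 1.4])
            assert max_diameter_3d(vol) * 10 == pytest.approx(
                brute_max_diameter(pts), abs=1e-9
            )

    def test_empty_tumor_raises(self):
        with pytest.raises(NoEnhancementError):
            compute_volumes(_volume_from_labels(np.zeros((3, 3, 3), dtype=np.uint8)))


class TestSurfaces:
    def test_one_voxel_thick_shell_is_both_surfaces(self):
        """Every CE voxel of a 1-voxel rim touches both the core and outside."""
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[1:4, 1:4, 1:4] = CE
        labels[2, 2, 2] = INNER
        vol = _volume_from_labels(labels)
        inner_pts, outer_pts = extract_rim_surfaces(vol, convention="voxel_centers")
        outer_set = {tuple(p) for p in outer_pts}
        ce_centers = {tuple(p.astype(float)) for p in np.argwhere(labels == CE)}
        assert outer_set == ce_centers
        # only the 6 face-adjacent voxels of the core are on the inner surface
        assert len(inner_pts) == 6

    def test_slab_inner_surface_is_contact_layer(self):
        """CE slab bounded by core on one face: inner surface = that layer."""
        labels = np.zeros((6, 4, 4), dtype=np.uint8)
        labels[0] = INNER
        labels[1:4] = CE
        vol = _volume_from_labels(labels)
        inner_pts, outer_pts = extract_rim_surfaces(vol, convention="voxel_centers")
        assert len(inner_pts) == 16
        assert set(inner_pts[:, 0]) == {1.0}

    def test_face_convention_offsets_half_voxel(self):
        labels = np.zeros((6, 4, 4), dtype=np.uint8)
        labels[0] = INNER
        labels[1:4] = CE
        inner_pts, _ = extract_rim_surfaces(_volume_from_labels(labels))
        assert set(inner_pts[:, 0]) == {0.5}  # on the INNER/CE interface

    def test_solid_tumor_has_empty_inner_surface(self):
        labels = np.zeros((5, 5, 5), dtype=np.uint8)
        labels[1:4, 1:4, 1:4] = CE
        inner_pts, outer_pts = extract_rim_surfaces(_volume_from_labels(labels))
        assert len(inner_pts) == 0 and len(outer_pts) > 0

    def test_surface_counts_match_bruteforce_census(self, uniform_shell):
        """Vectorized boundary detection equals a per-voxel neighbor scan."""
        lab = uniform_shell.labels
        inner_pts, outer_pts = extract_rim_surfaces(uniform_shell, convention="voxel_centers")
        n_inner = n_outer = 0
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
        nx, ny, nz = lab.shape
        for i, j, k in np.argwhere(lab == CE):
            neigh = []
            for dx, dy, dz in offsets:
                a, b, c = i + dx, j + dy, k + dz
                neigh.append(
                    lab[a, b, c] if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz else BACKGROUND
                )
            n_inner += INNER in neigh
            n_outer += BACKGROUND in neigh
        assert len(inner_pts) == n_inner
        assert len(outer_pts) == n_outer


class TestRimDistances:
    def test_parallel_planes(self):
        a = np.array([[0.0, y, z] for y in range(4) for z in range(4)])
        b = a + [5.0, 0, 0]
        d = rim_distance_set(a, b)
        assert np.allclose(d.distances, 5.0)
        assert len(d.distances) == 32  # pooled: both directions

    def test_pooling_modes(self):
        a = np.zeros((3, 3))
        b = np.ones((5, 3))
        assert len(rim_distance_set(a, b, pooling="inner").distances) == 3
        assert len(rim_distance_set(a, b, pooling="outer").distances) == 5
        with pytest.raises(ValueError):
            rim_distance_set(a, b, pooling="bogus")

    def test_empty_surface_raises(self):
        with pytest.raises(DegenerateRimError):
            rim_distance_set(np.empty((0, 3)), np.ones((4, 3)))

    def test_kdtree_equals_bruteforce(self, rng):
        """Accelerated nearest-neighbor equals the all-pairs scan exactly."""
        for _ in range(5):
            a = rng.uniform(0, 30, size=(rng.integers(2, 400), 3))
            b = rng.uniform(0, 30, size=(rng.integers(2, 400), 3))
            ours = np.sort(rim_distance_set(a, b).distances)
            oracle = np.sort(brute_min_distances(a, b))
            assert np.array_equal(ours, oracle)

    def test_uniform_shell_distances_concentrated(self, uniform_shell):
        inner_pts, outer_pts = extract_rim_surfaces(uniform_shell)
        d = rim_distance_set(inner_pts, outer_pts)
        q = rim_quartiles(d)
        assert all(abs(x - 10.0) < 0.75 for x in q)


class TestGeometricHeterogeneity:
    def test_constant_distances(self):
        d = RimDistanceSet(np.full(50, 3.3), 25, 25)
        assert geometric_heterogeneity(d) == 0.0

    def test_two_mass_80_20(self):
        """Q3 sits in the lower mass, Q4 at the upper one."""
        d = RimDistanceSet(np.array([1.0] * 80 + [2.0] * 20), 50, 50)
        assert geometric_heterogeneity(d) == pytest.approx(0.5)

    def test_two_mass_50_50(self):
        d = RimDistanceSet(np.array([1.0] * 50 + [2.0] * 50), 50, 50)
        assert geometric_heterogeneity(d) == 0.0

    def test_all_zero_distances_degenerate(self):
        d = RimDistanceSet(np.zeros(10), 5, 5)
        with pytest.raises(DegenerateRimError):
            geometric_heterogeneity(d)

    @given(
        scale=st.floats(1e-3, 1e3),
        values=st.lists(st.floats(0.01, 100.0), min_size=2, max_size=50),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale, values):
        """G_H is unit-free: invariant under uniform distance rescaling."""
        base = RimDistanceSet(np.array(values), 1, len(values) - 1)
        scaled = RimDistanceSet(np.array(values) * scale, 1, len(values) - 1)
        assert geometric_heterogeneity(base) == pytest.approx(
            geometric_heterogeneity(scaled), abs=1e-9
        )

    def test_uniform_shell_low_gh(self, uniform_shell):
        feats = geometric_features(uniform_shell)
        assert feats.g_h <= 0.1

    def test_twomass_shell_matches_closed_form(self, twomass_shell):
        feats = geometric_features(twomass_shell)
        assert feats.g_h == pytest.approx(twomass_shell.meta["expected_gh"], abs=0.05)

    def test_quartiles_ordered(self, twomass_shell):
        f = geometric_features(twomass_shell)
        assert f.rim_q1_mm <= f.rim_q2_mm <= f.rim_q3_mm <= f.rim_q4_mm


class TestGeometricFeatures:
    def test_solid_tumor_gh_missing(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        labels[1:5, 1:5, 1:5] = CE
        feats = geometric_features(_volume_from_labels(labels))
        assert np.isnan(feats.g_h) and np.isnan(feats.rim_q4_mm)
        assert feats.v_i_cm3 == 0.0 and feats.delta_s_cm > 0

    def test_row_layout(self, uniform_shell):
        row = geometric_features(uniform_shell).to_row()
        assert list(row) == [
            "V_ce_cm3", "V_i_cm3", "V_cm3", "d_max_cm", "delta_s_cm", "g_h",
            "rim_q1_mm", "rim_q2_mm", "rim_q3_mm", "rim_q4_mm",
        ]
        assert row["V_cm3"] == row["V_ce_cm3"] + row["V_i_cm3"]
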