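"""Geometric measures of the contrast-enhancing (CE) tumor rim.

Given a labeled volume this module computes the volumetric measures (V_CE,
V_I, V = V_CE + V_I), the 3D maximal diameter d_max, the spherical rim width

    delta_s = (3 / (4 pi))^(1/3) * (V^(1/3) - V_I^(1/3))

i.e. the shell thickness of the sphere-equivalent tumor, and the geometric
heterogeneity of the rim

    G_H = (Q4 - Q3) / Q4

where Q3 and Q4 are the third quartile and the maximum of the distribution of
minimal distances between the inner and outer CE surfaces. G_H is 0 for a
perfectly even rim and approaches 1 for a highly uneven one.

Surfaces are defined on voxel centers with 6-connectivity: an outer-surface
voxel is a CE voxel with a background (or out-of-grid) face neighbor, an
inner-surface voxel is a CE voxel with an inner-core face neighbor. Distances
are Euclidean in physical mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist

from .volume import BACKGROUND, CE, INNER, LabeledVolume

PREFACTOR = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # ~0.62 in the rim-width formula


class NoEnhancementError(ValueError):
    """Tumor has no CE voxels (excluded from analysis)."""


class DegenerateRimError(ValueError):
    """CE region is not rim-shaped (no inner core), so G_H is undefined."""


@dataclass
class RimDistanceSet:
    """Pooled minimal surface-to-surface distances of the CE rim (mm)."""

    distances: np.ndarray
    n_inner: int
    n_outer: int

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.size and (self.distances < 0).any():
            raise ValueError("distances must be non-negative")


@dataclass
class GeometricFeatures:
    """Per-tumor geometric feature vector (units as in the clinical tables)."""

    v_ce_cm3: float
    v_i_cm3: float
    v_cm3: float
    d_max_cm: float
    delta_s_cm: float
    g_h: float
    rim_q1_mm: float
    rim_q2_mm: float
    rim_q3_mm: float
    rim_q4_mm: float

    def to_row(self) -> dict:
        """Fixed CSV column layout."""
        return {
            "V_ce_cm3": self.v_ce_cm3,
            "V_i_cm3": self.v_i_cm3,
            "V_cm3": self.v_cm3,
            "d_max_cm": self.d_max_cm,
            "delta_s_cm": self.delta_s_cm,
            "g_h": self.g_h,
            "rim_q1_mm": self.rim_q1_mm,
            "rim_q2_mm": self.rim_q2_mm,
            "rim_q3_mm": self.rim_q3_mm,
            "rim_q4_mm": self.rim_q4_mm,
        }


def compute_volumes(vol: LabeledVolume) -> tuple[float, float, float]:
    """(V_CE, V_I, V) in cm^3 by voxel counting."""
    n_ce = int(vol.ce_mask.sum())
    if n_ce == 0:
        raise NoEnhancementError("no contrast-enhancing voxels")
    n_inner = int(vol.inner_mask.sum())
    vox_cm3 = vol.voxel_volume_mm3 / 1000.0
    v_ce = n_ce * vox_cm3
    v_i = n_inner * vox_cm3
    return v_ce, v_i, v_ce + v_i


def spherical_rim_width(v_cm3: float, v_i_cm3: float) -> float:
    """Sphere-equivalent rim thickness in cm.

    Collapses to R - r for an ideal spherical shell of radii R and r.
    """
    if v_i_cm3 < 0 or v_cm3 < v_i_cm3:
        raise ValueError(f"need V >= V_I >= 0, got V={v_cm3}, V_I={v_i_cm3}")
    return PREFACTOR * (v_cm3 ** (1.0 / 3.0) - v_i_cm3 ** (1.0 / 3.0))


def _touches(mask: np.ndarray, target_padded: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a 6-neighbor set in the 1-voxel-padded target."""
    out = np.zeros_like(mask)
    core = (slice(1, -1),) * 3
    for axis in range(3):
        for step in (-1, 1):
            out |= mask & np.roll(target_padded, step, axis=axis)[core]
    return out


def _free_boundary(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a 6-neighbor outside the mask or the grid."""
    return _touches(mask, ~np.pad(mask, 1, constant_values=False))


def _physical_coords(mask: np.ndarray, spacing) -> np.ndarray:
    idx = np.argwhere(mask)
    return idx * np.asarray(spacing, dtype=float)


def max_diameter_3d(vol: LabeledVolume) -> float:
    """Maximum Euclidean voxel-center distance within the tumor, in cm.

    Restricted to tumor surface voxels (interior points cannot realize the
    maximum); the exact pairwise maximum is taken over convex-hull vertices,
    falling back to all pairs for small or degenerate (coplanar) point sets.
    """
    tumor = vol.tumor_mask
    if not tumor.any():
        raise ValueError("empty tumor")
    surface = _free_boundary(tumor)
    pts = _physical_coords(surface, vol.spacing)
    if len(pts) == 1:
        return 0.0
    if len(pts) > 16:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # coplanar/collinear — brute force below
    return float(pdist(pts).max()) / 10.0


def _face_points(mask: np.ndarray, target_padded: np.ndarray, spacing) -> np.ndarray:
    """Centers of voxel faces between ``mask`` and the padded target, in mm."""
    spacing = np.asarray(spacing, dtype=float)
    core = (slice(1, -1),) * 3
    pts = []
    for axis in range(3):
        for step in (-1, 1):
            touching = mask & np.roll(target_padded, step, axis=axis)[core]
            if touching.any():
                coords = np.argwhere(touching) * spacing
                # face midpoint: half a voxel toward the neighbor
                coords[:, axis] -= step * spacing[axis] / 2.0
                pts.append(coords)
    return np.concatenate(pts) if pts else np.empty((0, 3))


def extract_rim_surfaces(
    vol: LabeledVolume, convention: str = "faces"
) -> tuple[np.ndarray, np.ndarray]:
    """(inner_points, outer_points) of the CE rim, in physical mm.

    Outer surface: where CE meets a non-tumor 6-neighbor (background or
    out-of-grid). Inner surface: where CE meets the inner core. With the
    default ``convention='faces'`` the points are the midpoints of the
    separating voxel faces — an unbiased sampling of the enclosing surfaces.
    ``convention='voxel_centers'`` returns the centers of the boundary CE
    voxels instead; that convention under-measures each rim width by about
    one voxel (half a voxel per side). An empty inner surface signals a
    solid (non-rim-shaped) tumor.
    """
    ce = vol.ce_mask
    if not ce.any():
        raise NoEnhancementError("no contrast-enhancing voxels")
    # out-of-grid neighbors count as non-tumor for the outer surface
    non_tumor = ~np.pad(vol.tumor_mask, 1, constant_values=False)
    inner_core = np.pad(vol.inner_mask, 1, constant_values=False)
    if convention == "faces":
        inner_pts = _face_points(ce, inner_core, vol.spacing)
        outer_pts = _face_points(ce, non_tumor, vol.spacing)
    elif convention == "voxel_centers":
        inner_pts = _physical_coords(_touches(ce, inner_core), vol.spacing)
        outer_pts = _physical_coords(_touches(ce, non_tumor), vol.spacing)
    else:
        raise ValueError(f"unknown surface convention {convention!r}")
    return inner_pts, outer_pts


def rim_distance_set(
    inner_points: np.ndarray,
    outer_points: np.ndarray,
    pooling: str = "both",
) -> RimDistanceSet:
    """Minimal distance of every surface point to the opposite surface.

    ``pooling='both'`` (default) pools inner->outer and outer->inner minima
    into one multiset; 'inner' or 'outer' keep a single direction.
    """
    inner_points = np.atleast_2d(np.asarray(inner_points, dtype=float))
    outer_points = np.atleast_2d(np.asarray(outer_points, dtype=float))
    if inner_points.size == 0 or outer_points.size == 0:
        raise DegenerateRimError("both surfaces must be non-empty")
    d_in = cKDTree(outer_points).query(inner_points)[0]
    d_out = cKDTree(inner_points).query(outer_points)[0]
    if pooling == "both":
        distances = np.concatenate([d_in, d_out])
    elif pooling == "inner":
        distances = d_in
    elif pooling == "outer":
        distances = d_out
    else:
        raise ValueError(f"unknown pooling {pooling!r}")
    return RimDistanceSet(distances=distances, n_inner=len(inner_points), n_outer=len(outer_points))


def rim_quartiles(d: RimDistanceSet, method: str = "linear") -> tuple[float, float, float, float]:
    """(Q1, Q2, Q3, Q4) of the rim-width distribution in mm.

    Q1-Q3 use the requested numpy quantile rule (default 'linear', the common
    type-7 estimator); Q4 is the sample maximum.
    """
    if d.distances.size == 0:
        raise DegenerateRimError("empty distance set")
    q1, q2, q3 = np.quantile(d.distances, [0.25, 0.5, 0.75], method=method)
    return float(q1), float(q2), float(q3), float(d.distances.max())


def geometric_heterogeneity(d: RimDistanceSet, method: str = "linear") -> float:
    """G_H = (Q4 - Q3) / Q4 in [0, 1]; undefined for an all-zero distance set."""
    _, _, q3, q4 = rim_quartiles(d, method=method)
    if q4 <= 0:
        raise DegenerateRimError("all rim distances are zero; G_H undefined")
    return (q4 - q3) / q4


def geometric_features(
    vol: LabeledVolume,
    pooling: str = "both",
    quantile_rule: str = "linear",
    surface_convention: str = "faces",
) -> GeometricFeatures:
    """All geometric measures of one tumor.

    For solid tumors (no inner core) the rim-width distribution and G_H are
    reported as NaN: the rim-based measures are defined only for rim-shaped
    CE regions. Volumes, delta_s (with V_I = 0) and d_max are still computed.
    """
    v_ce, v_i, v = compute_volumes(vol)
    d_max = max_diameter_3d(vol)
    delta_s = spherical_rim_width(v, v_i)
    try:
        inner_pts, outer_pts = extract_rim_surfaces(vol, convention=surface_convention)
        dset = rim_distance_set(inner_pts, outer_pts, pooling=pooling)
        q1, q2, q3, q4 = rim_quartiles(dset, method=quantile_rule)
        g_h = geometric_heterogeneity(dset, method=quantile_rule)
    except DegenerateRimError:
        q1 = q2 = q3 = q4 = g_h = float("nan")
    return GeometricFeatures(
        v_ce_cm3=v_ce,
        v_i_cm3=v_i,
        v_cm3=v,
        d_max_cm=d_max,
        delta_s_cm=delta_s,
        g_h=g_h,
        rim_q1_mm=q1,
        rim_q2_mm=q2,
        rim_q3_mm=q3,
        rim_q4_mm=q4,
    )
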