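"""Synthetic tumor phantoms and survival cohorts with known ground truth.

Shell phantoms emulate the shell-shaped geometry of contrast-enhancing (CE)
glioblastoma rims: an inner (necrotic) sphere of radius ``inner_radius``
wrapped by a CE shell whose outer radius is ``outer_radius_base`` everywhere
except on a spherical cap around +z covering a chosen fraction of solid angle,
where it is raised to ``bump_outer_radius``. This gives a rim-width
distribution with exactly two masses, so the spherical rim width and the
geometric heterogeneity have closed-form ground truth.

Texture phantoms provide ROIs whose co-occurrence and run-length features are
hand-computable (a constant block, axis-aligned stripes of period 2).

Cohort simulation draws two-group exponential survival with a known hazard
ratio across a marker threshold, plus optional independent uniform censoring —
the recovery harness for the Cox/log-rank layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .volume import BACKGROUND, CE, INNER, LabeledVolume


class PhantomSizingError(ValueError):
    """Grid too small to contain the requested shell plus margin."""


class DegeneratePhantomError(ValueError):
    """A requested label received zero voxels."""


@dataclass
class ShellSpec:
    """Geometry of a bumped spherical-shell phantom (all lengths in mm)."""

    inner_radius: float
    outer_radius_base: float
    bump_fraction: float = 0.0
    bump_outer_radius: float | None = None
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.bump_outer_radius is None:
            self.bump_outer_radius = self.outer_radius_base
        if not (0.0 < self.inner_radius < self.outer_radius_base <= self.bump_outer_radius):
            raise ValueError(
                "need inner_radius < outer_radius_base <= bump_outer_radius, got "
                f"{self.inner_radius}, {self.outer_radius_base}, {self.bump_outer_radius}"
            )
        if not 0.0 <= self.bump_fraction <= 1.0:
            raise ValueError(f"bump_fraction must be in [0, 1], got {self.bump_fraction}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.grid_shape is None:
            # auto-size: shell diameter plus a 2-voxel margin per side
            self.grid_shape = tuple(
                int(np.ceil(2.0 * self.bump_outer_radius / s)) + 5 for s in self.spacing
            )


def expected_rim_widths(spec: ShellSpec) -> dict:
    """Closed-form ground truth of the two-mass rim-width distribution.

    The width is w2 = bump_outer_radius - inner_radius on the cap (solid-angle
    fraction f) and w1 = outer_radius_base - inner_radius elsewhere (fraction
    1 - f). Q4 is the maximum; Q3 is the 75th percentile of the two-mass law,
    so the predicted geometric heterogeneity is 0 when f >= 0.25 and
    1 - w1/w2 when f < 0.25.
    """
    w1 = spec.outer_radius_base - spec.inner_radius
    w2 = spec.bump_outer_radius - spec.inner_radius
    f = spec.bump_fraction if w2 > w1 else 0.0
    q4 = w2 if f > 0 else w1
    q3 = w1 if f < 0.25 else q4
    # delta_s of the exact (continuum) phantom: sphere-equivalent outer radius
    # from the solid-angle-weighted outer radii, minus the inner radius.
    r_eq = ((1 - f) * spec.outer_radius_base**3 + f * spec.bump_outer_radius**3) ** (1.0 / 3.0)
    return {
        "w1_mm": w1,
        "w2_mm": w2,
        "bump_fraction": f,
        "expected_gh": (q4 - q3) / q4,
        "expected_delta_s_mm": r_eq - spec.inner_radius,
    }


def make_shell_phantom(spec: ShellSpec) -> LabeledVolume:
    """Voxelize the bumped shell; membership decided at voxel centers.

    The bump is a spherical cap around +z with half-angle theta such that the
    solid-angle fraction f = (1 - cos theta) / 2 equals ``bump_fraction``.
    Ground-truth widths and fractions are attached to ``meta``.
    """
    shape = spec.grid_shape
    half_extent = [s * (n - 1) / 2.0 for n, s in zip(shape, spec.spacing)]
    margin = 2.0 * max(spec.spacing)
    if any(h < spec.bump_outer_radius + margin for h in half_extent):
        raise PhantomSizingError(
            f"grid {shape} at spacing {spec.spacing} cannot contain the shell "
            f"(outer radius {spec.bump_outer_radius} mm plus a 2-voxel margin)"
        )

    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spec.spacing)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)

    cos_cap = 1.0 - 2.0 * spec.bump_fraction  # cap: cos(theta) >= 1 - 2f
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.where(r > 0, z / np.where(r > 0, r, 1.0), 1.0)
    on_cap = cos_theta >= cos_cap if spec.bump_fraction > 0 else np.zeros_like(r, bool)
    outer_r = np.where(on_cap, spec.bump_outer_radius, spec.outer_radius_base)

    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    labels[r < spec.inner_radius] = INNER
    labels[(r >= spec.inner_radius) & (r < outer_r)] = CE
    if not (labels == INNER).any() or not (labels == CE).any():
        raise DegeneratePhantomError("a shell label received zero voxels")

    intensity = np.zeros(shape)
    intensity[labels == CE] = 120.0
    intensity[labels == INNER] = 30.0

    meta = expected_rim_widths(spec)
    meta["spec"] = {
        "inner_radius": spec.inner_radius,
        "outer_radius_base": spec.outer_radius_base,
        "bump_fraction": spec.bump_fraction,
        "bump_outer_radius": spec.bump_outer_radius,
        "spacing": list(spec.spacing),
        "grid_shape": list(shape),
    }
    return LabeledVolume(intensity=intensity, labels=labels, spacing=spec.spacing, meta=meta)


def make_texture_phantom(
    pattern: str,
    levels: tuple[float, float] = (10.0, 20.0),
    roi_shape: tuple[int, int, int] = (8, 8, 8),
) -> LabeledVolume:
    """A rectangular all-CE ROI with an analytically tractable texture.

    ``constant`` fills the ROI with ``levels[0]``; ``stripes`` alternates
    ``levels`` along axis 0 with period 2 (slab i carries levels[i % 2]).
    """
    if any(n < 1 for n in roi_shape):
        raise ValueError(f"roi_shape must be positive, got {roi_shape}")
    a, b = levels
    intensity = np.empty(roi_shape)
    if pattern == "constant":
        intensity[:] = a
    elif pattern == "stripes":
        stripe = np.where(np.arange(roi_shape[0]) % 2 == 0, a, b)
        intensity[:] = stripe[:, None, None]
    else:
        raise ValueError(f"unknown pattern {pattern!r} (use 'constant' or 'stripes')")
    labels = np.full(roi_shape, CE, dtype=np.uint8)
    return LabeledVolume(
        intensity=intensity,
        labels=labels,
        spacing=(1.0, 1.0, 1.0),
        meta={"pattern": pattern, "levels": [a, b]},
    )


# ---------------------------------------------------------------------------
# survival cohort simulation
# ---------------------------------------------------------------------------

_MARKER_SAMPLERS = {
    "normal": lambda rng, n, p: rng.normal(p.get("loc", 0.0), p.get("scale", 1.0), n),
    "lognormal": lambda rng, n, p: rng.lognormal(p.get("mean", 0.0), p.get("sigma", 1.0), n),
    "uniform": lambda rng, n, p: rng.uniform(p.get("low", 0.0), p.get("high", 1.0), n),
}


@dataclass
class CohortSimSpec:
    """Two-arm cohort with a marker-threshold hazard effect.

    Survival is exponential with hazard ``baseline_hazard`` (per day) for
    patients with marker <= ``split_threshold`` and ``baseline_hazard *
    hazard_ratio`` above it. Censoring, when requested, is independent
    Uniform(0, T_max) with T_max solved so the expected censored fraction
    matches ``censoring_rate``.
    """

    n_patients: int
    split_threshold: float
    hazard_ratio: float = 1.0
    baseline_hazard: float = 1.0 / 300.0
    arm_fraction: float = 0.5
    marker_distribution: tuple[str, dict] = ("normal", None)
    censoring_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazard_ratio and baseline_hazard must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must be in [0, 1)")
        name, params = self.marker_distribution
        if name not in _MARKER_SAMPLERS:
            raise ValueError(f"unknown marker distribution {name!r}")
        self.marker_distribution = (name, dict(params or {}))


def _censoring_tmax(hazards: np.ndarray, rate: float) -> float:
    """T_max of Uniform(0, T_max) censoring hitting the requested expected rate.

    For T ~ Exp(h) and C ~ U(0, c), P(C < T) = (1 - exp(-h c)) / (h c); the
    cohort-average rate is monotone in c, so solve by bracketing.
    """

    def mean_rate(c: float) -> float:
        hc = hazards * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1.0 / hazards.min()
    while mean_rate(hi) > rate:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda c: mean_rate(c) - rate, lo, hi)


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw one cohort; reproducible under ``spec.seed``.

    Returns a table with columns patient_id, arm, os_days, event, marker.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    name, params = spec.marker_distribution
    marker = _MARKER_SAMPLERS[name](rng, n, params)

    high = marker > spec.split_threshold
    if high.all() or (~high).all():
        warnings.warn(
            "degenerate split: all simulated patients fall on one side of "
            f"split_threshold={spec.split_threshold}",
            stacklevel=2,
        )
    hazards = spec.baseline_hazard * np.where(high, spec.hazard_ratio, 1.0)
    t_death = rng.exponential(1.0 / hazards)

    if spec.censoring_rate > 0:
        tmax = _censoring_tmax(hazards, spec.censoring_rate)
        t_cens = rng.uniform(0.0, tmax, n)
        os_days = np.minimum(t_death, t_cens)
        event = t_death <= t_cens
    else:
        os_days, event = t_death, np.ones(n, dtype=bool)

    n_bvz = int(round(spec.arm_fraction * n))
    arm = np.where(np.arange(n) < n_bvz, "BVZ+", "BVZ-")
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "arm": arm,
            "os_days": os_days,
            "event": event.astype(int),
            "marker": marker,
        }
    )


def cohort_to_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)
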