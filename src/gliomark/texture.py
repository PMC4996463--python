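"""3D gray-level co-occurrence and run-length texture measures.

Sixteen heterogeneity measures over the tumor region of interest: five from
the co-occurrence matrix (entropy, homogeneity, contrast, dissimilarity,
uniformity — local heterogeneity) and eleven from the run-length matrix (the
Galloway family: LRE, SRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU,
RLNU, RPC — regional heterogeneity).

Conventions: intensities are min-max quantized within the ROI into N equal
width gray classes (default N=32); pair and run statistics are pooled over
the 13 unique 3D directions at Chebyshev distance 1; the co-occurrence matrix
is symmetric (both orderings counted) and normalized to unit mass; runs are
maximal same-class segments broken by the ROI boundary; entropy uses the
natural logarithm. Run percentage is the classical ratio of the number of
runs to the total voxel-direction count, nr / sum_ij RLM(i,j) * j, which
lies in (0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import LabeledVolume

#: The 13 unique 3D offsets at Chebyshev distance 1 (first nonzero positive).
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

CM_FEATURE_NAMES = ("entropy", "homogeneity", "contrast", "dissimilarity", "uniformity")
RLM_FEATURE_NAMES = (
    "lre", "sre", "lgre", "hgre", "srlge", "srhge", "lrlge", "lrhge",
    "glnu", "rlnu", "rpc",
)


@dataclass
class QuantizedROI:
    """ROI voxels carrying gray classes 1..n_levels (0 outside the ROI)."""

    levels: np.ndarray
    n_levels: int
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        inside = self.levels[self.roi_mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-ROI levels must lie in 1..n_levels")


@dataclass
class TextureMatrices:
    """Co-occurrence and run-length matrices plus run bookkeeping."""

    cm: np.ndarray | None = None       # N x N, probabilities summing to 1
    rlm: np.ndarray | None = None      # N x M, run counts
    nr: int = 0                        # total number of runs
    max_run: int = 0                   # M, longest run observed


def quantize(vol: LabeledVolume, n_levels: int = 32, roi: str = "tumor") -> QuantizedROI:
    """Uniform min-max quantization of in-ROI intensities into n_levels classes.

    ``roi`` selects the region: 'tumor' (CE + inner, the default) or 'ce'.
    The ROI maximum maps to class n_levels; a constant ROI collapses to a
    single class 1 (features then take their trivial values).
    """
    mask = vol.tumor_mask if roi == "tumor" else vol.ce_mask
    if roi not in ("tumor", "ce"):
        raise ValueError(f"unknown roi mode {roi!r}")
    if not mask.any():
        raise ValueError("empty ROI")
    vals = vol.intensity[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(vol.intensity.shape, dtype=np.int32)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = (vol.intensity[mask] - lo) / (hi - lo) * n_levels
        levels[mask] = np.minimum(np.floor(scaled).astype(np.int32) + 1, n_levels)
    return QuantizedROI(levels=levels, n_levels=n_levels, roi_mask=mask)


def cooccurrence_matrix(q: QuantizedROI, offsets=OFFSETS_3D) -> np.ndarray:
    """Symmetric, unit-mass co-occurrence matrix pooled over ``offsets``.

    Only pairs with both voxels inside the ROI are counted; each unordered
    neighbor pair contributes to CM(a, b) and CM(b, a).
    """
    n = q.n_levels
    counts = np.zeros((n, n), dtype=np.int64)
    lev, roi = q.levels, q.roi_mask
    shape = lev.shape
    for off in offsets:
        src = tuple(
            slice(max(0, -d), min(s, s - d)) for d, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, d), min(s, s + d)) for d, s in zip(off, shape)
        )
        valid = roi[src] & roi[dst]
        a = lev[src][valid] - 1
        b = lev[dst][valid] - 1
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-ROI voxel pairs for any offset")
    return counts / total


def cm_features(cm: np.ndarray) -> dict[str, float]:
    """Entropy, homogeneity, contrast, dissimilarity, uniformity of a CM."""
    cm = np.asarray(cm, dtype=float)
    n = cm.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    diff = i - j
    nz = cm > 0
    return {
        "entropy": float(-(cm[nz] * np.log(cm[nz])).sum() + 0.0),  # avoid -0.0
        "homogeneity": float((cm / (1.0 + diff**2)).sum()),
        "contrast": float((cm * diff**2).sum()),
        "dissimilarity": float((cm * np.abs(diff)).sum()),
        "uniformity": float((cm**2).sum()),
    }


def _line_keys(idx: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Integer invariants identifying the lattice line through each voxel.

    The cross-product-style pairs (i*dy - j*dx, i*dz - k*dx, j*dz - k*dy) are
    constant along a line of direction (dx, dy, dz) and differ across lines.
    """
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    dx, dy, dz = direction
    return np.stack([i * dy - j * dx, i * dz - k * dx, j * dz - k * dy], axis=1)


def run_length_matrix(q: QuantizedROI, directions=OFFSETS_3D) -> TextureMatrices:
    """Run-length matrix pooled over the 13 3D directions.

    A run is a maximal sequence of collinear in-ROI voxels of equal gray
    class; voxels outside the ROI break runs. Returns the (N x M) count
    matrix, the total run count nr, and M.
    """
    idx = np.argwhere(q.roi_mask)
    if idx.size == 0:
        raise ValueError("empty ROI")
    lev_flat = q.levels[q.roi_mask]
    run_records: list[tuple[np.ndarray, np.ndarray]] = []
    max_run = 1
    for off in directions:
        d = np.asarray(off)
        t = idx @ d  # strictly increasing by |d|^2 along the line
        keys = _line_keys(idx, d)
        order = np.lexsort((t, keys[:, 2], keys[:, 1], keys[:, 0]))
        t_s, keys_s, lev_s = t[order], keys[order], lev_flat[order]
        same_line = (np.diff(keys_s, axis=0) == 0).all(axis=1)
        contiguous = np.diff(t_s) == int(d @ d)
        same_level = np.diff(lev_s) == 0
        # a new run starts wherever continuity breaks
        new_run = np.ones(len(t_s), dtype=bool)
        new_run[1:] = ~(same_line & contiguous & same_level)
        starts = np.flatnonzero(new_run)
        lengths = np.diff(np.append(starts, len(t_s)))
        run_records.append((lev_s[starts], lengths))
        max_run = max(max_run, int(lengths.max()))
    rlm = np.zeros((q.n_levels, max_run), dtype=np.int64)
    for levels_r, lengths_r in run_records:
        np.add.at(rlm, (levels_r - 1, lengths_r - 1), 1)
    return TextureMatrices(rlm=rlm, nr=int(rlm.sum()), max_run=max_run)


def rlm_features(m: TextureMatrices) -> dict[str, float]:
    """The eleven run-length measures of the Galloway family."""
    rlm = np.asarray(m.rlm, dtype=float)
    nr = float(m.nr)
    if nr <= 0:
        raise ValueError("nr must be positive")
    n, mx = rlm.shape
    i = np.arange(1, n + 1)[:, None].astype(float)   # gray level
    j = np.arange(1, mx + 1)[None, :].astype(float)  # run length
    total_voxel_runs = float((rlm * j).sum())
    return {
        "lre": float((rlm * j**2).sum() / nr),
        "sre": float((rlm / j**2).sum() / nr),
        "lgre": float((rlm / i**2).sum() / nr),
        "hgre": float((rlm * i**2).sum() / nr),
        "srlge": float((rlm / (i**2 * j**2)).sum() / nr),
        "srhge": float((rlm * i**2 / j**2).sum() / nr),
        "lrlge": float((rlm * j**2 / i**2).sum() / nr),
        "lrhge": float((rlm * i**2 * j**2).sum() / nr),
        "glnu": float((rlm.sum(axis=1) ** 2).sum() / nr),
        "rlnu": float((rlm.sum(axis=0) ** 2).sum() / nr),
        "rpc": float(nr / total_voxel_runs),
    }


def texture_features(
    vol: LabeledVolume, n_levels: int = 32, roi: str = "tumor"
) -> dict[str, float]:
    """All 16 texture measures of one tumor, as a flat name -> value dict."""
    q = quantize(vol, n_levels=n_levels, roi=roi)
    cm = cooccurrence_matrix(q)
    out = cm_features(cm)
    out.update(rlm_features(run_length_matrix(q)))
    return out
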