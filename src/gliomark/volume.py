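"""Labeled 3D tumor volumes and NIfTI-1 input/output.

A :class:`LabeledVolume` holds a postcontrast T1 intensity grid together with a
3-label segmentation mask — background (0), contrast-enhancing rim (1), inner
(necrotic) core (2) — and the voxel spacing in millimetres. It is the common
input type for the rim-geometry and texture modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Label codes used throughout the package.
BACKGROUND = 0
CE = 1
INNER = 2


class VolumeError(ValueError):
    """Invalid labeled volume (shape/spacing/label problems)."""


@dataclass
class LabeledVolume:
    """3D intensity grid + 3-label mask + voxel spacing in mm.

    Parameters
    ----------
    intensity : ndarray
        3D scalar intensity grid, arbitrary units.
    labels : ndarray
        Integer grid of the same shape over {0: background, 1: CE rim,
        2: inner core}.
    spacing : tuple of float
        Voxel edge lengths in mm per axis; slice thickness is simply the
        third spacing component.
    meta : dict
        Free-form metadata (phantom ground truth, provenance).
    """

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.labels = np.asarray(self.labels)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.intensity.ndim != 3:
            raise VolumeError(f"intensity must be 3D, got ndim={self.intensity.ndim}")
        if self.intensity.shape != self.labels.shape:
            raise VolumeError(
                f"intensity shape {self.intensity.shape} != labels shape {self.labels.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeError(f"spacing must be 3 positive values, got {self.spacing}")
        bad = set(np.unique(self.labels)) - {BACKGROUND, CE, INNER}
        if bad:
            raise VolumeError(f"unexpected label values {sorted(bad)}")

    # -- masks -----------------------------------------------------------

    @property
    def ce_mask(self) -> np.ndarray:
        return self.labels == CE

    @property
    def inner_mask(self) -> np.ndarray:
        return self.labels == INNER

    @property
    def tumor_mask(self) -> np.ndarray:
        """CE rim plus inner core."""
        return self.labels != BACKGROUND

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    # -- I/O -------------------------------------------------------------

    def save(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>_img.nii`` + ``<prefix>_lab.nii`` (and a JSON
        sidecar ``<prefix>_meta.json`` when metadata is present)."""
        prefix = Path(prefix)
        affine = np.diag([*self.spacing, 1.0])
        img_path = prefix.with_name(prefix.name + "_img.nii")
        lab_path = prefix.with_name(prefix.name + "_lab.nii")
        nib.save(nib.Nifti1Image(self.intensity.astype(np.float32), affine), img_path)
        nib.save(nib.Nifti1Image(self.labels.astype(np.uint8), affine), lab_path)
        if self.meta:
            sidecar = prefix.with_name(prefix.name + "_meta.json")
            sidecar.write_text(json.dumps(self.meta, indent=2, default=float))
        return img_path, lab_path

    @classmethod
    def load(cls, image_path: str | Path, labels_path: str | Path) -> "LabeledVolume":
        """Read an intensity/labels NIfTI-1 pair; spacing from the header."""
        img = nib.load(str(image_path))
        lab = nib.load(str(labels_path))
        intensity = np.asarray(img.dataobj, dtype=float)
        labels = np.asarray(lab.dataobj).astype(np.uint8)
        if intensity.shape != labels.shape:
            raise VolumeError(
                f"{image_path} shape {intensity.shape} != {labels_path} shape {labels.shape}"
            )
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(intensity=intensity, labels=labels, spacing=spacing)
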