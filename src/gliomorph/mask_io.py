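"""Reading, writing and validating 3D binary segmentation masks.

Masks live on regular voxel grids with per-axis physical spacing in mm.
Any nonzero voxel value is treated as foreground, so label maps with
arbitrary integer labels binarize cleanly.  Orientation and handedness of
the source affine are deliberately ignored: every downstream quantity
(volume, area, sphericity) is intrinsic to the solid, not to its pose.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "MaskRole",
    "Connectivity",
    "SegmentationMask",
    "ComponentReport",
    "MaskFormatError",
    "read_mask",
    "write_mask",
    "connected_components",
    "validate_unifocal",
]


class MaskRole(str, enum.Enum):
    """What a mask represents in the pipeline."""

    TUMOR_PRE = "tumor_pre"
    TUMOR_POST = "tumor_post"
    BRAIN = "brain"


class Connectivity(str, enum.Enum):
    """Voxel adjacency rule for component labelling.

    ``FACE`` is the 6-neighbourhood; ``FACE_EDGE_VERTEX`` the full
    26-neighbourhood (diagonal contact keeps a tumor connected).
    """

    FACE = "face"
    FACE_EDGE_VERTEX = "face-edge-vertex"


class MaskFormatError(ValueError):
    """Raised when a volume on disk cannot be interpreted as a mask."""


@dataclass
class SegmentationMask:
    """Binary voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        3D uint8 array of {0, 1}.
    spacing
        mm per voxel along each array axis, all strictly positive.
    origin_offset
        Physical offset of voxel (0,0,0) in mm; informational only.
    role
        What the mask segments.
    """

    voxels: np.ndarray
    spacing: np.ndarray
    origin_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    role: MaskRole = MaskRole.TUMOR_PRE

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MaskFormatError(
                f"voxels: expected a 3D array, got {self.voxels.ndim}D"
            )
        uniq = np.unique(self.voxels)
        if not np.isin(uniq, [0, 1]).all():
            raise MaskFormatError(
                f"voxels: mask must be binary, found values {uniq[:10]}"
            )
        self.voxels = self.voxels.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.spacing.shape != (3,):
            raise MaskFormatError("spacing: expected 3 components")
        if not np.isfinite(self.spacing).all() or (self.spacing <= 0).any():
            raise MaskFormatError(
                f"spacing: components must be finite and > 0, got {self.spacing}"
            )
        self.origin_offset = np.asarray(self.origin_offset, dtype=float)
        self.role = MaskRole(self.role)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def is_empty(self) -> bool:
        return self.foreground_count == 0


@dataclass(frozen=True)
class ComponentReport:
    """Connected-component summary used for the multifocality rule."""

    n_components: int
    component_sizes: tuple
    unifocal: bool
    exclude: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        assert self.unifocal == (self.n_components == 1)


def _binarize(data: np.ndarray) -> np.ndarray:
    out = np.zeros(data.shape, dtype=np.uint8)
    out[np.nan_to_num(data, nan=0.0) != 0] = 1
    return out


def read_mask(path, role: MaskRole | str = MaskRole.TUMOR_PRE) -> SegmentationMask:
    """Load a NIfTI volume as a binary mask.

    Spacing is taken from the norms of the affine's spatial columns; any
    nonzero voxel value maps to foreground.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    MaskFormatError
        If the volume is not 3D or its spacing is non-finite or zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise MaskFormatError(
            f"{path.name}: expected a 3D volume, got shape {data.shape}"
        )
    affine = img.affine
    if affine is None or not np.isfinite(affine).all():
        raise MaskFormatError(f"{path.name}: affine is missing or non-finite")
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if (spacing <= 0).any() or not np.isfinite(spacing).all():
        raise MaskFormatError(
            f"{path.name}: spacing derived from affine is invalid: {spacing}"
        )
    mask = SegmentationMask(
        voxels=_binarize(data),
        spacing=spacing,
        origin_offset=affine[:3, 3].copy(),
        role=MaskRole(role),
    )
    logger.info(
        "read %s: shape=%s spacing=%s foreground=%d",
        path.name, mask.shape, np.round(mask.spacing, 4), mask.foreground_count,
    )
    return mask


def write_mask(mask: SegmentationMask, path) -> Path:
    """Write a mask to NIfTI so that :func:`read_mask` round-trips exactly."""
    path = Path(path)
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin_offset
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))
    return path


_STRUCTS = {
    Connectivity.FACE: ndimage.generate_binary_structure(3, 1),
    Connectivity.FACE_EDGE_VERTEX: ndimage.generate_binary_structure(3, 3),
}


def connected_components(
    mask: SegmentationMask,
    connectivity: Connectivity | str = Connectivity.FACE_EDGE_VERTEX,
) -> ComponentReport:
    """Label foreground components under the chosen adjacency.

    An empty mask yields ``n_components == 0`` and ``unifocal == False``.
    """
    connectivity = Connectivity(connectivity)
    labels, n = ndimage.label(mask.voxels, structure=_STRUCTS[connectivity])
    if n == 0:
        return ComponentReport(0, (), unifocal=False)
    sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1]
    return ComponentReport(int(n), tuple(int(s) for s in sizes), unifocal=(n == 1))


def validate_unifocal(
    mask: SegmentationMask,
    connectivity: Connectivity | str = Connectivity.FACE_EDGE_VERTEX,
) -> ComponentReport:
    """Apply the inclusion rule: multifocal or empty masks are flagged.

    Returns the component report with an ``exclude`` flag instead of
    raising, so a pipeline can drop the case and log the reason.
    """
    report = connected_components(mask, connectivity)
    if report.n_components == 0:
        return ComponentReport(0, (), unifocal=False, exclude=True, reason="empty")
    if not report.unifocal:
        return ComponentReport(
            report.n_components,
            report.component_sizes,
            unifocal=False,
            exclude=True,
            reason=f"multifocal ({report.n_components} components)",
        )
    return report


def exclusion_log_rows(case_id: str, report: ComponentReport) -> list[dict]:
    """Rows for the pipeline's exclusion CSV (case_id, reason, n_components)."""
    if not report.exclude:
        return []
    return [
        {
            "case_id": case_id,
            "reason": report.reason,
            "n_components": report.n_components,
        }
    ]
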