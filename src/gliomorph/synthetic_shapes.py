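"""Digitized 3D solids with known geometry, used as stand-ins for tumors.

Every generator rasterizes an analytic solid onto a voxel grid (a voxel is
foreground iff its center lies inside the solid) and, where closed forms
exist, returns the exact volume and surface area alongside the mask.  The
bumpy ball perturbs a sphere's radius with seeded low-order angular
harmonics, giving star-shaped, unifocal solids with tunable irregularity.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import sph_harm_y

from .mask_io import MaskRole, SegmentationMask

__all__ = [
    "ShapeKind",
    "ShapeSpec",
    "AnalyticReference",
    "ShapeGenerationError",
    "generate_shape",
    "generate_brain_context",
    "clip_to_brain",
    "ellipsoid_area_thomsen",
]

MARGIN_VOXELS = 3  # background border so meshes close


class ShapeKind(str, enum.Enum):
    BALL = "ball"
    CUBE = "cube"
    ELLIPSOID = "ellipsoid"
    BUMPY_BALL = "bumpy_ball"
    TRUNCATED_BALL = "truncated_ball"


class ShapeGenerationError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one synthetic solid.

    ``size_params`` is kind-specific, in mm: ball/bumpy_ball/truncated_ball
    use ``(radius,)``; cube ``(side,)``; ellipsoid ``(a, b, c)`` semi-axes.
    ``truncation_offset`` is the signed plane offset from the center along
    the last axis (the kept half-space is ``z <= offset``).
    """

    kind: ShapeKind
    size_params: tuple
    spacing: tuple = (1.0, 1.0, 1.0)
    bump_amplitude: float = 0.0
    bump_degree: int = 0
    truncation_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ShapeKind(self.kind))
        object.__setattr__(
            self, "size_params", tuple(float(s) for s in np.atleast_1d(self.size_params))
        )
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(s <= 0 for s in self.size_params):
            raise ShapeGenerationError("size_params must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ShapeGenerationError("spacing must be positive")
        if not 0 <= self.bump_amplitude < 1:
            raise ShapeGenerationError("bump_amplitude must be in [0, 1)")
        if self.bump_degree < 0:
            raise ShapeGenerationError("bump_degree must be >= 0")


@dataclass(frozen=True)
class AnalyticReference:
    """Closed-form geometry of the generated solid, where available."""

    volume_ml: Optional[float] = None
    area_cm2: Optional[float] = None
    contact_area_cm2: Optional[float] = None
    exact: bool = True


def ellipsoid_area_thomsen(a: float, b: float, c: float, p: float = 1.6075) -> float:
    """Thomsen's approximation to the ellipsoid surface area (mm^2).

    Relative error below ~1.1% for all axis ratios.
    """
    term = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * term ** (1.0 / p)


def _bump_field(theta: np.ndarray, phi: np.ndarray, degree: int, seed: int) -> np.ndarray:
    """Smooth angular perturbation in [-1, 1] from seeded harmonics.

    Uses all real spherical harmonics of order ``degree`` with coefficients
    drawn from a seeded normal, normalized to unit peak so the amplitude
    parameter directly bounds the radial excursion.
    """
    if degree == 0:
        return np.zeros_like(theta)
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(2 * degree + 1)
    out = np.zeros_like(theta, dtype=float)
    for i, m in enumerate(range(-degree, degree + 1)):
        y = sph_harm_y(degree, abs(m), theta, phi)
        out += coeffs[i] * (y.imag if m < 0 else y.real)
    peak = np.abs(out).max()
    if peak > 0:
        out /= peak
    return out


def _inside(spec: ShapeSpec, pts: np.ndarray) -> np.ndarray:
    """Membership test for points (n, 3) in mm, solid centered at origin."""
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    if spec.kind is ShapeKind.BALL:
        (r,) = spec.size_params
        return x * x + y * y + z * z <= r * r
    if spec.kind is ShapeKind.CUBE:
        (side,) = spec.size_params
        h = side / 2.0
        return (np.abs(x) <= h) & (np.abs(y) <= h) & (np.abs(z) <= h)
    if spec.kind is ShapeKind.ELLIPSOID:
        a, b, c = spec.size_params
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if spec.kind is ShapeKind.TRUNCATED_BALL:
        (r,) = spec.size_params
        return (x * x + y * y + z * z <= r * r) & (z <= spec.truncation_offset)
    if spec.kind is ShapeKind.BUMPY_BALL:
        (r,) = spec.size_params
        rho = np.sqrt(x * x + y * y + z * z)
        cos_theta = np.divide(z, rho, out=np.zeros_like(rho), where=rho > 0)
        theta = np.arccos(np.clip(cos_theta, -1, 1))
        phi = np.arctan2(y, x)
        radius = r * (
            1.0
            + spec.bump_amplitude
            * _bump_field(theta, phi, spec.bump_degree, spec.seed)
        )
        return rho <= radius
    raise ShapeGenerationError(f"unknown kind {spec.kind}")


def _reference(spec: ShapeSpec) -> AnalyticReference:
    if spec.kind is ShapeKind.BALL or (
        spec.kind is ShapeKind.BUMPY_BALL and spec.bump_amplitude == 0
    ):
        (r,) = spec.size_params
        return AnalyticReference(
            volume_ml=4.0 / 3.0 * math.pi * r**3 / 1000.0,
            area_cm2=4.0 * math.pi * r**2 / 100.0,
        )
    if spec.kind is ShapeKind.CUBE:
        (side,) = spec.size_params
        return AnalyticReference(
            volume_ml=side**3 / 1000.0, area_cm2=6.0 * side**2 / 100.0
        )
    if spec.kind is ShapeKind.ELLIPSOID:
        a, b, c = spec.size_params
        return AnalyticReference(
            volume_ml=4.0 / 3.0 * math.pi * a * b * c / 1000.0,
            area_cm2=ellipsoid_area_thomsen(a, b, c) / 100.0,
            exact=False,  # area is Thomsen's approximation
        )
    if spec.kind is ShapeKind.TRUNCATED_BALL:
        (r,) = spec.size_params
        d = spec.truncation_offset
        if not -r < d < r:
            return AnalyticReference()
        # kept piece: z <= d.  Removed cap height h = r - d.
        h = r - d
        cap_curved = 2.0 * math.pi * r * h  # removed curved area
        disc = math.pi * (r * r - d * d)
        volume = (4.0 / 3.0) * math.pi * r**3 - math.pi * h * h * (r - h / 3.0)
        return AnalyticReference(
            volume_ml=volume / 1000.0,
            area_cm2=(4.0 * math.pi * r**2 - cap_curved + disc) / 100.0,
            contact_area_cm2=disc / 100.0,
        )
    return AnalyticReference()


def _extent_mm(spec: ShapeSpec) -> float:
    """Half-extent of the solid's bounding cube, mm."""
    if spec.kind is ShapeKind.CUBE:
        return spec.size_params[0] / 2.0
    if spec.kind is ShapeKind.ELLIPSOID:
        return max(spec.size_params)
    r = spec.size_params[0]
    if spec.kind is ShapeKind.BUMPY_BALL:
        return r * (1.0 + spec.bump_amplitude)
    return r


def generate_shape(
    spec: ShapeSpec,
) -> tuple[SegmentationMask, AnalyticReference]:
    """Rasterize the solid onto an auto-sized grid with background margin.

    Deterministic given the spec (including its seed).  The grid is sized
    from the solid's extent so shapes are never clipped; generation fails
    if the result is empty.
    """
    half = _extent_mm(spec)
    spacing = np.array(spec.spacing)
    n_half = np.ceil(half / spacing + 0.5).astype(int) + MARGIN_VOXELS
    shape = 2 * n_half
    idx = [np.arange(s) for s in shape]
    grid = np.stack(np.meshgrid(*idx, indexing="ij"), axis=-1).reshape(-1, 3)
    # voxel centers at half-integer multiples of the spacing, solid centered
    # at 0: flat axis-aligned boundaries then fall midway between voxel
    # centers, so e.g. a 20 mm cube at 0.5 mm spacing is exactly 40^3 voxels
    pts = (grid - n_half + 0.5) * spacing
    voxels = _inside(spec, pts).reshape(tuple(shape))
    if not voxels.any():
        raise ShapeGenerationError(f"spec produced an empty mask: {spec}")
    if (
        voxels[0].any() or voxels[-1].any() or voxels[:, 0].any()
        or voxels[:, -1].any() or voxels[..., 0].any() or voxels[..., -1].any()
    ):
        raise ShapeGenerationError(f"solid clipped at grid edge: {spec}")
    mask = SegmentationMask(
        voxels=voxels.astype(np.uint8),
        spacing=spacing,
        origin_offset=-n_half * spacing,
        role=MaskRole.TUMOR_PRE,
    )
    return mask, _reference(spec)


class ContactKind(str, enum.Enum):
    NONE = "none"
    PLANAR = "planar"


def generate_brain_context(
    tumor: SegmentationMask,
    contact: ContactKind | str = ContactKind.NONE,
    offset_mm: float = 0.0,
    clearance_mm: float = 10.0,
) -> tuple[SegmentationMask, SegmentationMask]:
    """Brain mask plus the tumor re-gridded to share it.

    Returns ``(brain, tumor)`` on a common grid.  For ``planar`` contact
    the brain occupies the half-space ``z <= centroid_z + offset_mm`` and
    the tumor is clipped to it, so the flat cut of the tumor abuts the
    brain boundary (cutting a ball through its center yields the
    hemisphere fixture).  For ``none`` the grid is padded so the brain
    boundary stays at least ``clearance_mm`` from every tumor voxel.
    """
    contact = ContactKind(contact)
    voxels = tumor.voxels
    spacing = tumor.spacing
    if contact is ContactKind.NONE:
        pad = tuple(int(np.ceil(clearance_mm / s)) + 1 for s in spacing)
        voxels = np.pad(voxels, [(p, p) for p in pad])
    shape = voxels.shape
    brain = np.ones(shape, dtype=np.uint8)
    # one-voxel background border keeps the brain's own surface closed
    for axis in range(3):
        sl = [slice(None)] * 3
        for edge in (0, -1):
            sl[axis] = edge
            brain[tuple(sl)] = 0
    if contact is ContactKind.PLANAR:
        fg = np.argwhere(voxels)
        centroid_z = fg[:, 2].mean() * spacing[2]
        plane_z = centroid_z + offset_mm
        z_mm = np.arange(shape[2]) * spacing[2]
        brain[:, :, z_mm > plane_z + 1e-9] = 0
        voxels = (voxels & brain).astype(np.uint8)
        if not voxels.any():
            raise ShapeGenerationError(
                "contact plane places the whole tumor outside the brain"
            )
    brain_mask = SegmentationMask(
        voxels=brain,
        spacing=spacing.copy(),
        origin_offset=tumor.origin_offset.copy(),
        role=MaskRole.BRAIN,
    )
    tumor_out = dataclasses.replace(tumor, voxels=voxels)
    return brain_mask, tumor_out


def clip_to_brain(tumor: SegmentationMask, brain: SegmentationMask) -> SegmentationMask:
    """Intersect a tumor mask with the brain (tumor cannot extend outside)."""
    if tumor.voxels.shape != brain.voxels.shape:
        raise ShapeGenerationError("clip_to_brain: grids differ")
    return dataclasses.replace(
        tumor, voxels=(tumor.voxels & brain.voxels).astype(np.uint8)
    )


def spec_to_dict(spec: ShapeSpec, ref: AnalyticReference) -> dict:
    """JSON-ready sidecar describing a generated shape."""
    return {
        "kind": spec.kind.value,
        "size_params": list(spec.size_params),
        "spacing": list(spec.spacing),
        "bump_amplitude": spec.bump_amplitude,
        "bump_degree": spec.bump_degree,
        "truncation_offset": spec.truncation_offset,
        "seed": spec.seed,
        "reference": dataclasses.asdict(ref),
    }
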