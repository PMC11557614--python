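"""Shared fixtures: expensive digitized shapes are built once per session."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gliomorph.mask_io import SegmentationMask
from gliomorph.morphometry import compute_tsa, compute_volume, extract_mesh
from gliomorph.synthetic_shapes import (
    ShapeSpec,
    generate_brain_context,
    generate_shape,
)

BALL_RADIUS_MM = 20.0
BALL_VOLUME_ML = 4.0 / 3.0 * math.pi * BALL_RADIUS_MM**3 / 1000.0  # 33.510
BALL_AREA_CM2 = 4.0 * math.pi * BALL_RADIUS_MM**2 / 100.0  # 50.265


@pytest.fixture(scope="session")
def ball_mask():
    mask, ref = generate_shape(ShapeSpec(kind="ball", size_params=(BALL_RADIUS_MM,)))
    return mask, ref


@pytest.fixture(scope="session")
def ball_mesh(ball_mask):
    mask, _ = ball_mask
    return extract_mesh(mask)


@pytest.fixture(scope="session")
def ball_measures(ball_mask, ball_mesh):
    mask, _ = ball_mask
    return {"volume_ml": compute_volume(mask), "tsa_cm2": compute_tsa(ball_mesh)}


@pytest.fixture(scope="session")
def cube_mask():
    mask, ref = generate_shape(
        ShapeSpec(kind="cube", size_params=(20.0,), spacing=(0.5, 0.5, 0.5))
    )
    return mask, ref


@pytest.fixture(scope="session")
def hemisphere_context():
    """Ball of radius 20 clipped by a brain plane through its center."""
    ball, _ = generate_shape(ShapeSpec(kind="ball", size_params=(BALL_RADIUS_MM,)))
    brain, hemi = generate_brain_context(ball, contact="planar", offset_mm=0.0)
    return brain, hemi


@pytest.fixture()
def single_voxel_mask():
    voxels = np.zeros((5, 5, 5), dtype=np.uint8)
    voxels[2, 2, 2] = 1
    return SegmentationMask(voxels=voxels, spacing=(1.0, 1.0, 1.0))


@pytest.fixture()
def bifocal_mask():
    voxels = np.zeros((12, 12, 12), dtype=np.uint8)
    voxels[2:5, 2:5, 2:5] = 1
    voxels[8:11, 8:11, 8:11] = 1
    return SegmentationMask(voxels=voxels, spacing=(1.0, 1.0, 1.0))
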