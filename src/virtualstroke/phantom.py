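"""Ellipsoidal digital head phantom.

The phantom stands in for a registered anatomical template: an ellipsoidal
"brain" with two internal ventricle-like CSF compartments, a planar
midsagittal midline splitting the brain into hemispheres, and a small
mirrored region atlas (four quadrant regions per hemisphere).  Statistics
downstream do not depend on realistic anatomy, so no template registration
is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _seeds

LEFT = 1
RIGHT = 2

__all__ = ["PhantomAnatomy", "generate_phantom", "LEFT", "RIGHT"]


@dataclass(frozen=True)
class PhantomAnatomy:
    """Binary/label fields describing the synthetic head.

    All fields share one grid shape and voxel spacing (mm per axis).
    ``brain_mask`` and ``csf_mask`` are disjoint; ``hemisphere_labels``
    partitions ``brain_mask`` into LEFT (1) and RIGHT (2) across the
    midsagittal plane (first axis); ``region_atlas`` assigns each brain
    voxel one of four quadrant regions per hemisphere (mirror symmetric).
    """

    brain_mask: np.ndarray
    csf_mask: np.ndarray
    hemisphere_labels: np.ndarray
    region_atlas: np.ndarray
    spacing: tuple[float, float, float]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (mm) of voxel centres, midline at x=0."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * s
            for n, s in zip(self.shape, self.spacing)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def hemisphere_mask(self, side: int) -> np.ndarray:
        return self.hemisphere_labels == side


def generate_phantom(
    shape: tuple[int, int, int] = (48, 48, 24),
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0),
    seed: int = 0,
) -> PhantomAnatomy:
    """Build the deterministic ellipsoidal phantom.

    Parameters
    ----------
    shape
        Grid size per axis; each axis must be >= 16 and the first axis must
        be even so the midsagittal plane falls between voxel columns.
    spacing
        Voxel spacing in mm per axis (> 0).
    seed
        Jitters the brain semi-axes by a few percent (per-subject anatomy
        variability); the phantom is a pure function of (shape, spacing, seed).
    """
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    if len(shape) != 3 or len(spacing) != 3:
        raise ValueError("shape and spacing must be 3-vectors")
    if any(n < 16 for n in shape):
        raise ValueError(f"shape {shape} too small: need >= 16 voxels per axis")
    if shape[0] % 2 != 0:
        raise ValueError("first-axis dimension must be even (midline between voxels)")
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")

    rng = _seeds.rng_for(seed, _seeds.PHANTOM)
    # symmetric per-axis scale jitter keeps left/right mirror symmetry exact
    scale = rng.uniform(0.95, 1.05, size=3)

    half_fov = np.array([n * s / 2.0 for n, s in zip(shape, spacing)])
    semi = 0.82 * half_fov * scale

    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    head = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2 <= 1.0

    # two mirrored ventricle-like CSF compartments
    csf_semi = np.array([0.18, 0.30, 0.28]) * semi
    cx = 0.22 * semi[0]
    csf = np.zeros(shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        csf |= (
            ((x - sgn * cx) / csf_semi[0]) ** 2
            + (y / csf_semi[1]) ** 2
            + (z / csf_semi[2]) ** 2
        ) <= 1.0
    csf &= head

    brain = head & ~csf
    if not brain.any() or not csf.any():
        raise ValueError("grid too small to contain brain and CSF compartments")

    hemis = np.zeros(shape, dtype=np.int8)
    hemis[(x < 0) & brain] = LEFT
    hemis[(x > 0) & brain] = RIGHT

    # quadrant atlas: same label at mirrored positions in both hemispheres
    atlas = np.zeros(shape, dtype=np.int16)
    atlas[brain] = (1 + 2 * (y[brain] >= 0) + (z[brain] >= 0)).astype(np.int16)

    return PhantomAnatomy(
        brain_mask=brain,
        csf_mask=csf,
        hemisphere_labels=hemis,
        region_atlas=atlas,
        spacing=spacing,
    )
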