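"""Mask morphology: metric dilation, perilesional rim, mirroring, block
downsampling and lesion-overlap maps.

The perilesional rim is the gray-matter shell within a fixed Euclidean
distance (default 10 mm) of the lesion border, excluding the lesion itself;
its reflection across the mid-sagittal plane serves as a within-subject
control ROI with exactly the same voxel count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .geometry import LR_AXIS, BinaryMask, VolumeGeometry, VolumeMap

__all__ = [
    "RimParams",
    "dilate",
    "perilesional_rim",
    "mirror",
    "downsample_mask",
    "overlap_map",
]


@dataclass(frozen=True)
class RimParams:
    """Parameters of rim construction.

    dilation_radius_mm : metric dilation of the lesion mask (10 mm).
    gm_mask : gray-matter segmentation restricting the rim to cortex.
    downsample_factors : per-axis block factors to the functional grid
        (``(1, 1, 1)`` keeps the anatomical grid).
    downsample_rule : "any" (default) or "majority".
    """

    dilation_radius_mm: float = 10.0
    gm_mask: BinaryMask = None  # type: ignore[assignment]
    downsample_factors: tuple[int, int, int] = (1, 1, 1)
    downsample_rule: str = "any"

    def __post_init__(self) -> None:
        if self.dilation_radius_mm <= 0:
            raise ValueError("dilation radius must be > 0")


def dilate(mask: BinaryMask, radius_mm: float) -> BinaryMask:
    """Metric dilation: include every voxel whose center lies within
    ``radius_mm`` (Euclidean, anisotropic voxel sizes honored) of any set
    voxel's center.  Always a superset of the input; radius 0 is identity.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    if radius_mm == 0 or not mask.data.any():
        return BinaryMask(mask.data.copy(), mask.geometry)
    # EDT of the complement gives, at every voxel, the distance (mm) to the
    # nearest set voxel's center.
    dist = ndimage.distance_transform_edt(
        ~mask.data, sampling=mask.geometry.voxel_size
    )
    return BinaryMask(dist <= radius_mm, mask.geometry)


def perilesional_rim(lesion: BinaryMask, params: RimParams) -> BinaryMask:
    """(dilate(lesion) AND NOT lesion) AND gray matter, then downsampled to
    the functional grid.  Empty results are legal but warned about."""
    gm = params.gm_mask
    if gm is None:
        raise ValueError("RimParams.gm_mask is required")
    if gm.geometry != lesion.geometry:
        raise ValueError("lesion and gray-matter masks must share geometry")
    rim = (dilate(lesion, params.dilation_radius_mm) - lesion) & gm
    if tuple(params.downsample_factors) != (1, 1, 1):
        rim = downsample_mask(
            rim, params.downsample_factors, rule=params.downsample_rule
        )
    if rim.count == 0:
        warnings.warn("perilesional rim is empty after gray-matter masking")
    return rim


def mirror(mask: BinaryMask) -> BinaryMask:
    """Reflect across the mid-sagittal plane.

    Pure index reflection on the (symmetric) grid, so the output voxel
    count always equals the input count exactly.
    """
    geom = mask.geometry
    n = geom.shape[LR_AXIS]
    if not np.isclose(2.0 * geom.midline_index, n - 1):
        raise ValueError("grid is not symmetric about its midline; cannot mirror")
    return BinaryMask(np.flip(mask.data, axis=LR_AXIS), geom)


def downsample_mask(
    mask: BinaryMask,
    factors: Sequence[int],
    rule: Literal["any", "majority"] = "any",
) -> BinaryMask:
    """Block-reduce a mask by integer per-axis factors.

    "any" sets a coarse voxel if any constituent fine voxel is set;
    "majority" requires strictly more than half.  Shapes not divisible by
    the factors are zero-padded (with a warning).
    """
    factors = tuple(int(f) for f in factors)
    if any(f < 1 for f in factors):
        raise ValueError("factors must be >= 1")
    if rule not in ("any", "majority"):
        raise ValueError(f"unknown rule {rule!r}")
    data = mask.data
    geom = mask.geometry
    pad = [(-s) % f for s, f in zip(data.shape, factors)]
    if any(pad):
        warnings.warn(
            f"mask shape {data.shape} not divisible by {factors}; zero-padding"
        )
        data = np.pad(data, [(0, p) for p in pad])
    coarse_shape = tuple(s // f for s, f in zip(data.shape, factors))
    blocks = data.reshape(
        coarse_shape[0], factors[0], coarse_shape[1], factors[1],
        coarse_shape[2], factors[2],
    )
    counts = blocks.sum(axis=(1, 3, 5))
    block_size = int(np.prod(factors))
    out = counts > 0 if rule == "any" else counts > block_size / 2
    new_geom = VolumeGeometry(
        shape=coarse_shape,
        voxel_size=tuple(v * f for v, f in zip(geom.voxel_size, factors)),
    )
    return BinaryMask(out, new_geom)


def overlap_map(masks: Sequence[BinaryMask]) -> VolumeMap:
    """Voxelwise count of how many masks include each voxel."""
    if not masks:
        raise ValueError("need at least one mask")
    geom = masks[0].geometry
    if any(m.geometry != geom for m in masks):
        raise ValueError("all masks must share one geometry")
    total = np.zeros(geom.shape, dtype=float)
    for m in masks:
        total += m.data
    return VolumeMap(total, geom)
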