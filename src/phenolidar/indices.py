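"""LiDAR biomass indices for a segmented plot cloud: 3DVI and 3DPI.

3DVI (3D voxel index) — fraction of 0.05 m voxels in the plot's canopy
bounding volume (plot footprint × ground-to-top-of-canopy) that contain at
least one return. A volumetric occupancy measure: saturates once the canopy
fills most voxels.

3DPI (3D profile index) — sum over 0.01 m height layers, from the ground to
the maximum crop height, of the fractional interception of returns by the
canopy. The one-sentence published definition ("fractional number of points
intercepted") admits two readings, both implemented:

* ``interception`` (default): layers are processed top-down and each layer's
  fraction is its returns over the beams *not yet intercepted* above it —
  a discrete gap-fraction profile. Bounded by the number of layers.
* ``fraction_of_total``: each layer's fraction is its returns over all
  returns (including ground). This collapses to the canopy-return fraction
  and is bounded by 1; it is kept because the published wording also admits
  it, but it discards the vertical arrangement.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .design import PlotRect
from .errors import ValidationError
from .pointcloud import GroundModel, PointCloud

__all__ = ["compute_3dvi", "compute_3dpi", "canopy_mask"]


def canopy_mask(cloud: PointCloud, ground: GroundModel, ground_band: float | None = None):
    """Boolean mask of canopy (non-soil) returns.

    Returns within ``ground_band`` (default: one ground-histogram bin) of
    the ground elevation are treated as soil.
    """
    band = ground.bin_width if ground_band is None else ground_band
    return cloud.z >= ground.ground_z + band


def compute_3dvi(
    cloud: PointCloud,
    rect: PlotRect,
    ground: GroundModel,
    voxel_size: float = 0.05,
    *,
    ground_band: float | None = None,
    z_top: float | None = None,
) -> float:
    """3D voxel index: occupied / total voxels of the canopy bounding volume.

    The grid is anchored at ``(rect.x_min, rect.y_min, ground_z)`` with
    half-open cubic cells of ``voxel_size``; a point on a cell boundary
    belongs to the higher-index cell. The bounding volume spans the plot
    footprint from the ground elevation to the highest canopy return (or
    ``z_top`` when given), partial top cells included. A plot with no
    canopy returns yields 0.0 with a warning rather than an error.
    """
    if voxel_size <= 0:
        raise ValidationError("voxel_size must be > 0")
    mask = canopy_mask(cloud, ground, ground_band)
    if not mask.any():
        warnings.warn("no canopy returns above the ground band; 3DVI = 0", stacklevel=2)
        return 0.0
    x, y, z = cloud.x[mask], cloud.y[mask], cloud.z[mask]
    z0 = ground.ground_z
    top = float(z.max()) if z_top is None else float(z_top)
    if z_top is not None and top <= z0:
        raise ValidationError("z_top must lie above the ground elevation")
    nx = math.ceil(rect.width / voxel_size)
    ny = math.ceil(rect.length / voxel_size)
    nz = math.floor((top - z0) / voxel_size) + 1
    ix = np.floor((x - rect.x_min) / voxel_size).astype(np.int64)
    iy = np.floor((y - rect.y_min) / voxel_size).astype(np.int64)
    iz = np.floor((z - z0) / voxel_size).astype(np.int64)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
    occupied = len(np.unique(np.stack([ix[inside], iy[inside], iz[inside]]), axis=1).T)
    return occupied / (nx * ny * nz)


def compute_3dpi(
    cloud: PointCloud,
    ground: GroundModel,
    layer: float = 0.01,
    variant: str = "interception",
    *,
    beams_total: int | None = None,
    ground_band: float | None = None,
) -> float:
    """3D profile index over 0.01 m layers from the ground to canopy top.

    ``beams_total`` defaults to the number of returns in the cloud (one
    return per beam); soil returns count as beams that were never
    intercepted. See the module docstring for the two variants.
    """
    if layer <= 0:
        raise ValidationError("layer thickness must be > 0")
    if variant not in ("interception", "fraction_of_total"):
        raise ValidationError(f"unknown 3DPI variant {variant!r}")
    if beams_total is None:
        beams_total = len(cloud)
    mask = canopy_mask(cloud, ground, ground_band)
    n_canopy = int(mask.sum())
    if n_canopy == 0:
        return 0.0
    if beams_total < n_canopy:
        raise ValidationError("beams_total is smaller than the number of canopy returns")
    if variant == "interception" and beams_total < 1:
        raise ValidationError("interception variant needs beams_total >= 1")

    z = cloud.z[mask]
    iz = np.floor((z - ground.ground_z) / layer).astype(np.int64)
    counts = np.bincount(iz - iz.min())
    if variant == "fraction_of_total":
        return float(counts.sum() / beams_total)
    total = 0.0
    remaining = float(beams_total)
    for n_i in counts[::-1]:  # top-down
        if n_i == 0:
            continue
        if remaining <= 0:
            break
        total += n_i / remaining
        remaining -= n_i
    return float(total)
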