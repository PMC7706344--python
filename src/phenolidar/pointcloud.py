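"""Plot-level point clouds: I/O, segmentation, ground elevation, crop height.

A cloud is a flat table of (x, y, z) returns in field coordinates, metres,
z up. Ground elevation is estimated from the height histogram of a column of
plots — soil returns dominate the modal bin — and crop height is the mean of
the returns at or above the 95th percentile of the height distribution,
minus the ground elevation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import PlotRect
from .errors import CloudFormatError, CloudParseError, EmptyPlotError, ValidationError

__all__ = [
    "PointCloud",
    "GroundModel",
    "read_cloud",
    "write_cloud",
    "segment_plot",
    "estimate_ground",
    "crop_height",
]


@dataclass(frozen=True)
class PointCloud:
    """Immutable bundle of parallel coordinate arrays (metres)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        z = np.asarray(self.z, dtype=float)
        if not (x.shape == y.shape == z.shape) or x.ndim != 1:
            raise ValidationError("x, y, z must be 1-D arrays of equal length")
        if x.size and not (
            np.isfinite(x).all() and np.isfinite(y).all() and np.isfinite(z).all()
        ):
            raise ValidationError("point coordinates must be finite")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z": self.z})


@dataclass(frozen=True)
class GroundModel:
    """Ground elevation from the modal height bin of pooled soil returns."""

    ground_z: float
    bin_width: float
    n_ground_points: int

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be > 0")
        if self.n_ground_points < 1:
            raise ValidationError("ground model needs at least one point")


def read_cloud(path, format: str = "xyz_csv") -> PointCloud:
    """Read a point cloud; only ``xyz_csv`` (header x,y,z, metres) is supported.

    Raises :class:`CloudParseError` naming the offending line for malformed
    rows, :class:`CloudFormatError` for unknown formats.
    """
    if format != "xyz_csv":
        raise CloudFormatError(f"unknown format {format!r}; supported: 'xyz_csv'")
    raw = pd.read_csv(path, comment="#", dtype=str)
    cols = [c.strip().lower() for c in raw.columns]
    if not {"x", "y", "z"}.issubset(cols):
        raise CloudParseError(f"{path}: expected header with columns x,y,z")
    raw.columns = cols
    vals = {}
    for c in ("x", "y", "z"):
        num = pd.to_numeric(raw[c], errors="coerce")
        bad = num.isna() & raw[c].notna()
        if bad.any() or num.isna().any():
            line = int(num.index[num.isna()][0]) + 2  # header is line 1
            raise CloudParseError(
                f"{path}: non-numeric {c!r} value on line {line}", line=line
            )
        vals[c] = num.to_numpy(dtype=float)
    return PointCloud(vals["x"], vals["y"], vals["z"])


def write_cloud(cloud: PointCloud, path) -> None:
    """Write as XYZ CSV with micrometre precision (lossless at field scale)."""
    cloud.to_frame().to_csv(path, index=False, float_format="%.6f")


def segment_plot(
    cloud: PointCloud, rect: PlotRect, *, allow_empty: bool = False
) -> PointCloud:
    """Select the returns inside a plot rectangle.

    The rectangle is half-open — ``x_min <= x < x_max`` and likewise in y —
    so adjacent plots in a tiling never share points. Raises
    :class:`EmptyPlotError` when nothing falls inside, unless
    ``allow_empty``.
    """
    keep = (
        (cloud.x >= rect.x_min)
        & (cloud.x < rect.x_max)
        & (cloud.y >= rect.y_min)
        & (cloud.y < rect.y_max)
    )
    if not keep.any() and not allow_empty:
        raise EmptyPlotError(
            f"no points inside x=[{rect.x_min}, {rect.x_max}), "
            f"y=[{rect.y_min}, {rect.y_max})"
        )
    return PointCloud(cloud.x[keep], cloud.y[keep], cloud.z[keep])


def estimate_ground(clouds, bin_width: float = 0.01) -> GroundModel:
    """Ground elevation for one column of plots.

    Heights of all pooled returns are histogrammed into bins of
    ``bin_width`` anchored at integer multiples of the bin width; soil
    returns dominate the modal bin, and the ground elevation is the mean
    height of the points in that bin. Ties break toward the lower bin.

    ``clouds`` may be a single :class:`PointCloud` or an iterable of them
    (standalone single-plot use is the documented fallback).
    """
    if isinstance(clouds, PointCloud):
        clouds = [clouds]
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    zs = [c.z for c in clouds if len(c)]
    if not zs:
        raise ValidationError("cannot estimate ground from an empty point pool")
    z = np.concatenate(zs)
    idx = np.floor(z / bin_width).astype(np.int64)
    shift = idx.min()
    counts = np.bincount(idx - shift)
    modal = int(np.argmax(counts)) + shift  # argmax -> first (lowest) max
    in_bin = idx == modal
    return GroundModel(
        ground_z=float(z[in_bin].mean()),
        bin_width=float(bin_width),
        n_ground_points=int(in_bin.sum()),
    )


def crop_height(
    cloud: PointCloud,
    ground: GroundModel,
    *,
    exclude_ground: bool = True,
    ground_band: float | None = None,
    noise_tolerance: float = 0.01,
) -> float:
    """Crop height: mean of the top-95th-percentile heights minus ground.

    The 95th percentile is computed with linear interpolation of order
    statistics, and the "top" set is every return with ``z >= P95``. Soil
    returns within ``ground_band`` (default: one histogram bin) of the
    ground elevation are excluded first when ``exclude_ground`` — a bare
    plot then reports height 0. Small negative heights (within twice
    ``noise_tolerance``) clamp to zero; larger negatives additionally raise
    a data-quality warning.
    """
    if len(cloud) == 0:
        raise ValidationError("cannot compute crop height of an empty cloud")
    z = cloud.z
    if exclude_ground:
        band = ground.bin_width if ground_band is None else ground_band
        z = z[z >= ground.ground_z + band]
        if z.size == 0:
            return 0.0
    p95 = np.percentile(z, 95)  # linear interpolation of order statistics
    h = float(z[z >= p95].mean() - ground.ground_z)
    if h < 0.0:
        if h < -2.0 * noise_tolerance:
            warnings.warn(
                f"crop height {h:.3f} m is negative beyond noise tolerance; "
                "check ground model",
                stacklevel=2,
            )
        h = 0.0
    return h
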