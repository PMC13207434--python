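"""Shared 3-D Cartesian representation of secondary-structure elements.

Model-derived Cα traces and map-derived density sticks are brought into a
common fixed-length geometric description so that correspondence can be
learned directly from coordinates: arc-length resampling to ``k`` points,
a PCA axis with a first-to-last sign convention, voxel quantization for
diagnostics, and the concatenated feature vector

    [k resampled points (3k), centroid (3), unit axis (3), arc length (1),
     raw point count (1)]

of length ``3k + 8``.  Feature standardization (fit on training data only)
is applied on top of this layout when a scaler is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError

__all__ = [
    "FeatureVector",
    "VoxelSet",
    "resample_polyline",
    "compute_axis",
    "polyline_length",
    "voxelize",
    "featurize",
    "feature_length",
]


@dataclass
class FeatureVector:
    """Fixed-length geometric descriptor of one SSE (model- or map-derived).

    ``values`` follows the layout documented in the module docstring;
    ``scaled`` records whether per-dimension standardization was applied.
    """

    values: np.ndarray
    k: int
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3 * self.k + 8,):
            raise InvalidFeatureLayout(
                f"feature vector must have length 3k+8 = {3 * self.k + 8}, "
                f"got {self.values.shape}"
            )


class InvalidFeatureLayout(InputError):
    pass


@dataclass
class VoxelSet:
    """Set of integer voxel indices at a given edge spacing (Å)."""

    spacing: float
    indices: set = field(default_factory=set)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 3:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (n, 3) array of points, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise InputError("empty point list")
    if not np.isfinite(pts).all():
        raise InputError("points contain non-finite coordinates")
    return pts


def polyline_length(points) -> float:
    """Total arc length (Å) of the piecewise-linear curve through ``points``."""
    pts = _as_points(points)
    if len(pts) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def resample_polyline(points, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points at equal arc-length stations.

    Endpoints are preserved exactly.  A degenerate input (a single point, or
    all points coincident) yields ``k`` copies of the first point.
    """
    if k < 2:
        raise ConfigError(f"resample count k must be >= 2, got {k}")
    pts = _as_points(points)
    if len(pts) == 1:
        return np.repeat(pts[:1], k, axis=0)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0.0:
        return np.repeat(pts[:1], k, axis=0)
    stations = np.linspace(0.0, total, k)
    out = np.column_stack(
        [np.interp(stations, cum, pts[:, d]) for d in range(3)]
    )
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def compute_axis(points) -> np.ndarray:
    """Unit axis of an SSE: first principal direction of the centered points.

    The sign is fixed so that the axis points from the first toward the last
    point (non-negative dot product with last − first), which makes point-order
    reversal visible in the feature space.
    """
    pts = _as_points(points)
    if len(pts) < 2:
        raise InputError("axis requires at least 2 points")
    centered = pts - pts.mean(axis=0)
    if not np.any(np.linalg.norm(centered, axis=1) > 0):
        raise InputError("axis undefined: all points coincident")
    # eigh on the 3x3 scatter matrix; last eigenvector = largest eigenvalue
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    span = pts[-1] - pts[0]
    if float(axis @ span) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def voxelize(points, spacing: float) -> VoxelSet:
    """Quantize points onto a cubic grid: index = floor(coord / spacing).

    Half-open cells (floor, not round) so no point can land in two cells;
    duplicates collapse to one index.
    """
    if spacing <= 0:
        raise ConfigError(f"voxel spacing must be positive, got {spacing}")
    pts = _as_points(points)
    idx = np.floor(pts / spacing).astype(int)
    return VoxelSet(spacing=spacing, indices={tuple(row) for row in idx})


def feature_length(k: int) -> int:
    return 3 * k + 8


def assemble_feature(
    resampled: np.ndarray,
    axis: np.ndarray,
    arc_length: float,
    raw_count: int,
    k: int,
) -> FeatureVector:
    """Lay out the feature vector from its precomputed parts."""
    centroid = resampled.mean(axis=0)
    values = np.concatenate(
        [resampled.ravel(), centroid, axis, [arc_length], [float(raw_count)]]
    )
    return FeatureVector(values=values, k=k)


def featurize(element, k: int, scaler=None) -> FeatureVector:
    """Build the fixed-length geometric descriptor of an SSE or stick.

    ``element`` is anything exposing ordered 3-D points as ``calpha_coords``
    (model SSE) or ``axis_points`` (density stick).  When ``scaler`` (a fitted
    per-dimension standardizer) is given, the values are transformed with the
    means/deviations stored at training time.
    """
    pts = getattr(element, "calpha_coords", None)
    if pts is None:
        pts = getattr(element, "axis_points", None)
    if pts is None:
        pts = element  # raw point array
    pts = _as_points(pts)
    resampled = resample_polyline(pts, k)
    axis = compute_axis(pts)
    fv = assemble_feature(resampled, axis, polyline_length(pts), len(pts), k)
    if scaler is not None:
        fv = FeatureVector(
            values=scaler.transform(fv.values[None, :])[0], k=k, scaled=True
        )
    return fv
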