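"""Geometric similarity metrics on pairs of grid-compatible binary masks.

Implements the agreement measures standard in radiotherapy contour
evaluation:

* DSC — Dice similarity coefficient, volumetric overlap in [0, 1];
* MSD — mean surface distance (mm), symmetrized over both directions;
* HD95 — 95th-percentile Hausdorff distance (mm), max of the two directed
  95th percentiles;
* SDSC — surface Dice at tolerance tau (mm): the fraction of the combined
  surfaces lying within tau of the other surface;
* APL — added path length (mm): in-plane reference boundary not reproduced
  by the test contour within tolerance, a proxy for manual editing effort;
* physical volume in cc.

Surfaces are boundary voxels under 6-connectivity against the background
(the grid edge counts as background), and distances are Euclidean between
boundary-voxel centers in physical mm.  Distance queries use a KD-tree,
which is exact, so brute-force pairwise distances give identical values.

Degenerate inputs: DSC of two empty masks is 1.0 (perfect agreement on
absence) and 0.0 when exactly one is empty; the surface metrics are
undefined on empty masks and raise :class:`UndefinedMetricError`, which
callers record as a missing value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io import BinaryMask, require_grid_compatible

__all__ = [
    "Metric",
    "MetricValue",
    "Surface",
    "UndefinedMetricError",
    "dice",
    "extract_surface",
    "surface_distance_stats",
    "surface_dice",
    "added_path_length",
    "volume_cc",
    "compute_metric",
    "HIGHER_IS_BETTER",
]


class UndefinedMetricError(ValueError):
    """Metric undefined for the given masks (e.g. an empty surface)."""


class Metric(str, Enum):
    DSC = "DSC"
    SDSC = "SDSC"
    MSD = "MSD"
    HD95 = "HD95"
    APL = "APL"
    VOLUME = "VOLUME"


#: Metrics where larger values mean better agreement.
HIGHER_IS_BETTER = {Metric.DSC: True, Metric.SDSC: True, Metric.MSD: False,
                    Metric.HD95: False, Metric.APL: False}

_UNITS = {
    Metric.DSC: "dimensionless",
    Metric.SDSC: "dimensionless",
    Metric.MSD: "mm",
    Metric.HD95: "mm",
    Metric.APL: "mm",
    Metric.VOLUME: "cc",
}


@dataclass(frozen=True)
class MetricValue:
    metric: Metric
    value: float
    units: str = ""
    tolerance_mm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "metric", Metric(self.metric))
        if not self.units:
            object.__setattr__(self, "units", _UNITS[self.metric])
        if self.metric in (Metric.DSC, Metric.SDSC):
            if not (-1e-12 <= self.value <= 1 + 1e-12):
                raise ValueError(f"{self.metric.value} must lie in [0,1]: {self.value}")
        elif self.value < -1e-12:
            raise ValueError(f"{self.metric.value} must be >= 0: {self.value}")

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class Surface:
    """Boundary voxel centers of a mask, in physical mm.

    ``element_area`` is a per-element patch area approximation: the mean of
    the three pairwise spacing products.
    """

    points: np.ndarray  # (n, 3) physical mm
    element_area: float
    spacing: tuple[float, float, float]

    @property
    def n_elements(self) -> int:
        return int(self.points.shape[0])

    def is_empty(self) -> bool:
        return self.n_elements == 0


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _boundary_voxels(voxels: np.ndarray) -> np.ndarray:
    """Foreground voxels with >= 1 face-neighbor that is background/outside."""
    if not voxels.any():
        return np.zeros_like(voxels)
    interior = ndimage.binary_erosion(voxels, structure=_STRUCT6, border_value=0)
    return voxels & ~interior


def extract_surface(mask: BinaryMask) -> Surface:
    """Boundary voxels under 6-connectivity, grid edge counted as background."""
    boundary = _boundary_voxels(mask.voxels)
    idx = np.argwhere(boundary)
    points = mask.indices_to_physical(idx) if idx.size else idx.reshape(0, 3).astype(float)
    s = mask.spacing
    area = float(np.mean([s[0] * s[1], s[0] * s[2], s[1] * s[2]]))
    return Surface(points=points, element_area=area, spacing=s)


def dice(a: BinaryMask, b: BinaryMask) -> MetricValue:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) by voxel counts."""
    require_grid_compatible(a, b)
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        return MetricValue(Metric.DSC, 1.0)
    inter = int(np.count_nonzero(a.voxels & b.voxels))
    return MetricValue(Metric.DSC, 2.0 * inter / (na + nb))


def _directed_distances(src: Surface, dst: Surface) -> np.ndarray:
    """Distance from each src element to the nearest dst element (mm)."""
    tree = cKDTree(dst.points)
    d, _ = tree.query(src.points, k=1)
    return np.asarray(d, dtype=float)


def surface_distance_stats(
    a: BinaryMask, b: BinaryMask
) -> tuple[MetricValue, MetricValue]:
    """Mean surface distance and 95% Hausdorff distance between two masks.

    MSD is the mean of the two directed mean distances; HD95 the max of the
    two directed 95th percentiles (linear interpolation).
    """
    require_grid_compatible(a, b)
    sa, sb = extract_surface(a), extract_surface(b)
    if sa.is_empty() or sb.is_empty():
        raise UndefinedMetricError("surface distances undefined for an empty mask")
    d_ab = _directed_distances(sa, sb)
    d_ba = _directed_distances(sb, sa)
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    hd95 = max(float(np.percentile(d_ab, 95)), float(np.percentile(d_ba, 95)))
    return MetricValue(Metric.MSD, msd), MetricValue(Metric.HD95, hd95)


def surface_dice(a: BinaryMask, b: BinaryMask, tau_mm: float) -> MetricValue:
    """Surface Dice at tolerance tau, element-count weighted."""
    require_grid_compatible(a, b)
    if tau_mm < 0:
        raise ValueError(f"tolerance must be >= 0, got {tau_mm}")
    sa, sb = extract_surface(a), extract_surface(b)
    if sa.is_empty() or sb.is_empty():
        raise UndefinedMetricError("surface Dice undefined for an empty mask")
    tol = tau_mm * (1 + 1e-12) + 1e-12  # guard float noise at exact tau
    d_ab = _directed_distances(sa, sb)
    d_ba = _directed_distances(sb, sa)
    hits = int(np.count_nonzero(d_ab <= tol)) + int(np.count_nonzero(d_ba <= tol))
    value = hits / (sa.n_elements + sb.n_elements)
    return MetricValue(Metric.SDSC, value, tolerance_mm=float(tau_mm))


_STRUCT4_2D = ndimage.generate_binary_structure(2, 1)


def added_path_length(
    ref: BinaryMask, test: BinaryMask, tau_mm: float = 0.0
) -> MetricValue:
    """Added path length: in-plane reference boundary farther than tau from
    the test surface, summed over axial slices and scaled by the in-plane
    pixel spacing (mean of row/column spacing).

    An empty test mask yields the total reference boundary path length.
    """
    require_grid_compatible(ref, test)
    if tau_mm < 0:
        raise ValueError(f"tolerance must be >= 0, got {tau_mm}")
    if ref.is_empty():
        raise UndefinedMetricError("APL undefined for an empty reference mask")
    pixel_mm = 0.5 * (ref.spacing[1] + ref.spacing[2])

    # 2D boundary (4-connectivity, in-plane only) of each axial slice
    boundary_pts = []
    for i in range(ref.shape[0]):
        sl = ref.voxels[i]
        if not sl.any():
            continue
        interior = ndimage.binary_erosion(sl, structure=_STRUCT4_2D, border_value=0)
        jk = np.argwhere(sl & ~interior)
        if jk.size:
            idx3 = np.column_stack([np.full(len(jk), i), jk])
            boundary_pts.append(idx3)
    idx = np.concatenate(boundary_pts, axis=0)
    pts = ref.indices_to_physical(idx)

    test_surface = extract_surface(test)
    if test_surface.is_empty():
        n_added = len(pts)
    else:
        d = cKDTree(test_surface.points).query(pts, k=1)[0]
        tol = tau_mm * (1 + 1e-12) + 1e-12
        n_added = int(np.count_nonzero(d > tol))
    return MetricValue(Metric.APL, n_added * pixel_mm, tolerance_mm=float(tau_mm))


def volume_cc(m: BinaryMask) -> MetricValue:
    """Physical foreground volume in cc (mm^3 / 1000)."""
    return MetricValue(Metric.VOLUME, m.n_foreground * m.voxel_volume_mm3() / 1000.0)


def compute_metric(
    metric: Metric | str,
    a: BinaryMask,
    b: BinaryMask,
    tau_mm: float | None = None,
) -> MetricValue:
    """Dispatch a symmetric pair metric by name (DSC, SDSC, MSD, HD95)."""
    metric = Metric(metric)
    if metric == Metric.DSC:
        return dice(a, b)
    if metric == Metric.SDSC:
        if tau_mm is None:
            raise ValueError("SDSC requires a tolerance tau_mm")
        return surface_dice(a, b, tau_mm)
    if metric == Metric.MSD:
        return surface_distance_stats(a, b)[0]
    if metric == Metric.HD95:
        return surface_distance_stats(a, b)[1]
    if metric == Metric.APL:
        return added_path_length(a, b, tau_mm if tau_mm is not None else 0.0)
    raise ValueError(f"not a pair metric: {metric}")
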