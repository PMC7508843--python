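"""Extraction of the 21 drusen imaging features from a segmented scan bundle.

The 15 internal features are computed from the drusen mask, the en-face
elevation map and the (percentile-normalized) intensity volume; the 6
device-reported duplicates are pass-through columns, mirrored from their
internal counterparts when not supplied.

Conventions (fixed here, not configurable unless noted):

* Drusen instances are separated by 26-connectivity in 3-D (configurable).
* The extent hull is the 2-D convex hull of the *corners* of footprint
  pixels in mm coordinates, which guarantees ``extent_area >= total_area``
  and hence ``density <= 1``.  Degenerate footprints fall back to the
  footprint area.
* Reflectivity normalization maps the volume-wide 5th/95th percentiles to
  0/1 and does not clip.
* Slope is the mean magnitude of the elevation gradient (central
  differences with physical spacing) over the drusen footprint.
* Standard deviations are population (divide by N).
* Regional features use Euclidean distance of pixel centers from the fovea
  center, with "3 mm" / "5 mm" read as radii.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from amdprog.bundles import (
    CIRRUS_TO_INTERNAL,
    DrusenScanBundle,
    ImagingFeatureVector,
)

__all__ = [
    "label_instances",
    "compute_size_features",
    "compute_extent_density",
    "compute_height_slope",
    "normalize_reflectivity",
    "compute_reflectivity_stats",
    "compute_regional",
    "assemble_features",
    "average_session",
]


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be one of 6, 18, 26")


def label_instances(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a 3-D binary drusen mask.

    Returns the instance-labeled array (0 = background) and the component
    count.  Raises ``ValueError`` for non-binary input.
    """
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if mask.dtype != bool:
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask must be binary")
        mask = mask.astype(bool)
    labels, count = ndimage.label(mask, structure=_structure(connectivity))
    return labels, int(count)


def _instance_footprints(labels: np.ndarray, count: int) -> list[np.ndarray]:
    """Per-instance en-face footprint masks (any drusen voxel in the column)."""
    footprints = []
    objects = ndimage.find_objects(labels)
    for idx in range(1, count + 1):
        sl = objects[idx - 1]
        fp = np.zeros(labels.shape[:2], dtype=bool)
        fp[sl[0], sl[1]] = np.any(labels[sl] == idx, axis=2)
        footprints.append(fp)
    return footprints


def compute_size_features(
    bundle: DrusenScanBundle, labels: np.ndarray, count: int
) -> dict[str, float]:
    """Per-druse and total volume (mm^3) and en-face footprint area (mm^2).

    Volume of a druse is its voxel count times the voxel volume; area is its
    footprint pixel count times the pixel area.  Totals are over the union
    (overlapping footprints counted once for total area).
    """
    if count == 0:
        return {
            "n_drusen": 0.0,
            "mean_volume": 0.0,
            "total_volume": 0.0,
            "mean_area": 0.0,
            "total_area": 0.0,
        }
    voxel_counts = np.bincount(labels.ravel(), minlength=count + 1)[1:]
    volumes = voxel_counts * bundle.voxel_volume_mm3
    footprints = _instance_footprints(labels, count)
    areas = np.array([fp.sum() for fp in footprints]) * bundle.pixel_area_mm2
    union_area = float(np.any(labels > 0, axis=2).sum() * bundle.pixel_area_mm2)
    return {
        "n_drusen": float(count),
        "mean_volume": float(volumes.mean()),
        "total_volume": float(volumes.sum()),
        "mean_area": float(areas.mean()),
        "total_area": union_area,
    }


def _hull_area_of_footprint(footprint: np.ndarray, pixel_size: tuple[float, float]) -> float:
    """Area (mm^2) of the convex hull of the footprint pixels' corner points."""
    ij = np.argwhere(footprint)
    dx, dy = pixel_size
    # four corners of each occupied pixel, in mm
    offsets = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
    pts = (ij[:, None, :] + offsets[None, :, :]).reshape(-1, 2) * np.array([dx, dy])
    try:
        return float(ConvexHull(pts).volume)  # 2-D hull "volume" is its area
    except QhullError:
        return float("nan")


def compute_extent_density(
    bundle: DrusenScanBundle, labels: np.ndarray, count: int
) -> dict[str, float]:
    """Convex-hull extent of the drusen-affected region and drusen density.

    ``density = total_area / extent_area``.  With no drusen both are 0 by
    convention; degenerate hulls fall back to the footprint area (density 1).
    """
    if count == 0:
        return {"extent_area": 0.0, "density": 0.0}
    footprint = np.any(labels > 0, axis=2)
    total_area = float(footprint.sum()) * bundle.pixel_area_mm2
    hull_area = _hull_area_of_footprint(
        footprint, (bundle.voxel_size_mm[0], bundle.voxel_size_mm[1])
    )
    if not np.isfinite(hull_area) or hull_area < total_area:
        hull_area = total_area
    return {"extent_area": hull_area, "density": total_area / hull_area}


def compute_height_slope(
    bundle: DrusenScanBundle, labels: np.ndarray, count: int
) -> dict[str, float]:
    """Maximum elevation (mm) and mean elevation-gradient magnitude over the
    drusen footprint.  Empty footprint yields (0, 0)."""
    if count == 0:
        return {"max_height": 0.0, "avg_slope": 0.0}
    footprint = np.any(labels > 0, axis=2)
    elev = bundle.elevation_map_mm
    gx, gy = np.gradient(elev, bundle.voxel_size_mm[0], bundle.voxel_size_mm[1])
    grad_mag = np.hypot(gx, gy)
    return {
        "max_height": float(elev[footprint].max()),
        "avg_slope": float(grad_mag[footprint].mean()),
    }


def normalize_reflectivity(intensity_volume: np.ndarray) -> np.ndarray:
    """Linearly map the volume-wide 5th/95th intensity percentiles to 0/1.

    Values outside [0, 1] are permitted (no clipping).  Raises
    ``ValueError("degenerate intensity range")`` when p95 == p5.
    """
    vol = np.asarray(intensity_volume, dtype=float)
    p5, p95 = np.percentile(vol, [5.0, 95.0])
    if p95 <= p5:
        raise ValueError("degenerate intensity range")
    return (vol - p5) / (p95 - p5)


def compute_reflectivity_stats(
    normalized_volume: np.ndarray, mask: np.ndarray
) -> dict[str, float]:
    """Mean and population std of normalized intensity inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return {"mean_reflectivity": 0.0, "std_reflectivity": 0.0, "undefined_stats": True}
    vals = np.asarray(normalized_volume, dtype=float)[mask]
    return {
        "mean_reflectivity": float(vals.mean()),
        "std_reflectivity": float(vals.std(ddof=0)),
        "undefined_stats": False,
    }


def compute_regional(
    bundle: DrusenScanBundle,
    labels: np.ndarray,
    radius_mm: float,
) -> dict[str, float]:
    """Total drusen area/volume within ``radius_mm`` of the fovea center.

    Restriction is on en-face pixel centers (Euclidean distance in the
    en-face plane); a column's whole voxel stack counts when its center is
    inside the circle.
    """
    x, y = bundle.enface_coords_mm()
    fx, fy = bundle.fovea_center_mm
    dist = np.hypot(x[:, None] - fx, y[None, :] - fy)
    inside = dist <= radius_mm
    drusen_cols = labels > 0
    footprint = np.any(drusen_cols, axis=2)
    area = float((footprint & inside).sum()) * bundle.pixel_area_mm2
    volume = float(drusen_cols[inside].sum()) * bundle.voxel_volume_mm3
    key = f"{radius_mm:g}mm"
    return {f"area_{key}": area, f"volume_{key}": volume}


def assemble_features(
    bundle: DrusenScanBundle,
    cirrus: dict[str, float] | None = None,
    connectivity: int = 26,
    regional_radii_mm: tuple[float, float] = (3.0, 5.0),
) -> ImagingFeatureVector:
    """Compute the full 21-feature vector for one scan.

    ``cirrus`` optionally supplies the device-reported duplicate columns;
    otherwise they are mirrored from the internal values and flagged.
    """
    labels, count = label_instances(bundle.drusen_mask, connectivity=connectivity)
    out: dict[str, float] = {}
    out.update(compute_size_features(bundle, labels, count))
    out.update(compute_extent_density(bundle, labels, count))
    out.update(compute_height_slope(bundle, labels, count))
    undefined = count == 0
    if count > 0:
        try:
            norm = normalize_reflectivity(bundle.intensity_volume)
        except ValueError:
            # near-uniform volume: reflectivity undefined-as-zero
            out.update({"mean_reflectivity": 0.0, "std_reflectivity": 0.0})
            undefined = True
        else:
            stats = compute_reflectivity_stats(norm, bundle.drusen_mask)
            undefined = bool(stats.pop("undefined_stats"))
            out.update(stats)
    else:
        out.update({"mean_reflectivity": 0.0, "std_reflectivity": 0.0})
    for r in regional_radii_mm:
        out.update(compute_regional(bundle, labels, r))

    mirrored = cirrus is None
    for cirrus_name, internal_name in CIRRUS_TO_INTERNAL.items():
        if cirrus is not None and cirrus_name in cirrus:
            out[cirrus_name] = float(cirrus[cirrus_name])
        else:
            out[cirrus_name] = out[internal_name]
    return ImagingFeatureVector(**out, undefined_stats=undefined, cirrus_mirrored=mirrored)


def average_session(
    vectors: list[ImagingFeatureVector],
    eye_ids: list[str] | None = None,
    session_dates: list[str] | None = None,
) -> ImagingFeatureVector:
    """Element-wise mean of same-session feature vectors.

    Scans acquired in the same imaging session (same eye and date) are
    averaged into a single observation.  When ``eye_ids`` / ``session_dates``
    are given, mixing eyes or dates raises ``ValueError``.
    """
    if not vectors:
        raise ValueError("average_session requires at least one vector")
    for name, ids in (("eye_ids", eye_ids), ("session_dates", session_dates)):
        if ids is not None and len(set(ids)) > 1:
            raise ValueError(f"cannot average across mixed {name}: {sorted(set(ids))}")
    stacked = np.stack([v.as_array() for v in vectors])
    return ImagingFeatureVector.from_array(
        stacked.mean(axis=0),
        undefined_stats=all(v.undefined_stats for v in vectors),
        cirrus_mirrored=any(v.cirrus_mirrored for v in vectors),
    )
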