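"""Core data containers: segmented scan bundles and the drusen feature vector.

A :class:`DrusenScanBundle` holds one SD-OCT acquisition after drusen
segmentation: a 3-D binary drusen mask, a 2-D en-face RPE-elevation map
(height above the Bruch's membrane estimate, in mm), the B-scan intensity
volume and geometry metadata.  Axes are ordered (fast-scan, slow-scan,
axial); the en-face plane is the first two axes.

An :class:`ImagingFeatureVector` carries the 21 named drusen biomarkers:
15 internally computed features plus 6 optional device-reported ("cirrus")
duplicates that are treated as pass-through columns.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Internally computed features, in canonical column order.
INTERNAL_FEATURE_NAMES: tuple[str, ...] = (
    "n_drusen",
    "mean_volume",
    "total_volume",
    "mean_area",
    "total_area",
    "extent_area",
    "density",
    "max_height",
    "avg_slope",
    "mean_reflectivity",
    "std_reflectivity",
    "area_3mm",
    "area_5mm",
    "volume_3mm",
    "volume_5mm",
)

#: Device-reported pass-through duplicates.
CIRRUS_FEATURE_NAMES: tuple[str, ...] = (
    "total_area_cirrus",
    "area_3mm_cirrus",
    "area_5mm_cirrus",
    "total_volume_cirrus",
    "volume_3mm_cirrus",
    "volume_5mm_cirrus",
)

#: All 21 feature columns, canonical order.
FEATURE_NAMES: tuple[str, ...] = INTERNAL_FEATURE_NAMES + CIRRUS_FEATURE_NAMES

#: Maps each cirrus pass-through column to its internal counterpart.
CIRRUS_TO_INTERNAL: dict[str, str] = {
    "total_area_cirrus": "total_area",
    "area_3mm_cirrus": "area_3mm",
    "area_5mm_cirrus": "area_5mm",
    "total_volume_cirrus": "total_volume",
    "volume_3mm_cirrus": "volume_3mm",
    "volume_5mm_cirrus": "volume_5mm",
}


@dataclass
class DrusenScanBundle:
    """One segmented SD-OCT acquisition.

    Parameters
    ----------
    drusen_mask
        Boolean array of shape ``(nx, ny, nz)``; True inside drusen.
    elevation_map_mm
        Non-negative float array of shape ``(nx, ny)``: RPE height above the
        Bruch's membrane estimate at each en-face position, in mm.
    intensity_volume
        Float array of shape ``(nx, ny, nz)`` with B-scan intensities.
    voxel_size_mm
        Positive (dx, dy, dz) voxel dimensions in mm.
    fovea_center_mm
        (x, y) en-face coordinates of the fovea center in mm, origin at the
        scan corner.
    """

    drusen_mask: np.ndarray
    elevation_map_mm: np.ndarray
    intensity_volume: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    fovea_center_mm: tuple[float, float]
    eye_id: str = ""
    session_date: str = ""
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.drusen_mask = np.asarray(self.drusen_mask)
        self.elevation_map_mm = np.asarray(self.elevation_map_mm, dtype=float)
        self.intensity_volume = np.asarray(self.intensity_volume, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.drusen_mask.ndim != 3:
            raise ValueError("drusen_mask must be 3-D (fast, slow, axial)")
        if self.intensity_volume.shape != self.drusen_mask.shape:
            raise ValueError("intensity_volume and drusen_mask shapes differ")
        if self.elevation_map_mm.shape != self.drusen_mask.shape[:2]:
            raise ValueError("elevation_map_mm must match en-face dimensions")
        if np.any(self.elevation_map_mm < 0):
            raise ValueError("elevation_map_mm must be non-negative")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be three positive reals")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.drusen_mask.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.voxel_size_mm[0] * self.voxel_size_mm[1])

    def enface_coords_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of en-face pixel centers."""
        nx, ny = self.drusen_mask.shape[:2]
        dx, dy, _ = self.voxel_size_mm
        x = (np.arange(nx) + 0.5) * dx
        y = (np.arange(ny) + 0.5) * dy
        return x, y

    # -- persistence (NIfTI volumes + JSON sidecar) --------------------------

    def save(self, directory: str | Path) -> Path:
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(self.voxel_size_mm) + [1.0])
        nib.save(
            nib.Nifti1Image(self.drusen_mask.astype(np.uint8), affine),
            directory / "drusen_mask.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.intensity_volume.astype(np.float32), affine),
            directory / "intensity.nii.gz",
        )
        affine2d = np.diag([self.voxel_size_mm[0], self.voxel_size_mm[1], 1.0, 1.0])
        nib.save(
            nib.Nifti1Image(self.elevation_map_mm.astype(np.float32), affine2d),
            directory / "elevation_mm.nii.gz",
        )
        sidecar = {
            "voxel_size_mm": list(self.voxel_size_mm),
            "fovea_center_mm": list(self.fovea_center_mm),
            "laterality": self.laterality,
            "eye_id": self.eye_id,
            "session_date": self.session_date,
        }
        (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "DrusenScanBundle":
        import nibabel as nib

        directory = Path(directory)
        sidecar = json.loads((directory / "sidecar.json").read_text())
        mask = np.asanyarray(nib.load(directory / "drusen_mask.nii.gz").dataobj).astype(bool)
        vol = np.asanyarray(nib.load(directory / "intensity.nii.gz").dataobj).astype(float)
        elev = np.asanyarray(nib.load(directory / "elevation_mm.nii.gz").dataobj).astype(float)
        if elev.ndim == 3 and elev.shape[-1] == 1:  # NIfTI stores 2-D as (nx, ny, 1)
            elev = elev[..., 0]
        return cls(
            drusen_mask=mask,
            elevation_map_mm=elev,
            intensity_volume=vol,
            voxel_size_mm=tuple(sidecar["voxel_size_mm"]),
            fovea_center_mm=tuple(sidecar["fovea_center_mm"]),
            eye_id=sidecar.get("eye_id", ""),
            session_date=sidecar.get("session_date", ""),
            laterality=sidecar.get("laterality", "OD"),
        )


@dataclass
class ImagingFeatureVector:
    """The 21 named drusen biomarkers for one scan (or session average)."""

    n_drusen: float = 0.0
    mean_volume: float = 0.0
    total_volume: float = 0.0
    mean_area: float = 0.0
    total_area: float = 0.0
    extent_area: float = 0.0
    density: float = 0.0
    max_height: float = 0.0
    avg_slope: float = 0.0
    mean_reflectivity: float = 0.0
    std_reflectivity: float = 0.0
    area_3mm: float = 0.0
    area_5mm: float = 0.0
    volume_3mm: float = 0.0
    volume_5mm: float = 0.0
    total_area_cirrus: float = 0.0
    area_3mm_cirrus: float = 0.0
    area_5mm_cirrus: float = 0.0
    total_volume_cirrus: float = 0.0
    volume_3mm_cirrus: float = 0.0
    volume_5mm_cirrus: float = 0.0
    #: True when no drusen were present and density / reflectivity stats are
    #: reported as 0 by convention rather than measured.
    undefined_stats: bool = field(default=False, compare=False)
    #: True when the cirrus columns were mirrored from internal counterparts
    #: instead of being provided by the device.
    cirrus_mirrored: bool = field(default=False, compare=False)

    def as_array(self) -> np.ndarray:
        """Feature values in canonical :data:`FEATURE_NAMES` order."""
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: np.ndarray, **flags) -> "ImagingFeatureVector":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"expected {len(FEATURE_NAMES)} feature values")
        return cls(**dict(zip(FEATURE_NAMES, values.tolist())), **flags)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}

    def check_invariants(self, atol: float = 1e-9) -> None:
        """Raise AssertionError if internal consistency constraints fail."""
        v = self
        assert v.n_drusen >= 0 and float(v.n_drusen).is_integer()
        for name in FEATURE_NAMES:
            if name not in ("avg_slope", "mean_reflectivity", "std_reflectivity"):
                assert getattr(v, name) >= -atol, f"{name} negative"
        assert v.area_3mm <= v.area_5mm + atol <= v.total_area + 2 * atol
        assert v.volume_3mm <= v.volume_5mm + atol <= v.total_volume + 2 * atol
        if v.n_drusen > 0:
            assert v.total_area <= v.extent_area + atol
            assert 0.0 < v.density <= 1.0 + atol
        else:
            for name in INTERNAL_FEATURE_NAMES:
                if name != "n_drusen":
                    assert getattr(v, name) == 0.0, f"{name} nonzero with no drusen"


def feature_vector_fields() -> list[str]:
    """Names of all dataclass fields (features + flags), for CSV round-trips."""
    return [f.name for f in dataclasses.fields(ImagingFeatureVector)]
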