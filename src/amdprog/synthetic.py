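"""Synthetic inputs with known ground truth.

Two generators:

* :func:`generate_phantom` builds a segmented scan bundle from spherical-cap
  drusen on a flat Bruch's membrane plane.  Caps have closed-form footprint
  area ``pi * a**2`` and volume ``pi * h * (3 a**2 + h**2) / 6`` (``a`` base
  radius, ``h`` peak height), so every size feature has an analytic oracle.
* :func:`generate_cohort` simulates a longitudinal cohort of eyes with
  drifting drusen features and a discrete-time logistic exudation hazard
  planted on the features (and optionally on per-eye latent drift rates, so
  that visit history carries signal beyond the latest observation).

All randomness flows through one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from amdprog.bundles import (
    CIRRUS_TO_INTERNAL,
    FEATURE_NAMES,
    DrusenScanBundle,
    ImagingFeatureVector,
)
from amdprog.labeling import (
    GENDER_LEVELS,
    RACE_LEVELS,
    SMOKING_LEVELS,
    EyeHistory,
    VisitRecord,
)

# ---------------------------------------------------------------------------
# Drusen phantoms
# ---------------------------------------------------------------------------

#: Scanner geometries over a 6 x 6 x 2 mm field: the two clinical patterns
#: and a reduced grid for fast tests.
SCAN_GEOMETRIES: dict[str, tuple[tuple[int, int, int], tuple[float, float, float]]] = {
    "512x128": ((512, 128, 1024), (6.0 / 512, 6.0 / 128, 2.0 / 1024)),
    "200x200": ((200, 200, 1024), (6.0 / 200, 6.0 / 200, 2.0 / 1024)),
    "test": ((160, 160, 512), (6.0 / 160, 6.0 / 160, 2.0 / 512)),
    "test_doubled": ((320, 320, 512), (6.0 / 320, 6.0 / 320, 2.0 / 512)),
}


@dataclass
class CapDruse:
    """Spherical-cap druse: en-face center, base radius and peak height (mm)."""

    center_mm: tuple[float, float]
    radius_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("cap radius and height must be positive")

    @property
    def sphere_radius_mm(self) -> float:
        a, h = self.radius_mm, self.height_mm
        return (a * a + h * h) / (2.0 * h)

    @property
    def analytic_area_mm2(self) -> float:
        return float(np.pi * self.radius_mm**2)

    @property
    def analytic_volume_mm3(self) -> float:
        a, h = self.radius_mm, self.height_mm
        return float(np.pi * h * (3 * a * a + h * h) / 6.0)

    def elevation_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cap height (mm) at en-face positions; zero outside the footprint."""
        cx, cy = self.center_mm
        d2 = (x - cx) ** 2 + (y - cy) ** 2
        R = self.sphere_radius_mm
        inside = d2 < self.radius_mm**2
        e = np.zeros_like(d2, dtype=float)
        e[inside] = np.sqrt(R * R - d2[inside]) - (R - self.height_mm)
        return e


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = SCAN_GEOMETRIES["test"][0]
    voxel_size_mm: tuple[float, float, float] = SCAN_GEOMETRIES["test"][1]
    druse_list: list[CapDruse] = field(default_factory=list)
    background_intensity: float = 0.2
    druse_intensity_mean: float = 0.8
    druse_intensity_sd: float = 0.0
    noise_sd: float = 0.0
    fovea_center_mm: tuple[float, float] = (3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.druse_list = [
            d if isinstance(d, CapDruse) else CapDruse(*d) for d in self.druse_list
        ]
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if not (0.0 <= self.background_intensity <= 1.0):
            raise ValueError("background_intensity must be in [0, 1]")
        if self.druse_intensity_sd < 0 or self.noise_sd < 0:
            raise ValueError("intensity standard deviations must be non-negative")

    @property
    def field_size_mm(self) -> tuple[float, float]:
        return (
            self.grid_shape[0] * self.voxel_size_mm[0],
            self.grid_shape[1] * self.voxel_size_mm[1],
        )


@dataclass
class PhantomTruth:
    """Closed-form per-druse geometry, reported alongside the phantom."""

    areas_mm2: list[float]
    volumes_mm3: list[float]
    peak_heights_mm: list[float]
    overlapping: bool

    @property
    def total_area_mm2(self) -> float:
        return float(sum(self.areas_mm2))

    @property
    def total_volume_mm3(self) -> float:
        return float(sum(self.volumes_mm3))


def generate_phantom(spec: PhantomSpec) -> tuple[DrusenScanBundle, PhantomTruth]:
    """Voxelize the spec's drusen onto the scan grid.

    The drusen mask contains the voxels whose centers lie below each cap
    surface and above the BM plane (axial index 0 side).  The elevation map
    is the analytic cap height at en-face pixel centers (max over caps where
    footprints overlap).  Raises ``ValueError`` if any cap extends outside
    the scan field.
    """
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.voxel_size_mm
    fx, fy = spec.field_size_mm
    for d in spec.druse_list:
        cx, cy = d.center_mm
        if not (0 <= cx - d.radius_mm and cx + d.radius_mm <= fx
                and 0 <= cy - d.radius_mm and cy + d.radius_mm <= fy):
            raise ValueError(f"druse at {d.center_mm} extends outside the scan field")

    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(x, y, indexing="ij")

    elevation = np.zeros((nx, ny), dtype=float)
    overlap_count = np.zeros((nx, ny), dtype=int)
    for d in spec.druse_list:
        e = d.elevation_at(X, Y)
        overlap_count += e > 0
        np.maximum(elevation, e, out=elevation)
    overlapping = bool(np.any(overlap_count > 1))

    z_centers = (np.arange(nz) + 0.5) * dz
    mask = z_centers[None, None, :] < elevation[:, :, None]

    rng = np.random.default_rng(spec.seed)
    intensity = np.full((nx, ny, nz), spec.background_intensity, dtype=float)
    n_in = int(mask.sum())
    if n_in:
        intensity[mask] = spec.druse_intensity_mean + rng.normal(
            0.0, spec.druse_intensity_sd, size=n_in
        )
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=intensity.shape)

    bundle = DrusenScanBundle(
        drusen_mask=mask,
        elevation_map_mm=elevation,
        intensity_volume=intensity,
        voxel_size_mm=spec.voxel_size_mm,
        fovea_center_mm=spec.fovea_center_mm,
        eye_id="phantom",
        session_date="2000-01-01",
    )
    truth = PhantomTruth(
        areas_mm2=[d.analytic_area_mm2 for d in spec.druse_list],
        volumes_mm3=[d.analytic_volume_mm3 for d in spec.druse_list],
        peak_heights_mm=[d.height_mm for d in spec.druse_list],
        overlapping=overlapping,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Longitudinal cohorts
# ---------------------------------------------------------------------------

#: Baseline (mean, sd) for each feature; cirrus columns mirror internals.
DEFAULT_BASELINE: dict[str, tuple[float, float]] = {
    "n_drusen": (12.0, 6.0),
    "mean_volume": (0.01, 0.006),
    "total_volume": (0.12, 0.01),
    "mean_area": (0.06, 0.03),
    "total_area": (1.6, 0.9),
    "extent_area": (3.5, 1.5),
    "density": (0.45, 0.15),
    "max_height": (0.15, 0.01),
    "avg_slope": (0.30, 0.10),
    "mean_reflectivity": (0.70, 0.08),
    "std_reflectivity": (0.15, 0.05),
    "area_3mm": (1.1, 0.6),
    "area_5mm": (1.4, 0.8),
    "volume_3mm": (0.08, 0.05),
    "volume_5mm": (0.10, 0.07),
}


@dataclass
class DriftSpec:
    """Monthly drift of one feature: population mean slope, between-eye slope
    spread, and per-visit measurement noise."""

    mean: float = 0.0
    eye_sd: float = 0.0
    noise_sd: float = 0.0


#: Growth planted on the volumetric features; eyes differ in growth rate and
#: visits record the latent level with substantial measurement noise.
DEFAULT_DRIFT: dict[str, DriftSpec] = {
    "total_volume": DriftSpec(mean=0.008, eye_sd=0.006, noise_sd=0.08),
    "total_area": DriftSpec(mean=0.03, eye_sd=0.03, noise_sd=0.25),
    "max_height": DriftSpec(mean=0.004, eye_sd=0.002, noise_sd=0.06),
    "mean_reflectivity": DriftSpec(mean=0.0, eye_sd=0.0015, noise_sd=0.01),
    "n_drusen": DriftSpec(mean=0.05, eye_sd=0.1, noise_sd=1.5),
}

#: Log-odds of exudation per month.  Keys are feature names (weights apply
#: to the *latent* feature level, i.e. the disease state before measurement
#: noise), ``"slope:<feature>"`` for the eye's latent monthly drift rate, or
#: ``"intercept"``.  The steep level dependence plus the common upward drift
#: makes risk rise as an eye approaches conversion, so labels are largely a
#: function of the (estimable) latent state rather than Bernoulli timing.
DEFAULT_HAZARD: dict[str, float] = {
    "intercept": -60.0,
    "total_volume": 140.0,
    "max_height": 25.0,
    "slope:total_volume": 900.0,
}


@dataclass
class CohortSpec:
    n_eyes: int = 200
    months: int = 24
    visit_interval_months: float = 1.0
    irregular: bool = False
    baseline_feature_distribution: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE)
    )
    drift_model: dict[str, DriftSpec] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    hazard_coefficients: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HAZARD))
    missing_demographics: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_eyes < 0:
            raise ValueError("n_eyes must be non-negative")
        if self.months <= 0 or self.visit_interval_months <= 0:
            raise ValueError("months and visit_interval_months must be positive")
        unknown = set(self.baseline_feature_distribution) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown features in baseline distribution: {unknown}")


def _repair_invariants(values: dict[str, float]) -> dict[str, float]:
    """Clamp a raw feature draw onto the feature-vector invariant set."""
    v = dict(values)
    for name in FEATURE_NAMES:
        v[name] = max(0.0, v.get(name, 0.0))
    v["n_drusen"] = float(max(1, round(v["n_drusen"])))
    v["area_5mm"] = min(v["area_5mm"], v["total_area"])
    v["area_3mm"] = min(v["area_3mm"], v["area_5mm"])
    v["volume_5mm"] = min(v["volume_5mm"], v["total_volume"])
    v["volume_3mm"] = min(v["volume_3mm"], v["volume_5mm"])
    v["extent_area"] = max(v["extent_area"], v["total_area"], 1e-6)
    v["density"] = v["total_area"] / v["extent_area"] if v["total_area"] > 0 else 1e-3
    v["mean_volume"] = v["total_volume"] / v["n_drusen"]
    v["mean_area"] = v["total_area"] / v["n_drusen"]
    for cirrus, internal in CIRRUS_TO_INTERNAL.items():
        v[cirrus] = v[internal]
    return v


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(spec: CohortSpec) -> tuple[list[EyeHistory], pd.DataFrame]:
    """Simulate ``spec.n_eyes`` eyes over ``spec.months`` months.

    Per eye: visits at (ir)regular intervals carry drifting features; in each
    inter-visit interval an exudation event is drawn from a discrete-time
    logistic hazard evaluated on the interval-start features (scaled to the
    interval length).  After an event the eye contributes no further dry
    observations; its event month is the end of the interval (detection at
    the next scheduled contact).  Eyes without an event are censored at
    study end.

    Returns the eye histories and a ground-truth event table with one row
    per eye (``eye_id, patient_id, event_month, progressed, latent slopes``).
    """
    rng = np.random.default_rng(spec.seed)
    histories: list[EyeHistory] = []
    truth_rows: list[dict] = []

    slope_features = sorted(spec.drift_model)
    for i in range(spec.n_eyes):
        patient_id = f"P{i:04d}"
        eye_id = f"{patient_id}_OD"

        # demographics
        age0 = rng.normal(78.0 * 12, 8.0 * 12)
        gender = GENDER_LEVELS[int(rng.random() < 0.40)]
        race = RACE_LEVELS[rng.choice(len(RACE_LEVELS), p=[0.92, 0.03, 0.03, 0.01, 0.01])]
        smoking = SMOKING_LEVELS[rng.choice(3, p=[0.41, 0.48, 0.11])]
        va0 = rng.normal(76.0, 13.0)

        baseline = {
            name: rng.normal(mu, sd)
            for name, (mu, sd) in spec.baseline_feature_distribution.items()
        }
        slopes = {
            name: rng.normal(d.mean, d.eye_sd) for name, d in spec.drift_model.items()
        }

        # visit schedule: starts at month 0, ends strictly before study end
        times: list[float] = []
        t = 0.0
        while t < spec.months:
            times.append(t)
            if spec.irregular:
                t += rng.gamma(shape=2.0, scale=spec.visit_interval_months / 2.0) + 0.05
            else:
                t += spec.visit_interval_months
        times_arr = np.array(times)

        # latent disease trajectory (drives the hazard) and its noisy
        # measurements (what the visit records carry)
        latent_values: list[dict[str, float]] = []
        visit_values: list[dict[str, float]] = []
        for tm in times_arr:
            latent = {
                name: b + slopes.get(name, 0.0) * tm for name, b in baseline.items()
            }
            raw = {
                name: val
                + rng.normal(0.0, spec.drift_model.get(name, DriftSpec()).noise_sd)
                for name, val in latent.items()
            }
            latent_values.append(latent)
            visit_values.append(_repair_invariants(raw))

        # event draw per inter-visit interval (last interval runs to study end)
        event_month: float | None = None
        for j, tm in enumerate(times_arr):
            nxt = times_arr[j + 1] if j + 1 < len(times_arr) else float(spec.months)
            delta = nxt - tm
            eta = spec.hazard_coefficients.get("intercept", 0.0)
            for key, w in spec.hazard_coefficients.items():
                if key == "intercept":
                    continue
                if key.startswith("slope:"):
                    eta += w * slopes.get(key[len("slope:"):], 0.0)
                else:
                    eta += w * latent_values[j].get(key, 0.0)
            p_month = _logistic(eta)
            p_interval = 1.0 - (1.0 - p_month) ** delta
            if rng.random() < p_interval:
                event_month = float(min(nxt, spec.months))
                break

        n_dry = int(np.sum(times_arr < (event_month if event_month is not None else np.inf)))
        visits = []
        for j in range(n_dry):
            tm = float(times_arr[j])
            visits.append(
                VisitRecord(
                    patient_id=patient_id,
                    eye_id=eye_id,
                    month=tm,
                    age_months=age0 + tm,
                    gender=None if "gender" in spec.missing_demographics else gender,
                    race=None if "race" in spec.missing_demographics else race,
                    smoking_status=None
                    if "smoking_status" in spec.missing_demographics
                    else smoking,
                    visual_acuity=va0 - 0.05 * tm + rng.normal(0.0, 1.5),
                    features=ImagingFeatureVector(
                        **visit_values[j], cirrus_mirrored=True
                    ),
                )
            )
        histories.append(
            EyeHistory(
                eye_id=eye_id,
                patient_id=patient_id,
                visits=visits,
                event_month=event_month,
            )
        )
        row = {
            "eye_id": eye_id,
            "patient_id": patient_id,
            "event_month": event_month if event_month is not None else np.nan,
            "progressed": event_month is not None,
        }
        row.update({f"slope_{n}": slopes[n] for n in slope_features})
        truth_rows.append(row)

    columns = ["eye_id", "patient_id", "event_month", "progressed"] + [
        f"slope_{n}" for n in slope_features
    ]
    truth = pd.DataFrame(truth_rows, columns=columns)
    return histories, truth
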