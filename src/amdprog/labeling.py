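"""Longitudinal visit records and per-horizon outcome labeling.

Each dry (non-exudative) observation of an eye is labeled, for every
prediction horizon ``k`` in months, as:

* ``1`` (progressor) — a first exudation/treatment event occurred within
  ``k`` months of the observation (ties at exactly ``k`` count as within);
* ``0`` (non-progressor) — no event within ``k`` months AND a later dry
  observation of the same eye exists strictly beyond ``obs_month + k``,
  certifying the negative outcome;
* censored — neither can be certified (end of study / follow-up reached, or
  an event occurred after ``k`` months without a certifying dry visit).

Censored observations are excluded from training and evaluation at that
horizon.  Post-event data never enters a labeled sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from amdprog.bundles import ImagingFeatureVector

logger = logging.getLogger(__name__)

#: Default prediction horizons in months.
DEFAULT_HORIZONS: tuple[int, ...] = (3, 6, 9, 12, 15, 18, 21)

#: Sentinel label for censored observations (kept distinct from the padding
#: label 2 used at the model level).
CENSORED: int = -1

GENDER_LEVELS = ("female", "male")
RACE_LEVELS = ("white", "black", "asian", "native", "pacific")
SMOKING_LEVELS = ("never", "previous", "current")


@dataclass
class VisitRecord:
    """One dated observation of one eye."""

    patient_id: str
    eye_id: str
    month: float  # months from baseline (fractional allowed)
    age_months: float
    gender: str | None
    race: str | None
    smoking_status: str | None
    visual_acuity: float
    features: ImagingFeatureVector
    dx_status: str = "dry"  # "dry" | "exudative"
    treated: bool = False

    @property
    def is_event_marker(self) -> bool:
        return self.dx_status == "exudative" or self.treated


@dataclass
class EyeHistory:
    """Ordered per-eye series of dry visits plus the (optional) event time."""

    eye_id: str
    patient_id: str
    visits: list[VisitRecord] = field(default_factory=list)
    event_month: float | None = None

    def __post_init__(self) -> None:
        self.visits = sorted(self.visits, key=lambda v: v.month)
        months = [v.month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise ValueError(f"visit months not strictly increasing for {self.eye_id}")
        for v in self.visits:
            if v.is_event_marker:
                raise ValueError("event-marker visits cannot enter an EyeHistory")
            if self.event_month is not None and v.month >= self.event_month:
                raise ValueError(
                    f"dry visit at month {v.month} not before event at {self.event_month}"
                )

    @property
    def last_dry_followup_month(self) -> float | None:
        return self.visits[-1].month if self.visits else None

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def progressed(self) -> bool:
        return self.event_month is not None


@dataclass
class LabeledSequence:
    """Per-eye ordered feature series with per-horizon outcome labels.

    ``labels[i, j]`` is the outcome of visit ``i`` at horizon ``horizons[j]``:
    1, 0, or :data:`CENSORED`.
    """

    eye_id: str
    patient_id: str
    visits: list[VisitRecord]
    months: np.ndarray  # (n,)
    horizons: tuple[int, ...]
    labels: np.ndarray  # (n, n_horizons) int

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def label_at(self, visit_index: int, horizon: int) -> int:
        return int(self.labels[visit_index, self.horizons.index(horizon)])


def label_observation(history: EyeHistory, obs_month: float, horizon_k: float) -> int:
    """Label one dry observation of ``history`` at horizon ``horizon_k`` months.

    Returns 1 (progressor), 0 (non-progressor) or :data:`CENSORED`.
    """
    if history.event_month is not None and obs_month >= history.event_month:
        raise ValueError("observation at or after the exudation event is invalid")
    months = [v.month for v in history.visits]
    if not any(np.isclose(obs_month, m) for m in months):
        raise ValueError(f"month {obs_month} is not a dry observation of {history.eye_id}")

    if history.event_month is not None and history.event_month - obs_month <= horizon_k:
        return 1
    # Negative outcome requires a certifying dry visit strictly beyond obs + k.
    if any(m > obs_month + horizon_k for m in months):
        return 0
    return CENSORED


def build_labeled_sequences(
    histories: list[EyeHistory],
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
) -> tuple[list[LabeledSequence], dict[int, dict[str, int]]]:
    """Label every dry observation of every eye for every horizon.

    Eyes with no dry observations contribute nothing (logged and skipped).
    Returns the labeled sequences and per-horizon counts of
    ``{"progressor", "non_progressor", "censored"}``.
    """
    horizons = tuple(horizons)
    sequences: list[LabeledSequence] = []
    counts = {k: {"progressor": 0, "non_progressor": 0, "censored": 0} for k in horizons}
    for history in histories:
        if history.n_visits == 0:
            logger.info("eye %s has no dry observations; dropped", history.eye_id)
            continue
        months = np.array([v.month for v in history.visits], dtype=float)
        labels = np.empty((len(months), len(horizons)), dtype=int)
        for i, m in enumerate(months):
            for j, k in enumerate(horizons):
                lab = label_observation(history, m, k)
                labels[i, j] = lab
                key = {1: "progressor", 0: "non_progressor", CENSORED: "censored"}[lab]
                counts[k][key] += 1
        sequences.append(
            LabeledSequence(
                eye_id=history.eye_id,
                patient_id=history.patient_id,
                visits=list(history.visits),
                months=months,
                horizons=horizons,
                labels=labels,
            )
        )
    return sequences, counts


def days_to_months(days: float) -> float:
    """Convert calendar days to fractional months (mean month length)."""
    return days / 30.44


def filter_signal_strength(rows, min_strength: float = 7.0, column: str = "signal_strength"):
    """Utility flag filter: drop table rows whose scan quality is below cutoff.

    ``rows`` is a pandas DataFrame; rows lacking the column pass through.
    """
    if column not in rows.columns:
        return rows
    keep = rows[column].isna() | (rows[column] >= min_strength)
    return rows[keep]
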