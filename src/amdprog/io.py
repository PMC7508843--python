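"""Canonical tabular formats: the visit-table CSV, labeled long-format CSV
and count summaries.

Visit CSV schema (UTF-8, header required): ``patient_id, eye_id, month`` (or
``date`` in ISO-8601, auto-detected and converted to fractional months from
each eye's first visit), ``age_months, gender, race, smoking_status,
visual_acuity, dx_status, treated`` plus the 21 feature columns.  Event rows
carry ``dx_status=exudative`` / ``treated=1`` and may leave features empty.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from amdprog.bundles import FEATURE_NAMES, ImagingFeatureVector
from amdprog.labeling import EyeHistory, LabeledSequence, VisitRecord, days_to_months

REQUIRED_COLUMNS = ("patient_id", "eye_id")
DEMOGRAPHIC_COLUMNS = (
    "age_months",
    "gender",
    "race",
    "smoking_status",
    "visual_acuity",
)


class SchemaError(ValueError):
    """Raised when a table violates the canonical schema."""


def write_visit_csv(histories: list[EyeHistory], path: str | Path) -> Path:
    """Serialize eye histories (dry visits + event markers) to CSV."""
    rows = []
    for h in histories:
        for v in h.visits:
            row = {
                "patient_id": v.patient_id,
                "eye_id": v.eye_id,
                "month": v.month,
                "age_months": v.age_months,
                "gender": v.gender or "",
                "race": v.race or "",
                "smoking_status": v.smoking_status or "",
                "visual_acuity": v.visual_acuity,
                "dx_status": v.dx_status,
                "treated": int(v.treated),
            }
            row.update(v.features.as_dict())
            rows.append(row)
        if h.event_month is not None:
            rows.append(
                {
                    "patient_id": h.patient_id,
                    "eye_id": h.eye_id,
                    "month": h.event_month,
                    "dx_status": "exudative",
                    "treated": 1,
                }
            )
    columns = (
        ["patient_id", "eye_id", "month"]
        + list(DEMOGRAPHIC_COLUMNS)
        + ["dx_status", "treated"]
        + list(FEATURE_NAMES)
    )
    df = pd.DataFrame(rows, columns=columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def _months_column(df: pd.DataFrame) -> pd.Series:
    if "month" in df.columns and "date" in df.columns:
        raise SchemaError("visit table must carry either 'month' or 'date', not both")
    if "month" in df.columns:
        return pd.to_numeric(df["month"], errors="raise")
    if "date" in df.columns:
        dates = pd.to_datetime(df["date"], format="ISO8601")
        baseline = dates.groupby(df["eye_id"]).transform("min")
        return (dates - baseline).dt.days.map(days_to_months)
    raise SchemaError("visit table missing required column: month (or date)")


def read_visit_csv(path: str | Path) -> list[EyeHistory]:
    """Parse the canonical visit CSV back into eye histories.

    Raises :class:`SchemaError` naming any missing required column.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "eye_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"visit table missing required column(s): {', '.join(missing)}")
    df = df.copy()
    df["_month"] = _months_column(df)

    histories = []
    for eye_id, group in df.groupby("eye_id", sort=True):
        group = group.sort_values("_month")
        patient_id = str(group["patient_id"].iloc[0])
        event_month = None
        visits = []
        for _, row in group.iterrows():
            dx = str(row.get("dx_status", "dry") or "dry")
            treated = bool(int(row["treated"])) if not pd.isna(row.get("treated")) else False
            if dx == "exudative" or treated:
                m = float(row["_month"])
                event_month = m if event_month is None else min(event_month, m)
                continue
            feats = {}
            for name in FEATURE_NAMES:
                val = row.get(name, 0.0)
                feats[name] = 0.0 if pd.isna(val) else float(val)

            def _cat(name: str) -> str | None:
                val = row.get(name)
                if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                    return None
                return str(val)

            visits.append(
                VisitRecord(
                    patient_id=patient_id,
                    eye_id=str(eye_id),
                    month=float(row["_month"]),
                    age_months=float(row.get("age_months", np.nan))
                    if not pd.isna(row.get("age_months"))
                    else 0.0,
                    gender=_cat("gender"),
                    race=_cat("race"),
                    smoking_status=_cat("smoking_status"),
                    visual_acuity=float(row.get("visual_acuity", np.nan))
                    if not pd.isna(row.get("visual_acuity"))
                    else 0.0,
                    features=ImagingFeatureVector(**feats),
                )
            )
        # visits recorded at or after the event month are post-event data
        if event_month is not None:
            visits = [v for v in visits if v.month < event_month]
        histories.append(
            EyeHistory(
                eye_id=str(eye_id),
                patient_id=patient_id,
                visits=visits,
                event_month=event_month,
            )
        )
    return histories


def write_labeled_csv(
    sequences: list[LabeledSequence], path: str | Path
) -> Path:
    """Long-format labels: one row per (observation, horizon)."""
    rows = []
    for seq in sequences:
        for i, month in enumerate(seq.months):
            for j, k in enumerate(seq.horizons):
                rows.append(
                    {
                        "eye_id": seq.eye_id,
                        "patient_id": seq.patient_id,
                        "obs_month": float(month),
                        "horizon": int(k),
                        "label": int(seq.labels[i, j]),
                    }
                )
    df = pd.DataFrame(rows, columns=["eye_id", "patient_id", "obs_month", "horizon", "label"])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def write_counts_json(counts: dict[int, dict[str, int]], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps({str(k): v for k, v in counts.items()}, indent=2))
    return path
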