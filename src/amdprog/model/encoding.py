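"""Visit-level feature encoding for the sequence model.

Continuous features (the 21 imaging biomarkers, age and visual acuity) are
z-scored with statistics fitted on the *training split only*.  The three
categorical demographics (gender, race, smoking status) are one-hot encoded
with an explicit ``missing`` level; unseen levels at transform time map to
``missing`` with a warning.  The encoding is invertible for categoricals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from amdprog.bundles import FEATURE_NAMES
from amdprog.labeling import (
    GENDER_LEVELS,
    RACE_LEVELS,
    SMOKING_LEVELS,
    LabeledSequence,
    VisitRecord,
)

MISSING = "missing"

CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": GENDER_LEVELS,
    "race": RACE_LEVELS,
    "smoking_status": SMOKING_LEVELS,
}

CONTINUOUS_NAMES: tuple[str, ...] = FEATURE_NAMES + ("age_months", "visual_acuity")


@dataclass
class EncodedSequence:
    """One eye's encoded visit matrix with per-visit supervision targets.

    ``y`` uses 0/1 outcome labels; unsupervised (censored) positions carry
    the zero-weight label 2 so they contribute features but no loss.
    """

    eye_id: str
    patient_id: str
    X: np.ndarray  # (n, D)
    y: np.ndarray  # (n,) int in {0, 1, 2}
    months: np.ndarray  # (n,)


@dataclass
class FeatureSchema:
    """Fitted encoder mapping a :class:`VisitRecord` to a flat vector."""

    mean: np.ndarray | None = None
    std: np.ndarray | None = None
    categorical_levels: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(CATEGORICAL_LEVELS)
    )

    @property
    def dim(self) -> int:
        cat = sum(len(levels) + 1 for levels in self.categorical_levels.values())
        return len(CONTINUOUS_NAMES) + cat

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def _continuous(self, visit: VisitRecord) -> np.ndarray:
        vals = list(visit.features.as_array())
        vals += [visit.age_months, visit.visual_acuity]
        return np.asarray(vals, dtype=float)

    def fit(self, visits: list[VisitRecord]) -> "FeatureSchema":
        """Fit z-scoring statistics on the training visits."""
        if not visits:
            raise ValueError("cannot fit schema on an empty visit list")
        raw = np.stack([self._continuous(v) for v in visits])
        self.mean = raw.mean(axis=0)
        std = raw.std(axis=0, ddof=0)
        std[std == 0] = 1.0  # constant columns pass through centered
        self.std = std
        return self

    def _encode_categorical(self, name: str, value: str | None) -> np.ndarray:
        levels = self.categorical_levels[name]
        onehot = np.zeros(len(levels) + 1)
        if value is None:
            onehot[-1] = 1.0
        elif value in levels:
            onehot[levels.index(value)] = 1.0
        else:
            warnings.warn(
                f"unseen {name} level {value!r}; mapped to missing", stacklevel=2
            )
            onehot[-1] = 1.0
        return onehot

    def transform(self, visit: VisitRecord) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("schema must be fitted before transform")
        parts = [(self._continuous(visit) - self.mean) / self.std]
        for name in self.categorical_levels:
            parts.append(self._encode_categorical(name, getattr(visit, name)))
        x = np.concatenate(parts)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite encoded value for visit of {visit.eye_id}")
        return x

    def decode_categoricals(self, x: np.ndarray) -> dict[str, str | None]:
        """Recover the categorical levels from an encoded vector."""
        out: dict[str, str | None] = {}
        offset = len(CONTINUOUS_NAMES)
        for name, levels in self.categorical_levels.items():
            width = len(levels) + 1
            block = x[offset:offset + width]
            idx = int(np.argmax(block))
            out[name] = None if idx == len(levels) else levels[idx]
            offset += width
        return out

    def decode_continuous(self, x: np.ndarray) -> dict[str, float]:
        vals = x[: len(CONTINUOUS_NAMES)] * self.std + self.mean
        return dict(zip(CONTINUOUS_NAMES, vals.tolist()))


def encode_sequences(
    sequences: list[LabeledSequence],
    horizon: int,
    schema: FeatureSchema,
) -> list[EncodedSequence]:
    """Encode labeled sequences for one horizon.

    Outcome labels stay 0/1; censored positions get the zero-weight label 2
    (their features remain visible to later timesteps, but they carry no
    supervision).
    """
    out = []
    for seq in sequences:
        j = seq.horizons.index(horizon)
        y = seq.labels[:, j].copy()
        y[y < 0] = 2
        X = np.stack([schema.transform(v) for v in seq.visits])
        out.append(
            EncodedSequence(
                eye_id=seq.eye_id,
                patient_id=seq.patient_id,
                X=X,
                y=y.astype(int),
                months=seq.months.copy(),
            )
        )
    return out
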