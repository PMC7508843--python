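"""Evaluation protocols: patient-level stratified CV, visit-variant,
external-cohort testing and fixed-first-visits sensitivity/specificity.

All protocols enforce patient-level separation: every scored observation is
produced by a model whose training fold excluded that observation's patient,
and the audit trail needed to assert this programmatically is kept on the
result objects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from amdprog.labeling import CENSORED, DEFAULT_HORIZONS, LabeledSequence
from amdprog.model.encoding import EncodedSequence, FeatureSchema, encode_sequences
from amdprog.model.train import ModelConfig, TrainedModel, train_ensemble


# ---------------------------------------------------------------------------
# folds and basic metrics
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Disjoint patient-id sets with per-fold progressor proportions."""

    folds: list[frozenset[str]]
    progressor_proportion: list[float]

    @property
    def k(self) -> int:
        return len(self.folds)

    def fold_of(self, patient_id: str) -> int:
        for i, f in enumerate(self.folds):
            if patient_id in f:
                return i
        raise KeyError(patient_id)

    def train_patients(self, fold: int) -> frozenset[str]:
        out: set[str] = set()
        for i, f in enumerate(self.folds):
            if i != fold:
                out |= f
        return frozenset(out)


def make_folds(sequences: list[LabeledSequence], k: int = 10, seed: int = 0) -> FoldPlan:
    """Patient-level folds stratified by progressor status.

    A patient is a progressor if any of their eyes has a progressor label at
    any horizon.  Raises when fewer than ``k`` progressor patients exist.
    """
    status: dict[str, int] = {}
    for s in sequences:
        progressed = int(np.any(s.labels == 1))
        status[s.patient_id] = max(status.get(s.patient_id, 0), progressed)
    patients = sorted(status)
    y = np.array([status[p] for p in patients])
    if int(y.sum()) < k:
        raise ValueError(f"need at least {k} progressor patients, have {int(y.sum())}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[frozenset[str]] = []
    props: list[float] = []
    for _, test_idx in skf.split(np.zeros(len(patients)), y):
        fold_patients = frozenset(patients[i] for i in test_idx)
        folds.append(fold_patients)
        props.append(float(y[test_idx].mean()))
    return FoldPlan(folds=folds, progressor_proportion=props)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal AUC (equals pairwise concordance); NaN if single-class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pr_curve(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall curve; baseline precision equals positive prevalence."""
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    return precision, recall, thresholds


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Operating threshold maximizing Youden's J = sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(labels, scores)
    j = tpr - fpr
    return float(thr[int(np.argmax(j))])


# ---------------------------------------------------------------------------
# cross-validated scoring
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Held-out per-observation scores for one horizon, with audit trail."""

    horizon: int
    fold_plan: FoldPlan
    models: list[TrainedModel]
    scores: pd.DataFrame  # eye_id, patient_id, fold, visit_index, month, label, score
    encoded_by_fold: list[tuple[list[EncodedSequence], list[EncodedSequence]]] = field(
        repr=False, default_factory=list
    )

    def fold_aucs(self, exclude_censored: bool = True) -> list[float]:
        out = []
        for fold in range(self.fold_plan.k):
            df = self.scores[self.scores["fold"] == fold]
            if exclude_censored:
                df = df[df["label"] != CENSORED]
            out.append(roc_auc(df["score"].to_numpy(), df["label"].to_numpy()))
        return out

    def pooled_auc(self) -> float:
        df = self.scores[self.scores["label"] != CENSORED]
        return roc_auc(df["score"].to_numpy(), df["label"].to_numpy())


def _fold_config(config: ModelConfig, horizon: int, fold: int) -> ModelConfig:
    # fan the experiment seed out so folds and horizons are decorrelated
    seed = int(np.random.SeedSequence([config.seed, horizon, fold]).generate_state(1)[0])
    return dataclasses.replace(config, seed=seed, horizon_k=horizon)


def run_cv(
    sequences: list[LabeledSequence],
    horizon: int,
    config: ModelConfig,
    k: int = 10,
    seed: int = 0,
    fold_plan: FoldPlan | None = None,
) -> CVResult:
    """Train one model per fold and score every held-out observation.

    The feature schema (z-scoring statistics) is refitted on each fold's
    training visits.  Censored observations are scored too (rows kept with
    ``label = -1``) but are excluded from AUC computations.
    """
    plan = fold_plan if fold_plan is not None else make_folds(sequences, k=k, seed=seed)
    models: list[TrainedModel] = []
    encoded_by_fold = []
    rows = []
    for fold in range(plan.k):
        test_patients = plan.folds[fold]
        train_seqs = [s for s in sequences if s.patient_id not in test_patients]
        test_seqs = [s for s in sequences if s.patient_id in test_patients]
        schema = FeatureSchema().fit([v for s in train_seqs for v in s.visits])
        enc_train = encode_sequences(train_seqs, horizon, schema)
        enc_test = encode_sequences(test_seqs, horizon, schema)
        trained = train_ensemble(enc_train, _fold_config(config, horizon, fold), schema=schema)
        models.append(trained)
        encoded_by_fold.append((enc_train, enc_test))
        for seq, enc in zip(test_seqs, enc_test):
            visit_scores = trained.predict_sequence(enc.X)
            j = seq.horizons.index(horizon)
            for i in range(seq.n_visits):
                rows.append(
                    {
                        "eye_id": seq.eye_id,
                        "patient_id": seq.patient_id,
                        "fold": fold,
                        "visit_index": i,
                        "month": float(seq.months[i]),
                        "label": int(seq.labels[i, j]),
                        "score": float(visit_scores[i]),
                    }
                )
    scores = pd.DataFrame(
        rows,
        columns=["eye_id", "patient_id", "fold", "visit_index", "month", "label", "score"],
    )
    return CVResult(
        horizon=horizon,
        fold_plan=plan,
        models=models,
        scores=scores,
        encoded_by_fold=encoded_by_fold,
    )


def audit_no_leakage(result: CVResult) -> None:
    """Assert that no scored observation's patient was in its training fold."""
    for fold in range(result.fold_plan.k):
        train_patients = result.fold_plan.train_patients(fold)
        scored = set(result.scores.loc[result.scores["fold"] == fold, "patient_id"])
        overlap = scored & set(train_patients)
        if overlap:
            raise AssertionError(f"leakage: patients {sorted(overlap)} scored in fold {fold}")
        if not scored <= set(result.fold_plan.folds[fold]):
            raise AssertionError(f"fold {fold} scored patients outside its test set")


# ---------------------------------------------------------------------------
# the four evaluation settings
# ---------------------------------------------------------------------------

def overall_cv(
    sequences: list[LabeledSequence],
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    config: ModelConfig = None,
    k: int = 10,
    seed: int = 0,
) -> dict[int, dict]:
    """Setting 1: every non-censored observation scored once by the model
    that held its patient out; per-horizon fold-mean AUC +/- std, pooled AUC
    and PR curve."""
    config = config or ModelConfig()
    plan = make_folds(sequences, k=k, seed=seed)
    report: dict[int, dict] = {}
    for horizon in horizons:
        result = run_cv(sequences, horizon, config, k=k, seed=seed, fold_plan=plan)
        audit_no_leakage(result)
        fold_aucs = np.array(result.fold_aucs())
        valid = fold_aucs[~np.isnan(fold_aucs)]
        df = result.scores[result.scores["label"] != CENSORED]
        precision, recall, _ = pr_curve(df["score"].to_numpy(), df["label"].to_numpy())
        report[horizon] = {
            "fold_aucs": fold_aucs.tolist(),
            "mean_auc": float(valid.mean()) if valid.size else float("nan"),
            "std_auc": float(valid.std(ddof=0)) if valid.size else float("nan"),
            "pooled_auc": result.pooled_auc(),
            "prevalence": float((df["label"] == 1).mean()),
            "pr_precision": precision.tolist(),
            "pr_recall": recall.tolist(),
            "cv_result": result,
        }
    return report


def visit_variant(
    result: CVResult,
    n_visits: tuple[int, ...] = (2, 4, 6, 8, 10, 12, 14, 16),
) -> pd.DataFrame:
    """Setting 2: AUC as a function of the number of visits used.

    For each v, eyes with at least v visits are scored at their v-th visit
    (1 current + v-1 historic; the per-visit score at index v-1 uses exactly
    the first v visits).  Strata with a single outcome class report NaN.
    """
    rows = []
    for v in n_visits:
        df = result.scores[
            (result.scores["visit_index"] == v - 1) & (result.scores["label"] != CENSORED)
        ]
        fold_aucs = []
        for fold in range(result.fold_plan.k):
            dff = df[df["fold"] == fold]
            fold_aucs.append(roc_auc(dff["score"].to_numpy(), dff["label"].to_numpy()))
        fold_aucs = np.array(fold_aucs)
        valid = fold_aucs[~np.isnan(fold_aucs)]
        rows.append(
            {
                "n_visits": v,
                "n_obs": len(df),
                "pooled_auc": roc_auc(df["score"].to_numpy(), df["label"].to_numpy()),
                "mean_auc": float(valid.mean()) if valid.size else float("nan"),
                "std_auc": float(valid.std(ddof=0)) if valid.size else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def external_test(
    train_sequences: list[LabeledSequence],
    test_sequences: list[LabeledSequence],
    horizons: tuple[int, ...] = DEFAULT_HORIZONS,
    config: ModelConfig = None,
) -> dict[int, dict]:
    """Setting 3: train on cohort A, score cohort B with no refitting.

    The encoder schema (z-scoring statistics, categorical levels) comes from
    A; demographics absent in B map to the explicit missing level.
    """
    config = config or ModelConfig()
    report: dict[int, dict] = {}
    for horizon in horizons:
        schema = FeatureSchema().fit([v for s in train_sequences for v in s.visits])
        enc_train = encode_sequences(train_sequences, horizon, schema)
        trained = train_ensemble(enc_train, dataclasses.replace(config, horizon_k=horizon),
                                 schema=schema)
        enc_test = encode_sequences(test_sequences, horizon, schema)
        scores, labels = [], []
        for seq, enc in zip(test_sequences, enc_test):
            visit_scores = trained.predict_sequence(enc.X)
            j = seq.horizons.index(horizon)
            for i in range(seq.n_visits):
                lab = int(seq.labels[i, j])
                if lab != CENSORED:
                    scores.append(float(visit_scores[i]))
                    labels.append(lab)
        report[horizon] = {
            "auc": roc_auc(np.array(scores), np.array(labels)),
            "n_obs": len(labels),
            "model": trained,
        }
    return report


def patient_level(
    result: CVResult,
    n_first: int = 5,
) -> dict:
    """Setting 4: one prediction per eye from its first ``n_first`` visits.

    Eyes with fewer visits use all they have.  The operating threshold is
    chosen per fold by Youden's J on the training eyes' predictions (same
    first-visits protocol), then applied to the held-out eyes; sensitivity
    and specificity are pooled over folds.
    """
    tp = fp = tn = fn = 0
    per_fold = []
    horizon = result.horizon
    for fold in range(result.fold_plan.k):
        enc_train, enc_test = result.encoded_by_fold[fold]
        model = result.models[fold]

        def _first_visit_scores(encoded: list[EncodedSequence]):
            scores, labels = [], []
            for enc in encoded:
                m = min(n_first, enc.X.shape[0])
                lab = int(enc.y[m - 1])
                if lab == 2:  # unsupervised (censored) at that visit
                    continue
                scores.append(model.predict(enc.X[:m]))
                labels.append(lab)
            return np.array(scores), np.array(labels)

        s_train, y_train = _first_visit_scores(enc_train)
        s_test, y_test = _first_visit_scores(enc_test)
        if len(np.unique(y_train)) < 2 or len(s_test) == 0:
            continue
        thr = youden_threshold(s_train, y_train)
        pred = s_test >= thr
        tp += int(np.sum(pred & (y_test == 1)))
        fn += int(np.sum(~pred & (y_test == 1)))
        fp += int(np.sum(pred & (y_test == 0)))
        tn += int(np.sum(~pred & (y_test == 0)))
        per_fold.append({"fold": fold, "threshold": thr, "n_test": len(s_test)})
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "horizon": horizon,
        "n_first": n_first,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "per_fold": per_fold,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


def save_roc_pr_figure(scores: np.ndarray, labels: np.ndarray, path) -> None:
    """Write a two-panel ROC / precision-recall figure for one score set."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve as _roc_curve

    fpr, tpr, _ = _roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    prevalence = float(np.mean(np.asarray(labels) == 1))
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(fpr, tpr)
    ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax1.set_xlabel("1 - specificity")
    ax1.set_ylabel("sensitivity")
    ax1.set_title(f"ROC (AUC = {roc_auc(scores, labels):.3f})")
    ax2.plot(recall, precision)
    ax2.axhline(prevalence, color="k", ls=":", lw=0.8)
    ax2.set_xlabel("recall")
    ax2.set_ylabel("precision")
    ax2.set_title("Precision-recall")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def shuffled_label_control(
    sequences: list[LabeledSequence],
    horizon: int,
    config: ModelConfig,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> float:
    """Permutation null: shuffle supervised labels across all observations,
    train on an eye-level split and return the pooled held-out AUC (expected
    to be near 0.5)."""
    rng = np.random.default_rng(seed)
    schema = FeatureSchema().fit([v for s in sequences for v in s.visits])
    encoded = encode_sequences(sequences, horizon, schema)
    supervised = [
        (i, t) for i, e in enumerate(encoded) for t in range(len(e.y)) if e.y[t] != 2
    ]
    labels = np.array([encoded[i].y[t] for i, t in supervised])
    shuffled = labels[rng.permutation(len(labels))]
    for (i, t), lab in zip(supervised, shuffled):
        encoded[i].y[t] = lab
    order = rng.permutation(len(encoded))
    n_test = max(1, int(round(test_fraction * len(encoded))))
    test = [encoded[i] for i in order[:n_test]]
    train_seqs = [encoded[i] for i in order[n_test:]]
    trained = train_ensemble(train_seqs, dataclasses.replace(config, horizon_k=horizon),
                             schema=schema)
    scores, labs = [], []
    for e in test:
        keep = e.y != 2
        if not np.any(keep):
            continue
        scores.extend(trained.predict_sequence(e.X)[keep].tolist())
        labs.extend(e.y[keep].tolist())
    return roc_auc(np.array(scores), np.array(labs))


# ---------------------------------------------------------------------------
# reference baseline for signal-recovery checks
# ---------------------------------------------------------------------------

def logistic_last_visit_cv(
    sequences: list[LabeledSequence],
    horizon: int,
    fold_plan: FoldPlan,
) -> dict:
    """L2 logistic regression on each observation's own encoded visit vector
    (no history), under the same patient-level folds.

    Returns ``{"pooled_auc", "fold_aucs", "mean_auc"}`` for comparison with
    the sequence model."""
    from sklearn.linear_model import LogisticRegression

    scores, labels = [], []
    fold_aucs = []
    for fold in range(fold_plan.k):
        test_patients = fold_plan.folds[fold]
        train_seqs = [s for s in sequences if s.patient_id not in test_patients]
        test_seqs = [s for s in sequences if s.patient_id in test_patients]
        schema = FeatureSchema().fit([v for s in train_seqs for v in s.visits])
        enc_train = encode_sequences(train_seqs, horizon, schema)
        enc_test = encode_sequences(test_seqs, horizon, schema)
        X_tr = np.concatenate([e.X[e.y != 2] for e in enc_train])
        y_tr = np.concatenate([e.y[e.y != 2] for e in enc_train])
        clf = LogisticRegression(max_iter=2000).fit(X_tr, y_tr)
        fold_scores, fold_labels = [], []
        for enc in enc_test:
            keep = enc.y != 2
            if not np.any(keep):
                continue
            p = clf.predict_proba(enc.X[keep])[:, 1]
            fold_scores.extend(p.tolist())
            fold_labels.extend(enc.y[keep].tolist())
        fold_aucs.append(roc_auc(np.array(fold_scores), np.array(fold_labels)))
        scores.extend(fold_scores)
        labels.extend(fold_labels)
    valid = np.array([a for a in fold_aucs if not np.isnan(a)])
    return {
        "pooled_auc": roc_auc(np.array(scores), np.array(labels)),
        "fold_aucs": fold_aucs,
        "mean_auc": float(valid.mean()) if valid.size else float("nan"),
    }
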