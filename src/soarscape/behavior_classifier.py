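"""Random-forest classification of flight behavior from movement features.

A supervised random forest maps the six windowed movement features to the
four behavioral categories (perched, gliding, orographic soaring, thermal
soaring).  Training rows are drawn by sampling a fraction of tracking
days per bird (all fixes of a sampled day enter the training set, mirroring
how a human annotator labels whole days of track).  Accuracy is reported
as the out-of-bag (OOB) error: each row is predicted using only the trees
whose bootstrap sample excluded it, together with per-class errors and the
OOB confusion matrix.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from soarscape.synthetic_data import BEHAVIORS
from soarscape.track_features import FEATURE_COLUMNS

#: Fixed label order; argmax vote ties resolve to the earlier label.
LABEL_ORDER = list(BEHAVIORS)


@dataclass
class ClassifierReport:
    """OOB accuracy summary of a fitted behavior forest."""

    oob_error: float
    per_class_error: dict[str, float]
    confusion: pd.DataFrame  # rows = true label, cols = OOB-predicted label
    n_trees: int
    seed: int | None
    n_rows: int = 0
    labels: list[str] = field(default_factory=lambda: list(LABEL_ORDER))

    def to_json(self) -> str:
        return json.dumps(
            {
                "oob_error": self.oob_error,
                "per_class_error": self.per_class_error,
                "confusion": self.confusion.to_dict(),
                "n_trees": self.n_trees,
                "seed": self.seed,
                "n_rows": self.n_rows,
            },
            indent=2,
        )


def sample_training_days(
    fixes: pd.DataFrame, fraction: float = 0.10, seed: int | None = None
) -> dict[str, list]:
    """Per bird, draw ``ceil(fraction * n_days)`` distinct tracking days.

    Returns a mapping bird id -> sorted list of sampled dates.  Birds with
    no days are skipped.  Reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    ts = pd.to_datetime(fixes["timestamp_utc"])
    dates = ts.dt.date
    out: dict[str, list] = {}
    for bird in sorted(fixes["bird_id"].unique()):
        bird_days = sorted(set(dates[fixes["bird_id"] == bird]))
        if not bird_days:
            continue
        k = math.ceil(fraction * len(bird_days))
        chosen = rng.choice(len(bird_days), size=k, replace=False)
        out[bird] = sorted(bird_days[i] for i in chosen)
    return out


def build_training_set(
    features: pd.DataFrame, training_days: dict[str, list]
) -> pd.DataFrame:
    """All feature rows of the sampled bird-days (complete rows only)."""
    dates = pd.to_datetime(features["timestamp_utc"]).dt.date
    mask = np.zeros(len(features), dtype=bool)
    for bird, days in training_days.items():
        mask |= (features["bird_id"] == bird).to_numpy() & dates.isin(days).to_numpy()
    out = features.loc[mask]
    return out.loc[~out[FEATURE_COLUMNS].isna().any(axis=1)].reset_index(drop=True)


def _check_features(features: pd.DataFrame) -> np.ndarray:
    missing_cols = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing_cols:
        raise ValueError(f"feature table missing columns: {missing_cols}")
    X = features[FEATURE_COLUMNS].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(X).all(axis=1))
    if len(bad):
        raise ValueError(f"rows with missing features: {bad.tolist()[:20]}")
    return X


def train(
    training_set: pd.DataFrame,
    label_col: str = "true_label",
    n_trees: int = 500,
    seed: int | None = 0,
    class_weight: dict | None = None,
) -> tuple[RandomForestClassifier, ClassifierReport]:
    """Fit the forest and report out-of-bag accuracy.

    Defaults: 500 trees, sqrt(p) features per split, no class reweighting.
    OOB predictions use only the trees that did not see each row; ties in
    the OOB vote resolve in :data:`LABEL_ORDER`.
    """
    X = _check_features(training_set)
    y = training_set[label_col].to_numpy()
    present = [l for l in LABEL_ORDER if l in set(y)]
    if len(present) < 2:
        raise ValueError("training set must contain at least two classes")

    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        class_weight=class_weight,
        n_jobs=1,
    )
    model.fit(X, y)

    # OOB votes, reordered into the fixed label order for tie-breaking
    votes = model.oob_decision_function_
    order = [list(model.classes_).index(l) for l in present]
    votes = votes[:, order]
    pred = np.array(present)[np.argmax(votes, axis=1)]

    conf = pd.DataFrame(0, index=present, columns=present, dtype=int)
    for t_lab, p_lab in zip(y, pred):
        conf.loc[t_lab, p_lab] += 1
    per_class = {}
    for lab in present:
        total = int(conf.loc[lab].sum())
        per_class[lab] = float((total - conf.loc[lab, lab]) / total) if total else np.nan
    oob_error = float(np.mean(pred != y))
    report = ClassifierReport(
        oob_error=oob_error,
        per_class_error=per_class,
        confusion=conf,
        n_trees=n_trees,
        seed=seed,
        n_rows=len(y),
        labels=present,
    )
    return model, report


def classify(
    model: RandomForestClassifier, features: pd.DataFrame
) -> pd.DataFrame:
    """Predict a behavior label and per-class vote fractions per row.

    Vote fractions sum to 1 per row; the label is the argmax with ties
    broken in :data:`LABEL_ORDER`.  An empty table yields an empty result.
    """
    out = features.copy()
    if len(features) == 0:
        out["behavior"] = pd.Series(dtype=object)
        return out
    X = _check_features(features)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    present = [l for l in LABEL_ORDER if l in classes]
    proba = proba[:, [classes.index(l) for l in present]]
    out["behavior"] = np.array(present)[np.argmax(proba, axis=1)]
    for j, lab in enumerate(present):
        out[f"vote_{lab}"] = proba[:, j]
    return out


def exclude_perched(labeled: pd.DataFrame, label_col: str = "behavior") -> pd.DataFrame:
    """Drop perched rows, keeping only flight behavior; idempotent."""
    flying = labeled.loc[labeled[label_col] != "perched"].reset_index(drop=True)
    n_removed = len(labeled) - len(flying)
    flying.attrs["n_perched_removed"] = n_removed
    return flying


# ------------------------------------------------------------- persistence


def feature_schema_hash() -> str:
    return hashlib.sha256(",".join(FEATURE_COLUMNS).encode()).hexdigest()[:16]


def save_model(model: RandomForestClassifier, path) -> None:
    joblib.dump({"model": model, "schema": feature_schema_hash(), "version": 1}, path)


def load_model(path) -> RandomForestClassifier:
    payload = joblib.load(path)
    if payload.get("schema") != feature_schema_hash():
        raise ValueError("model was trained with a different feature schema")
    return payload["model"]
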