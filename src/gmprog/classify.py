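"""Linear-SVM discrimination of patient groups from region-level GMV
features under leave-one-out cross-validation.

Five fixed features (mean GMV in the overlapped areas, continuing areas,
left STG, right STG, and left caudate), a linear-kernel SVM (LIBSVM via
scikit-learn, cost C = 1 by default), and leakage-safe evaluation:
features are standardized on each fold's training rows only, and for the
within-patient contrast both scans of the held-out subject leave the
training set together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConstructionError, InsufficientDataError

FEATURE_COLUMNS = ("overlapped", "continuing", "STG_left", "STG_right", "caudate_left")

CONTRASTS = {
    "hc_vs_adt1": (("HC", "T1"), ("AD", "T1")),
    "hc_vs_adt2": (("HC", "T1"), ("AD", "T2")),
    "adt1_vs_adt2": (("AD", "T1"), ("AD", "T2")),
}


@dataclass
class FeatureMatrix:
    """Scans x features table with labels; the positive class is the
    patient (or later-timepoint) class."""

    X: pd.DataFrame
    y: np.ndarray
    subject_ids: np.ndarray
    positive_class: str
    contrast: str

    def __post_init__(self):
        if self.X.isna().any().any():
            raise ConstructionError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    predictions: pd.DataFrame
    positive_class: str
    contrast: str = ""


def build_feature_matrix(
    roitable: pd.DataFrame,
    phenotypes: pd.DataFrame,
    contrast: str,
    feature_columns: tuple[str, ...] = FEATURE_COLUMNS,
) -> FeatureMatrix:
    """Assemble the features for one two-class contrast.

    Rows are restricted to the contrast's two (group, timepoint) classes in
    deterministic (subject_id, timepoint) order.
    """
    if contrast not in CONTRASTS:
        raise ConstructionError(f"unknown contrast {contrast!r}; use one of {sorted(CONTRASTS)}")
    missing = [c for c in feature_columns if c not in roitable.columns]
    if missing:
        raise ConstructionError(f"missing region-group feature columns: {missing}")

    groups = phenotypes.set_index(["subject_id", "timepoint"])["group"]
    (ga, ta), (gb, tb) = CONTRASTS[contrast]

    rows, labels, sids = [], [], []
    for key in sorted(roitable.index):
        sid, tp = key
        if key not in groups.index:
            raise ConstructionError(f"scan {key} has no phenotype row")
        g = groups.loc[key]
        if (g, tp) == (ga, ta):
            labels.append(f"{ga}-{ta}" if ga == "AD" else ga)
        elif (g, tp) == (gb, tb):
            labels.append(f"{gb}-{tb}" if gb == "AD" else gb)
        else:
            continue
        rows.append(key)
        sids.append(sid)

    X = roitable.loc[rows, list(feature_columns)].copy()
    y = np.array(labels)
    positive = f"{gb}-{tb}" if gb == "AD" else gb
    return FeatureMatrix(X=X, y=y, subject_ids=np.array(sids), positive_class=positive, contrast=contrast)


def loocv_linear_svm(
    features: FeatureMatrix, paired: bool = False, C: float = 1.0
) -> ClassificationMetrics:
    """Leave-one-out linear SVM.

    ``paired=True`` (the within-patient contrast) holds out both scans of
    one subject per fold so the classifier never sees the tested subject's
    other timepoint during training.
    """
    X = features.X.to_numpy(dtype=float)
    y = features.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise InsufficientDataError(
            f"need two classes with >= 2 scans each, got {dict(zip(classes, counts))}"
        )

    if paired:
        folds = [np.flatnonzero(features.subject_ids == s) for s in pd.unique(features.subject_ids)]
    else:
        folds = [np.array([i]) for i in range(len(y))]

    preds = np.empty(len(y), dtype=object)
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        scaler = StandardScaler().fit(X[train])
        clf = SVC(kernel="linear", C=C)
        clf.fit(scaler.transform(X[train]), y[train])
        preds[test_idx] = clf.predict(scaler.transform(X[test_idx]))

    pos = features.positive_class
    tp = int(np.sum((y == pos) & (preds == pos)))
    fn = int(np.sum((y == pos) & (preds != pos)))
    tn = int(np.sum((y != pos) & (preds != pos)))
    fp = int(np.sum((y != pos) & (preds == pos)))
    pred_frame = pd.DataFrame(
        {
            "subject_id": features.subject_ids,
            "true": y,
            "predicted": preds.astype(str),
        }
    )
    return ClassificationMetrics(
        accuracy=(tp + tn) / len(y),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        predictions=pred_frame,
        positive_class=pos,
        contrast=features.contrast,
    )
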