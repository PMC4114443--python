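"""Stage classification of ROI texture features with a linear SVM.

The labelled dataset concatenates the per-stage feature tables: at the
default protocol, 6 stage classes x 20 ROIs = 120 samples of 9 GLCM
features each.  Evaluation is 10-fold cross-validation: rows are randomly
partitioned into 10 near-equal folds (plain random partition, no
stratification), every row serves in exactly one test fold (12 test / 108
train at defaults), and per-fold test accuracies are averaged.

The classifier is a maximum-margin linear SVM with one-vs-one voting over
the 6 class pairs; features are standardized with training-fold statistics
only, so no test information leaks into the fit.  Note that ROIs drawn from
the same image are statistically dependent, yet — matching the 120/12/108
arithmetic of the protocol — the ROI row, not the specimen, is the
cross-validation unit; accuracies are therefore optimistically biased
relative to a per-specimen split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DomainError
from .phantom import STAGE_ORDER, Stage
from .texture import FEATURE_NAMES


@dataclass
class StagedDataset:
    """Labelled feature rows with per-row provenance (image id + ROI corner)."""

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.provenance):
            raise DomainError("rows, labels and provenance must align")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


@dataclass
class CVReport:
    """Cross-validation outcome: per-fold accuracies, their mean, the fold map."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    fold_assignment: np.ndarray  # row index -> fold index
    seed: int
    confusion: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "fold_assignment": [int(f) for f in self.fold_assignment],
            "seed": int(self.seed),
        }


def build_dataset(tables: Mapping[Stage, pd.DataFrame] | Sequence[str | Path],
                  rows_per_stage: int | None = 20) -> StagedDataset:
    """Assemble the staged dataset from one feature table per stage.

    ``tables`` maps stages to feature DataFrames (columns ``image_id,
    roi_row, roi_col, T1..T9, stage``) or is a list of CSV paths in that
    layout.  Row counts are validated per stage (pass ``rows_per_stage=None``
    to skip) and duplicate ``(image_id, roi_row, roi_col)`` rows are rejected.
    """
    if not isinstance(tables, Mapping):
        frames = {}
        for path in tables:
            df = pd.read_csv(path)
            if "stage" not in df.columns or df["stage"].nunique() != 1:
                raise DomainError(f"{path}: expected a single-stage feature table")
            frames[Stage(df["stage"].iloc[0])] = df
        tables = frames

    missing = [s.value for s in STAGE_ORDER if s not in tables]
    if missing:
        raise DomainError(f"missing feature table(s) for stage(s): {missing}")

    parts = []
    for stage in STAGE_ORDER:
        df = tables[stage].copy()
        needed = {"image_id", "roi_row", "roi_col", *FEATURE_NAMES}
        if not needed.issubset(df.columns):
            raise DomainError(f"stage {stage.value}: table lacks columns "
                              f"{sorted(needed - set(df.columns))}")
        if rows_per_stage is not None and len(df) != rows_per_stage:
            raise DomainError(f"stage {stage.value}: expected {rows_per_stage} rows, "
                              f"got {len(df)}")
        df["stage"] = stage.value
        parts.append(df)
    full = pd.concat(parts, ignore_index=True)
    dup = full.duplicated(subset=["image_id", "roi_row", "roi_col"])
    if dup.any():
        raise DomainError(f"{int(dup.sum())} duplicate (image, corner) row(s) in dataset")
    X = full[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = full["stage"].to_numpy()
    return StagedDataset(X, y, full[["image_id", "roi_row", "roi_col", "stage"]])


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> Pipeline:
    """Fit a linear-kernel SVM (one-vs-one) on standardized features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DomainError("training requires at least 2 classes")
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=C, decision_function_shape="ovo")),
    ])
    model.fit(X, y)
    return model


def tenfold_cv(data: StagedDataset, seed: int, k: int = 10, C: float = 1.0) -> CVReport:
    """k-fold cross-validation of the linear SVM on the staged dataset.

    Folds are a seeded random partition into k near-equal parts (sizes differ
    by at most 1); every row is tested exactly once.  The report carries the
    per-fold accuracies, their mean, the row-to-fold map and the aggregated
    confusion matrix (rows true, columns predicted).
    """
    if k < 2:
        raise DomainError("k must be >= 2")
    if k > data.n_samples:
        raise DomainError(f"k = {k} exceeds the {data.n_samples} available rows")
    classes = sorted(np.unique(data.y).tolist())
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**32))
    fold_acc = np.empty(k)
    assignment = np.full(data.n_samples, -1, dtype=int)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(kf.split(data.X)):
        model = train_linear_svm(data.X[train_idx], data.y[train_idx], C=C)
        pred = model.predict(data.X[test_idx])
        truth = data.y[test_idx]
        fold_acc[fold] = float(np.mean(pred == truth))
        assignment[test_idx] = fold
        for t, p in zip(truth, pred):
            conf.loc[t, p] += 1
    return CVReport(fold_acc, float(fold_acc.mean()), assignment, int(seed), conf)
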