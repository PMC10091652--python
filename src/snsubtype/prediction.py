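"""PLS-DA subtype classifiers under three data-splitting schemes.

The classifier is partial least squares regression (NIPALS) on one-hot
class targets with argmax decoding. Three splitting schemes mirror the
three model designs the pipeline evaluates:

- random_cells: per-subtype stratified 7:3 cell split;
- leave_patient_out: all cells of one randomly chosen patient per
  subtype form the test set (no patient spans both sides);
- patient_level: per-patient mean profiles, one random patient per
  subtype held out, repeated with fresh draws.

The number of PLS components is chosen by repeated stratified k-fold
cross-validation on the training side (mean accuracy, ties to the
smallest grid value); performance is reported as micro / macro /
weighted F1 and accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold


@dataclass
class PredictionParams:
    scheme: str = "random_cells"            # random_cells | leave_patient_out | patient_level
    train_fraction: float = 0.7
    cv_folds: int = 10
    cv_repeats: int = 10
    component_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    outer_repeats: int = 10
    seed: int = 0

    def validate(self) -> "PredictionParams":
        if self.scheme not in ("random_cells", "leave_patient_out", "patient_level"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.component_grid or min(self.component_grid) < 1:
            raise ValueError("component_grid must contain integers >= 1")
        return self


class PLSDA:
    """PLS2 on one-hot targets with argmax decoding."""

    def __init__(self, n_components: int):
        if n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.n_components = n_components
        self._pls: PLSRegression | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y) -> "PLSDA":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need >= 2 classes")
        rank_cap = min(X.shape[0] - 1, X.shape[1])
        if self.n_components > rank_cap:
            raise ValueError(f"n_components={self.n_components} exceeds min(n-1, p)={rank_cap}")
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, onehot)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        if self._pls is None:
            raise RuntimeError("fit first")
        return self._pls.predict(np.asarray(X, dtype=float))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "classes": self.classes_.tolist(),
            "coef": np.asarray(self._pls.coef_).tolist(),
            "intercept": np.asarray(self._pls.intercept_).tolist(),
        }


def pls_da_fit(X, y, n_components: int) -> PLSDA:
    """Fit a PLS-DA model (see PLSDA)."""
    return PLSDA(n_components).fit(X, y)


def split_random_cells(cell_ids, labels, fraction: float = 0.7, seed: int = 0):
    """Per-class stratified split; train size rounds half up."""
    cell_ids = np.asarray(cell_ids)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 cells")
        perm = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * fraction + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return cell_ids[np.sort(train)], cell_ids[np.sort(test)]


def split_leave_patient_out(cell_ids, patient_of_cell, subtype_of_patient: dict, seed: int = 0):
    """Hold out every cell of one randomly chosen patient per subtype."""
    cell_ids = np.asarray(cell_ids)
    patient_of_cell = np.asarray(patient_of_cell)
    rng = np.random.default_rng(seed)
    by_subtype: dict[int, list[str]] = {}
    for p, s in subtype_of_patient.items():
        by_subtype.setdefault(s, []).append(p)
    held = []
    for s in sorted(by_subtype):
        patients = sorted(by_subtype[s])
        if len(patients) < 2:
            raise ValueError(f"subtype {s} has a single patient; cannot hold one out")
        held.append(patients[rng.integers(len(patients))])
    test_mask = np.isin(patient_of_cell, held)
    return cell_ids[~test_mask], cell_ids[test_mask], held


def split_patient_level(profiles: pd.DataFrame, subtype_of_patient: dict, seed: int = 0):
    """Patient-profile split: one random patient per subtype held out."""
    train_ids, test_ids, held = split_leave_patient_out(
        np.asarray(profiles.index), np.asarray(profiles.index), subtype_of_patient, seed
    )
    return profiles.loc[train_ids], profiles.loc[test_ids], held


def cv_select(X, y, params: PredictionParams) -> tuple[int, pd.DataFrame]:
    """Choose n_components by repeated stratified k-fold CV accuracy.

    Grid values exceeding the fold-wise rank cap are skipped; ties go
    to the smallest value. Returns (best, per-grid summary).
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    class_min = min(np.bincount(pd.factorize(y)[0]))
    folds = min(params.cv_folds, class_min)
    if folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    records = []
    for rep in range(params.cv_repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=params.seed + rep)
        for tr, te in skf.split(X, y):
            cap = min(len(tr) - 1, X.shape[1])
            for nc in params.component_grid:
                if nc > cap:
                    continue
                model = PLSDA(nc).fit(X[tr], y[tr])
                acc = accuracy_score(y[te], model.predict(X[te]))
                records.append({"n_components": nc, "repeat": rep, "accuracy": acc})
    if not records:
        raise ValueError("no grid value fits the training folds")
    summary = (pd.DataFrame(records).groupby("n_components")["accuracy"]
               .agg(["mean", "std", "count"]).reset_index())
    best_mean = summary["mean"].max()
    best = int(summary.loc[summary["mean"] >= best_mean - 1e-12, "n_components"].min())
    return best, summary


def f1_metrics(y_true, y_pred) -> dict:
    """Micro, macro and weighted F1 plus accuracy and the confusion
    matrix (rows true, columns predicted, label-sorted)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    labels = np.unique(np.concatenate([y_true, y_pred]))
    return {
        "micro_f1": float(f1_score(y_true, y_pred, labels=labels, average="micro", zero_division=0)),
        "macro_f1": float(f1_score(y_true, y_pred, labels=labels, average="macro", zero_division=0)),
        "weighted_f1": float(f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)),
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "labels": labels.tolist(),
        "confusion": confusion_matrix(y_true, y_pred, labels=labels).tolist(),
    }


def run_prediction(X: pd.DataFrame, labels: pd.Series, patient_of_cell: pd.Series,
                   subtype_of_patient: dict, params: PredictionParams) -> dict:
    """Train and evaluate one PLS-DA model under the configured scheme.

    X: samples x features (cells, or patients for patient_level);
    labels: per-sample subtype label. Returns a serializable report.
    """
    params.validate()
    if params.scheme == "random_cells":
        train_ids, test_ids = split_random_cells(X.index, labels.loc[X.index], params.train_fraction, params.seed)
        held = None
    elif params.scheme == "leave_patient_out":
        train_ids, test_ids, held = split_leave_patient_out(
            np.asarray(X.index), patient_of_cell.loc[X.index].to_numpy(), subtype_of_patient, params.seed
        )
    else:  # patient_level
        tr, te, held = split_patient_level(X, subtype_of_patient, params.seed)
        train_ids, test_ids = tr.index, te.index
    y_train = labels.loc[train_ids].to_numpy()
    y_test = labels.loc[test_ids].to_numpy()
    best, cv_summary = cv_select(X.loc[train_ids].to_numpy(), y_train, params)
    model = PLSDA(best).fit(X.loc[train_ids].to_numpy(), y_train)
    metrics = f1_metrics(y_test, model.predict(X.loc[test_ids].to_numpy()))
    return {
        "scheme": params.scheme,
        "n_components": best,
        "n_train": int(len(train_ids)),
        "n_test": int(len(test_ids)),
        "held_out_patients": held,
        **{k: metrics[k] for k in ("micro_f1", "macro_f1", "weighted_f1", "accuracy")},
        "labels": metrics["labels"],
        "confusion": metrics["confusion"],
        "cv": cv_summary.to_dict(orient="records"),
    }
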