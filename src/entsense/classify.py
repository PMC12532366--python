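"""Linear-SVM classification of transgenic vs control measurements.

Features are the entanglement metrics of individual repeated
measurements — tangle and linear entropy for the 2D classifier, the
Werner-probability estimate for the 1D comparison.  No feature scaling
is applied: both features are already bounded in [0, 1].

Evaluation is leave-one-replicate-out: the classifier (with its
regularization constant chosen by stratified 5-fold grid-search
cross-validation inside the training set) is trained on all but one
biological replicate and tested on the held-out one, once per
replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "DEFAULT_C_GRID",
    "FEATURES_2D",
    "FEATURES_1D",
    "SplitResult",
    "assemble_features",
    "train_linear_svm",
    "leave_one_replicate_out",
    "classifier_metrics",
    "compare_1d_2d",
    "split_results_frame",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
FEATURES_2D = ("tangle", "linear_entropy")
FEATURES_1D = ("werner_p_hat",)
POSITIVE_LABEL = "transgenic"

_REQUIRED_COLUMNS = {
    "tangle",
    "linear_entropy",
    "werner_p_hat",
    "label",
    "strain",
    "region",
    "replicate_id",
    "spot_id",
}


def assemble_features(
    measurements: pd.DataFrame,
    strain_pair: tuple[str, str] | None = None,
    region: str | None = None,
) -> pd.DataFrame:
    """Select the per-measurement feature records for one comparison.

    ``measurements`` is the per-repeat metrics table produced by the
    pipeline (one row per individual tomography, not per-spot means).
    ``strain_pair`` restricts to a (transgenic, control) strain pair and
    ``region`` to one brain region.  An empty selection is returned as an
    empty frame, not an error.
    """
    missing = _REQUIRED_COLUMNS - set(measurements.columns)
    if missing:
        raise ValueError(f"feature table is missing columns: {sorted(missing)}")
    if measurements["label"].isna().any():
        raise ValueError("feature table contains missing class labels")
    df = measurements
    if strain_pair is not None:
        df = df[df["strain"].isin(strain_pair)]
    if region is not None:
        df = df[df["region"] == region]
    return df.reset_index(drop=True)


def _check_replicate_labels(df: pd.DataFrame) -> None:
    mixed = df.groupby(["strain", "replicate_id"])["label"].nunique()
    if (mixed > 1).any():
        bad = mixed[mixed > 1].index.tolist()
        raise ValueError(f"replicate assigned to both classes: {bad}")


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C_grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
):
    """Fit a linear-kernel SVM with grid-searched regularization.

    The regularization constant C is chosen by stratified ``n_folds``
    cross-validation on the training data; among CV-score ties the
    smallest C (largest margin) wins.  Returns the fitted model with the
    selected C, weight vector and bias attached as attributes
    ``selected_C``, ``weights`` and ``bias``.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain two classes")
    C_grid = sorted(C_grid)
    min_class = int(min(np.sum(y == c) for c in classes))
    folds = min(n_folds, min_class)
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = [
            np.mean(cross_val_score(SVC(kernel="linear", C=C), X, y, cv=cv))
            for C in C_grid
        ]
        best = int(np.argmax(scores))  # first max -> smallest C among ties
        selected_C = C_grid[best]
    else:
        selected_C = C_grid[0]
    model = SVC(kernel="linear", C=selected_C)
    model.fit(X, y)
    model.selected_C = selected_C
    model.weights = model.coef_[0].copy()
    model.bias = float(model.intercept_[0])
    return model


def classifier_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """Performance panel from confusion counts (positive = transgenic).

    Undefined ratios (0/0) are reported as NaN with a warning, never
    silently as zero.  F1 is the harmonic mean of precision and recall.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"negative confusion count {name}={v}")

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what} undefined (0/0); reporting NaN", stacklevel=3)
            return float("nan")
        return num / den

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    specificity = ratio(tn, tn + fp, "specificity")
    precision_control = ratio(tn, tn + fn, "control precision")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = float("nan") if np.isnan(precision) or np.isnan(recall) else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "sensitivity": recall,  # recall of the transgenic class
        "specificity": specificity,
        "precision_control": precision_control,
        "recall_control": specificity,
        "f1": f1,
    }


@dataclass
class SplitResult:
    """Outcome of one leave-one-replicate-out split."""

    held_out_replicate: int
    selected_C: float
    tp: int
    fp: int
    fn: int
    tn: int
    metrics: dict[str, float] = field(default_factory=dict)
    weights: np.ndarray | None = None
    bias: float | None = None

    @property
    def test_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def leave_one_replicate_out(
    records: pd.DataFrame,
    features=FEATURES_2D,
    C_grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> list[SplitResult]:
    """Leave-one-replicate-out evaluation of the linear SVM.

    Each unique ``replicate_id`` (pairing the transgenic and control
    animal with the same index) is held out once; grid-search CV runs
    only inside the training replicates, so the test replicate is never
    seen during training or model selection.
    """
    records = records.reset_index(drop=True)
    _check_replicate_labels(records)
    labels = set(records["label"].unique())
    if labels - {"transgenic", "control"}:
        raise ValueError(f"unexpected class labels {labels}")
    rep_ids = sorted(records["replicate_id"].unique())
    if len(rep_ids) < 2:
        raise ValueError("need at least two replicates for leave-one-out")
    for label in ("transgenic", "control"):
        if records.loc[records["label"] == label, "replicate_id"].nunique() < 2:
            raise ValueError(f"need >= 2 replicates in class {label!r}")
    features = list(features)
    results = []
    for rep in rep_ids:
        train = records[records["replicate_id"] != rep]
        test = records[records["replicate_id"] == rep]
        model = train_linear_svm(
            train[features].to_numpy(),
            train["label"].to_numpy(),
            C_grid=C_grid,
            n_folds=n_folds,
            seed=seed,
        )
        pred = model.predict(test[features].to_numpy())
        truth = test["label"].to_numpy()
        tp = int(np.sum((truth == POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
        fn = int(np.sum((truth == POSITIVE_LABEL) & (pred != POSITIVE_LABEL)))
        tn = int(np.sum((truth != POSITIVE_LABEL) & (pred != POSITIVE_LABEL)))
        fp = int(np.sum((truth != POSITIVE_LABEL) & (pred == POSITIVE_LABEL)))
        results.append(
            SplitResult(
                held_out_replicate=rep,
                selected_C=model.selected_C,
                tp=tp,
                fp=fp,
                fn=fn,
                tn=tn,
                metrics=classifier_metrics(tp, fp, fn, tn),
                weights=model.weights,
                bias=model.bias,
            )
        )
    return results


def split_results_frame(results: list[SplitResult]) -> pd.DataFrame:
    """Tabulate split results, one row per held-out replicate."""
    rows = []
    for r in results:
        row = {
            "held_out_replicate": r.held_out_replicate,
            "selected_C": r.selected_C,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "tn": r.tn,
        }
        row.update(r.metrics)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_1d_2d(
    records: pd.DataFrame,
    C_grid=DEFAULT_C_GRID,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare the 2D (tangle, linear entropy) and 1D (Werner p̂) SVMs.

    Both feature sets are evaluated on the identical
    leave-one-replicate-out splits; the returned table carries per-split
    metrics for each feature set and their differences (2D − 1D).
    """
    res2 = leave_one_replicate_out(records, FEATURES_2D, C_grid, n_folds, seed)
    res1 = leave_one_replicate_out(records, FEATURES_1D, C_grid, n_folds, seed)
    f2 = split_results_frame(res2).add_prefix("2d_")
    f1 = split_results_frame(res1).add_prefix("1d_")
    out = pd.concat([f2, f1.drop(columns=["1d_held_out_replicate"])], axis=1)
    out = out.rename(columns={"2d_held_out_replicate": "held_out_replicate"})
    for m in ("precision", "recall", "sensitivity", "specificity", "f1"):
        out[f"delta_{m}"] = out[f"2d_{m}"] - out[f"1d_{m}"]
    return out
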