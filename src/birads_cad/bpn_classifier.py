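"""Back-propagation network classification of the four BI-RADS categories.

A single-hidden-layer perceptron (logistic hidden units, softmax output,
cross-entropy loss) maps a normalized feature subset to one of B2, B3, B4,
B5.  The hidden-layer width follows the sizing rule

    H = floor(O + 0.75 * I),  subject to  H < 2 * I,

with O = 4 output classes and I input features, so H = 1 for I = 1,
H = 38 for I = 46 and H = 101 for I = 130.  Data are split 60/40 into
stratified train and test sets; the GA fitness of a feature subset is the
validation accuracy on an inner 75/25 split carved from the training data
(the held-out test set never influences selection).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .feature_table import LABELS, feature_column

logger = logging.getLogger(__name__)


def hidden_size(I: int, O: int = 4) -> int:
    """Hidden-layer width: floor(O + 0.75 I), capped strictly below 2I."""
    if I < 1:
        raise ValueError("need at least one input feature")
    return max(1, min(int(np.floor(O + 0.75 * I)), 2 * I - 1))


@dataclass
class BPNConfig:
    """Training hyperparameters for the back-propagation network."""

    O: int = 4
    learning_rate: float = 0.01
    epochs: int = 500
    patience: int = 25
    solver: str = "adam"
    seed: int = 0


@dataclass
class SplitSpec:
    train_fraction: float = 0.6
    stratified: bool = True
    seed: int = 0


@dataclass
class BPNModel:
    """A trained network together with the feature ids it consumes."""

    estimator: MLPClassifier
    feature_ids: tuple[int, ...]
    hidden: int

    def save(self, path: str) -> None:
        payload = {
            "feature_ids": list(self.feature_ids),
            "hidden": self.hidden,
            "classes": list(self.estimator.classes_),
            "coefs": [w.tolist() for w in self.estimator.coefs_],
            "intercepts": [b.tolist() for b in self.estimator.intercepts_],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def stratified_split(
    table: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified 60/40 split of a labeled feature table."""
    spec = spec or SplitSpec()
    present = set(table["label"].unique())
    missing = [lab for lab in LABELS if lab not in present]
    if missing:
        raise ValueError(f"classes absent from the table: {missing}")
    train, test = train_test_split(
        table,
        train_size=spec.train_fraction,
        stratify=table["label"] if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _design(table: pd.DataFrame, feature_ids: tuple[int, ...]) -> np.ndarray:
    cols = [feature_column(fid) for fid in feature_ids]
    return table[cols].to_numpy(dtype=float)


def train(
    table: pd.DataFrame,
    feature_ids: tuple[int, ...],
    cfg: BPNConfig | None = None,
) -> BPNModel:
    """Fit the back-propagation network on a feature subset.

    Features are expected min-max normalized to [0, 1]; grossly
    out-of-range inputs trigger a warning but not an error.
    """
    cfg = cfg or BPNConfig()
    X = _design(table, feature_ids)
    y = table["label"].to_numpy()
    if X.size and (X.min() < -0.01 or X.max() > 1.01):
        warnings.warn("features outside [0, 1]; did you forget min-max scaling?")
    H = hidden_size(len(feature_ids), cfg.O)
    est = MLPClassifier(
        hidden_layer_sizes=(H,),
        activation="logistic",
        solver=cfg.solver,
        learning_rate_init=cfg.learning_rate,
        max_iter=cfg.epochs,
        n_iter_no_change=cfg.patience,
        random_state=cfg.seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", category=ConvergenceWarning)
        est.fit(X, y)
    return BPNModel(estimator=est, feature_ids=tuple(feature_ids), hidden=H)


def predict(model: BPNModel, table: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted BI-RADS labels (argmax of the output layer)."""
    if isinstance(table, pd.DataFrame):
        X = _design(table, model.feature_ids)
    else:
        X = np.atleast_2d(np.asarray(table, dtype=float))
    return model.estimator.predict(X)


def accuracy_score(model: BPNModel, table: pd.DataFrame) -> float:
    pred = predict(model, table)
    return float(np.mean(pred == table["label"].to_numpy()))


def ga_fitness(
    feature_ids: tuple[int, ...],
    train_table: pd.DataFrame,
    cfg: BPNConfig | None = None,
    cv_folds: int | None = 3,
    validation_fraction: float = 0.25,
) -> float:
    """GA fitness of a feature subset: inner validation accuracy in [0, 1].

    Validation is carved from the training table only, so the held-out
    test split never influences selection.  By default the accuracy is
    averaged over a stratified ``cv_folds``-fold rotation of the training
    data (a single-split estimate is noisy enough that subset selection
    becomes a lottery over validation noise rather than a comparison of
    subsets); with ``cv_folds=None`` a single stratified 75/25 split is
    used instead.  The hidden size is recomputed from the subset size.
    """
    if len(feature_ids) == 0:
        raise ValueError("empty feature subset")
    cfg = cfg or BPNConfig()
    ids = tuple(feature_ids)
    if cv_folds is None:
        inner_train, inner_val = train_test_split(
            train_table,
            test_size=validation_fraction,
            stratify=train_table["label"],
            random_state=cfg.seed,
            shuffle=True,
        )
        model = train(inner_train, ids, cfg)
        return accuracy_score(model, inner_val)
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=cfg.seed)
    y = train_table["label"].to_numpy()
    accs = []
    for tr_idx, val_idx in skf.split(train_table, y):
        model = train(train_table.iloc[tr_idx], ids, cfg)
        accs.append(accuracy_score(model, train_table.iloc[val_idx]))
    return float(np.mean(accs))


def make_fitness(
    train_table: pd.DataFrame,
    cfg: BPNConfig | None = None,
    cv_folds: int | None = 3,
):
    """Bind a training table into a GA fitness function over id tuples."""

    def fn(feature_ids: tuple[int, ...]) -> float:
        return ga_fitness(feature_ids, train_table, cfg, cv_folds=cv_folds)

    return fn
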