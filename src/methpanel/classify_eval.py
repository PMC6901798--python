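"""External validation: splitting, smoothed-bootstrap rebalancing, forests.

Validation of a discovered panel on a new cohort follows the study protocol:
recompute the per-probe binarization on the new cohort, hold out a stratified
20% test set, rebalance the training set by ROSE-style smoothed bootstrap
(synthetic minority samples drawn from Gaussian kernels centered on real
minority samples, bandwidth per feature ``h_q = (4 / ((d+2) n_j))^(1/(d+4))
sigma_jq``), train a random forest, and score the untouched test set by
accuracy and Cohen's kappa with ``tumor`` as the positive class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .binarization import rebinarize_panel
from .data_io import MethylationMatrix, SampleSheet
from .exceptions import ConfigurationError, DesignError, SplitError, ValidationError
from .panel_selection import Panel, SelectionConfig

__all__ = [
    "RoseParams",
    "EvalReport",
    "train_test_split_stratified",
    "rose_bandwidth",
    "rose_params",
    "rose_oversample",
    "train_forest",
    "predict",
    "evaluate",
    "validate_external",
]


@dataclass
class RoseParams:
    """Per-feature kernel bandwidths for the minority class."""

    h: np.ndarray  # one bandwidth per feature
    minority_label: str
    n_minority: int


@dataclass
class EvalReport:
    """Confusion counts and agreement metrics, ``tumor`` positive."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    kappa: float
    kappa_undefined: bool
    n_test: int

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "kappa_undefined": self.kappa_undefined,
            "n_test": self.n_test,
        }

    def summary(self) -> str:
        return (
            "External validation\n"
            "===================\n"
            f"test samples   {self.n_test}\n"
            f"confusion      TP={self.tp} FP={self.fp} FN={self.fn} TN={self.tn}\n"
            f"accuracy       {self.accuracy:.4f}\n"
            f"kappa          "
            + ("undefined" if self.kappa_undefined else f"{self.kappa:.4f}")
        )


def train_test_split_stratified(
    sample_ids: np.ndarray | list,
    labels: np.ndarray | list,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list, list]:
    """Seeded stratified split; per class, round(n * fraction) samples test."""
    if not 0.0 < test_fraction < 1.0:
        raise ConfigurationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if len(sample_ids) != len(labels):
        raise ValidationError("sample_ids and labels must have equal length")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise SplitError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise SplitError(f"class {cls!r} has fewer than 2 samples")
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        chosen = rng.choice(idx, size=n_test, replace=False)
        test_idx.extend(chosen.tolist())
    test_set = set(test_idx)
    train = [s for i, s in enumerate(sample_ids) if i not in test_set]
    test = [s for i, s in enumerate(sample_ids) if i in test_set]
    return train, test


def rose_bandwidth(d: int, n_j: int, sigma: float) -> float:
    """Silverman-style kernel bandwidth ``(4/((d+2) n_j))^(1/(d+4)) * sigma``."""
    if d < 1 or n_j < 1:
        raise ConfigurationError("d and n_j must be >= 1")
    if sigma < 0:
        raise ConfigurationError("sigma must be >= 0")
    return (4.0 / ((d + 2.0) * n_j)) ** (1.0 / (d + 4.0)) * sigma


def rose_params(X_minority: np.ndarray, minority_label: str) -> RoseParams:
    X = np.asarray(X_minority, dtype=float)
    n_j, d = X.shape
    sigma = X.std(axis=0, ddof=1) if n_j > 1 else np.zeros(d)
    h = np.array([rose_bandwidth(d, n_j, s) for s in sigma])
    return RoseParams(h=h, minority_label=minority_label, n_minority=n_j)


def rose_oversample(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    binarize_output: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-up minority oversampling by smoothed bootstrap.

    All original rows are kept; synthetic minority rows (a random minority
    row plus independent Gaussian noise with per-feature bandwidth ``h_q``)
    are appended until the classes balance. With ``binarize_output`` the
    synthetic values are thresholded at 0.5 back to {0, 1} so the training
    space matches the binarized test space.
    """
    labels = np.asarray(labels)
    values, counts = np.unique(labels, return_counts=True)
    if len(values) < 2:
        raise DesignError("need two classes to rebalance")
    minority = values[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return features.copy(), labels.copy()
    X_min = features[labels == minority].to_numpy(dtype=float)
    params = rose_params(X_min, str(minority))
    if X_min.shape[0] == 1 and np.all(params.h == 0):
        warnings.warn(
            "minority class has a single sample with zero variance; "
            "falling back to exact duplication",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, X_min.shape[0], size=n_needed)
    noise = rng.normal(0.0, 1.0, size=(n_needed, X_min.shape[1])) * params.h
    synthetic = X_min[picks] + noise
    if binarize_output:
        synthetic = (synthetic > 0.5).astype(features.to_numpy().dtype)
    synth_index = [f"rose{i:05d}" for i in range(n_needed)]
    out = pd.concat(
        [features, pd.DataFrame(synthetic, index=synth_index, columns=features.columns)]
    )
    out_labels = np.concatenate([labels, np.full(n_needed, minority, dtype=labels.dtype)])
    return out, out_labels


def train_forest(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    trees: int = 500,
    seed: int = 0,
) -> RandomForestClassifier:
    """Fit a seeded random forest predicting tumor/normal labels."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise DesignError("training labels contain a single class")
    forest = RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)
    forest.fit(np.asarray(features, dtype=float), labels)
    return forest


def predict(classifier: RandomForestClassifier, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    return classifier.predict(np.asarray(features, dtype=float))


def evaluate(predictions: np.ndarray | list, truth: np.ndarray | list) -> EvalReport:
    """Confusion counts, accuracy and Cohen's kappa (tumor positive)."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.ndim != 1 or len(truth) < 1:
        raise ValidationError("predictions and truth must be equal-length 1-D arrays")
    pos = "tumor"
    tp = int(np.sum((truth == pos) & (predictions == pos)))
    fn = int(np.sum((truth == pos) & (predictions != pos)))
    fp = int(np.sum((truth != pos) & (predictions == pos)))
    tn = int(np.sum((truth != pos) & (predictions != pos)))
    n = len(truth)
    accuracy = (tp + tn) / n
    p_pos_truth = (tp + fn) / n
    p_pos_pred = (tp + fp) / n
    p_e = p_pos_truth * p_pos_pred + (1 - p_pos_truth) * (1 - p_pos_pred)
    if p_e == 1.0:
        kappa, undefined = 0.0, True
    else:
        kappa, undefined = (accuracy - p_e) / (1 - p_e), False
    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        accuracy=accuracy, kappa=kappa, kappa_undefined=undefined, n_test=n,
    )


def validate_external(
    new_matrix: MethylationMatrix,
    new_sheet: SampleSheet,
    panel: Panel,
    config: SelectionConfig | None = None,
    test_fraction: float = 0.2,
    seed: int = 0,
    rose_seed: int | None = None,
) -> EvalReport:
    """Full external-validation protocol on a new cohort.

    Rebinarize the panel probes from the new cohort's own values, hold out a
    stratified ``test_fraction``, ROSE-rebalance only the training portion,
    train a forest, and evaluate on the untouched test set.
    """
    config = config or SelectionConfig()
    binary = rebinarize_panel(new_matrix, panel.probe_ids)
    sample_ids = binary.sample_ids
    labels = new_sheet.groups_for(sample_ids)
    train_ids, test_ids = train_test_split_stratified(
        sample_ids, labels, test_fraction=test_fraction, seed=seed
    )
    lookup = pd.Series(labels, index=sample_ids)
    X_train = binary.values.loc[train_ids]
    y_train = lookup.loc[train_ids].to_numpy()
    X_bal, y_bal = rose_oversample(
        X_train, y_train, seed=seed if rose_seed is None else rose_seed
    )
    forest = train_forest(X_bal, y_bal, trees=config.trees, seed=config.seed)
    preds = predict(forest, binary.values.loc[test_ids])
    return evaluate(preds, lookup.loc[test_ids].to_numpy())
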