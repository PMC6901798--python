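"""Correlation-filtered greedy panel construction over binarized probes.

Probes are first ranked by random-forest recursive feature elimination
(repeatedly fit a forest, score features by permutation importance on a
held-out split, drop the weakest 20%, until one feature remains; the rank is
the reverse elimination order). Candidates are then admitted to the panel in
rank order, skipping any probe whose absolute phi coefficient (Pearson
correlation of 0/1 vectors) with an already-admitted probe reaches the
redundancy cutoff (default 0.7). After every admission the panel prefix is
scored by stratified k-fold cross-validated accuracy and Cohen's kappa; the
final panel is the prefix with the best accuracy (kappa breaks ties, then
panel size).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, train_test_split

from .binarization import BinaryFeatureMatrix, ProbeSplit
from .exceptions import ConfigurationError, DesignError, ValidationError

__all__ = [
    "SelectionConfig",
    "ImportanceRanking",
    "PanelTrace",
    "Panel",
    "phi_correlation",
    "rf_importance_ranking",
    "greedy_panel_build",
    "choose_final_panel",
    "cross_validate",
    "PanelSelector",
    "PanelResults",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tunables of the selection stage (defaults follow the study protocol)."""

    corr_threshold: float = 0.7
    folds: int = 10
    trees: int = 500
    elimination_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.corr_threshold <= 1.0:
            raise ConfigurationError(f"corr_threshold must be in (0, 1], got {self.corr_threshold}")
        if self.folds < 2:
            raise ConfigurationError(f"folds must be >= 2, got {self.folds}")
        if self.trees < 1:
            raise ConfigurationError(f"trees must be >= 1, got {self.trees}")
        if not 0.0 < self.elimination_fraction < 1.0:
            raise ConfigurationError(
                f"elimination_fraction must be in (0, 1), got {self.elimination_fraction}"
            )


@dataclass
class ImportanceRanking:
    """Probes ordered most-important-first with score and elimination round."""

    probe_ids: list[str]
    importance: dict[str, float]
    elimination_round: dict[str, int]


@dataclass
class PanelTrace:
    """Cross-validated accuracy/kappa for each panel prefix."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["n_features", "probe_added", "cv_accuracy", "cv_kappa"])
    )


@dataclass
class Panel:
    """The chosen marker set plus everything needed to reapply it."""

    probe_ids: list[str]
    splits: dict[str, ProbeSplit]
    trace: PanelTrace
    candidate_order: list[str]
    chosen_size: int
    config: SelectionConfig


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    return (np.asarray(labels) == "tumor").astype(int)


def phi_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 0/1 vectors (the phi coefficient)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValidationError("phi_correlation needs two equal-length vectors of length >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("phi coefficient undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


def _forest(trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=trees, random_state=seed, n_jobs=1)


def rf_importance_ranking(
    features: BinaryFeatureMatrix, labels: np.ndarray, config: SelectionConfig
) -> ImportanceRanking:
    """Recursive feature elimination with permutation importance.

    Each round fits a seeded forest on a stratified 75% of the samples and
    permutes features on the held-out 25%; the lowest
    ``ceil(elimination_fraction * remaining)`` features are dropped. Ties in
    a round are broken by importance (descending) then probe id.
    """
    config.validate()
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise DesignError("both classes must be present for ranking")
    if features.values.shape[1] < 2:
        raise ValidationError("need at least 2 features to rank")

    remaining = list(features.values.columns)
    eliminated: list[list[str]] = []  # per round, in within-round rank order
    importance: dict[str, float] = {}
    round_of: dict[str, int] = {}
    rnd = 0
    while len(remaining) > 1:
        rnd += 1
        X = features.values[remaining].to_numpy()
        X_tr, X_ho, y_tr, y_ho = train_test_split(
            X, y, test_size=0.25, stratify=y, random_state=config.seed + rnd
        )
        forest = _forest(config.trees, config.seed + rnd)
        forest.fit(X_tr, y_tr)
        perm = permutation_importance(
            forest, X_ho, y_ho, n_repeats=5, random_state=config.seed + rnd, n_jobs=1
        )
        scores = dict(zip(remaining, perm.importances_mean))
        n_drop = math.ceil(config.elimination_fraction * len(remaining))
        n_drop = min(n_drop, len(remaining) - 1)
        # weakest first within the round; record in descending-importance order
        ordered = sorted(remaining, key=lambda p: (-scores[p], p))
        dropped = ordered[len(ordered) - n_drop :]
        for p in remaining:
            importance[p] = float(scores[p])
        for p in dropped:
            round_of[p] = rnd
        eliminated.append(dropped)
        remaining = [p for p in ordered if p not in set(dropped)]
    survivor = remaining[0]
    round_of[survivor] = rnd + 1
    # final rank: survivor first, then later-eliminated rounds first,
    # descending importance within a round
    ranked = [survivor]
    for dropped in reversed(eliminated):
        ranked.extend(dropped)
    return ImportanceRanking(probe_ids=ranked, importance=importance, elimination_round=round_of)


def cross_validate(
    X: np.ndarray, labels: np.ndarray, config: SelectionConfig
) -> tuple[float, float]:
    """Stratified k-fold CV; pooled out-of-fold predictions scored once."""
    from .classify_eval import evaluate  # local import to avoid a cycle

    config.validate()
    y = _encode_labels(labels)
    n = len(y)
    if n < config.folds:
        raise ValidationError(f"folds={config.folds} exceeds n={n}")
    if len(np.unique(y)) < 2:
        raise DesignError("both classes must be present for cross-validation")
    folds = config.folds
    min_class = int(np.bincount(y).min())
    if folds > min_class:
        folds = max(2, min_class)
        warnings.warn(
            f"reduced folds to {folds}: smallest class has {min_class} samples",
            stacklevel=2,
        )
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[:, None]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    oof = np.empty(n, dtype=int)
    for i, (tr, te) in enumerate(skf.split(X, y)):
        forest = _forest(config.trees, config.seed + 1000 + i)
        forest.fit(X[tr], y[tr])
        oof[te] = forest.predict(X[te])
    names = np.where(y == 1, "tumor", "normal")
    pred_names = np.where(oof == 1, "tumor", "normal")
    report = evaluate(pred_names, names)
    return report.accuracy, report.kappa


def greedy_panel_build(
    ranking: ImportanceRanking,
    features: BinaryFeatureMatrix,
    labels: np.ndarray,
    config: SelectionConfig,
) -> tuple[PanelTrace, list[str]]:
    """Admit probes in rank order under the pairwise |phi| < threshold filter,
    re-scoring the growing panel by CV after every admission."""
    config.validate()
    missing = set(features.values.columns) - set(ranking.probe_ids)
    if missing:
        raise ValidationError(f"ranking does not cover features: {sorted(missing)}")
    admitted: list[str] = []
    rows = []
    for probe in ranking.probe_ids:
        if probe not in features.values.columns:
            continue
        vec = features.values[probe].to_numpy()
        if admitted:
            max_phi = max(
                abs(phi_correlation(vec, features.values[q].to_numpy())) for q in admitted
            )
            if max_phi >= config.corr_threshold:
                continue
        admitted.append(probe)
        acc, kappa = cross_validate(
            features.values[admitted].to_numpy(), labels, config
        )
        rows.append(
            {
                "n_features": len(admitted),
                "probe_added": probe,
                "cv_accuracy": acc,
                "cv_kappa": kappa,
            }
        )
    trace = PanelTrace(pd.DataFrame(rows))
    return trace, admitted


def choose_final_panel(trace: PanelTrace) -> int:
    """Prefix size with best CV accuracy; ties -> higher kappa, then smaller."""
    rows = trace.rows
    if rows.empty:
        raise ValidationError("empty panel trace")
    best = rows.sort_values(
        by=["cv_accuracy", "cv_kappa", "n_features"],
        ascending=[False, False, True],
        kind="stable",
    ).iloc[0]
    return int(best["n_features"])


class PanelSelector:
    """Panel-selection model over binarized features.

    ``fit()`` runs RFE ranking, the greedy correlation-filtered build and the
    prefix choice, returning :class:`PanelResults`.
    """

    def __init__(
        self,
        features: BinaryFeatureMatrix,
        labels: np.ndarray,
        config: SelectionConfig | None = None,
    ):
        self.features = features
        self.labels = np.asarray(labels)
        self.config = config or SelectionConfig()

    def fit(self) -> "PanelResults":
        self.config.validate()
        ranking = rf_importance_ranking(self.features, self.labels, self.config)
        trace, admitted = greedy_panel_build(
            ranking, self.features, self.labels, self.config
        )
        size = choose_final_panel(trace)
        final = admitted[:size]
        panel = Panel(
            probe_ids=final,
            splits={p: self.features.splits[p] for p in final if p in self.features.splits},
            trace=trace,
            candidate_order=admitted,
            chosen_size=size,
            config=self.config,
        )
        return PanelResults(self, ranking, panel)


class PanelResults:
    """Ranking, trace and the chosen panel from one selection run."""

    def __init__(self, model: PanelSelector, ranking: ImportanceRanking, panel: Panel):
        self.model = model
        self.ranking = ranking
        self.panel = panel

    @property
    def trace(self) -> PanelTrace:
        return self.panel.trace

    def summary(self) -> str:
        rows = self.panel.trace.rows
        chosen = rows[rows["n_features"] == self.panel.chosen_size].iloc[0]
        lines = [
            "Panel selection (RF-RFE + correlation filter)",
            "=============================================",
            f"candidates ranked      {len(self.ranking.probe_ids)}",
            f"admitted by |phi|<{self.model.config.corr_threshold}   {len(self.panel.candidate_order)}",
            f"chosen panel size      {self.panel.chosen_size}",
            f"panel probes           {', '.join(self.panel.probe_ids)}",
            f"CV accuracy / kappa    {chosen['cv_accuracy']:.4f} / {chosen['cv_kappa']:.4f}",
            "",
            "trace (prefix size, probe added, accuracy, kappa):",
        ]
        for _, r in rows.iterrows():
            lines.append(
                f"  {int(r['n_features']):3d}  {r['probe_added']:<12s}"
                f"  {r['cv_accuracy']:.4f}  {r['cv_kappa']:.4f}"
            )
        return "\n".join(lines)
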