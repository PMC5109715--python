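"""Classifier comparison, property scoring and forward feature search.

Performance is estimated by bootstrap cross-validation: in each fold the
balanced dataset is randomly re-sampled, stratified, into an 80% training
and a 20% test portion; ten runs of five folds give 50 per-fold records of
precision, recall, F-score, MCC and AUC per configuration. Paired
differences between configurations are tested with the two-sided Wilcoxon
signed-rank test on the per-fold AUCs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, train_test_split

from .classifiers import ClassifierSpec, build_estimator, positive_scores
from .encoding import BLOCK_ORDER, block_of_column, select_blocks

logger = logging.getLogger(__name__)

METRIC_NAMES = ("precision", "recall", "f_score", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, F-score and MCC from confusion counts.

    Degenerate denominators (e.g. no positive predictions) yield 0 with a
    logged warning rather than an error.
    """
    if counts.total == 0:
        raise ValueError("all confusion counts are zero")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn

    def _ratio(num, den, name):
        if den == 0:
            logger.warning("degenerate denominator for %s; returning 0", name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f_score = _ratio(2 * precision * recall, precision + recall, "f_score")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        logger.warning("degenerate denominator for mcc; returning 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return {"precision": precision, "recall": recall, "f_score": f_score, "mcc": mcc}


def compute_auc(scores, labels) -> float:
    """ROC AUC; equals the Mann-Whitney pair statistic (ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both label values must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _fit_with_grid(spec: ClassifierSpec, X, y, random_state: int):
    est = build_estimator(spec, random_state=random_state)
    if spec.grid:
        search = GridSearchCV(est, spec.grid, scoring="roc_auc", cv=3, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X, y)
        return search.best_estimator_
    est.fit(X, y)
    return est


def bootstrap_cv(
    X,
    y,
    classifier_spec: ClassifierSpec | None = None,
    property_subset: list[str] | None = None,
    n_runs: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap cross-validation: repeated stratified 80/20 resampling.

    Returns one record per (run, fold) with precision, recall, F-score,
    MCC and AUC — 50 records at the default 10 runs of 5 folds. Grid
    hyperparameters (when the spec carries a grid) are re-searched inside
    each fold's training portion by mean AUC.
    """
    spec = classifier_spec or ClassifierSpec()
    if isinstance(X, pd.DataFrame) and property_subset:
        X = select_blocks(X, property_subset)
    Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    ya = np.asarray(y)
    if len(np.unique(ya)) < 2:
        raise ValueError("dataset must contain both classes")
    rng = np.random.default_rng(seed)
    records = []
    for run in range(n_runs):
        for fold in range(n_folds):
            for attempt in range(10):
                fold_seed = int(rng.integers(2**31 - 1))
                X_tr, X_te, y_tr, y_te = train_test_split(
                    Xa, ya, test_size=0.2, stratify=ya, random_state=fold_seed
                )
                if len(np.unique(y_te)) == 2 and len(np.unique(y_tr)) == 2:
                    break
                logger.warning("fold missing a class; re-drawing")
            model = _fit_with_grid(spec, X_tr, y_tr, random_state=fold_seed)
            scores = positive_scores(model, X_te)
            pred = model.predict(X_te)
            counts = ConfusionCounts(
                tp=int(np.sum((pred == 1) & (y_te == 1))),
                fp=int(np.sum((pred == 1) & (y_te == 0))),
                tn=int(np.sum((pred == 0) & (y_te == 0))),
                fn=int(np.sum((pred == 0) & (y_te == 1))),
            )
            rec = {"run": run, "fold": fold, "seed": fold_seed}
            rec.update(compute_metrics(counts))
            rec["auc"] = compute_auc(scores, y_te)
            records.append(rec)
    return pd.DataFrame(records)


def wilcoxon_compare(aucs_a, aucs_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value on per-fold scores.

    Zero differences are dropped (the classic procedure); if every
    difference is zero the comparison is uninformative and p = 1 is
    returned with a warning. The exact null distribution is used for
    small samples without ties, the normal approximation otherwise.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(a, b):
        logger.warning("all paired differences are zero; p = 1")
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon(
            a, b, zero_method="wilcox", alternative="two-sided", method="auto"
        )
    return float(res.pvalue)


def property_importance(
    X: pd.DataFrame,
    y,
    classifier_spec: ClassifierSpec | None = None,
    properties: list[str] | None = None,
    n_runs: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Score each property block by forest importance and by single-block AUC.

    Importance is the sum of the forest's per-bit impurity importances
    over the block's bits, normalized to sum to one across properties;
    it is reported as NaN for non-forest specs. The per-property AUC is
    a bootstrap CV on that block alone.
    """
    spec = classifier_spec or ClassifierSpec()
    props = list(properties or [b for b in BLOCK_ORDER if any(
        block_of_column(c) == b for c in X.columns)])
    importances = {p: np.nan for p in props}
    if spec.is_forest:
        forest = build_estimator(spec, random_state=seed)
        forest.fit(X.to_numpy(), np.asarray(y))
        per_bit = pd.Series(forest.feature_importances_, index=X.columns)
        raw = {p: float(per_bit[[c for c in X.columns if block_of_column(c) == p]].sum())
               for p in props}
        total = sum(raw.values())
        if total > 0:
            importances = {p: v / total for p, v in raw.items()}
    else:
        logger.warning("importance unavailable for %s; AUC still computed", spec.family)
    rows = []
    for prop in props:
        cv = bootstrap_cv(
            X, y, spec, property_subset=[prop],
            n_runs=n_runs, n_folds=n_folds, seed=seed,
        )
        rows.append(
            {"property": prop, "importance": importances[prop],
             "mean_auc": float(cv["auc"].mean())}
        )
    return pd.DataFrame(rows).sort_values("mean_auc", ascending=False, ignore_index=True)


@dataclass
class SearchStep:
    property_added: str
    mean_auc: float
    fold_aucs: np.ndarray
    wilcoxon_p: float | None


@dataclass
class FeatureSearchTrace:
    """Greedy forward best-first search trace over property blocks."""

    steps: list[SearchStep]

    @property
    def properties(self) -> list[str]:
        return [s.property_added for s in self.steps]

    @property
    def best_subset(self) -> list[str]:
        """The prefix of the trace with the highest mean AUC."""
        best = int(np.argmax([s.mean_auc for s in self.steps]))
        return self.properties[: best + 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": range(1, len(self.steps) + 1),
                "property_added": self.properties,
                "mean_auc": [s.mean_auc for s in self.steps],
                "wilcoxon_p": [s.wilcoxon_p for s in self.steps],
            }
        )


def forward_best_first(
    X: pd.DataFrame,
    y,
    classifier_spec: ClassifierSpec | None = None,
    properties: list[str] | None = None,
    n_runs: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> FeatureSearchTrace:
    """Greedy forward search over property blocks, ranked by mean CV AUC.

    The search starts from the single best property and at every step adds
    the remaining property with the best mean AUC, recording the paired
    Wilcoxon p-value against the previous step's per-fold AUCs. The full
    trace is recorded even where the AUC decreases; the selected subset is
    the prefix with maximal mean AUC.
    """
    spec = classifier_spec or ClassifierSpec()
    remaining = list(properties or [b for b in BLOCK_ORDER if any(
        block_of_column(c) == b for c in X.columns)])
    if not remaining:
        raise ValueError("no properties to search over")
    steps: list[SearchStep] = []
    current: list[str] = []
    prev_aucs = None
    while remaining:
        best = None
        for prop in remaining:
            cv = bootstrap_cv(
                X, y, spec, property_subset=current + [prop],
                n_runs=n_runs, n_folds=n_folds, seed=seed,
            )
            aucs = cv["auc"].to_numpy()
            if best is None or aucs.mean() > best[1]:
                best = (prop, float(aucs.mean()), aucs)
        prop, mean_auc, aucs = best
        p = None if prev_aucs is None else wilcoxon_compare(aucs, prev_aucs)
        steps.append(SearchStep(prop, mean_auc, aucs, p))
        current.append(prop)
        remaining.remove(prop)
        prev_aucs = aucs
    return FeatureSearchTrace(steps=steps)
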