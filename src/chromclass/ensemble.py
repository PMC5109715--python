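"""Balanced one-vs-rest ensemble classification.

The four-class problem (Pioneer, Settler, positive Migrant, negative
Migrant) is heavily imbalanced. For each specific-vs-rest case the larger
side is randomly partitioned, without replacement, into k near-equal
subsets with k = max(1, round(|larger| / |smaller|)); each subset paired
with the whole smaller side gives one balanced binary task. One classifier
is fitted per task, a TF's per-case score is the mean of its per-task
positive-class probabilities, and the final label is the argmax over the
four per-case averages, with the margin (top minus runner-up average
probability) as a confidence proxy.

With the reference training class sizes 45 / 47 / 77 / 288 this yields
9, 9, 5 and 2 balanced tasks respectively; for the negative-Migrant case
the specific class itself is the larger side, so it is the side split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, build_estimator, positive_scores
from .records import CLASS_LABELS, TFRecord

logger = logging.getLogger(__name__)


@dataclass
class BalancedTask:
    """One balanced specific-vs-rest training set."""

    case_name: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    split_index: int
    seed: int

    def __post_init__(self) -> None:
        if set(self.positives) & set(self.negatives):
            raise ValueError("positives and negatives overlap")
        if not self.positives or not self.negatives:
            raise ValueError("task is degenerate (single class)")


@dataclass
class CaseEnsemble:
    """The fitted models of one specific-vs-rest case."""

    case_name: str
    tasks: list[BalancedTask]
    models: list
    feature_columns: tuple[str, ...]
    seed: int


@dataclass
class EnsemblePrediction:
    """Averaged per-case probabilities and the resulting label for one TF."""

    tf_id: str
    avg_prob: dict[str, float]
    final_label: str
    margin: float


def _ids_and_labels(labeled) -> tuple[list[str], list[str]]:
    if isinstance(labeled, pd.Series):
        return list(labeled.index), list(labeled.values)
    ids, labels = [], []
    for rec in labeled:
        if isinstance(rec, TFRecord):
            ids.append(rec.tf_id)
            labels.append(rec.label)
        else:
            ids.append(rec[0])
            labels.append(rec[1])
    return ids, labels


def make_balanced_tasks(labeled, case_name: str, seed: int) -> list[BalancedTask]:
    """Build the balanced specific-vs-rest tasks for one case.

    *labeled* is a list of labeled TFRecords, a list of (tf_id, label)
    pairs, or a pandas Series mapping tf_id to label. The larger of the
    specific and rest sides is shuffled and partitioned into
    ``k = max(1, round(larger / smaller))`` near-equal subsets (remainders
    spread one-per-subset); each subset is paired with the entire smaller
    side.
    """
    if case_name not in CLASS_LABELS:
        raise ValueError(f"unknown case {case_name!r}")
    ids, labels = _ids_and_labels(labeled)
    specific = [i for i, lab in zip(ids, labels) if lab == case_name]
    rest = [i for i, lab in zip(ids, labels) if lab != case_name and lab in CLASS_LABELS]
    if not specific:
        raise ValueError(f"no TFs labeled {case_name}")
    if not rest:
        raise ValueError("rest side is empty")
    split_specific = len(specific) > len(rest)
    larger, smaller = (specific, rest) if split_specific else (rest, specific)
    k = max(1, round(len(larger) / len(smaller)))
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(larger)[rng.permutation(len(larger))])
    subsets = [list(chunk) for chunk in np.array_split(shuffled, k)]
    tasks = []
    for i, subset in enumerate(subsets):
        pos, neg = (subset, smaller) if split_specific else (smaller, subset)
        tasks.append(
            BalancedTask(
                case_name=case_name,
                positives=tuple(pos),
                negatives=tuple(neg),
                split_index=i,
                seed=seed,
            )
        )
    return tasks


def train_case_ensemble(
    tasks: list[BalancedTask],
    feature_matrix: pd.DataFrame,
    classifier_spec: ClassifierSpec | None = None,
) -> CaseEnsemble:
    """Fit one classifier per balanced task.

    *feature_matrix* is indexed by tf_id (as produced by
    :func:`chromclass.encoding.encode_table`, possibly block-restricted).
    """
    if not tasks:
        raise ValueError("no tasks given")
    spec = classifier_spec or ClassifierSpec()
    case_name = tasks[0].case_name
    missing = {t for task in tasks for t in (*task.positives, *task.negatives)} - set(
        feature_matrix.index
    )
    if missing:
        raise KeyError(f"TFs missing from feature matrix: {sorted(missing)[:5]} ...")
    models = []
    for task in tasks:
        tf_ids = list(task.positives) + list(task.negatives)
        X = feature_matrix.loc[tf_ids].to_numpy()
        y = np.array([1] * len(task.positives) + [0] * len(task.negatives))
        model = build_estimator(spec, random_state=task.seed + task.split_index)
        model.fit(X, y)
        models.append(model)
    return CaseEnsemble(
        case_name=case_name,
        tasks=list(tasks),
        models=models,
        feature_columns=tuple(feature_matrix.columns),
        seed=tasks[0].seed,
    )


def predict(
    bundles: dict[str, CaseEnsemble], features: pd.DataFrame
) -> list[EnsemblePrediction]:
    """Predict every TF in *features* from the four case ensembles.

    Each case's averaged positive-class probability is computed over that
    case's tasks; the final label is the argmax over cases, with ties
    resolved in the fixed order P, S, M+, M- (and a logged warning), and
    the margin is the difference between the two largest averages.
    """
    missing = set(CLASS_LABELS) - set(bundles)
    if missing:
        raise ValueError(f"missing case bundles: {sorted(missing)}")
    per_case = {}
    for case in CLASS_LABELS:
        bundle = bundles[case]
        X = features[list(bundle.feature_columns)].to_numpy()
        per_case[case] = np.mean(
            [positive_scores(model, X) for model in bundle.models], axis=0
        )
    predictions = []
    for i, tf_id in enumerate(features.index):
        avg = {case: float(per_case[case][i]) for case in CLASS_LABELS}
        ranked = sorted(avg.values(), reverse=True)
        top = max(avg.values())
        winners = [c for c in CLASS_LABELS if avg[c] == top]
        if len(winners) > 1:
            logger.warning(
                "tie between %s for %s; using priority order", winners, tf_id
            )
        predictions.append(
            EnsemblePrediction(
                tf_id=str(tf_id),
                avg_prob=avg,
                final_label=winners[0],
                margin=float(ranked[0] - ranked[1]),
            )
        )
    return predictions


def predictions_frame(predictions: list[EnsemblePrediction]) -> pd.DataFrame:
    """Tabulate predictions (tf_id, four averaged probabilities, label, margin)."""
    return pd.DataFrame(
        {
            "tf_id": [p.tf_id for p in predictions],
            **{
                f"prob_{case}": [p.avg_prob[case] for p in predictions]
                for case in CLASS_LABELS
            },
            "label": [p.final_label for p in predictions],
            "margin": [p.margin for p in predictions],
        }
    )


def group_code(code: str) -> str:
    """Reporting group of a dotted structural code: the two top levels,
    except that the C2H2 zinc-finger class (2.3) is reported per family."""
    parts = code.split(".")
    if parts[:2] == ["2", "3"] and len(parts) >= 3:
        return ".".join(parts[:3])
    return ".".join(parts[:2])


def summarize_by_class(
    predictions: list[EnsemblePrediction], tfclass_codes: dict[str, str]
) -> pd.DataFrame:
    """Summarize predictions per structural classification group.

    Returns, per group: the TF count, the count assigned to each
    regulatory class, the mean winning averaged probability and the mean
    margin.
    """
    if not predictions:
        raise ValueError("no predictions to summarize")
    rows = {}
    for p in predictions:
        grp = group_code(tfclass_codes[p.tf_id])
        row = rows.setdefault(
            grp,
            {"group": grp, "n": 0, **{f"n_{c}": 0 for c in CLASS_LABELS},
             "_probs": [], "_margins": []},
        )
        row["n"] += 1
        row[f"n_{p.final_label}"] += 1
        row["_probs"].append(p.avg_prob[p.final_label])
        row["_margins"].append(p.margin)
    out = []
    for grp in sorted(rows):
        row = rows[grp]
        out.append(
            {
                "group": grp,
                "n": row["n"],
                **{f"n_{c}": row[f"n_{c}"] for c in CLASS_LABELS},
                "mean_prob": float(np.mean(row["_probs"])),
                "mean_margin": float(np.mean(row["_margins"])),
            }
        )
    return pd.DataFrame(out)
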