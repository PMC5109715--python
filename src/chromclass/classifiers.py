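"""Candidate classifier families and their hyperparameter grids.

The ensemble and model-selection code never instantiates sklearn
estimators directly; everything goes through :class:`ClassifierSpec` so a
configuration is a plain, serializable description.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

FAMILIES = ("RF", "SVC-RBF", "SVC-poly", "SVC-linear", "kNN", "GNB")

_POW2 = [2.0**i for i in range(-4, 5)]

#: Default search grids: C and gamma over 2^-4 .. 2^4, polynomial degree
#: in {2, 3}, neighbour count in {3, 5, 7, 9}.
DEFAULT_GRIDS = {
    "RF": {},
    "SVC-RBF": {"C": _POW2, "gamma": _POW2},
    "SVC-poly": {"C": _POW2, "degree": [2, 3]},
    "SVC-linear": {"C": _POW2},
    "kNN": {"n_neighbors": [3, 5, 7, 9]},
    "GNB": {},
}

_GRID_KEYS = {
    "RF": set(),
    "SVC-RBF": {"C", "gamma"},
    "SVC-poly": {"C", "degree"},
    "SVC-linear": {"C"},
    "kNN": {"n_neighbors"},
    "GNB": set(),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter grid and fixed params.

    ``grid`` maps parameter names to candidate values searched during
    cross-validation; ``params`` are fixed constructor arguments (e.g.
    ``n_estimators`` for the random forest, which defaults to 500 trees
    with the Gini split criterion).
    """

    family: str = "RF"
    grid: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown classifier family {self.family!r}")
        bad = set(self.grid) - _GRID_KEYS[self.family]
        if bad:
            raise ValueError(f"grid keys {sorted(bad)} invalid for {self.family}")
        for key, values in self.grid.items():
            if not values:
                raise ValueError(f"empty candidate set for grid key {key!r}")

    @classmethod
    def with_default_grid(cls, family: str = "RF", **params) -> "ClassifierSpec":
        return cls(family=family, grid=dict(DEFAULT_GRIDS[family]), params=params)

    @property
    def is_forest(self) -> bool:
        return self.family == "RF"


def build_estimator(spec: ClassifierSpec, random_state: int | None = None):
    """Instantiate the sklearn estimator described by *spec*."""
    p = dict(spec.params)
    if spec.family == "RF":
        p.setdefault("n_estimators", 500)
        p.setdefault("criterion", "gini")
        return RandomForestClassifier(random_state=random_state, **p)
    if spec.family == "SVC-RBF":
        return SVC(kernel="rbf", probability=True, random_state=random_state, **p)
    if spec.family == "SVC-poly":
        return SVC(kernel="poly", probability=True, random_state=random_state, **p)
    if spec.family == "SVC-linear":
        return SVC(kernel="linear", probability=True, random_state=random_state, **p)
    if spec.family == "kNN":
        return KNeighborsClassifier(**p)
    if spec.family == "GNB":
        return GaussianNB(**p)
    raise AssertionError(spec.family)


def positive_scores(model, X):
    """Probability-like score for the positive class."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, list(model.classes_).index(1)]
    return model.decision_function(X)
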