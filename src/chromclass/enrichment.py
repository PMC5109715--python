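"""Fisher-exact enrichment and depletion machinery.

All tests reduce to a 2x2 contingency table (in-category x has-feature)
with the expected count of the top-left cell defined as
row-total x column-total / grand-total. Enrichment means observed >
expected, depletion the reverse; p-values are two-sided Fisher exact
probabilities (matching R's fisher.test default), adjusted where stated
by Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .records import CLASS_LABELS, PTM_NAMES, InteractionPairSet, TimeCourseSets

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = in-category AND has-feature; b, c, d the complements."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.total


@dataclass
class EnrichmentResult:
    label: str
    observed: int
    expected: float
    p_value: float
    direction: str  # "enriched" | "depleted"
    log_ratio: float
    p_adjusted: float | None = None


def fisher_2x2(
    table: ContingencyTable2x2, alternative: str = "two-sided"
) -> tuple[float, str]:
    """Two-sided Fisher exact p-value and the direction of association.

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins that are as or more extreme than the observed one.
    """
    _, p = fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    direction = "enriched" if table.a > table.expected_a else "depleted"
    return float(p), direction


def _log_ratio(observed: float, expected: float, base: float = 2.0) -> float:
    if expected == 0:
        return math.inf if observed > 0 else 0.0
    if observed == 0:
        return -math.inf
    return math.log(observed / expected, base)


def _result(label, table: ContingencyTable2x2, alternative="two-sided",
            log_base=2.0) -> EnrichmentResult:
    p, direction = fisher_2x2(table, alternative)
    return EnrichmentResult(
        label=label,
        observed=table.a,
        expected=table.expected_a,
        p_value=p,
        direction=direction,
        log_ratio=_log_ratio(table.a, table.expected_a, log_base),
    )


def property_enrichment(
    class_assignments: dict[str, str],
    feature_flags: dict[str, bool],
    feature_name: str = "feature",
    alternative: str = "two-sided",
) -> list[EnrichmentResult]:
    """Per-class enrichment of one boolean TF feature.

    Every classified TF must carry a flag; for each class the 2x2 table is
    (in class) x (has feature) over the full classified universe.
    """
    missing = set(class_assignments) - set(feature_flags)
    if missing:
        raise ValueError(f"TFs without a feature flag: {sorted(missing)[:5]} ...")
    n = len(class_assignments)
    feature_total = sum(bool(feature_flags[t]) for t in class_assignments)
    results = []
    for cls in CLASS_LABELS:
        members = [t for t, c in class_assignments.items() if c == cls]
        if not members:
            logger.warning("class %s is empty; skipped", cls)
            continue
        obs = sum(bool(feature_flags[t]) for t in members)
        table = ContingencyTable2x2(
            a=obs,
            b=len(members) - obs,
            c=feature_total - obs,
            d=n - len(members) - feature_total + obs,
        )
        res = _result(f"{cls}|{feature_name}", table, alternative)
        res.label = cls
        results.append(res)
    return results


def pair_class_enrichment(
    pairs: InteractionPairSet,
    class_assignments: dict[str, str],
    class_a: str,
    class_b: str,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Enrichment of interactions among pairs of two regulatory classes.

    The universe is every unordered pair of classified TFs; the 2x2 table
    crosses "the pair is a (class_a, class_b) combination" with "the pair
    is in the interaction set".
    """
    tfs = sorted(class_assignments)
    n = len(tfs)
    counts = {c: sum(1 for t in tfs if class_assignments[t] == c) for c in (class_a, class_b)}
    if min(counts.values()) < 1:
        raise ValueError(f"class with no members among {class_a}, {class_b}")
    n_pairs = n * (n - 1) // 2
    wanted = frozenset((class_a, class_b))
    if class_a == class_b:
        combo_total = counts[class_a] * (counts[class_a] - 1) // 2
    else:
        combo_total = counts[class_a] * counts[class_b]
    interacting = {p for p in pairs.pairs if all(t in class_assignments for t in p)}
    obs = sum(
        1
        for p in interacting
        if frozenset(class_assignments[t] for t in p) == wanted
    )
    table = ContingencyTable2x2(
        a=obs,
        b=combo_total - obs,
        c=len(interacting) - obs,
        d=n_pairs - combo_total - len(interacting) + obs,
    )
    res = _result(f"{class_a}-{class_b}|{pairs.source_name}", table, alternative)
    return res


def partner_log_ratio(
    tf: str,
    pairs: InteractionPairSet,
    class_assignments: dict[str, str],
    partner_class: str,
    base: float = 2.0,
) -> float:
    """Log ratio of a TF's observed vs expected partners in one class.

    The expectation is proportional to the class's share of the classified
    TFs available as partners. Returns -inf (with a warning) when the TF
    has no partner in the class; raises if it has no partners at all.
    """
    if tf not in class_assignments:
        raise ValueError(f"{tf} is not classified")
    partners = {
        next(iter(p - {tf}))
        for p in pairs.pairs
        if tf in p and all(t in class_assignments for t in p)
    }
    if not partners:
        raise ValueError(f"{tf} has no classified interaction partners")
    class_size = sum(
        1 for t, c in class_assignments.items() if c == partner_class and t != tf
    )
    if class_size == 0:
        raise ValueError(f"partner class {partner_class} is empty")
    expected = len(partners) * class_size / (len(class_assignments) - 1)
    observed = sum(1 for t in partners if class_assignments[t] == partner_class)
    if observed == 0:
        logger.warning("%s has no partner in class %s; log ratio is -inf",
                       tf, partner_class)
    return _log_ratio(observed, expected, base)


def benjamini_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def property_flags(records, domains: list[str] | None = None) -> pd.DataFrame:
    """Boolean property table for enrichment: Pfam presence, PTM types, PPI.

    Rows are TFs; columns are the given Pfam domains (default: every
    domain seen in the records), the six PTM types, and a PPI flag.
    """
    if domains is None:
        domains = sorted({d for r in records for d, n in r.pfam_counts.items() if n > 0})
    rows = {}
    for r in records:
        rows[r.tf_id] = {
            **{d: r.pfam_counts.get(d, 0) > 0 for d in domains},
            **{name: flag for name, flag in zip(PTM_NAMES, r.ptm_flags)},
            "PPI": r.has_ppi,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def timecourse_enrichment(
    sets: TimeCourseSets | tuple[set, set],
    background_flags: pd.DataFrame,
    class_assignments: dict[str, str] | None = None,
    min_obs: int = 9,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Property enrichment in significantly up-/down-regulated TF sets.

    For each direction, each property column of *background_flags*, and
    each regulatory class (plus an "All" row ignoring class), a Fisher
    test compares the regulated set against the full background. BH
    adjustment is applied across all tests of the analysis as one family,
    so a fully null experiment yields a rejection in at most ~5% of
    repetitions. Rows are kept only when the observed count (enrichments)
    or the expected count (depletions) is at least *min_obs*.
    """
    if isinstance(sets, TimeCourseSets):
        up, down = sets.pooled()
    else:
        up, down = (set(sets[0]), set(sets[1]))
    background = set(background_flags.index)
    stray = (up | down) - background
    if stray:
        raise ValueError(f"set members absent from background: {sorted(stray)[:5]} ...")
    groups: list[tuple[str, set[str]]] = [("All", background)]
    if class_assignments:
        for cls in CLASS_LABELS:
            members = {t for t, c in class_assignments.items() if c == cls} & background
            if members:
                groups.append((cls, members))
    all_rows = []
    for cls, universe in groups:
        for direction, regulated in (("up", up & universe), ("down", down & universe)):
            block = []
            for term in background_flags.columns:
                flags = background_flags.loc[sorted(universe), term].astype(bool)
                n = len(universe)
                feature_total = int(flags.sum())
                obs = int(flags.loc[sorted(regulated)].sum()) if regulated else 0
                table = ContingencyTable2x2(
                    a=obs,
                    b=len(regulated) - obs,
                    c=feature_total - obs,
                    d=n - len(regulated) - feature_total + obs,
                )
                res = _result(term, table, alternative)
                block.append(
                    {
                        "class": cls,
                        "direction": direction,
                        "term": term,
                        "observed": res.observed,
                        "expected": res.expected,
                        "p_value": res.p_value,
                        "effect": res.direction,
                        "log_ratio": res.log_ratio,
                    }
                )
            all_rows.extend(block)
    if all_rows:
        adj = benjamini_adjust([r["p_value"] for r in all_rows])
        for r, q in zip(all_rows, adj):
            r["p_adjusted"] = float(q)
    rows = [
        r for r in all_rows
        if (r["effect"] == "enriched" and r["observed"] >= min_obs)
        or (r["effect"] == "depleted" and r["expected"] >= min_obs)
    ]
    return pd.DataFrame(
        rows,
        columns=["class", "direction", "term", "observed", "expected",
                 "p_value", "p_adjusted", "effect", "log_ratio"],
    )


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results with a stable column order."""
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "p_value": [r.p_value for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
            "log_ratio": [r.log_ratio for r in results],
        }
    )


def all_pairs(tfs) -> list[frozenset]:
    """All unordered pairs over a TF collection (the pair universe)."""
    return [frozenset(p) for p in combinations(sorted(tfs), 2)]
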