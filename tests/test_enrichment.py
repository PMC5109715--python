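"""Fisher-exact enrichment machinery against brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from chromclass import (
    ContingencyTable2x2,
    InteractionPairSet,
    benjamini_adjust,
    fisher_2x2,
    pair_class_enrichment,
    partner_log_ratio,
    property_enrichment,
    timecourse_enrichment,
)
from chromclass.enrichment import property_flags
from chromclass.simulate import generate_pairs, reference_config


def fisher_enumeration_oracle(t: ContingencyTable2x2) -> float:
    """Two-sided p by enumerating all tables with the observed margins."""
    r1, c1 = t.a + t.b, t.a + t.c
    lo = max(0, c1 - (t.c + t.d))
    hi = min(r1, c1)
    pmf = {x: hypergeom(t.total, c1, r1).pmf(x) for x in range(lo, hi + 1)}
    cutoff = pmf[t.a] * (1 + 1e-7)
    return min(1.0, sum(v for v in pmf.values() if v <= cutoff))


class TestFisher:
    def test_matches_enumeration_for_small_tables(self, rng):
        checked = 0
        while checked < 60:
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if a + b + c + d == 0 or a + b + c + d > 30:
                continue
            table = ContingencyTable2x2(a, b, c, d)
            p, _ = fisher_2x2(table)
            assert p == pytest.approx(fisher_enumeration_oracle(table), abs=1e-9)
            checked += 1

    def test_no_association_gives_one(self):
        p, _ = fisher_2x2(ContingencyTable2x2(5, 10, 5, 10))
        assert p == 1.0

    def test_direction_follows_observed_vs_expected(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, 4))
            if a + b + c + d == 0:
                continue
            table = ContingencyTable2x2(a, b, c, d)
            _, direction = fisher_2x2(table)
            assert direction == ("enriched" if table.a > table.expected_a else "depleted")

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestPropertyEnrichment:
    def test_expected_counts_conserve_feature_total(self, default_cohort):
        _, records, truth = default_cohort
        flags = {r.tf_id: r.pfam_counts.get("zf-C2H2", 0) > 0 for r in records}
        results = property_enrichment(truth, flags, "zf-C2H2")
        assert sum(r.expected for r in results) == pytest.approx(sum(flags.values()))

    def test_universal_feature_is_unremarkable(self):
        classes = {f"T{i}": ("P" if i < 5 else "S") for i in range(20)}
        flags = {t: True for t in classes}
        results = property_enrichment(classes, flags)
        for r in results:
            assert r.p_value == 1.0
            assert r.expected == pytest.approx(r.observed)

    def test_missing_flag_rejected(self):
        with pytest.raises(ValueError, match="without a feature flag"):
            property_enrichment({"A": "P", "B": "S"}, {"A": True})


class TestPairEnrichment:
    def test_no_interactions_give_one(self):
        classes = {f"T{i}": ("P" if i < 4 else "S") for i in range(12)}
        empty = InteractionPairSet("none", set())
        res = pair_class_enrichment(empty, classes, "P", "P")
        assert res.p_value == 1.0 and res.observed == 0

    def test_expected_from_all_pairs_universe(self):
        # 4 P and 8 S -> 66 candidate pairs, 6 of them P-P
        classes = {f"T{i}": ("P" if i < 4 else "S") for i in range(12)}
        pairs = InteractionPairSet("x", {frozenset(("T0", "T1")),
                                         frozenset(("T5", "T6"))})
        res = pair_class_enrichment(pairs, classes, "P", "P")
        assert res.observed == 1
        assert res.expected == pytest.approx(6 * 2 / 66)

    def test_planted_within_class_rate_detected(self, default_cohort):
        config, _, truth = default_cohort
        pairs = generate_pairs(config, truth)
        res = pair_class_enrichment(pairs, truth, "P", "P")
        assert res.direction == "enriched" and res.p_value < 0.01

    def test_flat_rates_are_unremarkable(self, default_cohort):
        config, _, truth = default_cohort
        pairs = generate_pairs(config.flat_pair_rates(0.02), truth)
        res = pair_class_enrichment(pairs, truth, "P", "M-")
        assert res.p_value > 0.001  # no planted signal to find

    def test_empty_class_rejected(self):
        classes = {"A": "P", "B": "P"}
        with pytest.raises(ValueError):
            pair_class_enrichment(InteractionPairSet("x", set()), classes, "P", "S")


class TestPartnerLogRatio:
    def _setting(self):
        classes = {f"P{i}": "P" for i in range(10)}
        classes.update({f"S{i}": "S" for i in range(10)})
        classes["X"] = "M+"
        return classes

    def test_observed_equal_expected_is_zero(self):
        classes = self._setting()
        # X has 4 partners; P holds 10 of 20 remaining TFs -> expected 2
        pairs = InteractionPairSet("x", {frozenset(("X", t))
                                         for t in ("P0", "P1", "S0", "S1")})
        assert partner_log_ratio("X", pairs, classes, "P") == pytest.approx(0.0)

    def test_double_expectation_gives_one(self):
        classes = self._setting()
        pairs = InteractionPairSet("x", {frozenset(("X", t))
                                         for t in ("P0", "P1", "P2", "P3")})
        assert partner_log_ratio("X", pairs, classes, "P") == pytest.approx(1.0)

    def test_no_partner_in_class_is_minus_inf(self, caplog):
        classes = self._setting()
        pairs = InteractionPairSet("x", {frozenset(("X", "S0"))})
        with caplog.at_level("WARNING"):
            assert partner_log_ratio("X", pairs, classes, "P") == -math.inf
        assert "no partner" in caplog.text

    def test_zero_partners_rejected(self):
        classes = self._setting()
        with pytest.raises(ValueError, match="no classified"):
            partner_log_ratio("X", InteractionPairSet("x", set()), classes, "P")

    def test_planted_bias_recovered(self, rng):
        # P holds 1/3 of the 500 potential partners, but 2/3 of X's 200
        # partners are planted in P: log2 ratio should recover ~1
        classes = {f"T{i}": ("P" if i < 167 else "S") for i in range(500)}
        classes["X"] = "M+"
        partners = ([f"T{i}" for i in rng.choice(167, 133, replace=False)]
                    + [f"T{167 + i}" for i in rng.choice(333, 67, replace=False)])
        pairs = InteractionPairSet("x", {frozenset(("X", t)) for t in partners})
        lr = partner_log_ratio("X", pairs, classes, "P")
        assert lr == pytest.approx(1.0, abs=0.2)


class TestBenjamini:
    def test_three_element_hand_formula(self):
        np.testing.assert_allclose(
            benjamini_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert (benjamini_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_empty_list(self):
        assert len(benjamini_adjust([])) == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_order_preserving_and_bounded(self, ps):
        adj = benjamini_adjust(ps)
        assert ((adj >= np.asarray(ps) - 1e-12) & (adj <= 1.0)).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestTimecourseEnrichment:
    def test_planted_effect_detected(self, default_cohort):
        from chromclass.simulate import generate_timecourse
        config, records, truth = default_cohort
        sets = generate_timecourse(config, records, truth)
        table = timecourse_enrichment(sets, property_flags(records), truth)
        hits = table[(table["class"] == "All") & (table.p_adjusted < 0.05)]
        planted_up = set(config.timecourse_effects["up"])
        assert planted_up <= set(hits[hits.direction == "up"].term)

    def test_empty_sets_give_empty_table(self, default_cohort):
        _, records, _ = default_cohort
        table = timecourse_enrichment((set(), set()), property_flags(records))
        assert (table.observed == 0).all()
        assert not (table.effect == "enriched").any()

    def test_min_occurrence_filter(self):
        # universe of 100, feature in 25; up set of 20 with 8 flagged:
        # observed 8 (enriched, expected 5) -> dropped by the >= 9 rule
        import pandas as pd
        flags = pd.DataFrame(
            {"term": [True] * 25 + [False] * 75},
            index=[f"T{i}" for i in range(100)])
        up = {f"T{i}" for i in range(8)} | {f"T{i}" for i in range(30, 42)}
        table = timecourse_enrichment((up, set()), flags)
        assert table.empty
        table = timecourse_enrichment((up, set()), flags, min_obs=8)
        assert list(table.term) == ["term"] and table.iloc[0].observed == 8

    def test_stray_member_rejected(self):
        import pandas as pd
        flags = pd.DataFrame({"x": [True, False]}, index=["A", "B"])
        with pytest.raises(ValueError, match="absent from background"):
            timecourse_enrichment(({"C"}, set()), flags)
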