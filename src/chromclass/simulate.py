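"""Synthetic TF annotation data with planted class-conditional structure.

The generator emulates every input the pipeline consumes — annotation
tables, interaction pair lists, binding-site matrices and time-course
up/down sets — for a cohort of TFs drawn from the four regulatory classes
(Pioneer, Settler, positive Migrant, negative Migrant). Class structure is
planted the way the real annotation differs between classes:

* each class has its own categorical distribution over structural
  (TFClass-style) codes, with partial overlap between classes;
* Pfam domain presence is class-conditionally Bernoulli, with domain
  counts overdispersed (negative binomial);
* annotation counts (DBDs, PPIs, phosphorylation sites, zinc fingers)
  have class-specific means around the corpus conventions 4 / 9 / 14,
  e.g. Pioneers carry more DNA-binding domains and zinc fingers, positive
  Migrants more protein-protein interactions;
* TF-TF interaction pairs appear independently with a symmetric
  class-pair rate matrix (within-Pioneer co-binding elevated, Pioneer x
  positive-Migrant depressed);
* binding-site matrices are tuned to class-conditional GC and information
  content targets (negative Migrants AT-rich, Pioneers GC-rich and highly
  specific);
* time-course up/down sets are sampled with planted property-rate
  multipliers.

The default configuration mirrors the reference study conditions: class
sizes 45 / 47 / 77 / 288, about 20 frequent Pfam domains, count averages
near 4 / 9 / 14. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import CLASS_LABELS, PTM_NAMES, UNLABELED, InteractionPairSet, PFMMotif, TFRecord, TimeCourseSets

_ZF_DOMAINS = ("zf-C2H2", "zf-H2C2_2")

# Per-class categorical distributions over structural codes. Supports
# overlap partially (2.3.3 is shared between Pioneers and Settlers, 2.3.1
# between Pioneers and negative Migrants) so classification is hard but
# learnable, as for the real hierarchy where the C2H2 families span classes.
_DEFAULT_TFCLASS_DIST = {
    "P": {"1.1": 0.20, "2.3.3": 0.25, "3.5": 0.20, "6.1": 0.15, "2.3.1": 0.10, "4.1": 0.10},
    "S": {"1.2": 0.35, "6.5": 0.15, "4.1": 0.15, "2.3.3": 0.15, "5.3": 0.10, "1.1": 0.10},
    "M+": {"2.1": 0.35, "2.3.4": 0.25, "5.1": 0.15, "3.2": 0.10, "6.2": 0.10, "1.1": 0.05},
    "M-": {"3.1": 0.40, "3.3": 0.20, "2.3.1": 0.15, "7.1": 0.10, "8.1": 0.10, "3.5": 0.05},
}

# Class-conditional Bernoulli presence rates per Pfam domain. Rates are
# sized so that with the default cohort (457 TFs) roughly 20 domains occur
# in more than 20 TFs.
_DEFAULT_PFAM_RATES = {
    "zf-C2H2":      {"P": 0.65, "S": 0.30, "M+": 0.45, "M-": 0.15},
    "zf-H2C2_2":    {"P": 0.45, "S": 0.15, "M+": 0.25, "M-": 0.05},
    "KRAB":         {"P": 0.40, "S": 0.10, "M+": 0.15, "M-": 0.05},
    "Homeobox":     {"P": 0.05, "S": 0.10, "M+": 0.10, "M-": 0.55},
    "HLH":          {"P": 0.10, "S": 0.50, "M+": 0.10, "M-": 0.08},
    "bZIP_1":       {"P": 0.25, "S": 0.15, "M+": 0.10, "M-": 0.08},
    "Ets":          {"P": 0.30, "S": 0.08, "M+": 0.05, "M-": 0.05},
    "Fork_head":    {"P": 0.05, "S": 0.05, "M+": 0.05, "M-": 0.30},
    "HMG_box":      {"P": 0.08, "S": 0.10, "M+": 0.08, "M-": 0.20},
    "Hormone_recep": {"P": 0.05, "S": 0.08, "M+": 0.45, "M-": 0.05},
    "zf-C4":        {"P": 0.05, "S": 0.08, "M+": 0.40, "M-": 0.05},
    "PAS":          {"P": 0.05, "S": 0.25, "M+": 0.08, "M-": 0.05},
    "T-box":        {"P": 0.05, "S": 0.20, "M+": 0.05, "M-": 0.05},
    "POU":          {"P": 0.03, "S": 0.05, "M+": 0.05, "M-": 0.25},
    "Pou_homeo":    {"P": 0.03, "S": 0.05, "M+": 0.03, "M-": 0.18},
    "SCAN":         {"P": 0.18, "S": 0.08, "M+": 0.12, "M-": 0.05},
    "BTB":          {"P": 0.20, "S": 0.08, "M+": 0.10, "M-": 0.05},
    "Paired_box":   {"P": 0.03, "S": 0.08, "M+": 0.08, "M-": 0.15},
    "RHD_DNA_bind": {"P": 0.08, "S": 0.12, "M+": 0.12, "M-": 0.08},
    "STAT_bind":    {"P": 0.05, "S": 0.08, "M+": 0.12, "M-": 0.08},
    "MADF_DNA_bdg": {"P": 0.10, "S": 0.10, "M+": 0.10, "M-": 0.10},
    "GATA":         {"P": 0.12, "S": 0.12, "M+": 0.08, "M-": 0.08},
}

# Class-specific count means. Pioneers carry many DBDs and zinc fingers,
# positive Migrants many PPIs; phosphorylation is similar across classes.
_DEFAULT_COUNT_MEANS = {
    "n_dbd": {"P": 7.0, "S": 2.5, "M+": 5.0, "M-": 1.8},
    "n_ppi": {"P": 6.0, "S": 7.0, "M+": 15.0, "M-": 8.0},
    "n_phospho": {"P": 13.0, "S": 15.0, "M+": 16.0, "M-": 13.0},
    "n_zf": {"P": 5.0, "S": 1.2, "M+": 3.0, "M-": 0.6},
}

_DEFAULT_PTM_RATES = {
    "P": (0.80, 0.25, 0.20, 0.30, 0.15, 0.05),
    "S": (0.85, 0.30, 0.25, 0.50, 0.30, 0.05),
    "M+": (0.85, 0.35, 0.30, 0.35, 0.20, 0.08),
    "M-": (0.75, 0.25, 0.35, 0.30, 0.15, 0.05),
}

# Symmetric per-class-pair interaction probabilities: co-binding enriched
# within Pioneers and Settlers, depleted between Pioneers and positive
# Migrants, baseline 0.01.
_DEFAULT_PAIR_RATES = {
    ("P", "P"): 0.10, ("S", "S"): 0.05, ("M+", "M+"): 0.03, ("M-", "M-"): 0.015,
    ("P", "S"): 0.02, ("P", "M+"): 0.002, ("P", "M-"): 0.01,
    ("S", "M+"): 0.01, ("S", "M-"): 0.01, ("M+", "M-"): 0.01,
}

_DEFAULT_GC_TARGETS = {"P": 0.60, "S": 0.55, "M+": 0.50, "M-": 0.25}
_DEFAULT_IC_TARGETS = {"P": 10.4, "S": 10.3, "M+": 7.7, "M-": 9.3}

# Planted on moderately rare properties so the regulated sets stay a
# realistic minority of the cohort and the plants are not mutually diluting.
# Multipliers act on the per-time-point inclusion probability; pooling the
# time points compresses the ratio, so a multiplier of 5 yields a pooled-set
# property rate roughly 3.5x background — strong enough that the planted
# terms survive a whole-analysis BH correction with high probability even
# for terms carried by only ~40 of the 457 TFs.
_DEFAULT_TIMECOURSE_EFFECTS = {
    "up": {"Ets": 5.0, "Hormone_recep": 5.0},
    "down": {"KRAB": 5.0, "ubiquitination": 2.5},
}


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic cohort.

    The defaults are the study conditions used throughout the test suite;
    ``null_timecourse()`` and ``flat_pair_rates()`` derive null variants
    for calibration checks.
    """

    n_per_class: dict = field(default_factory=lambda: {"P": 45, "S": 47, "M+": 77, "M-": 288})
    class_tfclass_dist: dict = field(default_factory=lambda: {
        c: dict(d) for c, d in _DEFAULT_TFCLASS_DIST.items()})
    class_pfam_rates: dict = field(default_factory=lambda: {
        d: dict(r) for d, r in _DEFAULT_PFAM_RATES.items()})
    count_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in _DEFAULT_COUNT_MEANS.items()})
    count_family: str = "nbinom"  # or "poisson"
    nbinom_size: float = 5.0
    ptm_rates: dict = field(default_factory=lambda: dict(_DEFAULT_PTM_RATES))
    pair_rates: dict = field(default_factory=lambda: dict(_DEFAULT_PAIR_RATES))
    gc_targets: dict = field(default_factory=lambda: dict(_DEFAULT_GC_TARGETS))
    ic_targets: dict = field(default_factory=lambda: dict(_DEFAULT_IC_TARGETS))
    motif_length: int = 12
    motif_depth: int = 100
    timecourse_effects: dict | None = field(
        default_factory=lambda: {d: dict(m) for d, m in _DEFAULT_TIMECOURSE_EFFECTS.items()})
    timecourse_base_rate: float = 0.12
    time_points: tuple[str, ...] = ("t04h", "t24h")
    unlabeled_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        for cls in CLASS_LABELS:
            if self.n_per_class.get(cls, 0) < 1:
                errors.append(f"n_per_class[{cls}] must be >= 1")
            dist = self.class_tfclass_dist.get(cls, {})
            if not dist or abs(sum(dist.values()) - 1) > 1e-6:
                errors.append(f"class_tfclass_dist[{cls}] must sum to 1")
            if any(not (0 <= p <= 1) for p in dist.values()):
                errors.append(f"class_tfclass_dist[{cls}] has probability outside [0,1]")
        for dom, rates in self.class_pfam_rates.items():
            if any(not (0 <= rates.get(c, 0) <= 1) for c in CLASS_LABELS):
                errors.append(f"class_pfam_rates[{dom}] outside [0,1]")
        for key, rate in self.pair_rates.items():
            if not (0 <= rate <= 1):
                errors.append(f"pair_rates[{key}] outside [0,1]")
        if not (0 <= self.unlabeled_fraction <= 1):
            errors.append("unlabeled_fraction outside [0,1]")
        if not (0 <= self.timecourse_base_rate <= 1):
            errors.append("timecourse_base_rate outside [0,1]")
        if self.count_family not in ("nbinom", "poisson"):
            errors.append("count_family must be 'nbinom' or 'poisson'")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))

    def pair_rate(self, class_i: str, class_j: str) -> float:
        key = (class_i, class_j)
        if key in self.pair_rates:
            return self.pair_rates[key]
        return self.pair_rates[(class_j, class_i)]

    def null_timecourse(self) -> "SimulationConfig":
        """Same cohort, but no planted time-course effect (multipliers 1)."""
        return replace(self, timecourse_effects={"up": {}, "down": {}})

    def flat_pair_rates(self, rate: float = 0.02) -> "SimulationConfig":
        """Same cohort, but a uniform interaction rate for all class pairs."""
        flat = {key: rate for key in self.pair_rates}
        return replace(self, pair_rates=flat)


def reference_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The shipped default cohort: 45/47/77/288 TFs with planted structure."""
    return SimulationConfig(seed=seed, **overrides)


def _draw_count(rng: np.random.Generator, mean: float, config: SimulationConfig) -> int:
    if mean <= 0:
        return 0
    if config.count_family == "poisson":
        return int(rng.poisson(mean))
    size = config.nbinom_size
    return int(rng.negative_binomial(size, size / (size + mean)))


def generate_tf_table(config: SimulationConfig) -> tuple[list[TFRecord], dict[str, str]]:
    """Generate the annotation cohort and its ground-truth labels.

    Returns (records, truth). A configured fraction of records carries no
    label (``unlabeled``) while the truth mapping always holds the
    generating class; the truth is the sidecar, never written into the
    annotation table itself.
    """
    rng = np.random.default_rng(config.seed)
    classes = [c for c in CLASS_LABELS for _ in range(config.n_per_class[c])]
    order = rng.permutation(len(classes))
    records, truth = [], {}
    unlabeled = rng.random(len(classes)) < config.unlabeled_fraction
    for i, idx in enumerate(order):
        cls = classes[idx]
        tf_id = f"TF{i + 1:04d}"
        truth[tf_id] = cls
        dist = config.class_tfclass_dist[cls]
        codes = sorted(dist)
        code = codes[rng.choice(len(codes), p=np.array([dist[c] for c in codes]))]
        pfam: dict[str, int] = {}
        for dom in sorted(config.class_pfam_rates):
            if dom in _ZF_DOMAINS:
                continue  # zinc-finger content is drawn through its count model
            if rng.random() < config.class_pfam_rates[dom].get(cls, 0.0):
                pfam[dom] = 1 + int(rng.poisson(0.5))
        n_zf = _draw_count(rng, config.count_means["n_zf"][cls], config)
        if n_zf > 0:
            to_c2h2 = int(rng.binomial(n_zf, 0.7))
            if to_c2h2:
                pfam["zf-C2H2"] = to_c2h2
            if n_zf - to_c2h2:
                pfam["zf-H2C2_2"] = n_zf - to_c2h2
        n_dbd = _draw_count(rng, config.count_means["n_dbd"][cls], config)
        n_ppi = _draw_count(rng, config.count_means["n_ppi"][cls], config)
        ptm = tuple(rng.random() < r for r in config.ptm_rates[cls])
        n_phospho = (
            _draw_count(rng, config.count_means["n_phospho"][cls], config)
            if ptm[0] else 0
        )
        records.append(
            TFRecord(
                tf_id=tf_id,
                tfclass_code=code,
                pfam_counts=pfam,
                has_dbd=n_dbd > 0,
                n_dbd=n_dbd,
                has_ppi=n_ppi > 0,
                n_ppi=n_ppi,
                ptm_flags=ptm,
                n_phospho_sites=n_phospho,
                n_zf_frequent=n_zf,
                label=UNLABELED if unlabeled[i] else cls,
            )
        )
    return records, truth


def generate_pairs(
    config: SimulationConfig, class_assignments: dict[str, str]
) -> InteractionPairSet:
    """Draw TF-TF interaction pairs with class-pair-dependent rates.

    Every unordered pair is included independently with the rate of its
    class combination.
    """
    rng = np.random.default_rng(config.seed + 1)
    tfs = sorted(class_assignments)
    n = len(tfs)
    ii, jj = np.triu_indices(n, k=1)
    rates = np.array(
        [config.pair_rate(class_assignments[tfs[i]], class_assignments[tfs[j]])
         for i, j in zip(ii, jj)]
    )
    keep = rng.random(len(rates)) < rates
    pairs = {frozenset((tfs[i], tfs[j])) for i, j in zip(ii[keep], jj[keep])}
    return InteractionPairSet(source_name="synthetic", pairs=pairs)


def generate_motifs(
    config: SimulationConfig, class_assignments: dict[str, str]
) -> list[PFMMotif]:
    """Generate one binding-site matrix per TF with class GC/IC targets.

    Each column is either "specific" (one dominant base at frequency 0.94)
    or "degenerate" (Dirichlet noise around a GC-weighted background); the
    fraction of specific columns is solved per class so the expected total
    information content matches the class target, and dominant bases are
    drawn G/C with the class GC target probability.
    """
    rng = np.random.default_rng(config.seed + 2)
    L, depth = config.motif_length, config.motif_depth
    ic_specific = 1.58  # bits per column for a 0.94-dominant column
    motifs = []
    for tf_id in sorted(class_assignments):
        cls = class_assignments[tf_id]
        gc = config.gc_targets[cls]
        base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        # degenerate columns carry the information of the skewed background
        # plus ~0.1 bit of sampling noise
        ic_degenerate = float(2 + np.sum(base * np.log2(base))) + 0.10
        q = (config.ic_targets[cls] / L - ic_degenerate) / (ic_specific - ic_degenerate)
        q = float(np.clip(q, 0.0, 1.0))
        cols = []
        for _ in range(L):
            if rng.random() < q:
                if rng.random() < gc:
                    dominant = rng.choice([1, 2])  # C or G
                else:
                    dominant = rng.choice([0, 3])  # A or T
                p = np.full(4, 0.02)
                p[dominant] = 0.94
            else:
                base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
                p = rng.dirichlet(base * 60)
            cols.append(rng.multinomial(depth, p))
        counts = np.array(cols, dtype=float).T
        counts[:, counts.sum(axis=0) == 0] = 1.0  # guard: no all-zero column
        motifs.append(PFMMotif(tf_id=tf_id, counts=counts))
    return motifs


def generate_timecourse(
    config: SimulationConfig,
    records: list[TFRecord],
    class_assignments: dict[str, str] | None = None,
) -> TimeCourseSets:
    """Sample up/down regulated TF sets with planted property effects.

    Per time point each TF enters the up (or down) set with the base rate
    multiplied by the configured effect multipliers of the properties it
    carries (Pfam domain names or PTM type names). A TF never enters both
    directions at the same time point. With ``timecourse_effects=None``
    the experiment is absent and the sets are empty.
    """
    if config.timecourse_effects is None:
        return TimeCourseSets(time_points=config.time_points,
                              up_sets={t: set() for t in config.time_points},
                              down_sets={t: set() for t in config.time_points})
    rng = np.random.default_rng(config.seed + 3)
    effects = {d: config.timecourse_effects.get(d, {}) for d in ("up", "down")}

    def multiplier(rec: TFRecord, direction: str) -> float:
        m = 1.0
        for prop, mult in effects[direction].items():
            if prop in PTM_NAMES:
                has = rec.ptm_flags[PTM_NAMES.index(prop)]
            elif prop == "PPI":
                has = rec.has_ppi
            else:
                has = rec.pfam_counts.get(prop, 0) > 0
            if has:
                m *= mult
        return m

    up_sets = {t: set() for t in config.time_points}
    down_sets = {t: set() for t in config.time_points}
    base = config.timecourse_base_rate
    for tp in config.time_points:
        for rec in records:
            p_up = min(base * multiplier(rec, "up"), 0.6)
            p_down = min(base * multiplier(rec, "down"), 0.6)
            u = rng.random()
            if u < p_up:
                up_sets[tp].add(rec.tf_id)
            elif u < p_up + p_down:
                down_sets[tp].add(rec.tf_id)
    return TimeCourseSets(
        time_points=config.time_points, up_sets=up_sets, down_sets=down_sets
    )
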