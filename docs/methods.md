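# Methods

## The classification model

The package treats regulatory-function assignment as a four-class
problem over binary feature vectors. The classes are Pioneer (P),
Settler (S), positive Migrant (M+) and negative Migrant (M-); input
labels for a training subset are taken as given (the chromatin-opening
index that defines them upstream is not recomputed here).

### Feature encoding

Each TF is encoded as ten named bit blocks, concatenated in a fixed
order (`TF_Class, PD, DBD, N_DBD, PPI, N_PPI, N_PhS, PTM, Ind_PTM,
N_ZFD`):

* **TF_Class** — one bit per structural superclass and one per class of
  a configurable registry. The shipped registry has 10 superclasses and
  37 classes (47 bits). Because the C2H2 zinc-finger class dominates
  real corpora, the default variant replaces its single class bit with
  one bit per family (2.3.1–2.3.4), giving 50 bits. Setting exactly the
  superclass bit and one class bit yields Hamming distance 2 between
  classes of a superclass and 4 across superclasses, so nearest-neighbour
  structure in feature space follows the classification hierarchy. Codes
  that resolve only to a superclass (e.g. uncharacterized "0.0" entries)
  set the superclass bit alone, with a logged warning rather than an
  error, since real tables contain such rows. Note the registry class
  list is a package default: 36 of the 37 classes are those observed in
  the annotated human corpus, one ("5.2") is included to complete the
  documented 10 + 37 dimensionality.
* **PD** — presence bits for the "frequent" Pfam domains, defined as
  domains carried by more than `min_pfam_freq` TFs (default 20), ordered
  by descending corpus frequency with lexicographic tie-break (the order
  is a determinism choice; nothing downstream depends on it).
* **DBD, PPI, PTM** — single presence bits.
* **N_DBD, N_PPI, N_PhS** — two-bit thermometer encodings of counts
  against an average: `[1 1]` strictly above, `[1 0]` from one up to and
  including the average, `[0 0]` for zero. The boundary *count = average*
  maps to `[1 0]` (the "between one and the average" band is read as
  inclusive; "higher than" is strict). The averages default to the
  corpus conventions 4 (DBDs), 9 (PPIs) and 14 (phosphorylation sites);
  recomputation from the data at hand is available via
  `build_encoding_config(..., fixed_averages=False)`.
* **Ind_PTM** — six bits in fixed order: phosphorylation, acetylation,
  methylation, ubiquitination, sumoylation, O-GlcNAc.
* **N_ZFD** — thermometer of the combined zf-C2H2 + zf-H2C2_2 domain
  count with fixed cutoff 3 (`[1 1]` for >3, `[1 0]` for 1–3).

Encoding is a pure function: identical records and configuration give
byte-identical vectors.

### Balanced one-vs-rest ensemble

Each case *c* vs Rest is balanced by random under-sampling without
replacement: the larger of the two sides is shuffled and partitioned
into `k = max(1, round(|larger| / |smaller|))` subsets whose sizes
differ by at most one; each subset paired with the entire smaller side
is one training task. This single rule reproduces the reference split
counts 9 / 9 / 5 / 2 from training sizes 45 / 47 / 77 / 288, including
the negative-Migrant case where the *specific* class is the larger side
and is therefore the side split (two subsets averaging 144 against the
full 169-strong rest). Splits are drawn independently per case from the
case seed; whether the original procedure re-used splits across cases
is unknowable from its description, and independence is the simpler
contract.

One classifier is fitted per task — by default a random forest with the
Gini criterion and 500 trees (the tree count is a package default,
chosen large enough that forest-to-forest variance is negligible next
to split-to-split variance). A TF's per-case score is the mean of its
per-task positive-class probabilities; the final label is the argmax
over the four per-case averages and the margin is the difference
between the two largest averages. Exact ties are broken in the fixed
order P, S, M+, M- with a logged warning; ties are measure-zero but the
tie-break must be deterministic. "Ensemble" here means plain averaging
over split models; no boosting wrapper is applied.

### Model and feature selection

Performance estimation uses **bootstrap cross-validation**: each fold
draws an independent stratified 80/20 train/test split (Monte-Carlo
cross-validation, not disjoint k-fold partitions — the folds are
re-sampled, matching the repeated-random-sampling description of the
procedure), with 10 runs × 5 folds = 50 per-fold records of precision,
recall, F-score, MCC and AUC. Degenerate metric denominators (e.g. no
positive predictions) return 0 with a warning rather than failing a
whole run. AUC is the rank statistic (ties count one half), so it is
invariant under monotone transforms of the scores. Hyperparameter grids
(C, γ ∈ 2⁻⁴…2⁴; polynomial degree 2–3; k ∈ {3,5,7,9}) are re-searched
inside each fold's training portion with AUC as the inner criterion.

Configurations are compared with the **two-sided paired Wilcoxon
signed-rank test** on per-fold AUCs, dropping zero differences (the
classic reduction); the exact null distribution is used for small
samples without ties and the normal approximation otherwise. If all
paired differences are zero the comparison is uninformative and p = 1
is returned with a warning.

Property scoring reports, per block, the sum of the forest's per-bit
impurity importances (normalized to sum to one across blocks) and the
block's single-block CV AUC. The forward best-first search starts from
the best single block and greedily adds the block with the best mean
AUC, recording each step's Wilcoxon p against the previous step; the
full trace is kept even where AUC declines, and the selected subset is
the trace prefix with maximal mean AUC (the search itself has no early
stopping — the argmax prefix is the stop rule).

### Enrichment statistics

All enrichment tests are two-sided Fisher exact tests on 2×2 tables
(the two-sided variant is the default of standard statistical software;
one-sided alternatives are available by argument). Expected counts are
`row total × column total / grand total`; *enriched* means observed >
expected. Log ratios are log₂(observed/expected) by default (the base is
configurable; ratios are base-independent up to scale).

* **Per-class property enrichment** crosses class membership with a
  boolean feature over the full classified universe.
* **Class-pair interaction enrichment** uses the all-unordered-pairs
  universe over classified TFs — n(n−1)/2 candidate pairs — crossing
  "the pair is the (a,b) class combination" with "the pair interacts".
* **Partner log ratio** for one TF compares its observed partners in a
  class with the class's share of all available partners; a TF with no
  partner in the class yields −∞ with a warning, a TF with no partners
  at all is an error.
* **Time-course enrichment** pools the per-time-point up and down sets
  and tests every property per direction for each class and for the
  pooled "All" group. Benjamini–Hochberg adjustment is applied **across
  all tests of one analysis call as a single family**. A per-block
  (class × direction) family was considered and rejected: with ~10
  blocks each controlled at FDR 5%, a fully null experiment produces a
  spurious adjusted discovery in roughly one seed in six, whereas the
  single-family scope bounds the whole-analysis false-rejection rate
  near 5% (measured: 0 of 20 null seeds). Rows are reported only when
  observed ≥ 9 (enrichments) or expected ≥ 9 (depletions); the filter is
  applied after adjustment, so it affects listing, not correction.

Note BH adjustment is *not* idempotent in general (re-adjusting
[0, 0.75, 1] gives [0, 1, 1]); downstream code must not re-adjust
already-adjusted columns.

### Motif metrics

GC content is the pooled fraction of C+G counts over all matrix
positions (a per-column mean is available by flag; the two differ only
for position-dependent column depths). Information content is the
classic per-column `2 − H(p)` bits against a uniform background, summed
over columns, with no pseudocounts and no small-sample correction —
the standard choice, and the one consistent with per-class motif
averages in the 7–10 bit range. Both binary cutoffs are strict:
GC > 0.40, IC > 9.0.

## The synthetic cohort

The generator emulates the reference study conditions: 45 P + 47 S +
77 M+ + 288 M- TFs; ~20 Pfam domains frequent enough to encode;
annotation count means near 4 / 9 / 14. Class structure is planted as:

* per-class categorical distributions over structural codes, with
  deliberate overlap (e.g. the 2.3.3 zinc-finger family is shared
  between Pioneers and Settlers) so classes are learnable but not
  trivially separable on TF_Class alone;
* class-conditional Bernoulli Pfam presence and negative-binomial counts
  (size 5; Poisson available by flag) — annotation counts are
  overdispersed in real corpora, though the downstream thermometer
  encodings only see thresholded values, so the family choice is not
  critical;
* Pioneers carry many DBDs and zinc fingers, positive Migrants many
  PPIs, mirroring the qualitative enrichment pattern of the real
  classes;
* a symmetric class-pair interaction rate matrix (baseline ~0.01,
  within-Pioneer co-binding 0.10, Pioneer × positive-Migrant 0.002);
* binding-site matrices tuned to class GC targets (0.60 / 0.55 / 0.50 /
  0.25) and total-IC targets (10.4 / 10.3 / 7.7 / 9.3 bits over 12
  columns): each column is "specific" (one base at frequency 0.94,
  drawn G/C with the class GC target probability) or "degenerate"
  (Dirichlet noise around a GC-weighted background), with the specific
  fraction solved per class so the expected IC — including the
  information carried by the skewed background itself — meets the
  target;
* time-course up/down sets sampled per time point at base inclusion
  rate 0.12, multiplied by planted effect multipliers (5× on the
  moderately rare Ets and Hormone_recep domains for up, 5× KRAB and
  2.5× ubiquitination for down, capped at 0.6 per direction). The
  multipliers act per time point; pooling two time points compresses
  the realized pooled-set rate ratio to roughly 3.5× background.
  Planting on rare-to-moderate properties keeps the regulated sets a
  minority of the cohort, so the plants do not dilute one another —
  an earlier draft planting on a ~50%-prevalence domain made over half
  the cohort "regulated" and masked the rarer plants.

All generators are pure functions of (config, seed); ground-truth
labels live in a sidecar mapping, never in the annotation table handed
to the pipeline.

### What passing tests do and do not show

The synthetic cohort has conditionally independent features given the
class, clean labels, and no missing annotation beyond what the
unlabeled fraction hides. Real annotation is correlated (PTM detection
depends on study coverage), labels are thresholded continuous indices
with borderline noise, and identifier mapping loses TFs. Recovery of
≥ 90% of held-out synthetic labels therefore validates the machinery —
encoding, balancing, averaging, arbitration — not the real-data error
rate, which for the original corpus was materially lower
(cross-validated AUC around 0.82–0.92).

## Problem sizes and runtime defaults

The test suite and acceptance checks run the full cohort (457 TFs, 89
bits) with 300-tree forests for recovery and 50–100-tree forests inside
cross-validation loops; CV-based tests use 2–4 runs of 3–5 folds. These
sizes give stable statistics for the planted effect magnitudes while
keeping a full suite run under a minute; all entry points accept the
full 10 × 5 setting and 500-tree default for production use.

## Known limitations

* The registry ships one fixed class list; corpora classified under a
  different hierarchy revision need a custom `ClassRegistry`.
* Probabilities from the averaged ensemble are not calibrated; the
  margin is a ranking statistic, not a posterior gap.
* `bootstrap_cv` requires both classes in every resample, so very small
  balanced tasks (< ~10 TFs) can exhaust its re-draw budget.
* The Wilcoxon comparison assumes per-fold AUCs are exchangeable pairs;
  Monte-Carlo folds share training data, so p-values are approximate —
  a known property of repeated-resampling designs, acceptable for
  ranking configurations.
* Identifiers are opaque strings; nothing maps gene symbols to protein
  identifiers.
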