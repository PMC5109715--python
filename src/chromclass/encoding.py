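"""Binary feature encoding of transcription factor annotations.

Every TF property is encoded as a short binary block; the concatenation of
the ten blocks is the feature vector used for classification:

``TF_Class``
    One bit per structural superclass plus one bit per class; a TF sets
    the bit of its superclass and (when resolvable) of its class. Two TFs
    from different classes of the same superclass are then at Hamming
    distance 2, TFs from different superclasses at distance 4, so the
    encoding orders structural similarity the way the hierarchy does.
``PD``
    One presence bit per "frequent" Pfam domain in the corpus.
``DBD``, ``PPI``, ``PTM``
    Single presence bits.
``N_DBD``, ``N_PPI``, ``N_PhS``
    Two-bit thermometer encodings of counts against a corpus average:
    ``[1 1]`` above average, ``[1 0]`` between one and the average
    (inclusive), ``[0 0]`` for zero.
``Ind_PTM``
    Six bits, one per post-translational modification type.
``N_ZFD``
    Two-bit thermometer of the count of the frequent zinc-finger domains
    (zf-C2H2 + zf-H2C2_2) against a fixed cutoff of three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import PTM_NAMES, TFRecord, validate_tfclass_code

logger = logging.getLogger(__name__)

#: Fixed concatenation order of the ten named blocks.
BLOCK_ORDER = (
    "TF_Class",
    "PD",
    "DBD",
    "N_DBD",
    "PPI",
    "N_PPI",
    "N_PhS",
    "PTM",
    "Ind_PTM",
    "N_ZFD",
)

# Class codes present in the annotated human TF corpus, by superclass.
# The single C2H2 zinc-finger class (2.3) dominates the corpus; the "split"
# registry variant replaces its one bit by one bit per family (2.3.1-2.3.4)
# to balance subset sizes.
_DEFAULT_CLASSES = (
    "0.2", "0.3", "0.4",
    "1.1", "1.2", "1.3",
    "2.1", "2.2", "2.3", "2.5", "2.6", "2.7", "2.8", "2.9",
    "3.1", "3.2", "3.3", "3.4", "3.5", "3.6", "3.7",
    "4.1", "4.2",
    "5.1", "5.2", "5.3",
    "6.1", "6.2", "6.3", "6.4", "6.5", "6.7",
    "7.1", "7.2",
    "8.1", "8.2",
    "9.1",
)

_C2H2_FAMILIES = ("2.3.1", "2.3.2", "2.3.3", "2.3.4")


@dataclass(frozen=True)
class ClassRegistry:
    """Ordered superclass and class codes defining the TF_Class block."""

    superclasses: tuple[str, ...]
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.superclasses)) != len(self.superclasses):
            raise ValueError("duplicate superclass codes")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class codes")
        sc = set(self.superclasses)
        for code in self.classes:
            validate_tfclass_code(code)
            if code.split(".")[0] not in sc:
                raise ValueError(f"class {code} has no registered superclass")

    @property
    def n_bits(self) -> int:
        return len(self.superclasses) + len(self.classes)

    @property
    def bit_labels(self) -> tuple[str, ...]:
        return tuple(f"sc{c}" for c in self.superclasses) + self.classes


def default_registry(split_c2h2: bool = True) -> ClassRegistry:
    """The shipped human TF registry: 10 superclasses and 37 classes.

    With ``split_c2h2=False`` the registry yields the base 47-bit TF_Class
    block (10 + 37). With the default ``split_c2h2=True`` the single 2.3
    bit is replaced by the four C2H2 family bits, giving 50 bits.
    """
    superclasses = tuple(str(i) for i in range(10))
    if not split_c2h2:
        return ClassRegistry(superclasses, _DEFAULT_CLASSES)
    classes = []
    for code in _DEFAULT_CLASSES:
        if code == "2.3":
            classes.extend(_C2H2_FAMILIES)
        else:
            classes.append(code)
    return ClassRegistry(superclasses, tuple(classes))


@dataclass(frozen=True)
class EncodingConfig:
    """Everything needed to encode a TFRecord deterministically."""

    registry: ClassRegistry
    frequent_pfam: tuple[str, ...]
    avg_n_dbd: float = 4.0
    avg_n_ppi: float = 9.0
    avg_n_phospho: float = 14.0
    zf_high_threshold: int = 3

    def __post_init__(self) -> None:
        if not self.frequent_pfam:
            raise ValueError("frequent_pfam must be non-empty")
        if len(set(self.frequent_pfam)) != len(self.frequent_pfam):
            raise ValueError("duplicate frequent Pfam domains")
        for name in ("avg_n_dbd", "avg_n_ppi", "avg_n_phospho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class FeatureVector:
    """Named binary blocks for one TF, in fixed concatenation order."""

    tf_id: str
    blocks: dict[str, np.ndarray] = field(default_factory=dict)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.blocks[b] for b in BLOCK_ORDER])

    def __len__(self) -> int:
        return sum(len(self.blocks[b]) for b in BLOCK_ORDER)


def build_encoding_config(
    records: list[TFRecord],
    min_pfam_freq: int = 20,
    registry: ClassRegistry | None = None,
    fixed_averages: bool = True,
) -> EncodingConfig:
    """Derive an :class:`EncodingConfig` from an annotation corpus.

    Frequent Pfam domains are those present in more than ``min_pfam_freq``
    TFs, ordered by descending frequency with ties broken by name. Count
    averages default to the fixed conventions 4 (DBDs), 9 (PPIs) and 14
    (phosphorylation sites); pass ``fixed_averages=False`` to recompute
    them as arithmetic means over *records*.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if min_pfam_freq < 0:
        raise ValueError("min_pfam_freq must be >= 0")
    freq: dict[str, int] = {}
    for rec in records:
        for dom, count in rec.pfam_counts.items():
            if count > 0:
                freq[dom] = freq.get(dom, 0) + 1
    frequent = sorted(
        (d for d, n in freq.items() if n > min_pfam_freq),
        key=lambda d: (-freq[d], d),
    )
    if not frequent:
        raise ValueError(
            f"no Pfam domain occurs in more than {min_pfam_freq} TFs; "
            "lower min_pfam_freq"
        )
    if fixed_averages:
        avgs = {"avg_n_dbd": 4.0, "avg_n_ppi": 9.0, "avg_n_phospho": 14.0}
    else:
        avgs = {
            "avg_n_dbd": float(np.mean([r.n_dbd for r in records])),
            "avg_n_ppi": float(np.mean([r.n_ppi for r in records])),
            "avg_n_phospho": float(np.mean([r.n_phospho_sites for r in records])),
        }
    return EncodingConfig(
        registry=registry or default_registry(),
        frequent_pfam=tuple(frequent),
        **avgs,
    )


def encode_tfclass(code: str, registry: ClassRegistry) -> np.ndarray:
    """Encode a dotted structural code as the TF_Class bit block.

    The superclass bit is always set; the class bit (or, in a registry with
    the C2H2 family split, the family bit) is set when the code resolves to
    a registered class. Codes resolving only to a superclass — e.g. the
    uncharacterized "0.0" entries — get the superclass bit alone, with a
    logged warning.
    """
    validate_tfclass_code(code)
    parts = code.split(".")
    sc = parts[0]
    if sc not in registry.superclasses:
        raise ValueError(f"unknown superclass {sc!r} in code {code!r}")
    bits = np.zeros(registry.n_bits, dtype=np.int8)
    bits[registry.superclasses.index(sc)] = 1
    class_codes = registry.classes
    for depth in range(len(parts), 1, -1):
        candidate = ".".join(parts[:depth])
        if candidate in class_codes:
            bits[len(registry.superclasses) + class_codes.index(candidate)] = 1
            break
    else:
        logger.warning(
            "TFClass code %s resolves only to superclass %s; class bit left unset",
            code,
            sc,
        )
    return bits


def encode_thermometer(n: int, avg: float) -> np.ndarray:
    """Two-bit reduced-resolution count encoding against an average.

    ``[1 1]`` if ``n`` exceeds the average (strict), ``[1 0]`` if it lies
    between one and the average inclusive, ``[0 0]`` if it is zero.
    """
    if avg <= 0:
        raise ValueError("avg must be > 0")
    if n < 0:
        raise ValueError("count must be >= 0")
    if n > avg:
        return np.array([1, 1], dtype=np.int8)
    if n >= 1:
        return np.array([1, 0], dtype=np.int8)
    return np.array([0, 0], dtype=np.int8)


def encode_zf(n_zf: int, threshold: int = 3) -> np.ndarray:
    """Two-bit encoding of the frequent zinc-finger domain count.

    ``[1 1]`` for more than *threshold* domains, ``[1 0]`` for one to
    *threshold*, ``[0 0]`` for none.
    """
    if n_zf < 0:
        raise ValueError("count must be >= 0")
    if n_zf > threshold:
        return np.array([1, 1], dtype=np.int8)
    if n_zf >= 1:
        return np.array([1, 0], dtype=np.int8)
    return np.array([0, 0], dtype=np.int8)


def encode_tf(record: TFRecord, config: EncodingConfig) -> FeatureVector:
    """Encode one TFRecord into its named binary blocks."""
    blocks = {
        "TF_Class": encode_tfclass(record.tfclass_code, config.registry),
        "PD": np.array(
            [1 if record.pfam_counts.get(d, 0) > 0 else 0 for d in config.frequent_pfam],
            dtype=np.int8,
        ),
        "DBD": np.array([int(record.has_dbd)], dtype=np.int8),
        "N_DBD": encode_thermometer(record.n_dbd, config.avg_n_dbd),
        "PPI": np.array([int(record.has_ppi)], dtype=np.int8),
        "N_PPI": encode_thermometer(record.n_ppi, config.avg_n_ppi),
        "N_PhS": encode_thermometer(record.n_phospho_sites, config.avg_n_phospho),
        "PTM": np.array([int(record.has_ptm)], dtype=np.int8),
        "Ind_PTM": np.array([int(f) for f in record.ptm_flags], dtype=np.int8),
        "N_ZFD": encode_zf(record.n_zf_frequent, config.zf_high_threshold),
    }
    return FeatureVector(tf_id=record.tf_id, blocks=blocks)


def bit_labels(config: EncodingConfig) -> dict[str, tuple[str, ...]]:
    """Per-block bit labels used as feature-matrix column names."""
    return {
        "TF_Class": config.registry.bit_labels,
        "PD": tuple(config.frequent_pfam),
        "DBD": ("has",),
        "N_DBD": ("lo", "hi"),
        "PPI": ("has",),
        "N_PPI": ("lo", "hi"),
        "N_PhS": ("lo", "hi"),
        "PTM": ("has",),
        "Ind_PTM": PTM_NAMES,
        "N_ZFD": ("lo", "hi"),
    }


def encode_table(records: list[TFRecord], config: EncodingConfig) -> pd.DataFrame:
    """Encode a corpus into a feature matrix.

    Returns a DataFrame indexed by tf_id whose columns are named
    ``"<block>.<bit label>"`` (e.g. ``TF_Class.2.3.1``, ``PD.KRAB``,
    ``N_DBD.hi``), in the fixed block concatenation order.
    """
    labels = bit_labels(config)
    columns = [f"{b}.{lab}" for b in BLOCK_ORDER for lab in labels[b]]
    rows = [encode_tf(rec, config).concat() for rec in records]
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=pd.Index([r.tf_id for r in records], name="tf_id"),
        columns=columns,
    )


def block_of_column(column: str) -> str:
    """The block name of a feature-matrix column (prefix before first dot)."""
    return column.split(".", 1)[0]


def select_blocks(matrix: pd.DataFrame, property_names: list[str]) -> pd.DataFrame:
    """Restrict a feature matrix to the named property blocks.

    Blocks stay in their fixed concatenation order regardless of the order
    the names are given in.
    """
    if not property_names:
        raise ValueError("property_names must be non-empty")
    unknown = set(property_names) - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown property names: {sorted(unknown)}")
    wanted = set(property_names)
    cols = [c for c in matrix.columns if block_of_column(c) in wanted]
    return matrix[cols]


def hamming(a: np.ndarray, b: np.ndarray) -> int:
    """Number of differing bits between two equal-length bit vectors."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return int(np.sum(a != b))
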