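"""Core domain types shared across the pipeline.

A :class:`TFRecord` is one transcription factor's raw annotation: its
structural classification code (a dotted TFClass-style code such as
``"2.3.1"``), Pfam domain content, DNA-binding / protein-interaction /
post-translational-modification annotation, and an optional regulatory-
function label (Pioneer, Settler, positive or negative Migrant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: The four regulatory-function classes, in the fixed priority order used
#: for deterministic tie-breaking throughout the package.
CLASS_LABELS = ("P", "S", "M+", "M-")

#: Sentinel label for TFs without a training label.
UNLABELED = "unlabeled"

#: The six post-translational modification types, in encoding order.
PTM_NAMES = (
    "phosphorylation",
    "acetylation",
    "methylation",
    "ubiquitination",
    "sumoylation",
    "o_glcnac",
)

_TFCLASS_RE = re.compile(r"^\d+(\.\d+)*$")


def validate_tfclass_code(code: str) -> str:
    """Check that *code* matches the dotted-integer grammar (e.g. ``2.3.1``)."""
    if not _TFCLASS_RE.match(code):
        raise ValueError(f"malformed TFClass code: {code!r}")
    return code


@dataclass
class TFRecord:
    """Raw annotation for one transcription factor.

    Identifiers are treated as opaque strings. Counts default to zero and
    flags to False: absent annotation is read as "does not have property".
    """

    tf_id: str
    tfclass_code: str
    pfam_counts: dict[str, int] = field(default_factory=dict)
    has_dbd: bool = False
    n_dbd: int = 0
    has_ppi: bool = False
    n_ppi: int = 0
    ptm_flags: tuple[bool, ...] = (False,) * 6
    n_phospho_sites: int = 0
    n_zf_frequent: int = 0
    label: str = UNLABELED

    def __post_init__(self) -> None:
        validate_tfclass_code(self.tfclass_code)
        self.ptm_flags = tuple(bool(f) for f in self.ptm_flags)
        if len(self.ptm_flags) != 6:
            raise ValueError(f"{self.tf_id}: expected 6 PTM flags")
        for name in ("n_dbd", "n_ppi", "n_phospho_sites", "n_zf_frequent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.tf_id}: {name} must be >= 0")
        if any(c < 0 for c in self.pfam_counts.values()):
            raise ValueError(f"{self.tf_id}: negative Pfam count")
        if not self.has_dbd and self.n_dbd != 0:
            raise ValueError(f"{self.tf_id}: n_dbd > 0 requires has_dbd")
        if self.label not in CLASS_LABELS and self.label != UNLABELED:
            raise ValueError(f"{self.tf_id}: unknown label {self.label!r}")

    @property
    def has_ptm(self) -> bool:
        return any(self.ptm_flags)


@dataclass
class PFMMotif:
    """A position frequency matrix with rows in fixed A, C, G, T order."""

    tf_id: str
    counts: "object"  # (4, L) array-like of non-negative numbers

    def __post_init__(self) -> None:
        import numpy as np

        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError(f"{self.tf_id}: counts must be a 4 x L matrix")
        if self.counts.shape[1] < 1:
            raise ValueError(f"{self.tf_id}: motif length must be >= 1")
        if (self.counts < 0).any():
            raise ValueError(f"{self.tf_id}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError(f"{self.tf_id}: all-zero column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass
class InteractionPairSet:
    """A set of unordered TF-TF interaction pairs from one evidence source."""

    source_name: str
    pairs: set[frozenset]

    def __post_init__(self) -> None:
        clean = set()
        for pair in self.pairs:
            pair = frozenset(pair)
            if len(pair) != 2:
                raise ValueError(f"self-pair or malformed pair: {set(pair)}")
            clean.add(pair)
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair) -> bool:
        return frozenset(pair) in self.pairs


@dataclass
class TimeCourseSets:
    """Up- and down-regulated TF identifier sets per time point."""

    time_points: tuple[str, ...]
    up_sets: dict[str, set[str]]
    down_sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.time_points = tuple(self.time_points)
        for tp in self.time_points:
            up = self.up_sets.setdefault(tp, set())
            down = self.down_sets.setdefault(tp, set())
            both = up & down
            if both:
                raise ValueError(
                    f"time point {tp!r}: TFs in both up and down: {sorted(both)}"
                )

    def pooled(self) -> tuple[set[str], set[str]]:
        """Union of up and of down sets across all time points."""
        up = set().union(*(self.up_sets[t] for t in self.time_points)) if self.time_points else set()
        down = set().union(*(self.down_sets[t] for t in self.time_points)) if self.time_points else set()
        return up, down
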