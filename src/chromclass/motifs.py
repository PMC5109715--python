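"""GC content and information content of binding-site motifs.

GC content is the pooled fraction of C and G counts over all positions of
a position frequency matrix. Information content is the classic per-column
2 - H(p) bits against a uniform background, summed over columns, with no
pseudocounts or small-sample correction. The binary cutoffs used for
enrichment analysis are strict: GC > 40% and IC > 9.0 bits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import PFMMotif

logger = logging.getLogger(__name__)

GC_CUTOFF = 0.40
IC_CUTOFF = 9.0


@dataclass
class MotifStats:
    tf_id: str
    gc_fraction: float
    ic_bits: float
    gc_high: bool
    ic_high: bool


def gc_content(motif: PFMMotif, per_column: bool = False) -> float:
    """Fraction of C + G in the motif's counts.

    By default counts are pooled over positions; ``per_column=True``
    averages the per-column GC fractions instead (the two differ only
    when column depths differ).
    """
    counts = motif.counts
    col_totals = counts.sum(axis=0)
    if counts.sum() <= 0:
        raise ValueError(f"{motif.tf_id}: zero total count")
    gc = counts[1] + counts[2]  # rows are A, C, G, T
    if per_column:
        return float(np.mean(gc / col_totals))
    return float(gc.sum() / counts.sum())


def information_content(motif: PFMMotif) -> float:
    """Total information content in bits against a uniform background.

    Per column: 2 + sum_b p_b log2 p_b with p the column frequencies and
    0 log 0 = 0; summed over columns. Bounded by [0, 2L].
    """
    counts = motif.counts
    col_totals = counts.sum(axis=0)
    if (col_totals <= 0).any():
        raise ValueError(f"{motif.tf_id}: zero-total column")
    p = counts / col_totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return float(np.sum(2.0 + plogp.sum(axis=0)))


def motif_stats(motif: PFMMotif, gc_cut: float = GC_CUTOFF, ic_cut: float = IC_CUTOFF,
                per_column_gc: bool = False) -> MotifStats:
    gc = gc_content(motif, per_column=per_column_gc)
    ic = information_content(motif)
    return MotifStats(
        tf_id=motif.tf_id,
        gc_fraction=gc,
        ic_bits=ic,
        gc_high=gc > gc_cut,
        ic_high=ic > ic_cut,
    )


def motif_flags(
    motifs: list[PFMMotif],
    gc_cut: float = GC_CUTOFF,
    ic_cut: float = IC_CUTOFF,
    per_column_gc: bool = False,
) -> pd.DataFrame:
    """Per-motif GC/IC statistics with strict-cutoff boolean flags.

    Duplicate tf_ids keep the first motif with a logged warning. The
    returned table (indexed by tf_id) feeds property enrichment directly.
    """
    if not motifs:
        raise ValueError("no motifs given")
    rows = {}
    for m in motifs:
        if m.tf_id in rows:
            logger.warning("duplicate motif for %s; keeping first", m.tf_id)
            continue
        s = motif_stats(m, gc_cut, ic_cut, per_column_gc)
        rows[m.tf_id] = {
            "gc_fraction": s.gc_fraction,
            "ic_bits": s.ic_bits,
            "gc_high": s.gc_high,
            "ic_high": s.ic_high,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "tf_id"
    return out
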