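"""Readers and writers for every external representation the pipeline touches.

All tabular formats are plain tab-separated text. The annotation table is a
single self-describing TSV with one row per TF; Pfam domain content is held
in one column as ``name:count`` items joined by ``;``. Position frequency
matrices are read from JASPAR PFM text (both the bracketed and the plain
four-row dialect) through Bio.motifs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .records import (
    CLASS_LABELS,
    PTM_NAMES,
    UNLABELED,
    InteractionPairSet,
    PFMMotif,
    TFRecord,
    TimeCourseSets,
)

logger = logging.getLogger(__name__)

_PTM_COLS = tuple(f"ptm_{name}" for name in PTM_NAMES)

ANNOTATION_COLUMNS = (
    "tf_id",
    "tfclass",
    "pfam",
    "has_dbd",
    "n_dbd",
    "has_ppi",
    "n_ppi",
    *_PTM_COLS,
    "n_phospho_sites",
    "n_zf_frequent",
    "label",
)


def _parse_pfam(cell: str) -> dict[str, int]:
    if not cell or pd.isna(cell):
        return {}
    out: dict[str, int] = {}
    for item in str(cell).split(";"):
        item = item.strip()
        if not item:
            continue
        name, _, count = item.rpartition(":")
        if not name:
            raise ValueError(f"malformed Pfam item {item!r} (expected name:count)")
        out[name] = int(count)
    return out


def _format_pfam(counts: dict[str, int]) -> str:
    return ";".join(f"{name}:{n}" for name, n in sorted(counts.items()))


def read_annotation_table(path: str | Path) -> list[TFRecord]:
    """Read a TF annotation table into TFRecords, preserving row order.

    Missing numeric fields are read as 0, missing flags as False, and an
    empty label column as unlabeled.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "tf_id" not in df.columns or "tfclass" not in df.columns:
        raise ValueError(f"{path}: annotation table needs tf_id and tfclass columns")
    dupes = df["tf_id"][df["tf_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate tf_id values: {sorted(set(dupes))}")

    def _int(row, col):
        val = row.get(col, "")
        return int(val) if val not in ("", None) else 0

    def _bool(row, col):
        val = row.get(col, "")
        return str(val).strip() in ("1", "True", "true", "yes")

    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            label = row.get("label", "").strip() or UNLABELED
            records.append(
                TFRecord(
                    tf_id=row["tf_id"],
                    tfclass_code=row["tfclass"],
                    pfam_counts=_parse_pfam(row.get("pfam", "")),
                    has_dbd=_bool(row, "has_dbd"),
                    n_dbd=_int(row, "n_dbd"),
                    has_ppi=_bool(row, "has_ppi"),
                    n_ppi=_int(row, "n_ppi"),
                    ptm_flags=tuple(_bool(row, c) for c in _PTM_COLS),
                    n_phospho_sites=_int(row, "n_phospho_sites"),
                    n_zf_frequent=_int(row, "n_zf_frequent"),
                    label=label,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}: row {i + 2} ({row.get('tf_id', '?')}): {exc}") from exc
    return records


def write_annotation_table(records: list[TFRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "tf_id": rec.tf_id,
            "tfclass": rec.tfclass_code,
            "pfam": _format_pfam(rec.pfam_counts),
            "has_dbd": int(rec.has_dbd),
            "n_dbd": rec.n_dbd,
            "has_ppi": int(rec.has_ppi),
            "n_ppi": rec.n_ppi,
            **{c: int(f) for c, f in zip(_PTM_COLS, rec.ptm_flags)},
            "n_phospho_sites": rec.n_phospho_sites,
            "n_zf_frequent": rec.n_zf_frequent,
            "label": "" if rec.label == UNLABELED else rec.label,
        }
        rows.append(row)
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (tf_id, label) TSV of training labels."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["tf_id", "label"]:
        raise ValueError(f"{path}: expected columns tf_id, label")
    labels = {}
    for _, row in df.iterrows():
        if row["label"] not in CLASS_LABELS:
            raise ValueError(f"{path}: unknown label {row['label']!r} for {row['tf_id']}")
        labels[row["tf_id"]] = row["label"]
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"tf_id": list(labels), "label": [labels[k] for k in labels]}
    ).to_csv(path, sep="\t", index=False)


def read_jaspar_pfm(path: str | Path) -> list[PFMMotif]:
    """Read JASPAR PFM motifs, mapping rows to fixed A, C, G, T order.

    Both the bracketed (``A [ 1 2 3 ]``) and the plain four-row dialect
    are accepted and yield identical matrices for identical counts.
    """
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, "jaspar")
            out = []
            for m in parsed:
                counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
                out.append(PFMMotif(tf_id=m.name or m.matrix_id, counts=counts))
    except OSError:
        raise
    except Exception as exc:  # Bio.motifs raises bare Exception on bad rows
        raise ValueError(f"{path}: not valid JASPAR PFM: {exc}") from exc
    if not out:
        raise ValueError(f"{path}: no motifs found")
    return out


def write_jaspar_pfm(motif_list: list[PFMMotif], path: str | Path) -> None:
    """Write motifs in the bracketed JASPAR PFM dialect."""
    with open(path, "w") as handle:
        for m in motif_list:
            handle.write(f">{m.tf_id} {m.tf_id}\n")
            for base, row in zip("ACGT", m.counts):
                cells = " ".join(f"{v:6.0f}" if v == int(v) else f"{v:8.2f}" for v in row)
                handle.write(f"{base}  [ {cells} ]\n")


def read_pairs(path: str | Path, source_name: str | None = None) -> InteractionPairSet:
    """Read a two-column TSV of interacting TF pairs.

    Pairs are de-duplicated under unordered comparison; self-pairs are
    dropped with a logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    pairs = set()
    for a, b in zip(df[0], df[1]):
        if a == b:
            logger.warning("dropping self-pair (%s, %s) in %s", a, b, path)
            continue
        pairs.add(frozenset((a, b)))
    return InteractionPairSet(source_name=source_name or Path(path).stem, pairs=pairs)


def write_pairs(pair_set: InteractionPairSet, path: str | Path) -> None:
    rows = sorted(tuple(sorted(p)) for p in pair_set.pairs)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_timecourse(path: str | Path) -> TimeCourseSets:
    """Read a (time_point, direction, tf_id) TSV of regulated TF sets."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = {"time_point", "direction", "tf_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(needed)}")
    bad = set(df["direction"]) - {"up", "down"}
    if bad:
        raise ValueError(f"{path}: direction must be up/down, got {sorted(bad)}")
    time_points = tuple(dict.fromkeys(df["time_point"]))
    up = {tp: set() for tp in time_points}
    down = {tp: set() for tp in time_points}
    for _, row in df.iterrows():
        (up if row["direction"] == "up" else down)[row["time_point"]].add(row["tf_id"])
    return TimeCourseSets(time_points=time_points, up_sets=up, down_sets=down)


def write_timecourse(sets: TimeCourseSets, path: str | Path) -> None:
    rows = []
    for tp in sets.time_points:
        rows.extend({"time_point": tp, "direction": "up", "tf_id": t} for t in sorted(sets.up_sets[tp]))
        rows.extend({"time_point": tp, "direction": "down", "tf_id": t} for t in sorted(sets.down_sets[tp]))
    pd.DataFrame(rows, columns=["time_point", "direction", "tf_id"]).to_csv(
        path, sep="\t", index=False
    )


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with its column order preserved."""
    results.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
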