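"""Reading, writing and harmonising tabular inputs.

All on-disk formats are plain TSV.  Merged count/abundance matrices have the
feature identifier in the first column and one column per sample (or per
sample_fraction).  Single-sample species reports use the Bracken report
layout (name, taxonomy_id, taxonomy_lvl, kraken_assigned_reads, added_reads,
new_est_reads, fraction_total_reads).

Taxa absent from a file are treated as zero counts, never as missing values:
sorted fractions legitimately lack taxa that the total population contains.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, FormatError, ValidationError
from .tables import (
    CohortMetadata,
    FlowSummary,
    FractionCountTable,
    RelAbundanceTable,
)

logger = logging.getLogger(__name__)

BRACKEN_COLUMNS = (
    "name",
    "taxonomy_id",
    "taxonomy_lvl",
    "kraken_assigned_reads",
    "added_reads",
    "new_est_reads",
    "fraction_total_reads",
)

# ---------------------------------------------------------------------------
# Bracken-style single-sample reports


def read_bracken_report(path: str | Path) -> pd.Series:
    """Read one Bracken-style species report into a count vector.

    Returns the ``new_est_reads`` column as a Series keyed by
    ``"name|taxonomy_id"`` so that species names colliding across database
    dialects stay distinct.  Malformed rows raise :class:`FormatError` or
    :class:`ValidationError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in BRACKEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: empty report, returning empty count vector", path)
        return pd.Series(dtype=float, name="new_est_reads")
    reads = pd.to_numeric(df["new_est_reads"], errors="coerce")
    bad = reads.isna()
    if bad.any():
        # +2: one for the header, one for 1-based numbering
        line = int(np.flatnonzero(bad)[0]) + 2
        raise FormatError(f"{path}: non-numeric new_est_reads on line {line}")
    neg = reads < 0
    if neg.any():
        line = int(np.flatnonzero(neg)[0]) + 2
        raise ValidationError(f"{path}: negative read count on line {line}")
    keys = df["name"].str.strip() + "|" + df["taxonomy_id"].str.strip()
    out = pd.Series(reads.to_numpy(dtype=float), index=keys, name="new_est_reads")
    if out.index.has_duplicates:
        dupes = out.index[out.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate taxa {dupes[:5]}")
    return out


def write_bracken_report(counts: pd.Series, path: str | Path) -> None:
    """Write a count vector keyed by ``"name|taxonomy_id"`` as a Bracken report."""
    total = float(counts.sum())
    rows = []
    for key, reads in counts.items():
        name, _, taxid = str(key).rpartition("|")
        if not name:
            name, taxid = str(key), "0"
        rows.append(
            {
                "name": name,
                "taxonomy_id": taxid,
                "taxonomy_lvl": "S",
                "kraken_assigned_reads": int(reads),
                "added_reads": 0,
                "new_est_reads": int(reads),
                "fraction_total_reads": (reads / total) if total else 0.0,
            }
        )
    pd.DataFrame(rows, columns=list(BRACKEN_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Merged matrices

#: Significant digits preserved by the TSV round-trip.
_TSV_DIGITS = 12


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_name: str = "taxon_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format=f"%.{_TSV_DIGITS}g")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", index_col=0)


def write_count_table(table: FractionCountTable, path: str | Path) -> None:
    write_matrix_tsv(table.counts, path)


def read_count_table(path: str | Path, fraction_label: str) -> FractionCountTable:
    return FractionCountTable(read_matrix_tsv(path).astype(float), fraction_label)


def write_rel_abundance_table(table: RelAbundanceTable, path: str | Path) -> None:
    write_matrix_tsv(table.values, path)


def read_rel_abundance_table(path: str | Path, fraction_label: str) -> RelAbundanceTable:
    return RelAbundanceTable(read_matrix_tsv(path).astype(float), fraction_label)


def write_flow_summary(flow: FlowSummary, path: str | Path) -> None:
    out = flow.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=f"%.{_TSV_DIGITS}g")


def read_flow_summary(path: str | Path) -> FlowSummary:
    return FlowSummary(read_matrix_tsv(path).astype(float))


def write_metadata(meta: CohortMetadata, path: str | Path) -> None:
    out = meta.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> CohortMetadata:
    df = read_matrix_tsv(path)
    df["pair_id"] = df["pair_id"].astype(str)
    return CohortMetadata(df)


# ---------------------------------------------------------------------------
# Harmonisation and the threshold/zeroing rules


def harmonise_taxa(tables: Sequence[FractionCountTable]) -> list[FractionCountTable]:
    """Reindex every table onto the union of taxa, filling absences with 0."""
    union: pd.Index = pd.Index([])
    for t in tables:
        union = union.union(t.counts.index)
    return [
        FractionCountTable(t.counts.reindex(union, fill_value=0.0), t.fraction_label)
        for t in tables
    ]


def merge_sample_vectors(
    vectors: dict[str, pd.Series], fraction_label: str
) -> FractionCountTable:
    """Assemble per-sample count vectors into one table on the taxon union."""
    df = pd.DataFrame(vectors).fillna(0.0)
    return FractionCountTable(df, fraction_label)


def total_sum_scale(counts: FractionCountTable) -> RelAbundanceTable:
    """Convert read counts to relative abundances summing to 1 per sample."""
    totals = counts.counts.sum(axis=0)
    empty = totals[totals <= 0]
    if len(empty):
        raise ValidationError(
            f"cannot total-sum scale all-zero sample(s): {list(empty.index)}"
        )
    return RelAbundanceTable(counts.counts / totals, counts.fraction_label)


def apply_threshold(
    ra: RelAbundanceTable, threshold: float, pseudocount: float
) -> RelAbundanceTable:
    """Zero abundances at or below ``threshold``, then add ``pseudocount``.

    Detection is strictly greater-than: a value exactly equal to the
    threshold is removed.  The pseudocount is then added to every cell,
    zeroed and surviving alike, so downstream log-ratio arithmetic stays
    finite.  The input table is left unmodified.
    """
    if threshold < 0 or pseudocount < 0:
        raise ValidationError("threshold and pseudocount must be >= 0")
    values = ra.values.where(ra.values > threshold, 0.0) + pseudocount
    return RelAbundanceTable(values, ra.fraction_label)


def _require_aligned(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    if not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise AlignmentError(f"misaligned taxa or samples between {what}")


def zero_absent_in_all(
    pos: RelAbundanceTable,
    neg: RelAbundanceTable,
    all_fraction: RelAbundanceTable,
    threshold: float,
) -> tuple[RelAbundanceTable, RelAbundanceTable]:
    """Remove taxa undetected in the total population from the sorted fractions.

    Per sample: any taxon whose 'all'-fraction abundance is not strictly above
    ``threshold`` is zeroed in that sample's bound and unbound fractions.  The
    rule is per-sample — a taxon may survive in one participant and be zeroed
    in another.
    """
    _require_aligned(pos.values, neg.values, "igg_pos and igg_neg")
    _require_aligned(pos.values, all_fraction.values, "sorted fractions and 'all'")
    detected = all_fraction.values > threshold
    return (
        RelAbundanceTable(pos.values.where(detected, 0.0), pos.fraction_label),
        RelAbundanceTable(neg.values.where(detected, 0.0), neg.fraction_label),
    )
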