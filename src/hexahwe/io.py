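"""Readers and writers for marker-count tables and dosage matrices.

Supported inputs
----------------
* seven-class TSV: columns ``locus_id, n_6A, n_5A1a, n_4A2a, n_3A3a,
  n_2A4a, n_1A5a, n_6a`` (counts, descending A-dosage);
* three-class TSV: columns ``locus_id, n_6A, n_het, n_6a`` for
  dosage-ambiguous markers;
* dosage matrix CSV: one row per individual, one column per locus,
  integer allele dosages 0-6, missing values coded ``NA``.

Rows whose values sum to ~1 are auto-detected as frequencies and kept
as-is (total 1); tests applied to them run on the frequency scale unless
a pseudo sample size is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
import pandas as pd

from .estimation import CollapsedCounts, GenotypeCounts

__all__ = [
    "LocusRecord",
    "SEVEN_CLASS_COLUMNS",
    "THREE_CLASS_COLUMNS",
    "read_counts_table",
    "read_dosage_matrix",
    "write_counts_table",
]

logger = logging.getLogger("hexahwe")

SEVEN_CLASS_COLUMNS = [
    "n_6A", "n_5A1a", "n_4A2a", "n_3A3a", "n_2A4a", "n_1A5a", "n_6a",
]
THREE_CLASS_COLUMNS = ["n_6A", "n_het", "n_6a"]


@dataclass(frozen=True)
class LocusRecord:
    """One locus worth of genotype counts plus provenance.

    ``counts`` is ``None`` for loci excluded from testing (e.g. all
    dosages missing), with ``excluded`` set.
    """

    locus_id: str
    counts: Optional[Union[GenotypeCounts, CollapsedCounts]]
    line: int
    is_frequencies: bool = False
    n_missing: int = 0
    excluded: bool = False

    @property
    def n_classes(self) -> int:
        return 7 if isinstance(self.counts, GenotypeCounts) else 3


class DataError(ValueError):
    """Malformed input data; message carries the offending line."""


def _load_table(path, sep, expected_cols):
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in ["locus_id"] + expected_cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    return df


def read_counts_table(
    path,
    format: str = "seven_class",
    pseudo_n: Optional[float] = None,
) -> List[LocusRecord]:
    """Read a per-locus genotype-count TSV.

    Frequency rows (summing to ~1) are accepted; ``pseudo_n`` rescales
    them to pseudo-counts so that count-scale tests can be applied.
    """
    if format == "seven_class":
        cols, maker = SEVEN_CLASS_COLUMNS, GenotypeCounts
    elif format == "three_class":
        cols, maker = THREE_CLASS_COLUMNS, CollapsedCounts
    else:
        raise ValueError(f"format must be 'seven_class' or 'three_class': {format!r}")
    df = _load_table(path, "\t", cols)
    records: List[LocusRecord] = []
    seen = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        locus = str(row["locus_id"])
        if not locus or locus == "nan":
            raise DataError(f"{path}:{line}: empty locus_id")
        if locus in seen:
            raise DataError(f"{path}:{line}: duplicate locus_id {locus!r}")
        seen.add(locus)
        values = pd.to_numeric(row[cols], errors="coerce").to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            raise DataError(f"{path}:{line}: non-numeric or missing count")
        if np.any(values < 0):
            raise DataError(f"{path}:{line}: negative count in {locus!r}")
        total = values.sum()
        if total <= 0:
            raise DataError(f"{path}:{line}: all-zero counts in {locus!r}")
        is_freq = abs(total - 1.0) < 1e-3
        if is_freq and pseudo_n is not None:
            values = values / total * pseudo_n
        records.append(
            LocusRecord(
                locus_id=locus,
                counts=maker(values),
                line=line,
                is_frequencies=is_freq and pseudo_n is None,
            )
        )
    return records


def read_dosage_matrix(path) -> List[LocusRecord]:
    """Tally per-locus genotype counts from an individual x locus CSV of
    allele dosages 0-6 (``NA`` = missing).  All-missing loci are returned
    flagged ``excluded`` so callers can report rather than test them."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: file not found")
    df = pd.read_csv(path, na_values=["NA"])
    records = []
    for col in df.columns:
        values = df[col]
        miss = int(values.isna().sum())
        dosages = values.dropna().to_numpy()
        if dosages.size and (
            np.any(dosages != np.round(dosages))
            or np.any((dosages < 0) | (dosages > 6))
        ):
            raise DataError(f"{path}: locus {col!r} has dosages outside 0-6")
        if dosages.size == 0:
            logger.warning("locus %s: all dosages missing; excluded", col)
            records.append(
                LocusRecord(
                    locus_id=str(col),
                    counts=None,
                    line=0,
                    n_missing=miss,
                    excluded=True,
                )
            )
            continue
        counts = np.bincount(6 - dosages.astype(int), minlength=7)[:7]
        records.append(
            LocusRecord(
                locus_id=str(col),
                counts=GenotypeCounts(counts.astype(float)),
                line=0,
                n_missing=miss,
            )
        )
    return records


def write_counts_table(records, path) -> None:
    """Write seven- or three-class records back to TSV (inverse of read)."""
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    seven = records[0].n_classes == 7
    cols = SEVEN_CLASS_COLUMNS if seven else THREE_CLASS_COLUMNS
    rows = []
    for rec in records:
        if rec.n_classes != (7 if seven else 3):
            raise ValueError("cannot mix seven- and three-class records")
        row = {"locus_id": rec.locus_id}
        arr = np.asarray(rec.counts)
        row.update({c: v for c, v in zip(cols, arr)})
        rows.append(row)
    pd.DataFrame(rows, columns=["locus_id"] + cols).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )
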