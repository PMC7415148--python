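"""Analyte x sample tables -> residue x sample tables.

The input is an abundance table with one lipid identifier per row and one
sample per column (the shape vendor exports take after a single header
row).  Each row's identifier is parsed, its residue occurrences are
weighted by 1/index, and ``weight x abundance`` is accumulated into the
residue's output row, sample by sample.  Units pass through unchanged.

Rows whose identifier cannot be parsed are skipped and counted, never
fatal: a whole-dataset run must survive one vendor quirk.  Columns that
are not numeric throughout are dropped up front, mirroring how leftover
label columns are handled in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    LipresidueError,
    NoSampleColumnsError,
    NothingExtractedError,
)
from .nomenclature import Lexicon, Residue
from .parser import parse_identifier, weighted_residues

__all__ = [
    "ScreenedTable",
    "ExtractionResult",
    "drop_nonnumeric_columns",
    "extract_residues",
    "make_residues_table",
    "filter_max_carbons",
]

logger = logging.getLogger(__name__)


class ScreenedTable(NamedTuple):
    """Result of column screening: the numeric table plus what was dropped."""

    table: pd.DataFrame
    dropped: list[str]


@dataclass
class ExtractionResult:
    """Full accounting of one extraction run."""

    table: pd.DataFrame
    skipped_rows: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)
    rows_read: int = 0


def _coerce_numeric(column: pd.Series) -> pd.Series | None:
    """Return the column as numeric, or None if any non-missing cell is text.

    Cells holding decimal numbers stored as text ("1.5") count as
    numeric; empty strings count as missing, not text.
    """
    if pd.api.types.is_numeric_dtype(column):
        return column
    cleaned = column.replace(r"^\s*$", np.nan, regex=True)
    coerced = pd.to_numeric(cleaned, errors="coerce")
    if (coerced.isna() == cleaned.isna()).all():
        return coerced
    return None


def drop_nonnumeric_columns(table: pd.DataFrame) -> ScreenedTable:
    """Restrict the table to columns that are numeric throughout.

    Missing values are permitted (treated as missing, not text).  Dropped
    column names are returned alongside the screened table and logged.
    Raises :class:`NoSampleColumnsError` if nothing numeric remains.
    """
    kept: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for name in table.columns:
        coerced = _coerce_numeric(table[name])
        if coerced is None:
            dropped.append(str(name))
        else:
            kept[name] = coerced
    if not kept:
        raise NoSampleColumnsError(
            "no numeric sample columns remain after screening"
        )
    if dropped:
        logger.warning("dropped non-numeric columns: %s", ", ".join(dropped))
    screened = pd.DataFrame(kept, index=table.index)
    return ScreenedTable(table=screened, dropped=dropped)


def _sorted_residue_frame(
    accumulator: dict[tuple[int, int], np.ndarray], columns: pd.Index
) -> pd.DataFrame:
    keys = sorted(accumulator)  # (carbons, double_bonds) ascending
    labels = [f"{c}:{d}" for c, d in keys]
    values = np.array([accumulator[k] for k in keys], dtype=float)
    if values.size == 0:
        values = values.reshape(0, len(columns))
    frame = pd.DataFrame(values, index=labels, columns=columns)
    frame.index.name = "residue"
    return frame


def extract_residues(
    table: pd.DataFrame,
    dialect: str = "refmet",
    drop_ambiguous: bool = False,
    max_carbons: int | None = None,
    lexicon: Lexicon | None = None,
) -> ExtractionResult:
    """Run the full extraction and return the table plus its accounting.

    Same contract as :func:`make_residues_table`, but the result also
    carries the skipped identifiers and dropped columns, for reporting.
    """
    screened, dropped = drop_nonnumeric_columns(table)
    accumulator: dict[tuple[int, int], np.ndarray] = {}
    skipped: list[str] = []
    n_samples = screened.shape[1]

    for raw_name, row in screened.iterrows():
        name = str(raw_name)
        try:
            lipid = parse_identifier(name, dialect=dialect, lexicon=lexicon)
        except LipresidueError as exc:
            skipped.append(name)
            logger.warning("skipping unparseable row %r: %s", name, exc)
            continue
        # missing cells contribute nothing (absent, not zero)
        amounts = np.nan_to_num(row.to_numpy(dtype=float), nan=0.0)
        for entry in weighted_residues(lipid, drop_ambiguous=drop_ambiguous):
            residue = entry.residue
            if max_carbons is not None and residue.carbons > max_carbons:
                continue
            key = (residue.carbons, residue.double_bonds)
            if key not in accumulator:
                accumulator[key] = np.zeros(n_samples)
            accumulator[key] += entry.weight * amounts

    if skipped and len(skipped) == len(screened):
        raise NothingExtractedError(
            f"every one of the {len(screened)} rows was unparseable"
        )
    result_table = _sorted_residue_frame(accumulator, screened.columns)
    return ExtractionResult(
        table=result_table,
        skipped_rows=skipped,
        dropped_columns=dropped,
        rows_read=len(screened),
    )


def make_residues_table(
    table: pd.DataFrame,
    dialect: str = "refmet",
    drop_ambiguous: bool = False,
    max_carbons: int | None = None,
    lexicon: Lexicon | None = None,
) -> pd.DataFrame:
    """Convert an analyte x sample table into a residue x sample table.

    For each row the identifier (the row index) is parsed and each
    residue occurrence adds ``weight x abundance`` to its output row, per
    sample.  Duplicate identifiers are processed independently and sum
    into the same residue rows.  Output rows are labeled ``"C:D"`` and
    sorted by (carbons, double_bonds); units are unchanged from the
    input.

    Parameters
    ----------
    table
        Abundance table: identifier-keyed rows, sample columns.
    dialect
        Identifier dialect, ``"refmet"`` or ``"generic"``.
    drop_ambiguous
        Discard mass-isobar (index > 1) lipids entirely instead of
        splitting their amounts 1/index.
    max_carbons
        If set, residues longer than this many carbons (inclusive bound)
        are excluded — sum-composition totals included.
    lexicon
        Optional trivial-name lexicon override.
    """
    return extract_residues(
        table,
        dialect=dialect,
        drop_ambiguous=drop_ambiguous,
        max_carbons=max_carbons,
        lexicon=lexicon,
    ).table


def filter_max_carbons(table: pd.DataFrame, max_carbons: int) -> pd.DataFrame:
    """Drop residue rows longer than ``max_carbons`` (inclusive bound)."""
    if max_carbons < 1:
        raise ValueError(f"max_carbons must be positive, got {max_carbons}")
    keep = [
        label
        for label in table.index
        if Residue.from_label(str(label)).carbons <= max_carbons
    ]
    return table.loc[keep]
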