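"""Downstream residue summaries.

Once a residue x sample table exists, three views recur in practice:
splitting residues into saturated vs unsaturated, splitting them into
abundant vs less-abundant around a concentration threshold (0.5 pmol/ug
is a common choice for plasma and cell lipidomes), and expressing each
treated sample as a percent change against its own paired baseline.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IncompleteDesignError
from .nomenclature import Residue

__all__ = [
    "GroupDesign",
    "split_by_saturation",
    "split_by_abundance",
    "percent_change_vs_baseline",
]


@dataclass(frozen=True)
class GroupDesign:
    """Sample grouping, with optional per-sample baseline pairing.

    ``baseline_pairs`` maps each treatment sample to the sample that is
    its own baseline (the same subject before treatment), making the
    pairing explicit rather than positional.
    """

    sample_to_group: dict[str, str]
    baseline_pairs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for treatment, baseline in self.baseline_pairs.items():
            if treatment == baseline:
                raise IncompleteDesignError(
                    f"sample {treatment!r} is paired with itself as baseline"
                )
            if treatment not in self.sample_to_group:
                raise IncompleteDesignError(
                    f"baseline pair references unknown sample {treatment!r}"
                )
            if baseline not in self.sample_to_group:
                raise IncompleteDesignError(
                    f"baseline pair references unknown sample {baseline!r}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "GroupDesign":
        """Read a design from delimited text (comma or tab).

        Columns: sample, group and optionally baseline_sample.  A header
        row is detected by the literal first field "sample" and skipped.
        """
        sample_to_group: dict[str, str] = {}
        baseline_pairs: dict[str, str] = {}
        text = Path(path).read_text(encoding="utf-8")
        delimiter = "\t" if "\t" in text.splitlines()[0] else ","
        rows = list(csv.reader(text.splitlines(), delimiter=delimiter))
        if rows and rows[0] and rows[0][0].strip().lower() == "sample":
            rows = rows[1:]
        for row in rows:
            cells = [cell.strip() for cell in row if cell.strip()]
            if not cells:
                continue
            if len(cells) < 2:
                raise IncompleteDesignError(
                    f"design row needs at least sample and group: {row!r}"
                )
            sample_to_group[cells[0]] = cells[1]
            if len(cells) >= 3:
                baseline_pairs[cells[0]] = cells[2]
        return cls(sample_to_group=sample_to_group, baseline_pairs=baseline_pairs)


def split_by_saturation(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition residue rows into (saturated, unsaturated) tables.

    Saturated means zero double bonds.  The two outputs are an exact,
    disjoint partition of the input rows.
    """
    saturated_mask = [
        Residue.from_label(str(label)).double_bonds == 0 for label in table.index
    ]
    mask = np.asarray(saturated_mask, dtype=bool)
    return table.loc[mask], table.loc[~mask]


def split_by_abundance(
    table: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition residues into (abundant, less_abundant) around a threshold.

    A residue is abundant when its grand mean across all samples exceeds
    the threshold (same units as the table, e.g. pmol/ug).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    means = table.mean(axis=1)
    abundant = means > threshold
    return table.loc[abundant], table.loc[~abundant]


def percent_change_vs_baseline(
    table: pd.DataFrame, design: GroupDesign
) -> pd.DataFrame:
    """Percent change of each treatment sample against its own baseline.

    For every residue and every (treatment, baseline) pair in the design:
    ``100 * (treatment - baseline) / baseline``.  A zero baseline yields
    a missing value for that pair, never infinity.  The result has one
    column per treatment sample, in design order.
    """
    if not design.baseline_pairs:
        raise IncompleteDesignError("design carries no baseline pairs")
    missing = [
        sample
        for pair in design.baseline_pairs.items()
        for sample in pair
        if sample not in table.columns
    ]
    if missing:
        raise IncompleteDesignError(
            f"design references samples absent from the table: {sorted(set(missing))}"
        )
    out: dict[str, np.ndarray] = {}
    for treatment, baseline in design.baseline_pairs.items():
        base = table[baseline].to_numpy(dtype=float)
        treat = table[treatment].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            change = 100.0 * (treat - base) / base
        out[treatment] = np.where(base == 0.0, np.nan, change)
    result = pd.DataFrame(out, index=table.index)
    result.index.name = table.index.name
    return result
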