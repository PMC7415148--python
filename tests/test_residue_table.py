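"""Table conversion: column screening and index-weighted aggregation."""

import numpy as np
import pandas as pd
import pytest

from lipresidue.errors import NoSampleColumnsError, NothingExtractedError
from lipresidue.fixtures import GeneratorConfig, generate_lipidome
from lipresidue.residue_table import (
    drop_nonnumeric_columns,
    extract_residues,
    filter_max_carbons,
    make_residues_table,
)
from tests.conftest import PG_ISOBAR


def frame(rows: dict[str, list[float]], columns: list[str]) -> pd.DataFrame:
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "lipid"
    return table


class TestDropNonnumericColumns:
    def test_text_column_dropped(self):
        table = pd.DataFrame(
            {"S1": [1.0, 2.0], "note": ["ok", "bad"], "S2": [3.0, 4.0]},
            index=["FA(16:0)", "FA(18:1)"],
        )
        screened, dropped = drop_nonnumeric_columns(table)
        assert list(screened.columns) == ["S1", "S2"]
        assert dropped == ["note"]

    def test_all_numeric_identity(self):
        table = pd.DataFrame({"S1": [1.0], "S2": [2.0]}, index=["FA(16:0)"])
        screened, dropped = drop_nonnumeric_columns(table)
        pd.testing.assert_frame_equal(screened, table)
        assert dropped == []

    def test_numbers_stored_as_text_retained(self):
        table = pd.DataFrame(
            {"S1": ["1.5", "2"], "S2": [1.0, np.nan]}, index=["a", "b"]
        )
        screened, dropped = drop_nonnumeric_columns(table)
        assert dropped == []
        assert screened["S1"].tolist() == [1.5, 2.0]

    def test_missing_values_are_not_text(self):
        table = pd.DataFrame(
            {"S1": [1.0, None], "S2": ["", "2.0"]}, index=["a", "b"]
        )
        _, dropped = drop_nonnumeric_columns(table)
        assert dropped == []

    def test_idempotent(self):
        table = pd.DataFrame(
            {"S1": [1.0], "note": ["x"]}, index=["FA(16:0)"]
        )
        once = drop_nonnumeric_columns(table).table
        twice = drop_nonnumeric_columns(once).table
        pd.testing.assert_frame_equal(once, twice)

    def test_nothing_numeric_raises(self):
        table = pd.DataFrame({"note": ["x"]}, index=["FA(16:0)"])
        with pytest.raises(NoSampleColumnsError):
            drop_nonnumeric_columns(table)


class TestMakeResiduesTable:
    def test_single_unambiguous_lipid_passes_through(self):
        table = frame({"FA(18:3)": [10.0]}, ["S1"])
        out = make_residues_table(table)
        assert out.index.tolist() == ["18:3"]
        assert out.loc["18:3", "S1"] == 10.0

    def test_isobar_amounts_split_by_index(self):
        table = frame({PG_ISOBAR: [4.0]}, ["S1"])
        out = make_residues_table(table, dialect="generic")
        assert out["S1"].to_dict() == {"18:1": 4.0, "22:1": 2.0, "22:2": 2.0}

    def test_drop_ambiguous_removes_isobar_contribution(self):
        table = frame({PG_ISOBAR: [4.0], "FA(18:3)": [1.0]}, ["S1"])
        out = make_residues_table(table, dialect="generic", drop_ambiguous=True)
        assert out["S1"].to_dict() == {"18:3": 1.0}

    def test_drop_ambiguous_equals_prefiltering_to_index1_rows(self, toy_lipid_table):
        dropped = make_residues_table(
            toy_lipid_table, dialect="generic", drop_ambiguous=True
        )
        unambiguous_rows = toy_lipid_table.drop(index=[PG_ISOBAR])
        prefiltered = make_residues_table(unambiguous_rows, dialect="generic")
        pd.testing.assert_frame_equal(dropped, prefiltered)

    def test_duplicate_identifiers_sum(self):
        table = pd.DataFrame(
            [[1.0], [2.0]], index=["FA(16:0)", "FA(16:0)"], columns=["S1"]
        )
        out = make_residues_table(table)
        assert out.loc["16:0", "S1"] == 3.0

    def test_missing_cells_contribute_nothing(self):
        table = frame({"FA(16:0)": [np.nan, 2.0], "PC(16:0/16:0)": [1.0, 1.0]}, ["S1", "S2"])
        out = make_residues_table(table)
        assert out.loc["16:0", "S1"] == 2.0  # only the PC row's two chains
        assert out.loc["16:0", "S2"] == 4.0

    def test_unparseable_rows_skipped_and_counted(self, toy_lipid_table):
        table = toy_lipid_table.copy()
        table.loc["garbage!!"] = [1.0, 1.0]
        result = extract_residues(table, dialect="generic")
        assert result.skipped_rows == ["garbage!!"]
        clean = make_residues_table(toy_lipid_table, dialect="generic")
        pd.testing.assert_frame_equal(result.table, clean)

    def test_all_rows_unparseable_raises(self):
        table = frame({"???": [1.0], "!!!": [2.0]}, ["S1"])
        with pytest.raises(NothingExtractedError):
            make_residues_table(table, dialect="generic")

    def test_rows_sorted_by_carbons_then_double_bonds(self, toy_lipid_table):
        out = make_residues_table(toy_lipid_table, dialect="generic")
        keys = [tuple(map(int, label.split(":"))) for label in out.index]
        assert keys == sorted(keys)

    def test_permutation_invariance(self, toy_lipid_table):
        shuffled = toy_lipid_table.iloc[[2, 0, 3, 1]]
        pd.testing.assert_frame_equal(
            make_residues_table(toy_lipid_table, dialect="generic"),
            make_residues_table(shuffled, dialect="generic"),
        )

    def test_max_carbons_excludes_long_residues(self, toy_lipid_table):
        out = make_residues_table(toy_lipid_table, dialect="generic", max_carbons=30)
        assert "42:2" not in out.index
        full = make_residues_table(toy_lipid_table, dialect="generic")
        pd.testing.assert_frame_equal(out, full.drop(index=["42:2"]))

    def test_conservation_on_equal_chain_counts(self):
        """With two chains per alternative everywhere, total output mass
        per sample is exactly 2 x total input mass."""
        config = GeneratorConfig(
            n_lipids=40,
            fraction_sum_composition=0.0,
            fraction_common_names=0.0,
            seed=11,
        )
        generated = generate_lipidome(config)
        # the generator's plain 2-chain classes and isobar pairs only
        two_chain = [
            row["name"]
            for row in generated.manifest
            if row["name"].count(":") in (2, 4) and " " not in row["name"]
        ]
        table = generated.lipid_table.loc[two_chain]
        out = make_residues_table(table, dialect="generic")
        np.testing.assert_allclose(
            out.sum(axis=0).to_numpy(), 2.0 * table.sum(axis=0).to_numpy(), rtol=1e-12
        )


class TestFilterMaxCarbons:
    def test_boundary_inclusive(self):
        table = pd.DataFrame(
            [[1.0], [2.0], [3.0]], index=["24:0", "30:0", "31:0"], columns=["S1"]
        )
        out = filter_max_carbons(table, 30)
        assert out.index.tolist() == ["24:0", "30:0"]

    def test_identity_when_cutoff_above_all(self):
        table = pd.DataFrame([[1.0]], index=["24:0"], columns=["S1"])
        pd.testing.assert_frame_equal(filter_max_carbons(table, 50), table)

    def test_rejects_nonpositive_cutoff(self):
        table = pd.DataFrame([[1.0]], index=["24:0"], columns=["S1"])
        with pytest.raises(ValueError):
            filter_max_carbons(table, 0)
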