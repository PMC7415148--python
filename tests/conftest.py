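import numpy as np
import pandas as pd
import pytest

# the worked mass-isobar example used throughout: a plasmalogen/ether pair
# of equal mass joined at top level
PG_ISOBAR = "PG(P-22:1/18:1)/PG(O-22:2/18:1)"


@pytest.fixture
def toy_lipid_table() -> pd.DataFrame:
    """Small hand-built analyte x sample table with known residues."""
    names = ["FA(18:3)", "PC(16:0/18:1)", PG_ISOBAR, "SM 42:2"]
    values = np.array(
        [
            [10.0, 1.0],
            [2.0, 4.0],
            [4.0, 8.0],
            [1.0, 0.5],
        ]
    )
    table = pd.DataFrame(values, index=names, columns=["S1", "S2"])
    table.index.name = "lipid"
    return table
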