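"""Reference tables shipped with the package.

These are the printed records of the Chinese cabbage diallel study this
pipeline models: the 8-parent design grid with its three missing crosses,
and the published per-gene correlation records for the ribosome and
terpenoid-backbone pathway gene sets (Pearson r and BH q against hybrid
plant growth weight and its mid-parent heterosis).
"""

from __future__ import annotations

from importlib import resources
from typing import NamedTuple

import pandas as pd

from .design import DiallelDesign, parse_design


def _data_path(name: str):
    return resources.files("heteroscope.data").joinpath(name)


def load_design_grid() -> pd.DataFrame:
    """The printed 8×8 diallel grid (rows = female, columns = male)."""
    with resources.as_file(_data_path("diallel_design_grid.tsv")) as path:
        grid = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                           keep_default_na=False, na_values=[])
    grid.index = grid.index.astype(str)
    return grid


def load_design() -> DiallelDesign:
    """The parsed reference design: 8 parents, 53 hybrids, 3 missing cells."""
    return parse_design(load_design_grid())


def _load_records(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as path:
        df = pd.read_csv(path, sep="\t", dtype={"gene": str, "symbol": str},
                         keep_default_na=False, na_values=[""])
    df["symbol"] = df["symbol"].fillna("")
    return df


def load_ribosome_records() -> pd.DataFrame:
    """Published correlation records for ribosome-pathway genes (17 rows)."""
    return _load_records("ribosome_pathway_correlations.tsv")


def load_terpenoid_records() -> pd.DataFrame:
    """Published correlation records for terpenoid-backbone genes (8 rows)."""
    return _load_records("terpenoid_pathway_correlations.tsv")


class FixtureTables(NamedTuple):
    design_grid: pd.DataFrame
    ribosome: pd.DataFrame
    terpenoid: pd.DataFrame


def fixture_tables() -> FixtureTables:
    """All shipped reference tables at once."""
    return FixtureTables(design_grid=load_design_grid(),
                         ribosome=load_ribosome_records(),
                         terpenoid=load_terpenoid_records())
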