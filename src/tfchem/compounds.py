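"""Packaged table of the 61 components identified by GC-MS in trophallactic
fluid, with printed vs. recomputed molecular weights.

The table mirrors the published compound list: retention time, printed
molecular weight, proposed molecular formula and structure, retention index,
chromatogram peak letter, and a flag for the three components found only in
trophallactic fluid and not on the cuticle (oleic acid, ethyl oleate and a
tricosene).  One printed MW (295 for C21H44) disagrees with its own formula
(296); the loader keeps both values and flags the row instead of deciding
which the authors intended.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chem_core import MolecularFormula, nominal_mass, parse_compound_name

__all__ = ["load_compound_table", "linear_alkane_rows"]


def load_compound_table() -> pd.DataFrame:
    """Load the packaged compound table.

    Returns a DataFrame with the printed columns plus:

    ``mw_computed``
        nominal mass recomputed from the printed formula,
    ``mw_discrepant``
        True where printed and recomputed MW disagree,
    ``is_hydrocarbon``, ``total_carbons``, ``n_branches``, ``n_double_bonds``,
    ``ambiguous_positions``
        derived from parsing the proposed structure name.
    """
    with resources.files("tfchem.data").joinpath("tf_compounds.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"peak_id": "string"})
    table["tf_only"] = table["tf_only"].astype(bool)
    table["mw_computed"] = [
        nominal_mass(MolecularFormula.from_string(f)) for f in table["formula"]
    ]
    table["mw_discrepant"] = table["mw_computed"] != table["mw_printed"]
    parsed = [parse_compound_name(name) for name in table["structure"]]
    table["is_hydrocarbon"] = [p.is_hydrocarbon for p in parsed]
    table["total_carbons"] = [p.total_carbons for p in parsed]
    table["n_branches"] = [p.n_branches for p in parsed]
    table["n_double_bonds"] = [p.n_double_bonds for p in parsed]
    table["ambiguous_positions"] = [p.ambiguous_positions for p in parsed]
    return table


def linear_alkane_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Rows that are unbranched saturated alkanes (the in-table RI ladder)."""
    mask = (
        table["is_hydrocarbon"]
        & (table["n_branches"] == 0)
        & (table["n_double_bonds"] == 0)
        & ~table["ambiguous_positions"]
    )
    return table[mask]
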