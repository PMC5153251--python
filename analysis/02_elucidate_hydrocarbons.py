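#!/usr/bin/env python
"""Elucidate the branched-alkane panel from its EI spectra.

For each generated spectrum: extract the alkyl fragment series, fit the
exponential envelope, flag enhanced ions, count and place the methyl
branches, and cross-check the hypothesis against the retention-index
reference curves.  Writes results/elucidation.csv and reports how many
structures were recovered exactly.
"""

from pathlib import Path

import pandas as pd

from tfchem.chem_core import format_structure, formula_of
from tfchem.kovats import AlkaneLadder, build_ri_curves
from tfchem.spectrum_inference import EISpectrum, identify_compound

ROOT = Path(__file__).resolve().parents[1]
INPUTS = ROOT / "results" / "inputs"


def main() -> None:
    ladder = AlkaneLadder.from_csv(INPUTS / "ladder.csv")
    curves = build_ri_curves(pd.read_csv(INPUTS / "reference_ri.csv"))
    manifest = pd.read_csv(INPUTS / "spectra" / "peaks.csv")

    rows = []
    exact = 0
    for _, entry in manifest.iterrows():
        spectrum = EISpectrum.from_csv(
            INPUTS / "spectra" / entry["file"],
            parent_mass=int(entry["parent_mass"]),
        )
        result = identify_compound(spectrum, None, ladder, curves)
        proposed = result.proposed_name()
        recovered = proposed == entry["true_structure"]
        exact += recovered
        rows.append({
            "peak_id": entry["peak_id"],
            "mw": spectrum.parent_mass,
            "proposed_mf": None if result.structure is None
            else str(formula_of(result.structure)),
            "proposed_structure": proposed,
            "branch_count": result.branch_count,
            "enhanced_ions": ";".join(str(m) for m, _ in result.enhanced),
            "true_structure": entry["true_structure"],
            "recovered": recovered,
        })
    table = pd.DataFrame(rows)
    out = ROOT / "results" / "elucidation.csv"
    table.to_csv(out, index=False)
    print(table.to_string(index=False))
    print(f"\nrecovered {exact}/{len(table)} structures exactly -> {out}")


if __name__ == "__main__":
    main()
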