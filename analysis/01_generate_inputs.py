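#!/usr/bin/env python
"""Generate every synthetic input class used by the downstream analyses.

Writes, under results/inputs/:

* an n-alkane calibration ladder (C8-C40),
* EI spectra for a small panel of known alkane structures (with truth),
* the five-colony trophallactic-fluid / whole-body chromatogram cohort
  (with the true peak table),
* an in-colony vs. isolated spectral-count matrix (with truth flags).

All outputs are seeded and reproducible.
"""

import json
from pathlib import Path

import pandas as pd

from tfchem.chem_core import HydrocarbonStructure, format_structure, formula_of, nominal_mass
from tfchem.synthetic_data import (
    CohortConfig,
    CountsConfig,
    LadderConfig,
    ReferenceRIConfig,
    SpectrumConfig,
    gen_alkane_ladder,
    gen_cohort,
    gen_count_matrix,
    gen_ei_spectrum,
    gen_reference_ri_table,
)

SEED = 20160
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"

#: Panel of structures elucidated in 02: a linear alkane, three monomethyl
#: positional isomers, and a dimethyl alkane.
PANEL = [
    HydrocarbonStructure(26),
    HydrocarbonStructure(29, (9,)),
    HydrocarbonStructure(29, (7,)),
    HydrocarbonStructure(29, (5,)),
    HydrocarbonStructure(29, (5, 9)),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ladder = gen_alkane_ladder(LadderConfig())
    ladder.to_csv(OUT / "ladder.csv")

    reference = gen_reference_ri_table(
        ReferenceRIConfig(branch_offset=62.0, noise_sd=2.0, n_replicates=10,
                          carbon_min=20, carbon_max=36),
        seed=SEED,
    )
    reference.to_csv(OUT / "reference_ri.csv", index=False)

    spectra_dir = OUT / "spectra"
    spectra_dir.mkdir(exist_ok=True)
    manifest = []
    for i, structure in enumerate(PANEL):
        spec = gen_ei_spectrum(structure, SpectrumConfig(), seed=SEED + i)
        name = f"peak{i:02d}"
        spec.to_csv(spectra_dir / f"{name}.csv")
        manifest.append({
            "peak_id": name,
            "file": f"{name}.csv",
            "parent_mass": spec.parent_mass,
            "rt_min": "",
            "true_structure": format_structure(structure),
            "true_mf": str(formula_of(structure)),
        })
    pd.DataFrame(manifest).to_csv(spectra_dir / "peaks.csv", index=False)

    cohort_dir = OUT / "cohort"
    cohort_dir.mkdir(exist_ok=True)
    chroms, truth = gen_cohort(CohortConfig(), seed=SEED)
    rows = []
    for chrom in chroms:
        chrom.to_csv(cohort_dir / f"{chrom.sample_id}.csv")
        rows.append((chrom.sample_id, chrom.colony, chrom.source,
                     f"{chrom.sample_id}.csv"))
    pd.DataFrame(rows, columns=["sample_id", "colony", "source", "path"]).to_csv(
        cohort_dir / "manifest.csv", index=False)
    truth.to_csv(cohort_dir / "truth_peaks.csv", index=False)

    counts_dir = OUT / "counts"
    counts_dir.mkdir(exist_ok=True)
    matrix, flags = gen_count_matrix(CountsConfig(), seed=SEED)
    matrix.to_csv(counts_dir / "counts.csv", counts_dir / "metadata.csv")
    flags.to_csv(counts_dir / "truth_flags.csv")

    (OUT / "seed.json").write_text(json.dumps({"seed": SEED}) + "\n")
    print(f"wrote ladder ({len(ladder.entries)} alkanes), "
          f"{len(PANEL)} spectra, {len(chroms)} chromatograms and a "
          f"{matrix.counts.shape[0]}x{matrix.counts.shape[1]} count matrix "
          f"to {OUT}")


if __name__ == "__main__":
    main()
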