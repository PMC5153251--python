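import numpy as np
import pandas as pd
import pytest

from tfchem import compounds, profile_analysis as pa
from tfchem.kovats import AlkaneLadder
from tfchem.synthetic_data import CohortConfig, gen_cohort


@pytest.fixture(scope="session")
def compound_table() -> pd.DataFrame:
    return compounds.load_compound_table()


@pytest.fixture(scope="session")
def table_ladder(compound_table) -> AlkaneLadder:
    """n-alkane ladder built from the compound table's own linear alkanes."""
    rows = compounds.linear_alkane_rows(compound_table)
    return AlkaneLadder.from_pairs(zip(rows["total_carbons"], rows["rt_min"]))


def cohort_similarity(config: CohortConfig, seed: int) -> pa.SimilarityMatrix:
    """Full profile pipeline: generate -> normalize -> peaks -> bins -> xcorr."""
    chroms, _ = gen_cohort(config, seed=seed)
    profiles = {}
    meta_rows = []
    for chrom in chroms:
        normed = pa.normalize_profile(chrom, config.window)
        peaks = pa.find_peaks(normed)
        profiles[chrom.sample_id] = pa.bin_peaks(peaks)
        meta_rows.append((chrom.sample_id, chrom.colony, chrom.source))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "colony", "source"])
    return pa.similarity_matrix(profiles, meta)


@pytest.fixture(scope="session")
def default_cohort_similarity() -> pa.SimilarityMatrix:
    return cohort_similarity(CohortConfig(), seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
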