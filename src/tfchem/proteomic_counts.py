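"""NSAF spectral-count quantification and between-condition testing.

Spectral counting quantifies a protein by the number of MS/MS spectra
matched to it.  The normalized spectral abundance factor corrects the raw
count SpC for protein length L (longer proteins yield more peptides) and
for per-sample depth:

    NSAF_p,s = (SpC_p,s / L_p) / sum_q (SpC_q,s / L_q)

so each sample column sums to 1.  For displaying a subset of proteins
(e.g. the 40 most abundant) the values are re-normalized within the subset.
Condition effects (in-colony vs. socially isolated fluid) are tested per
protein with a two-sample t-test on NSAF values, paired by colony when the
design permits, with Bonferroni control over the tested family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind, ttest_rel

from .profile_analysis import ClusteringResult, hierarchical_cluster

__all__ = [
    "SpectralCountMatrix",
    "ConditionTestResult",
    "nsaf",
    "relative_nsaf",
    "top_proteins",
    "condition_test",
    "cluster_samples",
]


@dataclass(frozen=True)
class SpectralCountMatrix:
    """Proteins x samples spectral counts with protein lengths and metadata.

    ``counts``: DataFrame indexed by protein id, one integer column per
    sample.  ``lengths``: per-protein length in residues.  ``meta``:
    DataFrame with columns sample_id, condition, colony.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.lengths.index):
            raise ValueError("lengths must be indexed like the count rows")
        if (self.lengths <= 0).any():
            raise ValueError("protein lengths must be positive")
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be non-negative integers")
        missing = set(self.counts.columns) - set(self.meta["sample_id"])
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")
        zero = [s for s in self.counts.columns if self.counts[s].sum() == 0]
        if zero:
            raise ValueError(f"sample(s) with all-zero counts: {zero}")

    @classmethod
    def from_csv(cls, counts_path, meta_path) -> "SpectralCountMatrix":
        """Counts CSV: ``protein_id, length_aa, <sample>...``; metadata CSV:
        ``sample_id, condition, colony``."""
        counts = pd.read_csv(counts_path).set_index("protein_id")
        counts.index.name = None
        lengths = counts.pop("length_aa")
        meta = pd.read_csv(meta_path, dtype=str)
        for col in ("sample_id", "condition", "colony"):
            if col not in meta.columns:
                raise ValueError(f"metadata is missing column {col!r}")
        return cls(counts=counts, lengths=lengths, meta=meta)

    def to_csv(self, counts_path, meta_path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_aa", self.lengths)
        out.to_csv(counts_path, index_label="protein_id")
        self.meta.to_csv(meta_path, index=False)


def nsaf(matrix: SpectralCountMatrix) -> pd.DataFrame:
    """NSAF values; every sample column sums to exactly 1."""
    rate = matrix.counts.div(matrix.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return rate.div(totals, axis=1)


def relative_nsaf(nsaf_values: pd.DataFrame, protein_subset) -> pd.DataFrame:
    """Re-normalize NSAF within ``protein_subset`` so the subset sums to 1
    per sample (the convention used when displaying the top proteins)."""
    subset = nsaf_values.loc[list(protein_subset)]
    totals = subset.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(
            f"subset has zero NSAF sum in sample(s): {list(zero.index)}"
        )
    return subset.div(totals, axis=1)


def top_proteins(nsaf_values: pd.DataFrame, n: int = 40) -> list[str]:
    """The ``n`` proteins with the highest mean NSAF (ties broken by id)."""
    means = nsaf_values.mean(axis=1)
    order = sorted(means.index, key=lambda p: (-means[p], str(p)))
    return order[:n]


@dataclass(frozen=True)
class ConditionTestResult:
    table: pd.DataFrame  # per protein: t, pvalue, direction, flagged, skipped
    alpha: float
    family_size: int
    paired: bool

    @property
    def threshold(self) -> float:
        return self.alpha / self.family_size

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["flagged"]])


def condition_test(
    nsaf_values: pd.DataFrame,
    meta: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.05,
    family_size: int | None = None,
    paired: bool | str = "auto",
) -> ConditionTestResult:
    """Per-protein two-sample t-test between two conditions, Bonferroni-flagged.

    With ``paired="auto"`` the test pairs samples by colony whenever every
    colony contributes exactly one sample to each condition, and falls back
    to an unpaired (Welch) test otherwise.  Proteins with zero variance in
    both groups are skipped with a warning.  A protein is flagged when
    p <= alpha / family_size; the family defaults to the number of proteins
    tested.
    """
    meta_a = meta[meta["condition"] == condition_a]
    meta_b = meta[meta["condition"] == condition_b]
    if len(meta_a) < 2 or len(meta_b) < 2:
        raise ValueError("need at least two samples per condition")

    if paired == "auto":
        col_a = sorted(meta_a["colony"])
        col_b = sorted(meta_b["colony"])
        paired = (
            col_a == col_b
            and len(set(col_a)) == len(col_a)
        )
    if paired:
        order = sorted(meta_a["colony"])
        ids_a = [meta_a.set_index("colony")["sample_id"][c] for c in order]
        ids_b = [meta_b.set_index("colony")["sample_id"][c] for c in order]
    else:
        ids_a = list(meta_a["sample_id"])
        ids_b = list(meta_b["sample_id"])
    group_a = nsaf_values[ids_a].to_numpy()
    group_b = nsaf_values[ids_b].to_numpy()

    n_prot = nsaf_values.shape[0]
    family = family_size if family_size is not None else n_prot
    if family < n_prot:
        raise ValueError("family size must cover every tested protein")
    thresh = alpha / family

    rows = []
    skipped: list[str] = []
    for i, prot in enumerate(nsaf_values.index):
        a, b = group_a[i], group_b[i]
        if a.std() == 0 and b.std() == 0 and (not paired or (a - b).std() == 0):
            rows.append((np.nan, np.nan, "none", False, True))
            skipped.append(str(prot))
            continue
        if paired:
            res = ttest_rel(a, b)
        else:
            res = ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        direction = "up" if b.mean() > a.mean() else "down"
        rows.append((float(res.statistic), p, direction, p <= thresh, False))
    if skipped:
        warnings.warn(
            f"skipped zero-variance protein(s): {skipped}", UserWarning,
            stacklevel=2,
        )
    table = pd.DataFrame(
        rows,
        index=nsaf_values.index,
        columns=["statistic", "pvalue", "direction", "flagged", "skipped"],
    )
    return ConditionTestResult(
        table=table, alpha=alpha, family_size=family, paired=bool(paired)
    )


def cluster_samples(
    nsaf_values: pd.DataFrame,
    n_boot: int = 10000,
    seed: int | None = None,
    multiscale: bool = False,
) -> ClusteringResult:
    """Cluster sample columns by their NSAF profiles (correlation distance,
    average linkage) with bootstrap support over proteins."""
    return hierarchical_cluster(
        nsaf_values.T,
        labels=[str(c) for c in nsaf_values.columns],
        n_boot=n_boot,
        seed=seed,
        multiscale=multiscale,
    )
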