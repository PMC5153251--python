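"""Chromatographic profile comparison between trophallactic fluid and cuticle.

The pipeline behind the profile-similarity analysis: each total-ion
chromatogram is min-max normalized within the cuticular-hydrocarbon
retention-time window, dominant peaks are detected above a relative
abundance threshold (7% of the normalized range by default), filtered into
fixed-width retention-time bins (0.03 min) shared across the cohort, and
pairs of binned profiles are compared by coefficient-normalized
cross-correlation.  Within-fluid pairwise similarities (trophallactic fluid
of different colonies) are then tested against within-body pairs with a
two-sample t-test, and samples are clustered hierarchically with bootstrap
support on the dendrogram edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm, ttest_ind

__all__ = [
    "Chromatogram",
    "PeakTable",
    "BinnedProfile",
    "SimilarityMatrix",
    "GroupComparison",
    "ClusteringResult",
    "FlatTraceError",
    "ZeroNormError",
    "DegenerateVarianceError",
    "DEFAULT_WINDOW",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_REL_THRESHOLD",
    "normalize_profile",
    "find_peaks",
    "bin_peaks",
    "xcorr_similarity",
    "similarity_matrix",
    "compare_groups",
    "hierarchical_cluster",
]

#: Retention-time window (min) holding the C28-C37 cuticular hydrocarbons.
DEFAULT_WINDOW = (36.0, 51.0)
DEFAULT_BIN_WIDTH = 0.03
DEFAULT_REL_THRESHOLD = 0.07
#: Shared origin for bin edges so that every sample uses the same bins.
BIN_ORIGIN = 0.0


class FlatTraceError(ValueError):
    """Trace has no dynamic range inside the analysis window."""


class ZeroNormError(ValueError):
    """A binned profile with zero norm has no defined similarity."""


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance; use the permutation test instead."""


@dataclass(frozen=True)
class Chromatogram:
    """Abundance vs. retention time for one sample."""

    sample_id: str
    colony: str
    source: str  # "tf" | "body"
    rt: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        rt = np.asarray(self.rt, dtype=float)
        ab = np.asarray(self.abundance, dtype=float)
        if rt.shape != ab.shape or rt.ndim != 1:
            raise ValueError("rt and abundance must be matching 1-D arrays")
        if np.any(np.diff(rt) <= 0):
            raise ValueError("retention times must be strictly increasing")
        if np.any(ab < 0):
            raise ValueError("abundances must be non-negative")
        object.__setattr__(self, "rt", rt)
        object.__setattr__(self, "abundance", ab)

    @classmethod
    def from_csv(cls, path, sample_id: str, colony: str, source: str) -> "Chromatogram":
        frame = pd.read_csv(path, float_precision="round_trip")
        return cls(sample_id, colony, source,
                   frame["rt_min"].to_numpy(), frame["abundance"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"rt_min": self.rt, "abundance": self.abundance}).to_csv(
            path, index=False, float_format=lambda x: repr(float(x))
        )


@dataclass(frozen=True)
class PeakTable:
    """Detected peaks: (retention time, normalized abundance)."""

    rt: np.ndarray
    abundance: np.ndarray


@dataclass(frozen=True)
class BinnedProfile:
    """Peak abundances summed into fixed retention-time bins."""

    bin_width: float
    bins: dict[int, float]  # bin index -> summed abundance

    def vector(self, lo: int, hi: int) -> np.ndarray:
        """Dense per-bin vector over bin indices [lo, hi]."""
        out = np.zeros(hi - lo + 1)
        for idx, val in self.bins.items():
            if lo <= idx <= hi:
                out[idx - lo] = val
        return out


def normalize_profile(
    chrom: Chromatogram, window: tuple[float, float] = DEFAULT_WINDOW
) -> Chromatogram:
    """Restrict to ``window`` and min-max normalize the abundance to [0, 1]."""
    lo, hi = window
    mask = (chrom.rt >= lo) & (chrom.rt <= hi)
    if not mask.any():
        raise ValueError(f"window {window} does not overlap the trace")
    rt = chrom.rt[mask]
    ab = chrom.abundance[mask]
    lo_v, hi_v = ab.min(), ab.max()
    if hi_v <= lo_v:
        raise FlatTraceError(f"trace of {chrom.sample_id} is flat in {window}")
    return replace(chrom, rt=rt, abundance=(ab - lo_v) / (hi_v - lo_v))


def find_peaks(
    chrom: Chromatogram, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> PeakTable:
    """Local maxima of a normalized trace above ``rel_threshold``.

    A peak is a point strictly greater than both neighbours; a flat-topped
    plateau contributes its leftmost point.  Endpoints are not peaks.
    """
    ab = chrom.abundance
    idx: list[int] = []
    i = 1
    n = len(ab)
    while i < n - 1:
        if ab[i] > ab[i - 1]:
            j = i
            while j < n - 1 and ab[j + 1] == ab[j]:
                j += 1
            if j < n - 1 and ab[j + 1] < ab[j]:
                idx.append(i)  # leftmost point of the plateau
            i = j + 1
        else:
            i += 1
    idx_arr = np.array([k for k in idx if ab[k] >= rel_threshold], dtype=int)
    return PeakTable(rt=chrom.rt[idx_arr], abundance=ab[idx_arr])


def bin_peaks(
    peaks: PeakTable,
    bin_width: float = DEFAULT_BIN_WIDTH,
    origin: float = BIN_ORIGIN,
) -> BinnedProfile:
    """Assign peaks to fixed bins; co-binned peaks have their abundances summed."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[int, float] = {}
    for rt, ab in zip(peaks.rt, peaks.abundance):
        idx = int(np.floor((rt - origin) / bin_width))
        bins[idx] = bins.get(idx, 0.0) + float(ab)
    return BinnedProfile(bin_width=bin_width, bins=bins)


def xcorr_similarity(
    p1: BinnedProfile, p2: BinnedProfile, max_lag: int = 0
) -> float:
    """Coefficient-normalized cross-correlation of two binned profiles.

    The maximum over integer bin lags |l| <= ``max_lag`` of
    sum(p1[i] * p2[i+l]) / (||p1|| * ||p2||); with the default lag 0 this is
    the cosine similarity of the aligned bin vectors, bounded by 1 and
    invariant to positive rescaling of either profile.
    """
    if p1.bin_width != p2.bin_width:
        raise ValueError("profiles must share the same binning")
    if not p1.bins or not p2.bins:
        raise ZeroNormError("a profile with no peaks has no defined similarity")
    lo = min(min(p1.bins), min(p2.bins)) - max_lag
    hi = max(max(p1.bins), max(p2.bins)) + max_lag
    v1 = p1.vector(lo, hi)
    v2 = p2.vector(lo, hi)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ZeroNormError("zero-norm profile")
    best = -np.inf
    for lag in range(-max_lag, max_lag + 1):
        shifted = np.roll(v2, lag)
        if lag > 0:
            shifted[:lag] = 0.0
        elif lag < 0:
            shifted[lag:] = 0.0
        best = max(best, float(np.dot(v1, shifted)))
    return best / (n1 * n2)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise similarities with sample metadata.

    ``values`` is a symmetric DataFrame (diagonal 1) indexed by sample id;
    ``meta`` carries sample_id, colony and source for partitioning pairs
    into within-fluid, within-body and cross sets.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def within_source_pairs(self, source: str, across_colonies: bool = True) -> np.ndarray:
        """Pairwise similarities among samples of ``source``.

        With ``across_colonies`` (the default) only pairs from different
        colonies are kept — the cross-colony similarity the group test uses.
        """
        rows = self.meta[self.meta["source"] == source]
        vals = []
        for (_, a), (_, b) in combinations(rows.iterrows(), 2):
            if across_colonies and a["colony"] == b["colony"]:
                continue
            vals.append(self.values.loc[a["sample_id"], b["sample_id"]])
        return np.asarray(vals, dtype=float)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def similarity_matrix(
    profiles: dict[str, BinnedProfile],
    meta: pd.DataFrame,
    max_lag: int = 0,
) -> SimilarityMatrix:
    """All pairwise cross-correlation similarities for a cohort.

    ``profiles`` maps sample_id to its binned profile; ``meta`` must have
    columns sample_id, colony, source covering every profile.
    """
    ids = list(profiles)
    missing = set(ids) - set(meta["sample_id"])
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    mat = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for a, b in combinations(ids, 2):
        sim = xcorr_similarity(profiles[a], profiles[b], max_lag=max_lag)
        mat.loc[a, b] = sim
        mat.loc[b, a] = sim
    meta = meta[meta["sample_id"].isin(ids)].reset_index(drop=True)
    return SimilarityMatrix(values=mat, meta=meta)


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    pvalue: float
    method: str
    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    median_a: float
    median_b: float
    iqr_a: tuple[float, float]
    iqr_b: tuple[float, float]
    n_a: int
    n_b: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "pvalue": self.pvalue,
            "method": self.method,
            "groups": {
                self.group_a: {
                    "n": self.n_a, "mean": self.mean_a, "median": self.median_a,
                    "iqr": list(self.iqr_a),
                },
                self.group_b: {
                    "n": self.n_b, "mean": self.mean_b, "median": self.median_b,
                    "iqr": list(self.iqr_b),
                },
            },
        }


def _permutation_pvalue(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator, n_perm: int
) -> tuple[float, float]:
    """Two-sided mean-difference randomization test.

    Enumerates every regrouping exactly when there are at most ``n_perm``
    of them (the p-value is then k / C(n, n_a), so the smallest attainable
    value is realized); otherwise falls back to Monte Carlo with the +1
    correction."""
    from itertools import combinations
    from math import comb

    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    n_a = len(a)
    n_total = len(pooled)
    if comb(n_total, n_a) <= n_perm:
        count = total = 0
        for idx in combinations(range(n_total), n_a):
            mask = np.zeros(n_total, dtype=bool)
            mask[list(idx)] = True
            diff = pooled[mask].mean() - pooled[~mask].mean()
            count += abs(diff) >= abs(observed) - 1e-12
            total += 1
        return observed, count / total
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = pooled[:n_a].mean() - pooled[n_a:].mean()
        if abs(diff) >= abs(observed) - 1e-12:
            count += 1
    return observed, (count + 1) / (n_perm + 1)


def compare_groups(
    similarities: SimilarityMatrix,
    source_a: str = "tf",
    source_b: str = "body",
    method: str = "welch",
    n_perm: int = 10000,
    seed: int | None = None,
) -> GroupComparison:
    """Two-sample test of within-``source_a`` vs within-``source_b`` similarity.

    Methods: ``welch`` (default), ``pooled`` (equal-variance t), or
    ``permutation`` (mean-difference randomization, two-sided).  Degenerate
    variance under a t-test raises with a pointer to the permutation
    alternative.
    """
    a = similarities.within_source_pairs(source_a)
    b = similarities.within_source_pairs(source_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two pairwise values per partition")
    if method in ("welch", "pooled"):
        if a.std() == 0 and b.std() == 0:
            raise DegenerateVarianceError(
                "both partitions have zero variance; use method='permutation'"
            )
        res = ttest_ind(a, b, equal_var=(method == "pooled"))
        stat, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        stat, p = _permutation_pvalue(a, b, rng, n_perm)
    else:
        raise ValueError(f"unknown method {method!r}")
    q_a = np.percentile(a, [25, 75])
    q_b = np.percentile(b, [25, 75])
    return GroupComparison(
        statistic=stat, pvalue=p, method=method,
        group_a=f"within-{source_a}", group_b=f"within-{source_b}",
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        iqr_a=(float(q_a[0]), float(q_a[1])),
        iqr_b=(float(q_b[0]), float(q_b[1])),
        n_a=len(a), n_b=len(b),
    )


# --- hierarchical clustering with bootstrap support ------------------------


@dataclass(frozen=True)
class ClusteringResult:
    labels: tuple[str, ...]
    linkage: np.ndarray
    support: dict[frozenset, float]  # leaf-label set -> support (%)

    def support_for(self, members) -> float | None:
        return self.support.get(frozenset(members))

    def to_newick(self) -> str:
        """Newick string with bootstrap support (%) as internal node labels."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            members = frozenset(
                self.labels[i] for i in node.pre_order(lambda leaf: leaf.id)
            )
            sup = self.support.get(members)
            label = f"{sup:.0f}" if sup is not None else ""
            return f"({left},{right}){label}:{length:.6g}"

        root = render(tree, tree.dist)
        return root + ";"


def _cluster_sets(linkage: np.ndarray, labels: list[str]) -> set[frozenset]:
    n = len(labels)
    members: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    sets: set[frozenset] = set()
    for i, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        sets.add(merged)
    return sets


def _linkage_of(matrix: np.ndarray, metric: str, method: str) -> np.ndarray:
    dist = pdist(matrix, metric=metric)
    dist = np.nan_to_num(dist, nan=1.0)  # constant rows: maximal corr distance
    return hierarchy.linkage(dist, method=method)


def hierarchical_cluster(
    profiles: np.ndarray | pd.DataFrame,
    labels: list[str] | None = None,
    n_boot: int = 10000,
    method: str = "average",
    metric: str = "correlation",
    seed: int | None = None,
    multiscale: bool = False,
) -> ClusteringResult:
    """Agglomerative clustering of row profiles with bootstrap edge support.

    Rows of ``profiles`` are the objects to cluster, columns the features
    (bins or proteins).  Support for each internal edge is the percentage of
    ``n_boot`` feature-resampled replicates whose tree contains the same
    leaf set (ordinary bootstrap probability).  With ``multiscale=True`` a
    multiscale-bootstrap correction is applied: bootstrap proportions are
    measured at several resampling sizes r*p and extrapolated to the
    approximately unbiased support via the probit regression
    z(r) = v*sqrt(r) + c/sqrt(r), AU = 1 - Phi(v - c).
    """
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in profiles.index]
        matrix = profiles.to_numpy(dtype=float)
    else:
        matrix = np.asarray(profiles, dtype=float)
        if labels is None:
            labels = [f"S{i}" for i in range(matrix.shape[0])]
    if matrix.shape[0] < 3:
        raise ValueError("clustering needs at least three profiles")
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least two features")
    labels = list(labels)

    linkage = _linkage_of(matrix, metric, method)
    observed = _cluster_sets(linkage, labels)

    rng = np.random.default_rng(seed)
    p = matrix.shape[1]
    scales = [0.5, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.4] if multiscale else [1.0]
    counts = {r: {s: 0 for s in observed} for r in scales}
    for r in scales:
        size = max(2, int(round(r * p)))
        for _ in range(n_boot):
            cols = rng.integers(0, p, size=size)
            boot = _cluster_sets(_linkage_of(matrix[:, cols], metric, method), labels)
            for s in observed:
                if s in boot:
                    counts[r][s] += 1

    support: dict[frozenset, float] = {}
    if not multiscale:
        for s in observed:
            support[s] = 100.0 * counts[1.0][s] / n_boot
    else:
        eps = 1.0 / (2 * n_boot)
        sq = np.sqrt(np.asarray(scales))
        design = np.column_stack([sq, 1.0 / sq])
        for s in observed:
            bp = np.array(
                [min(max(counts[r][s] / n_boot, eps), 1 - eps) for r in scales]
            )
            z = norm.ppf(1.0 - bp)
            (v, c), *_ = np.linalg.lstsq(design, z, rcond=None)
            support[s] = 100.0 * float(1.0 - norm.cdf(v - c))
    return ClusteringResult(labels=tuple(labels), linkage=linkage, support=support)
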