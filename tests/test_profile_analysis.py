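"""Chromatogram normalization, peak detection, similarity and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfchem import profile_analysis as pa
from tfchem.synthetic_data import CohortConfig, gen_cohort

from conftest import cohort_similarity


def _chrom(rt, ab, sample_id="s", colony="C11", source="tf"):
    return pa.Chromatogram(sample_id, colony, source,
                           np.asarray(rt, float), np.asarray(ab, float))


class TestNormalize:
    def test_range_is_unit_interval(self):
        rt = np.linspace(36, 51, 200)
        ab = 3.0 + np.sin(rt) ** 2
        normed = pa.normalize_profile(_chrom(rt, ab))
        assert normed.abundance.min() == 0.0
        assert normed.abundance.max() == 1.0

    def test_affine_invariance(self):
        rt = np.linspace(36, 51, 200)
        ab = np.random.default_rng(0).uniform(1, 5, 200)
        base = pa.normalize_profile(_chrom(rt, ab))
        scaled = pa.normalize_profile(_chrom(rt, 2.5 * ab + 7.0))
        np.testing.assert_allclose(base.abundance, scaled.abundance, atol=1e-12)

    def test_window_restriction(self):
        rt = np.linspace(30, 55, 100)
        normed = pa.normalize_profile(_chrom(rt, rt * 0 + np.arange(100.0)))
        assert normed.rt.min() >= 36.0 and normed.rt.max() <= 51.0

    def test_flat_trace_rejected(self):
        rt = np.linspace(36, 51, 50)
        with pytest.raises(pa.FlatTraceError):
            pa.normalize_profile(_chrom(rt, np.ones(50)))


class TestFindPeaks:
    def test_single_triangular_peak(self):
        ab = [0, 0.25, 0.5, 0.75, 1.0, 0.75, 0.5, 0.25, 0]
        rt = 36 + 0.1 * np.arange(len(ab))
        peaks = pa.find_peaks(_chrom(rt, ab))
        assert len(peaks.rt) == 1
        assert peaks.rt[0] == pytest.approx(36.4)

    def test_subthreshold_peak_excluded(self):
        ab = [0, 0.05, 0, 0.5, 0]
        peaks = pa.find_peaks(_chrom(36 + 0.1 * np.arange(5), ab))
        assert list(peaks.abundance) == [0.5]

    def test_plateau_contributes_leftmost_point(self):
        ab = [0, 0.8, 0.8, 0.8, 0]
        rt = 36 + 0.1 * np.arange(5)
        peaks = pa.find_peaks(_chrom(rt, ab))
        assert list(peaks.rt) == [pytest.approx(36.1)]

    def test_known_peak_count_from_explicit_profile(self):
        heights = [0.9, 0.5, 0.03, 0.8, 0.04, 0.3, 0.6, 0.02, 0.2, 0.45, 0.7, 0.1]
        centers = 36.5 + 1.1 * np.arange(12)
        rt = np.arange(36.0, 51.0, 0.005)
        trace = sum(
            h * np.exp(-0.5 * ((rt - c) / 0.02) ** 2)
            for h, c in zip(heights, centers)
        )
        peaks = pa.find_peaks(_chrom(rt, trace))
        assert len(peaks.rt) == 9  # three peaks sit below the 7% threshold
        detected = sorted(peaks.rt)
        expected = sorted(c for h, c in zip(heights, centers) if h >= 0.07)
        np.testing.assert_allclose(detected, expected, atol=0.005)


class TestBinning:
    def test_close_peaks_share_a_bin(self):
        peaks = pa.PeakTable(np.array([42.70, 42.71]), np.array([0.5, 0.25]))
        binned = pa.bin_peaks(peaks, 0.03)
        assert len(binned.bins) == 1
        assert list(binned.bins.values()) == [pytest.approx(0.75)]

    def test_distant_peaks_separate_bins(self):
        peaks = pa.PeakTable(np.array([42.70, 42.74]), np.array([0.5, 0.25]))
        assert len(pa.bin_peaks(peaks, 0.03).bins) == 2

    def test_empty_peak_table(self):
        binned = pa.bin_peaks(pa.PeakTable(np.array([]), np.array([])))
        assert binned.bins == {}
        assert list(binned.vector(0, 10)) == [0.0] * 11


class TestXcorr:
    def test_self_similarity_is_one(self):
        p = pa.BinnedProfile(0.03, {100: 0.5, 110: 1.0, 120: 0.25})
        assert pa.xcorr_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_profiles_zero(self):
        p1 = pa.BinnedProfile(0.03, {100: 1.0})
        p2 = pa.BinnedProfile(0.03, {200: 1.0})
        assert pa.xcorr_similarity(p1, p2) == pytest.approx(0.0)

    def test_lag_search_recovers_unit_shift(self):
        p1 = pa.BinnedProfile(0.03, {100: 0.5, 110: 1.0})
        p2 = pa.BinnedProfile(0.03, {101: 0.5, 111: 1.0})
        assert pa.xcorr_similarity(p1, p2, max_lag=0) == pytest.approx(0.0)
        assert pa.xcorr_similarity(p1, p2, max_lag=1) == pytest.approx(1.0)

    def test_zero_profile_rejected(self):
        p1 = pa.BinnedProfile(0.03, {100: 1.0})
        with pytest.raises(pa.ZeroNormError):
            pa.xcorr_similarity(p1, pa.BinnedProfile(0.03, {}))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        bins1=st.dictionaries(st.integers(0, 30), st.floats(0.01, 1.0),
                              min_size=1, max_size=8),
        bins2=st.dictionaries(st.integers(0, 30), st.floats(0.01, 1.0),
                              min_size=1, max_size=8),
        scale=st.floats(0.1, 50.0),
    )
    def test_symmetry_bound_and_scale_invariance(self, bins1, bins2, scale):
        p1 = pa.BinnedProfile(0.03, bins1)
        p2 = pa.BinnedProfile(0.03, bins2)
        s12 = pa.xcorr_similarity(p1, p2)
        s21 = pa.xcorr_similarity(p2, p1)
        assert s12 == pytest.approx(s21)
        assert -1.0 <= s12 <= 1.0 + 1e-12
        scaled = pa.BinnedProfile(0.03, {k: scale * v for k, v in bins1.items()})
        assert pa.xcorr_similarity(scaled, p2) == pytest.approx(s12)


class TestCompareGroups:
    def test_fluid_more_uniform_than_body(self, default_cohort_similarity):
        report = pa.compare_groups(default_cohort_similarity)
        assert report.mean_a > report.mean_b
        assert report.pvalue < 0.01

    def test_identical_distributions_not_significant(self):
        # same cohort statistics for both sources: p should not be small
        sim = cohort_similarity(CohortConfig(tf_share=0.7, body_share=0.7), seed=42)
        report = pa.compare_groups(sim)
        assert report.pvalue > 0.05

    def test_degenerate_variance_directs_to_permutation(self):
        ids = [f"s{i}" for i in range(6)]
        meta = pd.DataFrame({
            "sample_id": ids,
            "colony": [f"C{i}" for i in range(6)],
            "source": ["tf"] * 3 + ["body"] * 3,
        })
        values = pd.DataFrame(np.eye(6), index=ids, columns=ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids[i + 1:], start=i + 1):
                v = 0.9 if (i < 3 and j < 3) else (0.5 if (i >= 3 and j >= 3) else 0.7)
                values.loc[a, b] = values.loc[b, a] = v
        sim = pa.SimilarityMatrix(values=values, meta=meta)
        with pytest.raises(pa.DegenerateVarianceError):
            pa.compare_groups(sim)
        report = pa.compare_groups(sim, method="permutation", seed=0)
        # exhaustive enumeration: the observed split is one of the two most
        # extreme of C(6,3) = 20, so p is the smallest attainable value
        assert report.pvalue == pytest.approx(2 / 20)

    def test_too_few_pairs_rejected(self):
        meta = pd.DataFrame({
            "sample_id": ["a", "b"], "colony": ["C1", "C2"],
            "source": ["tf", "body"],
        })
        values = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            pa.compare_groups(pa.SimilarityMatrix(values, meta))


class TestHierarchicalCluster:
    def test_identical_pair_joined_first_with_full_support(self):
        x = np.array([[1.0, 0.2, 0.3, 0.9],
                      [1.0, 0.2, 0.3, 0.9],
                      [0.1, 0.9, 0.8, 0.2]])
        res = pa.hierarchical_cluster(x, labels=["a", "b", "c"], n_boot=50, seed=0)
        assert res.support_for({"a", "b"}) == 100.0

    def test_single_bootstrap_support_is_binary(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(4, 10))
        res = pa.hierarchical_cluster(x, n_boot=1, seed=0)
        assert set(res.support.values()) <= {0.0, 100.0}

    def test_requires_three_profiles(self):
        with pytest.raises(ValueError):
            pa.hierarchical_cluster(np.ones((2, 5)))

    def test_fluid_samples_form_a_cluster(self):
        """With higher cross-colony sharing, the fluid block joins together."""
        chroms, _ = gen_cohort(CohortConfig(), seed=2)
        profiles = {
            c.sample_id: pa.bin_peaks(pa.find_peaks(pa.normalize_profile(c)))
            for c in chroms
        }
        bins = sorted({b for p in profiles.values() for b in p.bins})
        ids = list(profiles)
        matrix = np.vstack([profiles[s].vector(bins[0], bins[-1]) for s in ids])
        res = pa.hierarchical_cluster(matrix, labels=ids, n_boot=30, seed=2)
        fluid = frozenset(s for s in ids if s.endswith("_tf"))
        assert fluid in res.support

    def test_newick_is_well_formed(self):
        import dendropy

        rng = np.random.default_rng(5)
        x = rng.uniform(size=(5, 12))
        res = pa.hierarchical_cluster(x, labels=list("abcde"), n_boot=20, seed=1)
        tree = dendropy.Tree.get(data=res.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set("abcde")

    def test_bootstrap_support_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=(5, 15))
        a = pa.hierarchical_cluster(x, n_boot=40, seed=9)
        b = pa.hierarchical_cluster(x, n_boot=40, seed=9)
        assert a.support == b.support

    def test_multiscale_support_in_range(self):
        x = np.array([[1.0, 0.2, 0.3, 0.9, 0.1],
                      [0.9, 0.25, 0.28, 0.8, 0.12],
                      [0.1, 0.9, 0.8, 0.2, 0.7],
                      [0.15, 0.85, 0.9, 0.1, 0.75]])
        res = pa.hierarchical_cluster(x, n_boot=30, seed=0, multiscale=True)
        assert all(0.0 <= v <= 100.0 for v in res.support.values())
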