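"""NSAF quantification, condition testing and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from tfchem import proteomic_counts as pc
from tfchem.synthetic_data import CountsConfig, gen_count_matrix


def _matrix(counts: dict, lengths: dict, conditions=None, colonies=None):
    frame = pd.DataFrame(counts)
    lens = pd.Series(lengths)
    samples = list(frame.columns)
    meta = pd.DataFrame({
        "sample_id": samples,
        "condition": conditions or ["a"] * len(samples),
        "colony": colonies or [f"C{i}" for i in range(len(samples))],
    })
    return pc.SpectralCountMatrix(counts=frame, lengths=lens, meta=meta)


class TestNsaf:
    def test_single_protein_is_one(self):
        counts = pd.DataFrame({"s1": [7]}, index=["p1"])
        lengths = pd.Series({"p1": 300})
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["a"], "colony": ["C1"]}
        )
        m = pc.SpectralCountMatrix(counts, lengths, meta)
        assert pc.nsaf(m).iloc[0, 0] == pytest.approx(1.0)

    def test_length_normalization_closed_form(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["p1", "p2"])
        lengths = pd.Series({"p1": 100, "p2": 200})
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["a"], "colony": ["C1"]}
        )
        values = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        assert values.loc["p1", "s1"] == pytest.approx(2 / 3)
        assert values.loc["p2", "s1"] == pytest.approx(1 / 3)

    def test_columns_sum_to_one(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(20, 6)),
            index=[f"p{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        lengths = pd.Series(rng.integers(100, 900, 20), index=counts.index)
        meta = pd.DataFrame({
            "sample_id": counts.columns, "condition": ["a"] * 6,
            "colony": [f"C{i}" for i in range(6)],
        })
        values = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        np.testing.assert_allclose(values.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_rejected_at_construction(self):
        with pytest.raises(ValueError, match="s2"):
            _matrix({"s1": [5, 3], "s2": [0, 0]}, {0: 100, 1: 200})

    def test_naive_row_duplication_changes_values(self):
        """Splitting a protein's counts across duplicate rows redistributes
        NSAF mass: the quantity is not invariant to naive duplication."""
        counts = pd.DataFrame({"s1": [10, 10]}, index=["p1", "p2"])
        lengths = pd.Series({"p1": 100, "p2": 200})
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["a"], "colony": ["C1"]}
        )
        base = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        dup_counts = pd.DataFrame({"s1": [10, 10, 10]}, index=["p1", "p1b", "p2"])
        dup_lengths = pd.Series({"p1": 100, "p1b": 100, "p2": 200})
        dup = pc.nsaf(pc.SpectralCountMatrix(dup_counts, dup_lengths, meta))
        assert dup.loc["p2", "s1"] != pytest.approx(base.loc["p2", "s1"])


class TestRelativeNsaf:
    def test_full_subset_is_identity(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(8, 3)), index=[f"p{i}" for i in range(8)],
            columns=["s0", "s1", "s2"],
        )
        lengths = pd.Series(rng.integers(100, 500, 8), index=counts.index)
        meta = pd.DataFrame({
            "sample_id": counts.columns, "condition": ["a"] * 3,
            "colony": list("XYZ"),
        })
        values = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        np.testing.assert_allclose(
            pc.relative_nsaf(values, values.index), values, atol=1e-12
        )

    def test_half_subset_sums_to_one(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 30, size=(8, 3)), index=[f"p{i}" for i in range(8)],
            columns=["s0", "s1", "s2"],
        )
        lengths = pd.Series(rng.integers(100, 500, 8), index=counts.index)
        meta = pd.DataFrame({
            "sample_id": counts.columns, "condition": ["a"] * 3,
            "colony": list("XYZ"),
        })
        values = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        rel = pc.relative_nsaf(values, values.index[:4])
        np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_top_protein_selection_matches_brute_force(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 40, size=(30, 5)),
            index=[f"p{i:02d}" for i in range(30)],
            columns=[f"s{i}" for i in range(5)],
        )
        counts.iloc[:, 0] += 1  # keep every column nonzero
        lengths = pd.Series(rng.integers(100, 900, 30), index=counts.index)
        meta = pd.DataFrame({
            "sample_id": counts.columns, "condition": ["a"] * 5,
            "colony": [f"C{i}" for i in range(5)],
        })
        values = pc.nsaf(pc.SpectralCountMatrix(counts, lengths, meta))
        top = pc.top_proteins(values, n=10)
        brute = (
            values.mean(axis=1)
            .sort_values(ascending=False, kind="stable")
            .index[:10]
        )
        assert set(top) == set(brute)


def _nsaf_like(rng, n_prot=40, n_per=6, shift_protein=None, shift_sd=5.0):
    """Synthetic NSAF-scale values: two conditions, optional shifted protein."""
    base = rng.uniform(0.01, 0.05, size=n_prot)
    data = {}
    meta_rows = []
    for j in range(n_per):
        for cond in ("in_colony", "isolated"):
            sample = f"C{j}_{cond}"
            vals = base + rng.normal(0, 0.004, size=n_prot)
            if shift_protein is not None and cond == "isolated":
                vals[shift_protein] += shift_sd * 0.004
            data[sample] = np.clip(vals, 1e-6, None)
            meta_rows.append((sample, cond, f"C{j}"))
    values = pd.DataFrame(data, index=[f"p{i:02d}" for i in range(n_prot)])
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "condition", "colony"])
    return values, meta


class TestConditionTest:
    def test_shifted_protein_is_flagged(self, rng):
        values, meta = _nsaf_like(rng, shift_protein=7, shift_sd=5.0)
        result = pc.condition_test(values, meta, "in_colony", "isolated")
        assert "p07" in result.flagged
        assert result.table.loc["p07", "direction"] == "up"

    def test_zero_alpha_flags_nothing(self, rng):
        values, meta = _nsaf_like(rng, shift_protein=7)
        result = pc.condition_test(values, meta, "in_colony", "isolated", alpha=0.0)
        assert result.flagged == []

    def test_bonferroni_flags_subset_of_unadjusted(self, rng):
        values, meta = _nsaf_like(rng, shift_protein=3, shift_sd=3.0)
        adjusted = pc.condition_test(values, meta, "in_colony", "isolated")
        unadjusted = pc.condition_test(
            values, meta, "in_colony", "isolated", family_size=values.shape[0]
        )
        raw_flags = set(
            unadjusted.table.index[unadjusted.table["pvalue"] <= 0.05]
        )
        assert set(adjusted.flagged) <= raw_flags

    def test_pairing_detected_from_metadata(self, rng):
        values, meta = _nsaf_like(rng)
        result = pc.condition_test(values, meta, "in_colony", "isolated")
        assert result.paired
        unpaired_meta = meta.copy()
        unpaired_meta["colony"] = [f"G{i}" for i in range(len(meta))]
        result2 = pc.condition_test(values, unpaired_meta, "in_colony", "isolated")
        assert not result2.paired

    def test_zero_variance_protein_skipped(self, rng):
        values, meta = _nsaf_like(rng)
        values.iloc[0, :] = 0.02
        with pytest.warns(UserWarning, match="p00"):
            result = pc.condition_test(values, meta, "in_colony", "isolated")
        assert bool(result.table.loc["p00", "skipped"])

    def test_family_smaller_than_tested_rejected(self, rng):
        values, meta = _nsaf_like(rng)
        with pytest.raises(ValueError):
            pc.condition_test(
                values, meta, "in_colony", "isolated", family_size=10
            )


def test_low_noise_limit_recovers_all_affected_proteins():
    """With near-Poisson counts at high depth, every truth-affected protein
    is flagged (direction up); other proteins may legitimately flag down,
    since boosting a subset depresses all other relative abundances."""
    import warnings

    cfg = CountsConfig(dispersion=1e5, count_scale=20.0, abundance_sigma=0.5)
    matrix, truth = gen_count_matrix(cfg, seed=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        result = pc.condition_test(
            pc.nsaf(matrix), matrix.meta, "in_colony", "isolated"
        )
    affected = set(truth[truth].index)
    assert affected <= set(result.flagged)
    assert (result.table.loc[sorted(affected), "direction"] == "up").all()


class TestClusterSamples:
    def test_duplicate_samples_join_first(self, rng):
        values, meta = _nsaf_like(rng, n_prot=20, n_per=2)
        values["C0_in_colony"] = values["C1_isolated"]
        res = pc.cluster_samples(values, n_boot=40, seed=0)
        assert res.support_for({"C0_in_colony", "C1_isolated"}) == 100.0

    def test_condition_effect_separates_samples(self):
        matrix, truth = gen_count_matrix(
            CountsConfig(effect_size=10.0, affected_fraction=0.5,
                         abundance_sigma=0.3, dispersion=50.0),
            seed=11,
        )
        values = pc.nsaf(matrix)
        res = pc.cluster_samples(values, n_boot=30, seed=1)
        isolated = frozenset(s for s in values.columns if s.endswith("isolated"))
        assert isolated in res.support

    def test_single_protein_rejected(self, rng):
        values = pd.DataFrame(
            {"s1": [1.0], "s2": [1.0], "s3": [1.0]}, index=["p1"]
        )
        with pytest.raises(ValueError):
            pc.cluster_samples(values, n_boot=5, seed=0)
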