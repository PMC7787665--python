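"""Count I/O, prevalence filtering, RLE factors and NSAF conservation."""

import numpy as np
import pandas as pd
import pytest

from subpop.counts import (CountMatrix, CountMatrixError, filter_by_prevalence,
                           normalize_counts, nsaf_table, read_counts,
                           rle_factors, write_counts)


def make_matrix(counts, lengths=None, organisms=None,
                samples=("Srich_R1_XS", "Srich_R1_S")):
    counts = np.asarray(counts)
    n = counts.shape[0]
    ids = [f"P{i}" for i in range(n)]
    return CountMatrix(
        pd.DataFrame(counts, index=pd.Index(ids, name="protein_id"),
                     columns=list(samples)),
        pd.DataFrame({"organism": organisms or ["symbiont"] * n,
                      "length_aa": lengths or [100] * n,
                      "category": "unknown"},
                     index=pd.Index(ids, name="protein_id")))


class TestIO:
    def test_round_trip(self, tmp_path, small_data):
        m, _ = small_data
        path = tmp_path / "counts.tsv"
        write_counts(m, path)
        back = read_counts(path)
        pd.testing.assert_frame_equal(back.counts, m.counts)
        pd.testing.assert_frame_equal(back.proteins, m.proteins)

    def test_duplicate_protein_rejected(self):
        with pytest.raises(CountMatrixError, match="duplicate"):
            CountMatrix(
                pd.DataFrame([[1], [2]], index=["P1", "P1"],
                             columns=["Srich_R1_XS"]),
                pd.DataFrame({"organism": "host", "length_aa": 100,
                              "category": ""}, index=["P1", "P1"]))

    def test_non_integer_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\torganism\tlength_aa\tcategory\tSrich_R1_XS\n"
                        "P1\thost\t100\tx\t3.7\n")
        with pytest.raises(CountMatrixError, match="non-integer"):
            read_counts(path)

    def test_negative_count_and_missing_length_rejected(self):
        with pytest.raises(CountMatrixError, match="negative"):
            make_matrix([[-1, 2]])
        with pytest.raises(CountMatrixError, match="length_aa"):
            make_matrix([[1, 2]], lengths=[np.nan])


class TestPrevalenceFilter:
    def test_kept_and_dropped_examples(self):
        m = make_matrix([[5, 5, 0, 0], [4, 9, 0, 0]],
                        samples=["Srich_R1_XS", "Srich_R1_S",
                                 "Srich_R1_M", "Srich_R1_L"])
        out = filter_by_prevalence(m, min_count=5, min_samples=2)
        assert list(out.protein_ids) == ["P0"]

    def test_monotone_in_both_thresholds(self, small_data):
        m, _ = small_data
        base = set(filter_by_prevalence(m, 5, 4).protein_ids)
        assert set(filter_by_prevalence(m, 6, 4).protein_ids) <= base
        assert set(filter_by_prevalence(m, 5, 5).protein_ids) <= base

    def test_min_samples_exceeding_samples_errors(self):
        m = make_matrix([[5, 5]])
        with pytest.raises(ValueError):
            filter_by_prevalence(m, min_count=5, min_samples=3)


class TestRle:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(rle_factors(counts), 1.0)

    def test_hand_computed_factor_ratio(self):
        """3x2 example: column 2 doubled everywhere => s2/s1 = 2."""
        counts = pd.DataFrame([[10, 20], [10, 20], [40, 80]],
                              columns=["a", "b"])
        s = rle_factors(counts)
        assert s["b"] / s["a"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0)

    def test_scaled_columns_equal_after_normalization(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 100, 50)
        m = make_matrix(np.column_stack([col, 2 * col]))
        norm = normalize_counts(m)
        np.testing.assert_allclose(norm.normalized.iloc[:, 0],
                                   norm.normalized.iloc[:, 1])

    def test_equivariance_under_sample_scaling(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(1, 200, size=(40, 4)))
        s0 = rle_factors(counts)
        scaled = counts.copy()
        scaled[2] = counts[2] * 3
        s1 = rle_factors(scaled)
        assert (s1[2] / s0[2]) / (s1[0] / s0[0]) == pytest.approx(3.0)

    def test_invariant_to_protein_order(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 200, size=(40, 4)))
        shuffled = counts.sample(frac=1, random_state=3)
        np.testing.assert_allclose(rle_factors(counts), rle_factors(shuffled))

    def test_no_universally_detected_protein_errors(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="filter"):
            rle_factors(counts)

    def test_agrees_with_deseq2_size_factors(self):
        """Cross-check against pydeseq2's median-of-ratios implementation."""
        preprocessing = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(4)
        # odd protein count: the linear- and log-scale medians coincide, so
        # our median-of-ratios agrees exactly with DESeq2's construction
        counts = pd.DataFrame(rng.integers(1, 500, size=(61, 5)))
        _, sf = preprocessing.deseq2_norm(counts.T)  # expects samples x genes
        ours = rle_factors(counts).to_numpy()
        theirs = np.asarray(sf, dtype=float).ravel()
        theirs = theirs / np.exp(np.mean(np.log(theirs)))
        np.testing.assert_allclose(ours, theirs, rtol=1e-10)


class TestNsaf:
    def test_worked_example(self):
        m = make_matrix([[10], [40]], lengths=[100, 200],
                        samples=["Srich_R1_XS"])
        t = nsaf_table(m)
        np.testing.assert_allclose(t.saf["Srich_R1_XS"], [0.1, 0.2])
        np.testing.assert_allclose(t.nsaf["Srich_R1_XS"], [1 / 3, 2 / 3])
        np.testing.assert_allclose(t.pct_orgnsaf["Srich_R1_XS"],
                                   [100 / 3, 200 / 3])

    def test_single_protein_per_organism_gets_100_percent(self):
        m = make_matrix([[10], [40]], lengths=[100, 200],
                        organisms=["host", "symbiont"],
                        samples=["Srich_R1_XS"])
        np.testing.assert_allclose(nsaf_table(m).pct_orgnsaf["Srich_R1_XS"],
                                   [100.0, 100.0])

    def test_zero_count_protein_and_all_zero_sample(self):
        m = make_matrix([[0, 0], [10, 0]], lengths=[100, 200])
        t = nsaf_table(m)
        assert t.nsaf.iloc[0, 0] == 0.0
        assert t.nsaf["Srich_R1_S"].isna().all()
        assert any("Srich_R1_S" in e for e in t.errors)

    def test_conservation_on_real_layout(self, small_data):
        m, _ = small_data
        t = nsaf_table(m)
        np.testing.assert_allclose(t.nsaf.sum(axis=0), 1.0, atol=1e-9)
        for org in ("host", "symbiont"):
            sub = t.pct_orgnsaf.loc[m.proteins["organism"] == org]
            np.testing.assert_allclose(sub.sum(axis=0), 100.0, atol=1e-6)
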