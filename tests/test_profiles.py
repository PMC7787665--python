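"""Ordered-profile arm: log-ratios, filters, model profiles, permutation null."""

import itertools

import numpy as np
import pandas as pd
import pytest

from subpop.counts import sample_table
from subpop.profiles import (ModelProfileSet, ProfileMatrix, assign_profiles,
                             generate_model_profiles, log_ratio_profiles,
                             profile_significance, replicate_filter)


def pm_from_values(values):
    values = np.asarray(values, dtype=float)
    return ProfileMatrix(values, pd.Index([f"P{i}" for i in range(len(values))]),
                         list(range(values.shape[1])))


class TestLogRatios:
    @pytest.mark.parametrize("x,pc,expected", [
        ((8, 16, 32, 64), 0.0, (0, 1, 2, 3)),
        ((5, 5, 5, 5), 1.0, (0, 0, 0, 0)),
        ((0, 1, 3, 7), 1.0, (0, 1, 2, 3)),
    ])
    def test_examples(self, x, pc, expected):
        ids = [f"Srich_R1_{f}" for f in ("XS", "S", "M", "L")]
        normalized = pd.DataFrame([x], index=["P0"], columns=ids, dtype=float)
        pm = log_ratio_profiles(normalized, sample_table(ids), "S-rich",
                                pseudocount=pc)
        np.testing.assert_allclose(pm.values[0, 0], expected)

    def test_incomplete_replicate_dropped_with_warning(self):
        ids = [f"Srich_R1_{f}" for f in ("XS", "S", "M", "L")] + ["Srich_R2_XS"]
        normalized = pd.DataFrame(np.ones((2, 5)), columns=ids)
        with pytest.warns(UserWarning, match="R2"):
            pm = log_ratio_profiles(normalized, sample_table(ids), "S-rich")
        assert pm.values.shape[1] == 1


class TestReplicateFilter:
    def test_identical_replicates_with_unit_change_retained(self):
        pm = pm_from_values([[[0, 1, 1, 1], [0, 1, 1, 1]]])
        assert replicate_filter(pm).tolist() == [True]

    def test_anticorrelated_replicates_dropped(self):
        pm = pm_from_values([[[0, 1, 2, 3], [0, -1, -2, -3]]])
        assert replicate_filter(pm).tolist() == [False]

    def test_flat_profiles_fail_minimum_change(self):
        pm = pm_from_values([[[0, 0.2, 0.3, 0.4], [0, 0.2, 0.3, 0.4]]])
        assert replicate_filter(pm, delta_min=0.5).tolist() == [False]

    def test_min_mode_stricter_than_mean(self):
        # pairwise correlations 1.0 / 0.316 / 0.316: mean 0.544, min 0.316
        reps = [[0, 1, 2, 3], [0, 1, 2, 3], [0, 2, 1, 1]]
        pm = pm_from_values([reps])
        assert replicate_filter(pm, mode="mean").tolist() == [True]
        assert replicate_filter(pm, mode="min").tolist() == [False]


class TestModelProfiles:
    def test_candidate_counts(self):
        assert generate_model_profiles(T=4, c=1, m=100).n == 26
        assert generate_model_profiles(T=4, c=2, m=200).n == 124
        assert generate_model_profiles(T=4, c=2, m=50).n == 50

    def test_greedy_selection_matches_independent_oracle(self):
        """Re-run the greedy max-min rule naively and compare selections."""
        full = generate_model_profiles(T=4, c=2, m=124).profiles
        picked = generate_model_profiles(T=4, c=2, m=10).profiles

        def corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            return (a @ b) / np.sqrt((a @ a) * (b @ b))

        d = np.round(np.array([[1 - corr(a.astype(float), b.astype(float))
                                for b in full] for a in full]), 12)
        sel = [int(np.argmax(np.round(d.sum(axis=1), 10)))]
        while len(sel) < 10:
            rest = [i for i in range(len(full)) if i not in sel]
            mins = [d[i, sel].min() for i in rest]
            sel.append(rest[int(np.argmax(mins))])  # first max = lowest index
        oracle = full[sorted(sel)]
        np.testing.assert_array_equal(picked, oracle)

    def test_no_flat_profile_and_all_distinct(self):
        profs = generate_model_profiles(T=4, c=2, m=124).profiles
        assert not (profs == 0).all(axis=1).any()
        assert len(np.unique(profs, axis=0)) == len(profs)


class TestAssignment:
    def test_exact_match_and_sign_discrimination(self):
        model = ModelProfileSet(np.array([[0, 1, 2, 3], [0, -1, -2, -3]]))
        pm = pm_from_values([[[0, 1, 2, 3]], [[0, -2, -4, -6]]])
        out = assign_profiles(pm, model)
        assert out.loc["P0", "profile_id"] == 0
        assert out.loc["P0", "correlation"] == pytest.approx(1.0)
        assert out.loc["P1", "profile_id"] == 1

    def test_correlation_tie_takes_lowest_profile_id(self):
        # (0,1,1,0) is symmetric between the two models -> equal correlations
        model = ModelProfileSet(np.array([[0, 1, 0, 0], [0, 0, 1, 0]]))
        pm = pm_from_values([[[0, 1, 1, 0]]])
        out = assign_profiles(pm, model)
        assert out.loc["P0", "profile_id"] == 0

    def test_zero_variance_profile_unassigned(self):
        model = ModelProfileSet(np.array([[0, 1, 2, 3]]))
        pm = pm_from_values([[[0, 0, 0, 0]]])
        assert assign_profiles(pm, model).loc["P0", "profile_id"] == -1


def brute_force_significance(values, model_profiles, alpha=0.05):
    """Independent enumeration of the 24-permutation null (plain loops)."""
    from scipy.stats import binom
    from statsmodels.stats.multitest import multipletests

    def assign_one(v):
        best, best_c = -1, -np.inf
        if np.std(v) == 0:
            return -1
        for j, mp in enumerate(model_profiles):
            c = np.corrcoef(v, mp)[0, 1]
            if c > best_c + 1e-12:
                best, best_c = j, c
        return best

    n_model = len(model_profiles)
    perms = list(itertools.permutations(range(4)))
    counts = np.zeros((len(perms), n_model))
    for k, perm in enumerate(perms):
        for prot in values:
            reb = np.array([[rep[p] - rep[perm[0]] for p in perm]
                            for rep in prot])
            j = assign_one(reb.mean(axis=0))
            if j >= 0:
                counts[k, j] += 1
    n_obs = counts[0]          # identity permutation is first
    expected = counts.mean(axis=0)
    N = int(n_obs.sum())
    pvals = np.array([binom.sf(n_obs[j] - 1, N, expected[j] / N)
                      for j in range(n_model)])
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return n_obs, expected, pvals, reject


@pytest.fixture(scope="module")
def small_instance():
    rng = np.random.default_rng(10)
    base = np.array([[0, 1, 2, 3]], dtype=float)
    trending = base + rng.normal(0, 0.2, size=(6, 2, 4))
    noise = rng.normal(0, 1.0, size=(4, 2, 4))
    values = np.concatenate([trending, noise])
    values -= values[:, :, [0]]
    model = ModelProfileSet(np.array([[0, 1, 2, 3], [0, -1, -2, -3]]))
    return pm_from_values(values), model


class TestSignificance:
    def test_matches_brute_force_enumeration(self, small_instance):
        pm, model = small_instance
        res = profile_significance(pm, model)
        n_obs, expected, pvals, reject = brute_force_significance(
            pm.values, model.profiles.astype(float))
        np.testing.assert_array_equal(res.profile_table["n_obs"], n_obs)
        np.testing.assert_allclose(res.profile_table["expected"], expected)
        np.testing.assert_allclose(res.profile_table["pvalue"], pvals)
        np.testing.assert_array_equal(res.profile_table["significant"], reject)

    def test_expected_counts_conserve_assigned_total(self, small_instance):
        pm, model = small_instance
        res = profile_significance(pm, model)
        assert res.profile_table["expected"].sum() == pytest.approx(
            res.n_assigned, abs=1e-6)

    def test_protein_order_does_not_change_significance(self, small_instance):
        pm, model = small_instance
        res = profile_significance(pm, model)
        perm = np.random.default_rng(3).permutation(len(pm.proteins))
        res2 = profile_significance(pm.subset(perm), model)
        pd.testing.assert_series_equal(
            res.protein_table["significant"].sort_index(),
            res2.protein_table["significant"].sort_index())

    def test_binomial_tail_monotone_in_observed_count(self):
        from scipy.stats import binom
        p = [binom.sf(n - 1, 50, 0.2) for n in (10, 15, 20)]
        assert p[0] > p[1] > p[2]

    def test_no_assigned_proteins_warns(self):
        model = ModelProfileSet(np.array([[0, 1, 2, 3]]))
        pm = pm_from_values([[[0, 0, 0, 0]]])
        with pytest.warns(UserWarning):
            res = profile_significance(pm, model)
        assert res.n_assigned == 0

    def test_null_data_rarely_significant(self):
        """Exchangeable fractions: profile-significant rate stays near alpha."""
        from subpop.profiles import generate_model_profiles
        model = generate_model_profiles()
        rates = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            values = rng.normal(0, 1, size=(150, 4, 4))
            values -= values[:, :, [0]]
            pm = pm_from_values(values)
            keep = replicate_filter(pm)
            res = profile_significance(pm.subset(keep), model)
            rates.append(len(res.significant_proteins) / 150)
        mc_sigma = np.std(rates) / np.sqrt(len(rates))
        assert np.mean(rates) <= 0.05 + 3 * max(mc_sigma, 1e-3)
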