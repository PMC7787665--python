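"""Overdispersed-count two-group exact tests.

For comparing the same size class between sulfur conditions, and for testing
host-protein enrichment in the light gradient fractions versus homogenate,
counts are modeled as negative binomial with variance mu + phi*mu^2 and a
single common dispersion phi.  Libraries are first equalized to a common
effective size (pseudo-counts), the common dispersion is estimated by
profile maximum likelihood, and each protein is tested with a conditional
exact test: under the null of equal means the two group sums A and B are NB
with sizes n_A/phi and n_B/phi, and the two-sided p-value sums the
probabilities of all outcomes a' with P(a'|A+B=t) <= P(a_obs|t).  At phi = 0
this reduces to the classical binomial (Poisson-conditional) test.  BH
correction is applied across proteins.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, filter_by_prevalence, normalize_counts, rle_factors

_POISSON_PHI = 1e-6
_REL_EQ = 1 + 1e-7      # float slack when comparing point probabilities


def equalize_libraries(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Rescale counts to a common effective library size (integer pseudo-counts).

    The median-of-ratios size factor s_j is itself proportional to the
    effective depth of sample j, so pseudo_ij = round(y_ij * gmean(s)/s_j)
    equalizes depth; rounding is round-half-to-even (numpy's default).
    """
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("need a positive size factor for every sample")
    scale = np.exp(np.mean(np.log(factors))) / factors
    return pd.DataFrame(
        np.round(counts.to_numpy() * scale.to_numpy()).astype(np.int64),
        index=counts.index, columns=counts.columns)


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Sum of NB(mu, var = mu + phi mu^2) log-pmfs; Poisson below 1e-6."""
    pos = mu > 0
    y, mu = y[pos], mu[pos]
    if phi < _POISSON_PHI:
        return float(stats.poisson.logpmf(y, mu).sum())
    r = 1.0 / phi
    return float(stats.nbinom.logpmf(y, r, r / (r + mu)).sum())


def estimate_common_dispersion(pseudo: pd.DataFrame, groups) -> float:
    """Single common dispersion by profile ML over a log grid + refinement.

    Group means are plugged in per protein; phi maximizes the summed NB
    log-likelihood over [1e-6, 10].
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    y = pseudo.to_numpy(dtype=float)
    mu = np.empty_like(y)
    for g in levels:
        cols = groups == g
        mu[:, cols] = y[:, cols].mean(axis=1, keepdims=True)

    def nll(log_phi):
        return -_nb_loglik(y.ravel(), mu.ravel(), float(np.exp(log_phi)))

    grid = np.log(np.logspace(-6, 1, 25))
    vals = [nll(g) for g in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    if lo == hi:
        return float(np.exp(grid[k]))
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded")
    best = res.x if res.fun <= vals[k] else grid[k]
    return float(np.exp(best))


def _conditional_pvalue(a: int, t: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p of group-A sum ``a`` given total ``t``."""
    if t == 0:
        return 1.0
    av = np.arange(t + 1)
    if phi < _POISSON_PHI:
        logp = stats.binom.logpmf(av, t, n_a / (n_a + n_b))
    else:
        mu = t / (n_a + n_b)
        ra, rb = n_a / phi, n_b / phi
        logp = (stats.nbinom.logpmf(av, ra, ra / (ra + n_a * mu))
                + stats.nbinom.logpmf(t - av, rb, rb / (rb + n_b * mu)))
        logp -= np.max(logp)
    p = np.exp(logp)
    p /= p.sum()
    return float(min(1.0, p[p <= p[a] * _REL_EQ].sum()))


def nb_exact_test(pseudo: pd.DataFrame, groups, phi: float,
                  alpha: float = 0.05, prior: float = 0.5) -> pd.DataFrame:
    """Per-protein conditional exact test of group A vs group B.

    Returns group means (pseudo-count scale), log2 fold change (with a
    ``prior`` added to each group mean), the dispersion used, exact p, BH q,
    and the significance flag at q < alpha.
    """
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    ca, cb = (groups == levels[0]), (groups == levels[1])
    n_a, n_b = int(ca.sum()), int(cb.sum())
    y = pseudo.to_numpy()
    a_sums = y[:, ca].sum(axis=1)
    b_sums = y[:, cb].sum(axis=1)
    pvals = np.array([_conditional_pvalue(int(a), int(a + b), n_a, n_b, phi)
                      for a, b in zip(a_sums, b_sums)])
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    mean_a, mean_b = a_sums / n_a, b_sums / n_b
    return pd.DataFrame({
        "group_a": levels[0], "group_b": levels[1],
        "mean_a": mean_a, "mean_b": mean_b,
        "log2_fc": np.log2((mean_a + prior) / (mean_b + prior)),
        "dispersion": phi, "pvalue": pvals, "qvalue": qvals,
        "significant": qvals < alpha,
    }, index=pseudo.index)


def enrich_host_proteins(matrix: CountMatrix, condition: str,
                         min_count: int = 5, min_samples: int | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Host proteins enriched in light fractions (XS, S) vs homogenate.

    Prevalence-filters host proteins over the XS/S/Hom samples of one
    condition (default min_samples = the number of biological replicates),
    RLE-normalizes those samples, runs the exact test {XS,S} vs {Hom}, and
    flags proteins that are significant AND have a higher mean normalized
    abundance in the fractions than in homogenate.
    """
    host = matrix.subset_proteins(
        matrix.protein_ids[matrix.proteins["organism"] == "host"])
    frac_ids = host.select_samples(condition, ("XS", "S"))
    hom_ids = host.select_samples(condition, ("Hom",))
    if not hom_ids:
        raise ValueError(f"no homogenate samples for condition {condition!r}")
    use = frac_ids + hom_ids
    if min_samples is None:
        min_samples = host.samples.loc[use, "replicate"].nunique()
    host = filter_by_prevalence(host, min_count=min_count,
                                min_samples=min_samples, sample_ids=use)
    sub = host.subset_samples(use)
    factors = rle_factors(sub.counts)
    norm = normalize_counts(sub, factors)
    pseudo = equalize_libraries(sub.counts, factors)
    groups = np.where(np.isin(use, frac_ids), "fraction", "homogenate")
    phi = estimate_common_dispersion(pseudo, groups)
    res = nb_exact_test(pseudo, groups, phi, alpha=alpha)
    res["mean_norm_fraction"] = norm.normalized[frac_ids].mean(axis=1)
    res["mean_norm_homogenate"] = norm.normalized[hom_ids].mean(axis=1)
    res["enriched"] = res["significant"] & (
        res["mean_norm_fraction"] > res["mean_norm_homogenate"])
    return res
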