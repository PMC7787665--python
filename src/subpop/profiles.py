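"""Ordered-series model-profile significance over gradient fractions.

The four gradient fractions form a short ordered series XS < S < M < L
(ordered by symbiont cell size).  Per protein and biological replicate a
log2-ratio profile relative to fraction XS is computed from RLE-normalized
abundances; proteins whose replicate profiles are mutually consistent and
show a minimum absolute change are assigned, by Pearson correlation, to the
closest of a set of integer-step model profiles.  Significance of a model
profile is judged against a permutation null: assignments are recomputed
under every permutation of the fraction order, the expected count per profile
is the mean over permutations, and the observed count is tested with a
binomial tail, Benjamini-Hochberg corrected across profiles.  Proteins
assigned to a significant profile are the profile-significant set.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import FRACTIONS


@dataclass
class ProfileMatrix:
    """Per-protein, per-replicate log2 profiles over ordered fractions.

    values has shape (n_proteins, n_replicates, T); the first fraction's
    entry is identically 0 (profiles are ratios to the first fraction).
    """

    values: np.ndarray
    proteins: pd.Index
    replicates: list
    fractions: tuple = FRACTIONS

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profiles contain non-finite values")
        if not np.allclose(self.values[:, :, 0], 0.0):
            raise ValueError("first fraction entry of every profile must be 0")

    def subset(self, mask) -> "ProfileMatrix":
        return ProfileMatrix(self.values[mask], self.proteins[mask],
                             self.replicates, self.fractions)

    def mean_profiles(self) -> np.ndarray:
        return self.values.mean(axis=1)


def log_ratio_profiles(normalized: pd.DataFrame, samples: pd.DataFrame,
                       condition: str, pseudocount: float = 1.0,
                       fraction_order: tuple = FRACTIONS) -> ProfileMatrix:
    """log2((x_t + pc) / (x_first + pc)) per protein and replicate.

    ``normalized``: proteins x samples RLE-normalized abundances.  A replicate
    missing any fraction sample is dropped with a warning.
    """
    meta = samples[(samples["condition"] == condition)
                   & samples["sample_type"].isin(fraction_order)]
    reps = sorted(meta["replicate"].unique())
    layers, kept = [], []
    for rep in reps:
        sub = meta[meta["replicate"] == rep]
        by_type = sub.reset_index().set_index("sample_type")["sample_id"]
        if not all(f in by_type.index for f in fraction_order):
            warnings.warn(f"replicate {rep}: missing fraction sample, dropped")
            continue
        cols = [by_type[f] for f in fraction_order]
        x = normalized[cols].to_numpy(dtype=float)
        logx = np.log2(x + pseudocount)
        layers.append(logx - logx[:, [0]])
        kept.append(rep)
    if not layers:
        raise ValueError(f"no complete replicate for condition {condition!r}")
    return ProfileMatrix(np.stack(layers, axis=1), normalized.index, kept,
                         tuple(fraction_order))


def _pairwise_corr_stats(vecs: np.ndarray, mode: str) -> float:
    """Mean (or min) pairwise Pearson correlation; zero-variance vectors fail."""
    sd = vecs.std(axis=1)
    if (sd == 0).any():
        return -np.inf
    z = (vecs - vecs.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = z @ z.T / vecs.shape[1]
    iu = np.triu_indices(len(vecs), k=1)
    vals = corr[iu]
    return float(vals.mean() if mode == "mean" else vals.min())


def replicate_filter(pm: ProfileMatrix, r_min: float = 0.5,
                     delta_min: float = 0.5, mode: str = "mean") -> np.ndarray:
    """Boolean mask of proteins with consistent, non-flat replicate profiles.

    Retains a protein iff (a) the mean (or, with mode='min', minimum) pairwise
    Pearson correlation between its replicate profiles is >= r_min, and
    (b) the largest absolute entry of its mean profile is >= delta_min.
    """
    if pm.values.shape[1] < 2:
        raise ValueError("replicate filter needs >= 2 replicates")
    if mode not in ("mean", "min"):
        raise ValueError("mode must be 'mean' or 'min'")
    n = len(pm.proteins)
    keep = np.zeros(n, dtype=bool)
    mean_prof = pm.mean_profiles()
    for i in range(n):
        if np.abs(mean_prof[i]).max() < delta_min:
            continue
        keep[i] = _pairwise_corr_stats(pm.values[i], mode) >= r_min
    return keep


@dataclass
class ModelProfileSet:
    """Integer-step template profiles of length T starting at 0."""

    profiles: np.ndarray          # (n_profiles, T)
    max_unit_change: int = 2
    max_profiles: int = 50

    @property
    def n(self) -> int:
        return len(self.profiles)


def generate_model_profiles(T: int = 4, c: int = 2,
                            m: int = 50) -> ModelProfileSet:
    """All non-flat step profiles with steps in {-c..c}; at most m retained.

    When more than m candidates exist, m maximally distinct profiles are kept
    greedily: the seed is the candidate with the largest summed
    correlation-distance to all others, and each subsequent pick maximizes the
    minimum distance to the already-selected set (distance = 1 - Pearson;
    ties resolved by lexicographic order of the step sequence).
    """
    if T < 2 or c < 1 or m < 1:
        raise ValueError("need T >= 2, c >= 1, m >= 1")
    steps = np.array(list(itertools.product(range(-c, c + 1), repeat=T - 1)))
    profiles = np.concatenate([np.zeros((len(steps), 1), dtype=int),
                               np.cumsum(steps, axis=1)], axis=1)
    profiles = profiles[np.abs(profiles).sum(axis=1) > 0]
    if len(profiles) <= m:
        return ModelProfileSet(profiles, c, m)
    z = profiles - profiles.mean(axis=1, keepdims=True)
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    dist = np.round(1.0 - z @ z.T, 12)   # rounded so exact ties break by index
    selected = [int(np.argmax(np.round(dist.sum(axis=1), 10)))]
    remaining = set(range(len(profiles))) - set(selected)
    while len(selected) < m:
        cand = sorted(remaining)
        mind = dist[np.ix_(cand, selected)].min(axis=1)
        pick = cand[int(np.argmax(mind))]
        selected.append(pick)
        remaining.remove(pick)
    return ModelProfileSet(profiles[sorted(selected)], c, m)


def _assign(mean_profiles: np.ndarray, model: ModelProfileSet):
    """Best-correlated model profile per protein (-1 = unassigned).

    Ties go to the lowest profile id; zero-variance mean profiles are
    unassigned.
    """
    mp = model.profiles.astype(float)
    zm = mp - mp.mean(axis=1, keepdims=True)
    zm /= np.linalg.norm(zm, axis=1, keepdims=True)
    x = mean_profiles - mean_profiles.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(x, axis=1)
    ok = norm > 0
    corr = np.full((len(mean_profiles), model.n), -np.inf)
    corr[ok] = (x[ok] / norm[ok, None]) @ zm.T
    corr = np.round(corr, 12)        # stabilize float ties -> lowest id wins
    assigned = np.where(ok, corr.argmax(axis=1), -1)
    best = np.where(ok, corr.max(axis=1), np.nan)
    return assigned, best


def assign_profiles(pm: ProfileMatrix, model: ModelProfileSet) -> pd.DataFrame:
    """Assign each protein's across-replicate mean profile to a model profile."""
    assigned, corr = _assign(pm.mean_profiles(), model)
    return pd.DataFrame({"profile_id": assigned, "correlation": corr},
                        index=pm.proteins)


@dataclass
class ProfileAssignment:
    """Result of profile significance: per-protein and per-profile tables."""

    protein_table: pd.DataFrame   # profile_id, correlation, significant
    profile_table: pd.DataFrame   # n_obs, expected, pvalue, qvalue, significant, group
    n_assigned: int
    model: ModelProfileSet = field(repr=False, default=None)

    @property
    def significant_proteins(self) -> pd.Index:
        t = self.protein_table
        return t.index[t["significant"]]


def _group_profiles(model: ModelProfileSet, which: np.ndarray,
                    threshold: float = 0.5) -> dict:
    """Group profiles whose pairwise Pearson correlation >= threshold
    (connected components, i.e. single linkage on the correlation graph)."""
    ids = list(np.flatnonzero(which))
    if not ids:
        return {}
    mp = model.profiles[ids].astype(float)
    z = mp - mp.mean(axis=1, keepdims=True)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    adj = (z @ z.T) >= threshold
    parent = list(range(len(ids)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if adj[i, j]:
                parent[find(i)] = find(j)
    roots = {}
    groups = {}
    for k, pid in enumerate(ids):
        r = find(k)
        groups[pid] = roots.setdefault(r, len(roots) + 1)
    return groups


def profile_significance(pm: ProfileMatrix, model: ModelProfileSet,
                         alpha: float = 0.05,
                         group_corr: float = 0.5) -> ProfileAssignment:
    """Permutation-null significance of model-profile membership.

    For every permutation of the fraction order the profiles are re-based to
    the permuted first fraction, mean profiles recomputed and re-assigned; the
    expected count E_p of profile p is the mean assigned count over all T!
    permutations.  The observed count n_p is tested with the binomial tail
    P(X >= n_p), X ~ Bin(N, E_p/N), and BH-corrected across profiles at
    ``alpha``.  Significant profiles are then grouped at pairwise correlation
    >= ``group_corr``.
    """
    T = pm.values.shape[2]
    assigned, corr = _assign(pm.mean_profiles(), model)
    n_obs = np.bincount(assigned[assigned >= 0], minlength=model.n)
    N = int((assigned >= 0).sum())
    if N == 0:
        warnings.warn("no protein assigned to any model profile")
        empty = pd.DataFrame({"profile_id": assigned, "correlation": corr,
                              "significant": False}, index=pm.proteins)
        return ProfileAssignment(empty, pd.DataFrame(), 0, model)

    perm_counts = []
    for perm in itertools.permutations(range(T)):
        w = pm.values[:, :, perm]
        w = w - w[:, :, [0]]
        a, _ = _assign(w.mean(axis=1), model)
        perm_counts.append(np.bincount(a[a >= 0], minlength=model.n))
    expected = np.mean(perm_counts, axis=0)

    pvals = stats.binom.sf(n_obs - 1, N, np.clip(expected / N, 0.0, 1.0))
    reject, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    groups = _group_profiles(model, reject, group_corr)

    profile_table = pd.DataFrame({
        "n_obs": n_obs, "expected": expected, "pvalue": pvals,
        "qvalue": qvals, "significant": reject,
        "group": [groups.get(p, 0) for p in range(model.n)],
    }, index=pd.RangeIndex(model.n, name="profile_id"))
    sig_profiles = set(np.flatnonzero(reject))
    protein_table = pd.DataFrame({
        "profile_id": assigned, "correlation": corr,
        "significant": [a in sig_profiles for a in assigned],
    }, index=pm.proteins)
    return ProfileAssignment(protein_table, profile_table, N, model)


def profile_significant_proteins(normalized: pd.DataFrame, samples: pd.DataFrame,
                                 condition: str, pseudocount: float = 1.0,
                                 r_min: float = 0.5, delta_min: float = 0.5,
                                 rep_mode: str = "mean", c: int = 2, m: int = 50,
                                 alpha: float = 0.05) -> ProfileAssignment:
    """Full profile arm: log-ratio profiles -> replicate filter -> significance."""
    pm = log_ratio_profiles(normalized, samples, condition, pseudocount)
    keep = replicate_filter(pm, r_min=r_min, delta_min=delta_min, mode=rep_mode)
    model = generate_model_profiles(T=pm.values.shape[2], c=c, m=m)
    return profile_significance(pm.subset(keep), model, alpha=alpha)
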