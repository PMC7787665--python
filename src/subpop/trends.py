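"""Combining the two significance arms and classifying abundance trends.

A protein is *significant* if either the ordered-profile arm or the
random-forest stability arm (or both) flags it — set union, not p-value
combination.  For significant proteins the across-replicate mean
RLE-normalized abundance per fraction is classified as monotonically
increasing, monotonically decreasing, or other over XS -> S -> M -> L, and
the z-scored fraction means are clustered hierarchically (Pearson
correlation distance, complete linkage) for heatmap ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .synth import FRACTIONS


def combine_significance(profile_set, rf_set, universe) -> pd.DataFrame:
    """OR of the two significance arms over the filtered protein universe."""
    universe = pd.Index(universe)
    for name, s in (("profiles", profile_set), ("rf", rf_set)):
        extra = pd.Index(s).difference(universe)
        if len(extra):
            raise ValueError(f"{name} set contains proteins outside the "
                             f"universe: {list(extra[:5])}")
    out = pd.DataFrame(index=universe)
    out["significant_by_profiles"] = universe.isin(set(profile_set))
    out["significant_by_rf"] = universe.isin(set(rf_set))
    out["significant"] = out["significant_by_profiles"] | out["significant_by_rf"]
    return out


def classify_trend(fraction_means, tolerance: float = 0.0) -> str:
    """'monotonic_up' / 'monotonic_down' / 'other' over ordered fraction means.

    Successive steps may dip by up to ``tolerance`` (default 0: non-strict
    monotone), but the overall change last-vs-first must be strict.
    """
    x = np.asarray(fraction_means, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite fraction mean")
    d = np.diff(x)
    if np.all(d >= -tolerance) and x[-1] > x[0]:
        return "monotonic_up"
    if np.all(d <= tolerance) and x[-1] < x[0]:
        return "monotonic_down"
    return "other"


def fraction_means(normalized: pd.DataFrame, samples: pd.DataFrame,
                   condition: str) -> pd.DataFrame:
    """Across-replicate mean normalized abundance per fraction (XS..L)."""
    meta = samples[(samples["condition"] == condition)
                   & samples["sample_type"].isin(FRACTIONS)]
    cols = {}
    for f in FRACTIONS:
        ids = meta.index[meta["sample_type"] == f]
        cols[f] = normalized[ids].mean(axis=1)
    return pd.DataFrame(cols)


def zscore_rows(means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores; zero-variance rows become all zeros."""
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    z = means.sub(mu, axis=0).div(sd.where(sd > 0), axis=0)
    return z.fillna(0.0)


def significance_table(flags: pd.DataFrame, means: pd.DataFrame,
                       tolerance: float = 0.0) -> pd.DataFrame:
    """Per-protein significance flags, fraction means, z-scores and trend.

    Trend labels are only defined for significant proteins; zero-variance
    proteins are forced to 'other'.
    """
    out = flags.join(means.add_prefix("mean_"))
    z = zscore_rows(means)
    out = out.join(z.add_prefix("z_"))
    trend = []
    for pid in out.index:
        if not out.at[pid, "significant"]:
            trend.append("")
        elif means.loc[pid].std(ddof=0) == 0:
            trend.append("other")
        else:
            trend.append(classify_trend(means.loc[pid].to_numpy(), tolerance))
    out["trend"] = trend
    return out


def cluster_significant(means: pd.DataFrame, cut_height: float = 0.5):
    """Hierarchical clustering of z-scored fraction means of significant proteins.

    Distance = 1 - Pearson correlation between z-scored profiles; complete
    linkage; flat clusters cut at ``cut_height``.  Zero-variance proteins go
    to a dedicated cluster 0 ('flat') and are excluded from the tree.
    Returns (cluster ids Series, linkage matrix, Index of clustered proteins).
    """
    sd = means.std(axis=1, ddof=0)
    flat = means.index[sd == 0]
    live = means.index[sd > 0]
    if len(live) < 2:
        raise ValueError("need >= 2 significant proteins with nonzero variance")
    z = zscore_rows(means.loc[live])
    dist = pdist(z.to_numpy(), metric="correlation")
    linkage = hierarchy.linkage(dist, method="complete")
    ids = hierarchy.fcluster(linkage, t=cut_height, criterion="distance")
    clusters = pd.Series(0, index=means.index, name="cluster")
    clusters.loc[live] = ids
    clusters.loc[flat] = 0
    return clusters, linkage, live
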