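"""Random-forest stability selection with mirrored-null importance p-values.

Many independently seeded random forests are trained to predict the size-class
label of each sample from protein abundances.  Per forest, each protein gets a
signed out-of-bag permutation importance; a heuristic p-value is computed
against an empirical null built by mirroring the non-positive importance
scores (irrelevant features are sign-symmetric around zero, so {v <= 0} union
{-v : v < 0} estimates the null distribution).  A protein is selected when its
p-value falls below ``alpha`` in more than a ``consensus`` fraction of the
forests — a stability-selection rule that rewards consistency rather than any
single small p-value.

The tree primitive is sklearn's DecisionTreeClassifier; the bagging loop, OOB
bookkeeping and permutation importance live here so that importances are
signed and every forest is reproducible from (base seed, forest index).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from sklearn.tree import DecisionTreeClassifier

from .synth import FRACTIONS


def janitza_pvalues(importances: np.ndarray) -> np.ndarray:
    """Heuristic p-values from the mirrored null of non-positive importances.

    null = {v : v <= 0} U {-v : v < 0};  p(feature) = #{null >= v} / |null|.
    p = 0 is permitted (importance above every null value).
    """
    v = np.asarray(importances, dtype=float)
    nonpos = v[v <= 0]
    if nonpos.size == 0:
        raise ValueError(
            "no feature has importance <= 0; the mirrored null is empty — "
            "use more (noise) features or a permutation-importance fallback")
    null = np.sort(np.concatenate([nonpos, -v[v < 0]]))
    # p = fraction of null values >= v_i
    idx = np.searchsorted(null, v, side="left")
    return (null.size - idx) / null.size


def _forest_importance(X32: np.ndarray, y: np.ndarray, n_trees: int,
                       rng: np.random.Generator,
                       max_features: str | int = "sqrt") -> np.ndarray:
    """Mean OOB permutation importance over one forest's trees.

    Per tree: bootstrap the samples, fit, measure OOB accuracy, then re-measure
    with each used feature permuted within the OOB set; the importance of a
    feature is the mean accuracy drop (0 for trees not using it).  Negative
    values arise when permuting a feature improves OOB accuracy.
    """
    n, p = X32.shape
    imp = np.zeros(p)
    boots = rng.integers(0, n, size=(n_trees, n))
    seeds = rng.integers(0, 2**31, size=n_trees)
    all_idx = np.arange(n)
    with sklearn.config_context(skip_parameter_validation=True,
                                assume_finite=True):
        for t in range(n_trees):
            idx = boots[t]
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            oob = all_idx[mask]
            if oob.size == 0:
                continue
            tree = DecisionTreeClassifier(max_features=max_features,
                                          random_state=int(seeds[t]))
            tree.fit(X32[idx], y[idx], check_input=False)
            Xo, yo = X32[oob], y[oob]
            used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
            k, m = used.size, oob.size
            stacked = np.tile(Xo, (k + 1, 1))
            for j, f in enumerate(used):
                stacked[(j + 1) * m:(j + 2) * m, f] = Xo[rng.permutation(m), f]
            pred = tree.predict(stacked, check_input=False).reshape(k + 1, m)
            acc = (pred == yo).mean(axis=1)
            imp[used] += acc[0] - acc[1:]
    return imp / n_trees


def _shadow_gini_importance(X32: np.ndarray, y: np.ndarray, n_trees: int,
                            rng: np.random.Generator,
                            max_features: str | int = "sqrt") -> np.ndarray:
    """Shadow-corrected Gini importance (signed).

    The feature matrix is augmented with a row-permuted copy of itself (the
    'shadow' block, redrawn per forest); a feature's score is its summed Gini
    importance minus its shadow's.  A feature with no real association is
    exchangeable with its shadow, so its score is symmetric around zero —
    the premise the mirrored null needs.
    """
    n, p = X32.shape
    shadow = X32[rng.permutation(n)]
    Xaug = np.ascontiguousarray(np.concatenate([X32, shadow], axis=1))
    imp = np.zeros(2 * p)
    boots = rng.integers(0, n, size=(n_trees, n))
    seeds = rng.integers(0, 2**31, size=n_trees)
    with sklearn.config_context(skip_parameter_validation=True,
                                assume_finite=True):
        for t in range(n_trees):
            tree = DecisionTreeClassifier(max_features=max_features,
                                          random_state=int(seeds[t]))
            tree.fit(Xaug[boots[t]], y[boots[t]], check_input=False)
            imp += tree.tree_.compute_feature_importances(normalize=False)
    return (imp[:p] - imp[p:]) / n_trees


_IMPORTANCES = {"oob_permutation": _forest_importance,
                "gini_corrected": _shadow_gini_importance}


@dataclass
class PValueMatrix:
    """Per-protein, per-forest heuristic importance p-values."""

    pvalues: pd.DataFrame       # proteins x forests, in [0, 1]
    n_forests: int
    n_trees: int
    classes: tuple
    base_seed: int

    def __post_init__(self):
        vals = self.pvalues.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")


def forest_ensemble(features: pd.DataFrame, labels, n_forests: int = 100,
                    n_trees: int = 500, seed: int = 0,
                    max_features: str | int = "sqrt",
                    importance: str = "oob_permutation",
                    permute_labels: bool = False) -> PValueMatrix:
    """Train ``n_forests`` independently seeded forests; p-values per protein.

    ``features``: samples x proteins (normalized abundances); ``labels``: one
    class per sample.  Forest f's generator is spawned from (seed, f), so the
    ensemble is reproducible and forests are independent of execution order.
    ``importance`` selects the signed measure ('oob_permutation' or
    'gini_corrected').

    ``permute_labels=True`` trains every forest on labels freshly permuted by
    that forest's generator — the permutation-null ensemble used to validate
    type-I behavior of the downstream consensus rule.  (With labels fixed, a
    small sample set always contains features whose chance association with
    the labels is real at the dataset level and identically ranked by every
    forest; no consensus over forests can, or should, reject those.)
    """
    labels = np.asarray(labels)
    classes = tuple(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if importance not in _IMPORTANCES:
        raise ValueError(f"unknown importance {importance!r}")
    imp_fn = _IMPORTANCES[importance]
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in labels])
    X32 = np.ascontiguousarray(features.to_numpy(), dtype=np.float32)
    pmat = np.empty((features.shape[1], n_forests))
    for f in range(n_forests):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(f,)))
        yf = y[rng.permutation(len(y))] if permute_labels else y
        imp = imp_fn(X32, yf, n_trees, rng, max_features)
        pmat[:, f] = janitza_pvalues(imp)
    return PValueMatrix(
        pd.DataFrame(pmat, index=features.columns,
                     columns=[f"forest_{f}" for f in range(n_forests)]),
        n_forests, n_trees, classes, seed)


@dataclass
class StabilityResult:
    """Consensus selection across forests."""

    table: pd.DataFrame         # frac_significant, selected per protein
    alpha: float
    consensus: float

    @property
    def selected(self) -> pd.Index:
        return self.table.index[self.table["selected"]]


def stability_select(pmat: PValueMatrix, alpha: float = 0.05,
                     consensus: float = 0.9) -> StabilityResult:
    """Select proteins with p < alpha in strictly more than ``consensus``
    of the forests (90 of 100 forests is NOT enough at consensus 0.9)."""
    if pmat.pvalues.empty:
        raise ValueError("empty p-value matrix")
    frac = (pmat.pvalues < alpha).mean(axis=1)
    table = pd.DataFrame({"frac_significant": frac,
                          "selected": frac > consensus})
    return StabilityResult(table, alpha, consensus)


def rf_significant_proteins(normalized: pd.DataFrame, samples: pd.DataFrame,
                            condition: str, mode: str = "all",
                            n_forests: int = 100, n_trees: int = 500,
                            seed: int = 0, alpha: float = 0.05,
                            consensus: float = 0.9,
                            pairwise_universe: pd.Index | None = None) -> pd.DataFrame:
    """Stability selection over fraction-class contrasts for one condition.

    mode='all' trains on all four fraction classes at once; mode='pairwise'
    runs the six pairwise fraction contrasts (restricted to
    ``pairwise_universe`` proteins if given, reflecting the stricter
    prevalence filter used for two-class comparisons); mode='both' unions
    them.  Returns one boolean column per contrast plus 'selected' (the union)
    per protein.
    """
    if mode not in ("all", "pairwise", "both"):
        raise ValueError("mode must be 'all', 'pairwise' or 'both'")
    meta = samples[(samples["condition"] == condition)
                   & samples["sample_type"].isin(FRACTIONS)]
    out = pd.DataFrame(index=normalized.index)
    contrasts = []
    if mode in ("all", "both"):
        contrasts.append(("all4", tuple(FRACTIONS), normalized.index))
    if mode in ("pairwise", "both"):
        universe = pairwise_universe if pairwise_universe is not None \
            else normalized.index
        for a, b in itertools.combinations(FRACTIONS, 2):
            contrasts.append((f"{a}_vs_{b}", (a, b), universe))
    for k, (name, types, universe) in enumerate(contrasts):
        sub = meta[meta["sample_type"].isin(types)]
        feats = normalized.loc[universe, sub.index].T
        pmat = forest_ensemble(feats, sub["sample_type"].to_numpy(),
                               n_forests=n_forests, n_trees=n_trees,
                               seed=seed + k)
        sel = stability_select(pmat, alpha=alpha, consensus=consensus)
        out[name] = pd.Series(False, index=out.index)
        out.loc[sel.selected, name] = True
    out["selected"] = out.any(axis=1)
    return out
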