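"""Convenience chains over the pipeline stages.

The significance analysis operates on the symbiont proteome: host proteins
are excluded before filtering/normalization (they enter only the NSAF tables
and the host-enrichment contrast), mirroring the study design where the
fraction-trend question is about symbiont cell stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counts import CountMatrix, NormalizedMatrix, filter_by_prevalence, normalize_counts
from .profiles import ProfileAssignment, profile_significant_proteins
from .rf_stability import rf_significant_proteins
from .synth import FRACTIONS
from .trends import combine_significance, fraction_means, significance_table

#: prevalence presets: (replicates, min_samples 4-class, min_samples pairwise)
PREVALENCE = {"S-rich": {"min_samples": 4, "min_samples_pairwise": 6},
              "S-depleted": {"min_samples": 3, "min_samples_pairwise": 4}}


@dataclass
class ConditionData:
    """Filtered, normalized symbiont fraction samples of one condition."""

    matrix: CountMatrix          # filtered symbiont proteins, fraction samples
    normalized: NormalizedMatrix
    condition: str
    fraction_sample_ids: list


def prepare_condition(matrix: CountMatrix, condition: str,
                      min_count: int = 5,
                      min_samples: int | None = None) -> ConditionData:
    """Subset to symbiont proteins, prevalence-filter over the condition's
    fraction samples, and RLE-normalize those samples."""
    if min_samples is None:
        min_samples = PREVALENCE[condition]["min_samples"]
    sym = matrix.subset_proteins(
        matrix.protein_ids[matrix.proteins["organism"] == "symbiont"])
    frac_ids = sym.select_samples(condition, FRACTIONS)
    filt = filter_by_prevalence(sym, min_count=min_count,
                                min_samples=min_samples, sample_ids=frac_ids)
    norm = normalize_counts(filt, sample_ids=frac_ids)
    return ConditionData(filt, norm, condition, frac_ids)


@dataclass
class CombinedSignificance:
    table: pd.DataFrame          # flags, means, z-scores, trend per protein
    profile_result: ProfileAssignment
    rf_table: pd.DataFrame


def combined_significance(data: ConditionData, n_forests: int = 100,
                          n_trees: int = 500, seed: int = 0,
                          rf_mode: str = "all") -> CombinedSignificance:
    """Both significance arms, their union, and trend labels."""
    samples = data.matrix.samples.loc[data.fraction_sample_ids]
    prof = profile_significant_proteins(data.normalized.normalized, samples,
                                        data.condition)
    rf = rf_significant_proteins(data.normalized.normalized, samples,
                                 data.condition, mode=rf_mode,
                                 n_forests=n_forests, n_trees=n_trees,
                                 seed=seed)
    flags = combine_significance(prof.significant_proteins,
                                 rf.index[rf["selected"]],
                                 data.normalized.normalized.index)
    means = fraction_means(data.normalized.normalized, samples, data.condition)
    table = significance_table(flags, means)
    return CombinedSignificance(table, prof, rf)
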