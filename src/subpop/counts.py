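"""Spectral-count matrices: I/O, prevalence filtering, RLE normalization, NSAF.

Spectral counts are the raw abundance unit of the metaproteome: the number of
peptide-spectrum matches attributed to a protein in one sample.  Two
complementary normalizations are used downstream:

* **RLE (median-of-ratios) normalization** makes one protein comparable
  *across samples*.  Counts are divided by per-sample size factors computed as
  the median ratio of each sample's counts to a per-protein geometric-mean
  reference.  Values are deliberately *not* length-normalized, so a protein's
  trend can be followed across gradient fractions.

* **NSAF / %orgNSAF** make proteins comparable *within one sample*.  The
  spectral abundance factor SAF = count / protein length is renormalized to
  sum to 1 over all proteins of a sample (NSAF), or to 100 over the proteins
  of one organism (%orgNSAF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ORGANISMS = ("host", "symbiont")
SAMPLE_TYPES = ("XS", "S", "M", "L", "Hom")
CONDITIONS = {"Srich": "S-rich", "Sdep": "S-depleted"}
_META_COLS = ("organism", "length_aa", "category")


class CountMatrixError(ValueError):
    """Malformed count table (duplicate ids, negative or fractional counts...)."""


def parse_sample_id(sample_id: str) -> dict:
    """Split a sample id like ``Srich_R1_XS`` into condition/replicate/type."""
    parts = sample_id.split("_")
    if len(parts) != 3 or parts[0] not in CONDITIONS or parts[2] not in SAMPLE_TYPES:
        raise CountMatrixError(f"cannot parse sample id {sample_id!r} "
                               "(expected <Srich|Sdep>_R<k>_<XS|S|M|L|Hom>)")
    return {"condition": CONDITIONS[parts[0]], "replicate": parts[1],
            "sample_type": parts[2]}


def sample_table(sample_ids) -> pd.DataFrame:
    """Sample metadata table (condition, replicate, sample_type) from ids."""
    return pd.DataFrame([parse_sample_id(s) for s in sample_ids],
                        index=pd.Index(sample_ids, name="sample_id"))


@dataclass
class CountMatrix:
    """Integer spectral counts (proteins x samples) with protein metadata.

    ``counts`` is indexed by protein id with one column per sample id;
    ``proteins`` carries organism / length_aa / category per protein;
    ``samples`` carries condition / replicate / sample_type per sample.
    """

    counts: pd.DataFrame
    proteins: pd.DataFrame
    samples: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate protein ids: {dups}")
        if self.counts.columns.has_duplicates:
            raise CountMatrixError("duplicate sample ids")
        if not self.proteins.index.equals(self.counts.index):
            self.proteins = self.proteins.reindex(self.counts.index)
        missing_len = self.proteins.index[self.proteins["length_aa"].isna()]
        if len(missing_len):
            raise CountMatrixError(f"missing length_aa for protein(s) {list(missing_len)}")
        if (self.proteins["length_aa"] < 1).any():
            raise CountMatrixError("length_aa must be >= 1")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.isfinite(vals)) or np.any(vals != np.round(vals)):
                bad = self.counts.index[~np.isfinite(vals).all(axis=1)
                                        | (vals != np.round(vals)).any(axis=1)]
                raise CountMatrixError(f"non-integer counts for protein(s) {list(bad[:5])}")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise CountMatrixError("negative counts")
        if self.samples is None:
            self.samples = sample_table(self.counts.columns)

    @property
    def protein_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_proteins(self, ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[ids], self.proteins.loc[ids],
                           self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)], self.proteins,
                           self.samples.loc[list(sample_ids)])

    def select_samples(self, condition=None, sample_types=None) -> list:
        """Sample ids matching a condition and/or a set of sample types."""
        meta = self.samples
        keep = pd.Series(True, index=meta.index)
        if condition is not None:
            keep &= meta["condition"] == condition
        if sample_types is not None:
            keep &= meta["sample_type"].isin(sample_types)
        return list(meta.index[keep])


def read_counts(path) -> CountMatrix:
    """Read a counts TSV (protein_id, organism, length_aa, category, samples...)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in df.columns:
        raise CountMatrixError("counts table lacks a protein_id column")
    df = df.set_index("protein_id")
    for col in _META_COLS:
        if col not in df.columns:
            raise CountMatrixError(f"counts table lacks the {col} column")
    proteins = df[list(_META_COLS)].copy()
    counts = df.drop(columns=list(_META_COLS))
    return CountMatrix(counts, proteins)


def write_counts(matrix: CountMatrix, path) -> None:
    out = pd.concat([matrix.proteins[list(_META_COLS)], matrix.counts], axis=1)
    out.index.name = "protein_id"
    out.to_csv(path, sep="\t")


def filter_by_prevalence(matrix: CountMatrix, min_count: int = 5,
                         min_samples: int = 4, sample_ids=None) -> CountMatrix:
    """Keep proteins seen with >= min_count counts in >= min_samples samples.

    ``sample_ids`` restricts which samples count toward prevalence (e.g. the
    16 S-rich gradient-fraction samples, excluding homogenate); the returned
    matrix keeps all original samples.
    """
    if min_count < 1 or min_samples < 1:
        raise ValueError("min_count and min_samples must be >= 1")
    cols = list(sample_ids) if sample_ids is not None else list(matrix.sample_ids)
    if min_samples > len(cols):
        raise ValueError(f"min_samples={min_samples} exceeds the {len(cols)} "
                         "samples considered")
    prev = (matrix.counts[cols] >= min_count).sum(axis=1)
    return matrix.subset_proteins(matrix.protein_ids[prev >= min_samples])


def rle_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (RLE) size factors, rescaled to geometric mean 1.

    The reference r_i is the geometric mean of protein i across samples,
    computed over proteins with positive counts in every sample; the raw
    factor of sample j is median_i(y_ij / r_i).
    """
    if counts.shape[1] < 2:
        raise ValueError("RLE needs at least 2 samples")
    y = counts.to_numpy(dtype=float)
    allpos = (y > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no protein has positive counts in every sample; "
                         "apply a prevalence filter or restrict samples first")
    logy = np.log(y[allpos])
    ref = np.exp(logy.mean(axis=1))  # geometric mean per protein
    raw = np.median(y[allpos] / ref[:, None], axis=0)
    factors = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class NormalizedMatrix:
    """RLE-normalized abundances with the factors and library sizes used."""

    normalized: pd.DataFrame
    size_factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self):
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")


def normalize_counts(matrix: CountMatrix, factors: pd.Series | None = None,
                     sample_ids=None) -> NormalizedMatrix:
    """Divide each sample's counts by its RLE size factor."""
    counts = matrix.counts if sample_ids is None else matrix.counts[list(sample_ids)]
    if factors is None:
        factors = rle_factors(counts)
    factors = factors.reindex(counts.columns)
    if factors.isna().any() or (factors <= 0).any():
        raise ValueError("need a positive size factor for every sample")
    return NormalizedMatrix(counts / factors, factors,
                            counts.sum(axis=0).rename("library_size"))


@dataclass
class NsafTable:
    """SAF / NSAF / %orgNSAF per protein and sample (wide tables)."""

    saf: pd.DataFrame
    nsaf: pd.DataFrame
    pct_orgnsaf: pd.DataFrame
    errors: list = field(default_factory=list)


def nsaf_table(matrix: CountMatrix) -> NsafTable:
    """Length-normalized within-sample relative abundances.

    Computed from *unfiltered* counts.  SAF = count / length; NSAF rescales
    SAF to sum to 1 per sample; %orgNSAF rescales within one organism's
    proteins and is reported on a 0-100 scale.  A sample with all-zero counts
    yields NaN columns and an error record rather than an exception.
    """
    saf = matrix.counts.div(matrix.proteins["length_aa"], axis=0)
    totals = saf.sum(axis=0)
    errors = [f"sample {s}: all counts zero, NSAF undefined"
              for s in totals.index[totals == 0]]
    nsaf = saf.div(totals.where(totals > 0), axis=1)
    org = matrix.proteins["organism"]
    org_totals = saf.groupby(org, observed=True).transform("sum")
    pct = 100.0 * saf / org_totals.where(org_totals > 0)
    return NsafTable(saf, nsaf, pct, errors)
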