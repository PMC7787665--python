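"""Quartile-based cell-size classes and representative-fraction selection.

Measured cell objects (longest dimension, um) are filtered to the plausible
cell-size window [2, 20] um, a quartile split is fitted on the unfractionated
homogenate sample (so 25% of homogenate cells fall in each class by
construction), and each density-gradient fraction is profiled for its share
of cells per class.  The fraction with the highest percentage of cells in a
class becomes that class's representative (fractions XS, S, M, L); a fraction
that tops two classes keeps the class where its percentage is higher and the
other class falls back to its runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASS_LABELS = ("XS", "S", "M", "L")
LOWER_UM = 2.0
UPPER_UM = 20.0
#: boundaries fitted in the original study's homogenate samples (um)
REFERENCE_BOUNDARIES = (3.912, 5.314, 6.83275)


class DegenerateInputError(ValueError):
    """Too few distinct sizes (or zero variance) to fit a quartile scheme."""


@dataclass(frozen=True)
class SizeClassScheme:
    """Partition of [2, 20] um into XS [2,q1), S [q1,q2), M [q2,q3), L [q3,20]."""

    q1: float
    q2: float
    q3: float
    lower: float = LOWER_UM
    upper: float = UPPER_UM

    def __post_init__(self):
        bounds = (self.lower, self.q1, self.q2, self.q3, self.upper)
        if not all(a < b for a, b in zip(bounds, bounds[1:])):
            raise DegenerateInputError(
                f"size-class boundaries must be strictly increasing, got {bounds}")

    @classmethod
    def reference(cls) -> "SizeClassScheme":
        return cls(*REFERENCE_BOUNDARIES)

    @classmethod
    def from_homogenate(cls, sizes, interpolation: str = "linear") -> "SizeClassScheme":
        """Fit q1/q2/q3 as the 25/50/75th percentiles of filtered homogenate sizes.

        Uses linear interpolation between order statistics by default
        (numpy's 'linear', the classic type-7 estimator).
        """
        sizes = np.asarray(sizes, dtype=float)
        if len(np.unique(sizes)) < 4 or np.std(sizes) == 0:
            raise DegenerateInputError(
                "need at least 4 distinct sizes with nonzero variance")
        q1, q2, q3 = np.percentile(sizes, [25, 50, 75], method=interpolation)
        return cls(float(q1), float(q2), float(q3))

    @property
    def boundaries(self) -> tuple:
        return (self.lower, self.q1, self.q2, self.q3, self.upper)

    def assign(self, sizes) -> np.ndarray:
        """Class label per size; intervals half-open except L closed at 20."""
        sizes = np.asarray(sizes, dtype=float)
        if ((sizes < self.lower) | (sizes > self.upper)).any():
            raise ValueError("sizes outside the filtered range; run "
                             "filter_objects first")
        idx = np.searchsorted((self.q1, self.q2, self.q3), sizes, side="right")
        return np.asarray(CLASS_LABELS)[idx]


def filter_objects(measurements: pd.DataFrame,
                   size_col: str = "size_um") -> pd.DataFrame:
    """Keep objects with 2 um <= size <= 20 um (sub-2-um objects are mostly
    imaging artifacts); both bounds inclusive, row order preserved."""
    sizes = pd.to_numeric(measurements[size_col], errors="coerce")
    bad = measurements.index[sizes.isna() & measurements[size_col].notna()]
    if len(bad):
        raise ValueError(f"non-numeric size in row(s) {list(bad[:5])}")
    keep = (sizes >= LOWER_UM) & (sizes <= UPPER_UM)
    return measurements.loc[keep.fillna(False)]


def class_percentages(measurements: pd.DataFrame, scheme: SizeClassScheme,
                      size_col: str = "size_um",
                      sample_col: str = "sample_id") -> pd.DataFrame:
    """Per-sample percentage of objects in each size class.

    Returns one row per sample with XS/S/M/L percentages (summing to 100) and
    the object count; a sample with zero objects yields an ``error`` entry
    instead of percentages.
    """
    rows = {}
    for sample, grp in measurements.groupby(sample_col, sort=True):
        n = len(grp)
        if n == 0:
            rows[sample] = {"n": 0, "error": "no objects"}
            continue
        labels = scheme.assign(grp[size_col].to_numpy())
        pct = {c: 100.0 * float((labels == c).sum()) / n for c in CLASS_LABELS}
        rows[sample] = {**pct, "n": n, "error": ""}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = sample_col
    return out


def select_representatives(profiles: pd.DataFrame) -> pd.DataFrame:
    """Choose one gradient fraction per size class by highest class percentage.

    ``profiles``: one row per fraction (index = fraction id, assumed ordered
    top-to-bottom of the gradient), columns XS/S/M/L percentages.  If one
    fraction has the top percentage for two classes it serves the class where
    its percentage is higher (percentage ties go to the earlier class
    XS<S<M<L), and the displaced class takes its next-ranked fraction;
    percentage ties between fractions go to the fraction nearer the gradient
    top (lower row position).  Returns per class the chosen fraction, the
    rank used (1 = that class's top fraction) and the percentage.
    """
    if len(profiles) < len(CLASS_LABELS):
        raise ValueError(f"need at least {len(CLASS_LABELS)} fraction profiles, "
                         f"got {len(profiles)}")
    fractions = list(profiles.index)
    order = {f: i for i, f in enumerate(fractions)}
    # per class: fractions ranked by percentage desc, gradient position asc
    ranking = {c: sorted(fractions, key=lambda f: (-profiles.at[f, c], order[f]))
               for c in CLASS_LABELS}
    assigned: dict = {}
    taken: set = set()
    unresolved = list(CLASS_LABELS)
    while unresolved:
        proposals = {}
        for c in unresolved:
            frac = next(f for f in ranking[c] if f not in taken)
            proposals.setdefault(frac, []).append(c)
        for frac, classes in proposals.items():
            winner = max(classes,
                         key=lambda c: (profiles.at[frac, c],
                                        -CLASS_LABELS.index(c)))
            assigned[winner] = frac
            taken.add(frac)
            unresolved.remove(winner)
    out = pd.DataFrame({
        "fraction": [assigned[c] for c in CLASS_LABELS],
        "rank": [ranking[c].index(assigned[c]) + 1 for c in CLASS_LABELS],
        "percentage": [profiles.at[assigned[c], c] for c in CLASS_LABELS],
    }, index=pd.Index(CLASS_LABELS, name="size_class"))
    return out
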