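"""Flow-cytometry gating and DNA-content quantification.

Events are gated into two populations by axis-aligned rectangles in
(log10 FSC, log10 SSC) space, mirroring manual bivariate dot-plot gating.
Per sample and population the median fluorescence intensity (MFI) of the
DNA stain is computed; with a stoichiometric stain the population-2 over
population-1 MFI ratio estimates the genome-copy (DNA content) fold
difference between larger and smaller cells.  Both the mean of per-sample
fold ratios and the ratio of pooled medians are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml


class GateError(ValueError):
    """Degenerate or overlapping gate rectangles."""


@dataclass(frozen=True)
class Gate:
    """Inclusive rectangle in log10(FSC) x log10(SSC)."""

    fsc_min: float
    fsc_max: float
    ssc_min: float
    ssc_max: float

    def __post_init__(self):
        if not (self.fsc_min < self.fsc_max and self.ssc_min < self.ssc_max):
            raise GateError(f"degenerate gate rectangle {self}")

    def contains(self, log_fsc: np.ndarray, log_ssc: np.ndarray) -> np.ndarray:
        return ((log_fsc >= self.fsc_min) & (log_fsc <= self.fsc_max)
                & (log_ssc >= self.ssc_min) & (log_ssc <= self.ssc_max))

    def overlaps(self, other: "Gate") -> bool:
        # inclusive boundaries: touching rectangles would double-label events
        return (self.fsc_min <= other.fsc_max and other.fsc_min <= self.fsc_max
                and self.ssc_min <= other.ssc_max and other.ssc_min <= self.ssc_max)


@dataclass(frozen=True)
class GateSpec:
    pop1: Gate
    pop2: Gate

    def __post_init__(self):
        if self.pop1.overlaps(self.pop2):
            raise GateError("population gates overlap")


def read_gates(path) -> GateSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return GateSpec(Gate(**raw["pop1"]), Gate(**raw["pop2"]))


def write_gates(gates: GateSpec, path) -> None:
    spec = {pop: {k: float(v) for k, v in vars(g).items()}
            for pop, g in (("pop1", gates.pop1), ("pop2", gates.pop2))}
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh)


def default_gates(config) -> GateSpec:
    """Rectangles centred on the generating medians of a synthetic config,
    split at the log10 midpoint between the two populations."""
    mid_fsc = (np.log10(1e3) + np.log10(1e4)) / 2
    mid_ssc = (np.log10(5e2) + np.log10(5e3)) / 2
    span = 8 * config.flow_log10_sigma
    return GateSpec(
        Gate(np.log10(1e3) - span, mid_fsc - 1e-9,
             np.log10(5e2) - span, mid_ssc - 1e-9),
        Gate(mid_fsc + 1e-9, np.log10(1e4) + span,
             mid_ssc + 1e-9, np.log10(5e3) + span))


def apply_gates(events: pd.DataFrame, gates: GateSpec) -> pd.DataFrame:
    """Label each event population 1, 2, or 0 (ungated); boundaries inclusive."""
    if (events["fsc"] <= 0).any() or (events["ssc"] <= 0).any():
        raise ValueError("FSC and SSC must be positive")
    lf = np.log10(events["fsc"].to_numpy())
    ls = np.log10(events["ssc"].to_numpy())
    pop = np.zeros(len(events), dtype=int)
    pop[gates.pop1.contains(lf, ls)] = 1
    pop[gates.pop2.contains(lf, ls)] = 2
    out = events.copy()
    out["population"] = pop
    return out


def population_mfi(labeled: pd.DataFrame) -> pd.DataFrame:
    """Event count and median FI per sample x population (NaN if empty)."""
    rows = []
    for sample, grp in labeled.groupby("sample_id", sort=True):
        for pop in (1, 2):
            fi = grp.loc[grp["population"] == pop, "fi"]
            rows.append({"sample_id": sample, "population": pop,
                         "n_events": len(fi),
                         "mfi": float(fi.median()) if len(fi) else np.nan})
    return pd.DataFrame(rows)


def dna_fold(stats: pd.DataFrame) -> dict:
    """Population-2 : population-1 MFI fold ratio.

    Per-sample folds are averaged arithmetically (``mean_fold``); the ratio
    of the across-sample mean MFIs is also reported (``pooled_fold``).
    Samples with an empty population or MFI1 = 0 are excluded with a warning.
    """
    wide = stats.pivot(index="sample_id", columns="population", values="mfi")
    valid = wide.notna().all(axis=1) & (wide[1] > 0)
    dropped = wide.index[~valid]
    if len(dropped):
        warnings.warn(f"samples without a defined fold: {list(dropped)}")
    if not valid.any():
        raise ValueError("no sample has both population MFIs defined")
    folds = (wide.loc[valid, 2] / wide.loc[valid, 1])
    return {
        "per_sample": folds.to_dict(),
        "mean_fold": float(folds.mean()),
        "pooled_fold": float(wide.loc[valid, 2].mean() / wide.loc[valid, 1].mean()),
        "n_samples": int(valid.sum()),
    }
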