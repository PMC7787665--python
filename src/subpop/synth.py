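"""Synthetic study-data generator.

Emulates the three data streams of a density-gradient fractionation study of
a single bacterial symbiont population:

* **spectral counts** — negative-binomial counts for symbiont and host
  proteins over four ordered gradient fractions (XS < S < M < L) plus an
  unfractionated homogenate, in two sulfur conditions (4 S-rich and 3
  S-depleted biological replicates), with a planted subset of symbiont
  proteins whose generating mean changes by a constant fold per fraction
  step, and a planted subset of host proteins elevated in the light
  fractions (XS, S) relative to homogenate;

* **cell-size measurements** — per-fraction lognormal longest-dimension
  distributions whose equal-weight pooled mixture is the homogenate sample,
  so that a quartile split fitted on the homogenate calibrates to 25% per
  class by construction;

* **flow-cytometry events** — two lognormal populations in (FSC, SSC, FI)
  whose median fluorescence intensities differ by a configurable fold
  (default 9.7), with hidden population labels for gate validation.

Every generator is a pure function of (config, config.seed): the same config
gives byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .counts import CountMatrix, sample_table

FRACTIONS = ("XS", "S", "M", "L")
_CATEGORIES = ("energy metabolism", "carbon fixation", "stress response",
               "cell division", "membrane transport", "translation",
               "unknown function")


class InvalidConfigError(ValueError):
    """A SynthConfig field violates its constraints."""


@dataclass
class SynthConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    The proteome scale (300 symbiont proteins, 40 of them planted with a
    monotonic trend at fold 2 per fraction step, NB dispersion 0.1) is the
    pinned desk-scale configuration every downstream power/FDR property is
    stated against.
    """

    seed: int = 0
    n_fractions: int = 4
    n_replicates_rich: int = 4
    n_replicates_depleted: int = 3
    n_proteins_symbiont: int = 300
    n_proteins_host: int = 100
    frac_monotonic: float = 40 / 300
    per_step_fold: float = 2.0
    nb_dispersion: float = 0.1
    library_size_cv: float = 0.3
    base_mean_median: float = 20.0      # lognormal median of baseline counts
    base_mean_sigma: float = 1.0
    host_enriched_fraction: float = 0.1
    host_enrichment_factor: float = 5.0
    size_location_per_fraction: tuple = (3.0, 4.6, 6.0, 8.0)  # lognormal medians, um
    size_sigma: float = 0.25
    n_objects_per_fraction: int = 2000
    n_objects_homogenate: int = 8000
    flow_fold: float = 9.7
    flow_events_per_sample: int = 10000
    flow_n_samples: int = 3
    flow_pop2_weight: float = 0.5
    flow_fi_median_pop1: float = 800.0  # rfu
    flow_log10_sigma: float = 0.12

    def __post_init__(self):
        locs = np.asarray(self.size_location_per_fraction, dtype=float)
        if len(locs) != self.n_fractions or not np.all(np.diff(locs) > 0):
            raise InvalidConfigError("size_location_per_fraction must be one "
                                     "strictly increasing median per fraction")
        if self.per_step_fold <= 0:
            raise InvalidConfigError("per_step_fold must be > 0")
        if self.flow_fold <= 0:
            raise InvalidConfigError("flow_fold must be > 0")
        if not 0 <= self.frac_monotonic <= 1:
            raise InvalidConfigError("frac_monotonic must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise InvalidConfigError("nb_dispersion must be >= 0")
        if not 0 <= self.flow_pop2_weight <= 1:
            raise InvalidConfigError("flow_pop2_weight must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator per data stream, derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,)))


def _nb_draw(rng, mean, dispersion):
    """NB with variance mu + dispersion*mu^2; exact Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def _sample_ids(config: SynthConfig):
    ids = []
    for tag, n_rep in (("Srich", config.n_replicates_rich),
                       ("Sdep", config.n_replicates_depleted)):
        for rep in range(1, n_rep + 1):
            for stype in FRACTIONS + ("Hom",):
                ids.append(f"{tag}_R{rep}_{stype}")
    return ids


def simulate_counts(config: SynthConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Spectral-count matrix over all samples plus the ground-truth table.

    Protein i, sample j: count ~ NB(mean = true_mean_i(fraction_j) * M_j,
    dispersion = nb_dispersion) with lognormal library-size multipliers M_j.
    Planted 'up' proteins have their mean multiplied by per_step_fold at every
    fraction step XS->S->M->L ('down' mirrored); the homogenate mean is the
    equal-weight average of the four fraction means.  Planted host-enriched
    proteins are elevated in XS and S only.
    """
    rng = config.rng(0)
    n_sym, n_host = config.n_proteins_symbiont, config.n_proteins_host
    T = config.n_fractions

    ids = [f"SYM{i:04d}" for i in range(1, n_sym + 1)] + \
          [f"HOST{i:04d}" for i in range(1, n_host + 1)]
    organism = np.array(["symbiont"] * n_sym + ["host"] * n_host)
    length_aa = rng.integers(100, 1001, size=n_sym + n_host)
    category = rng.choice(_CATEGORIES, size=n_sym + n_host)
    base = config.base_mean_median * np.exp(
        rng.normal(0.0, config.base_mean_sigma, size=n_sym + n_host))

    trend = np.array(["none"] * (n_sym + n_host), dtype=object)
    n_planted = int(round(config.frac_monotonic * n_sym))
    if config.frac_monotonic > 0 and n_planted < 1:
        warnings.warn("frac_monotonic too small for one protein; planting none")
    if config.per_step_fold != 1.0 and n_planted >= 1:
        planted = rng.choice(n_sym, size=n_planted, replace=False)
        trend[planted[: (n_planted + 1) // 2]] = "up"
        trend[planted[(n_planted + 1) // 2:]] = "down"

    host_enriched = np.zeros(n_sym + n_host, dtype=bool)
    n_henr = int(round(config.host_enriched_fraction * n_host))
    if n_henr >= 1:
        host_enriched[n_sym + rng.choice(n_host, size=n_henr, replace=False)] = True

    # generating means per fraction (and homogenate = equal-weight mixture)
    steps = np.arange(T, dtype=float)
    fold = np.ones((n_sym + n_host, T))
    fold[trend == "up"] = config.per_step_fold ** steps
    fold[trend == "down"] = config.per_step_fold ** (-steps)
    fold[host_enriched, 0:2] = config.host_enrichment_factor
    frac_means = base[:, None] * fold
    hom_means = frac_means.mean(axis=1)
    # host-enriched proteins: homogenate stays at baseline (elevated XS/S only)
    hom_means[host_enriched] = base[host_enriched]

    sample_ids = _sample_ids(config)
    sigma2 = np.log1p(config.library_size_cv ** 2)
    libmult = np.exp(rng.normal(-sigma2 / 2, np.sqrt(sigma2), size=len(sample_ids)))

    counts = np.empty((n_sym + n_host, len(sample_ids)), dtype=np.int64)
    type_col = {st: t for t, st in enumerate(FRACTIONS)}
    for j, sid in enumerate(sample_ids):
        stype = sid.split("_")[2]
        mu = hom_means if stype == "Hom" else frac_means[:, type_col[stype]]
        counts[:, j] = _nb_draw(rng, mu * libmult[j], config.nb_dispersion)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(ids, name="protein_id"),
                     columns=sample_ids),
        pd.DataFrame({"organism": organism, "length_aa": length_aa,
                      "category": category},
                     index=pd.Index(ids, name="protein_id")),
        sample_table(sample_ids))
    truth = pd.DataFrame(
        {"organism": organism, "planted_trend": trend,
         "planted_host_enriched": host_enriched,
         **{f"true_mean_{f}": frac_means[:, t] for t, f in enumerate(FRACTIONS)},
         "true_mean_Hom": hom_means},
        index=pd.Index(ids, name="protein_id"))
    return matrix, truth


def simulate_cell_sizes(config: SynthConfig) -> pd.DataFrame:
    """Cell-object measurement table: per-fraction samples plus a homogenate.

    Sizes are lognormal draws (longest dimension, um).  The homogenate sample
    is the concatenation of equal-size draws from each fraction distribution,
    so the mixture weights are exactly equal.  No truncation is applied here;
    the [2, 20] um filter is the size-class module's job.
    """
    rng = config.rng(1)
    locs = np.asarray(config.size_location_per_fraction, dtype=float)
    rows = []
    for f, loc in enumerate(locs, start=1):
        sizes = np.exp(rng.normal(np.log(loc), config.size_sigma,
                                  size=config.n_objects_per_fraction))
        rows.append(pd.DataFrame({"sample_id": f"frac{f}", "size_um": sizes}))
    per = config.n_objects_homogenate // len(locs)
    hom = np.concatenate([
        np.exp(rng.normal(np.log(loc), config.size_sigma, size=per))
        for loc in locs])
    rows.append(pd.DataFrame({"sample_id": "Hom", "size_um": hom}))
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "object_id", np.arange(1, len(out) + 1))
    return out


def simulate_flow_events(config: SynthConfig) -> pd.DataFrame:
    """Flow-cytometry event table with hidden population labels.

    Population 1 (smaller cells) sits at lower FSC/SSC/FI medians; population
    2 at 10x FSC/SSC and flow_fold x FI.  All three channels are lognormal
    with a common log10 scale sigma.
    """
    rng = config.rng(2)
    med1 = {"fsc": 1.0e3, "ssc": 5.0e2, "fi": config.flow_fi_median_pop1}
    med2 = {"fsc": 1.0e4, "ssc": 5.0e3,
            "fi": config.flow_fold * config.flow_fi_median_pop1}
    frames = []
    for s in range(1, config.flow_n_samples + 1):
        n = config.flow_events_per_sample
        pop = 1 + (rng.random(n) < config.flow_pop2_weight).astype(int)
        cols = {"sample_id": f"FC{s}"}
        for ch in ("fsc", "ssc", "fi"):
            med = np.where(pop == 2, med2[ch], med1[ch])
            cols[ch] = 10 ** rng.normal(np.log10(med), config.flow_log10_sigma)
        cols["true_pop"] = pop
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def write_sizes(sizes: pd.DataFrame, path) -> None:
    sizes.to_csv(path, index=False)


def write_flow(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def config_to_dict(config: SynthConfig) -> dict:
    d = asdict(config)
    d["size_location_per_fraction"] = list(d["size_location_per_fraction"])
    return d
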