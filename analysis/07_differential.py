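#!/usr/bin/env python
"""Exact-test contrasts: (a) S-rich vs S-depleted within each size class,
(b) host proteins enriched in light fractions (XS+S) vs homogenate.
"""

from pathlib import Path

import numpy as np

from subpop.counts import filter_by_prevalence, read_counts, rle_factors
from subpop.exact_test import (enrich_host_proteins, equalize_libraries,
                               estimate_common_dispersion, nb_exact_test)
from subpop.synth import FRACTIONS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "differential"
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_counts(ROOT / "synthetic" / "counts.tsv")

    for size_class in FRACTIONS:
        ids = (matrix.select_samples("S-rich", (size_class,))
               + matrix.select_samples("S-depleted", (size_class,)))
        sub = matrix.subset_samples(ids)
        sub = filter_by_prevalence(sub, min_count=5, min_samples=2)
        factors = rle_factors(sub.counts)
        pseudo = equalize_libraries(sub.counts, factors)
        groups = sub.samples.loc[ids, "condition"].to_numpy()
        phi = estimate_common_dispersion(pseudo, groups)
        res = nb_exact_test(pseudo, groups, phi)
        res.to_csv(out / f"sulfur_{size_class}.tsv", sep="\t")
        print(f"fraction {size_class}: {int(res['significant'].sum())} of "
              f"{len(res)} proteins differ between sulfur conditions "
              f"(common dispersion {phi:.3f})")

    he = enrich_host_proteins(matrix, "S-rich")
    he.to_csv(out / "host_enrichment_srich.tsv", sep="\t")
    print(f"host enrichment (S-rich): {int(he['enriched'].sum())} of "
          f"{len(he)} filtered host proteins enriched in XS+S vs homogenate")


if __name__ == "__main__":
    main()
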