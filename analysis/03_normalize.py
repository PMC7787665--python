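#!/usr/bin/env python
"""Prevalence-filter and RLE-normalize the symbiont counts (per condition) and
compute the within-sample NSAF / %orgNSAF tables from the unfiltered matrix.
"""

from pathlib import Path

from subpop.counts import nsaf_table, read_counts
from subpop.pipeline import prepare_condition

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    matrix = read_counts(ROOT / "synthetic" / "counts.tsv")

    for condition, tag in (("S-rich", "srich"), ("S-depleted", "sdep")):
        data = prepare_condition(matrix, condition)
        data.normalized.normalized.to_csv(out / f"normalized_{tag}.tsv", sep="\t")
        data.normalized.size_factors.to_csv(out / f"size_factors_{tag}.tsv",
                                            sep="\t")
        n_sym = (matrix.proteins["organism"] == "symbiont").sum()
        print(f"{condition}: {len(data.matrix.protein_ids)} of {n_sym} "
              f"symbiont proteins pass the prevalence filter "
              f"(>=5 counts in >= {4 if condition == 'S-rich' else 3} "
              f"of {len(data.fraction_sample_ids)} fraction samples)")

    nsaf = nsaf_table(matrix)
    nsaf.pct_orgnsaf.to_csv(out / "pct_orgnsaf.tsv", sep="\t")
    top = nsaf.pct_orgnsaf.loc[matrix.proteins["organism"] == "symbiont",
                               "Srich_R1_XS"].idxmax()
    print(f"most abundant symbiont protein in Srich_R1_XS: {top} "
          f"({nsaf.pct_orgnsaf.at[top, 'Srich_R1_XS']:.1f} %orgNSAF)")


if __name__ == "__main__":
    main()
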