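#!/usr/bin/env python
"""Fit the quartile size-class scheme on the homogenate, profile each gradient
fraction, and select the representative fraction per class (XS/S/M/L).
"""

from pathlib import Path

import pandas as pd

from subpop.sizeclass import (CLASS_LABELS, SizeClassScheme, class_percentages,
                              filter_objects, select_representatives)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    out = ROOT / "sizeclass"
    out.mkdir(parents=True, exist_ok=True)
    raw = pd.read_csv(ROOT / "synthetic" / "sizes.csv")
    meas = filter_objects(raw)
    print(f"filtered {len(raw) - len(meas)} of {len(raw)} objects outside "
          "[2, 20] um")

    hom = meas.loc[meas["sample_id"] == "Hom", "size_um"]
    scheme = SizeClassScheme.from_homogenate(hom)
    print(f"quartile boundaries (um): {scheme.q1:.3f} / {scheme.q2:.3f} / "
          f"{scheme.q3:.3f}")

    profiles = class_percentages(meas, scheme)
    profiles.to_csv(out / "class_percentages.tsv", sep="\t")
    reps = select_representatives(
        profiles.loc[profiles.index != "Hom", list(CLASS_LABELS)])
    reps.to_csv(out / "representatives.tsv", sep="\t")
    pd.DataFrame([{"q1": scheme.q1, "q2": scheme.q2, "q3": scheme.q3}]) \
        .to_csv(out / "scheme.tsv", sep="\t", index=False)
    print(reps)


if __name__ == "__main__":
    main()
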