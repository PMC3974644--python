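#!/usr/bin/env python
"""Descriptor comparison between the allosteric and background sets.

Reports per-descriptor mean (SD) for both sets with display scaling, and
prints the headline physicochemical contrasts (rigidity, aromaticity,
size, lipophilicity).
"""

from pathlib import Path

import pandas as pd

from allokit.pipeline import descriptor_comparison

OUT = Path("results/analysis")


def main():
    desc = pd.read_csv(OUT / "descriptors.tsv", sep="\t")
    sets = {}
    for label in ("allosteric", "non_allosteric_balanced"):
        ids = set(pd.read_csv(OUT / f"dataset_{label}.tsv",
                              sep="\t")["compound_id"])
        sets[label] = desc[desc["compound_id"].isin(ids)]
    table = descriptor_comparison(sets["allosteric"],
                                  sets["non_allosteric_balanced"])
    table.to_csv(OUT / "descriptor_comparison.tsv", sep="\t", index=False)

    t = table.set_index("descriptor")
    for name in ("rigidity_index", "aromatic_bond_frac", "sp2_carbon_frac",
                 "mw", "logp"):
        print(f"{name}: allosteric {t.loc[name, 'allosteric_mean']:.3g} "
              f"vs background {t.loc[name, 'background_mean']:.3g}")
    more_rigid = (t.loc["rigidity_index", "allosteric_mean"]
                  > t.loc["rigidity_index", "background_mean"])
    print("allosteric set more rigid:", more_rigid)


if __name__ == "__main__":
    main()
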