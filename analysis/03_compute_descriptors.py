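#!/usr/bin/env python
"""Standardize structures and compute the descriptor panel.

Salt-strips and pH-7.4-protonates every compound used by the allosteric
or balanced background set, then computes the physicochemical panel
(size, lipophilicity, polarity, atom/bond fractions, rigidity index,
Lipinski pass) and writes descriptors.tsv.
"""

from pathlib import Path

import pandas as pd

from allokit.pipeline import describe_compounds
from allokit.synthetic import SyntheticCorpus

OUT = Path("results/analysis")


def main():
    corpus = SyntheticCorpus.read(OUT / "corpus")
    used = set()
    for label in ("allosteric", "non_allosteric_balanced"):
        ds = pd.read_csv(OUT / f"dataset_{label}.tsv", sep="\t")
        used |= set(ds["compound_id"])
    desc = describe_compounds(
        corpus.compounds[corpus.compounds["compound_id"].isin(used)])
    desc.to_csv(OUT / "descriptors.tsv", sep="\t", index=False)
    print(f"descriptors for {len(desc)} compounds "
          f"({desc.shape[1] - 1} columns)")
    print(f"Lipinski pass rate: {desc['lipinski_pass'].mean():.0%}")


if __name__ == "__main__":
    main()
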