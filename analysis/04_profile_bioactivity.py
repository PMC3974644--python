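#!/usr/bin/env python
"""Bioactivity profile: potency, efficiency indices, promiscuity.

Summarizes each set by median (MAD): pActivity, the efficiency-index
panel (LE, BEI, SEI, NBEI, NSEI, nBEI, mBEI), per-compound target counts,
and the active/inactive/other split at the 6-log-unit cutoff.
"""

from pathlib import Path

import pandas as pd

from allokit.mining import DataSet
from allokit.pipeline import profile_dataset

OUT = Path("results/analysis")


def main():
    desc = pd.read_csv(OUT / "descriptors.tsv", sep="\t")
    profiles = {}
    for label in ("allosteric", "non_allosteric_balanced"):
        rec = pd.read_csv(OUT / f"dataset_{label}.tsv", sep="\t")
        ds = DataSet(label, rec)
        prof = profile_dataset(ds, desc)
        prof.to_csv(OUT / f"bioactivity_profile_{label}.tsv", sep="\t",
                    index=False)
        profiles[label] = prof.set_index("metric")

    a = profiles["allosteric"]
    b = profiles["non_allosteric_balanced"]
    print("median pActivity (MAD): "
          f"allosteric {a.loc['Activity', 'median']:.2f} "
          f"(±{a.loc['Activity', 'mad']:.2f}) vs background "
          f"{b.loc['Activity', 'median']:.2f} "
          f"(±{b.loc['Activity', 'mad']:.2f})")
    print(f"active fraction: allosteric {a.loc['Active (%)', 'median']:.0f}% "
          f"vs background {b.loc['Active (%)', 'median']:.0f}%")
    print("efficiency indices (allosteric median): "
          + ", ".join(f"{k} {a.loc[k, 'median']:.3g}"
                      for k in ("LE", "BEI", "SEI", "NSEI")))


if __name__ == "__main__":
    main()
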