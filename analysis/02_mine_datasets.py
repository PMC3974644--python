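#!/usr/bin/env python
"""Partition the corpus and assemble the three data sets.

Keyword search over titles/abstracts splits documents into allosteric and
background; each document is reduced to its primary target, duplicate
(compound, target) measurements collapse by quality, and the balanced
background is drawn per L2 class capped at the allosteric class sizes.
Writes the dataset tables and a composition summary for each set.
"""

import json
from pathlib import Path

from allokit.mining import (assemble_set, balance_background,
                            class_distribution, classify_documents,
                            composition_summary)
from allokit.synthetic import DEFAULT_KEYWORDS, SyntheticCorpus

OUT = Path("results/analysis")


def main():
    corpus = SyntheticCorpus.read(OUT / "corpus")
    allo_docs, bg_docs = classify_documents(corpus.documents,
                                            DEFAULT_KEYWORDS)
    print(f"keyword partition: {len(allo_docs)} allosteric documents, "
          f"{len(bg_docs)} background")

    allo = assemble_set(allo_docs, corpus.activities, corpus.targets,
                        label="allosteric")
    bg_full = assemble_set(bg_docs, corpus.activities, corpus.targets,
                           label="non_allosteric_full")
    bg_bal = balance_background(bg_full, allo, seed=42)

    reports = {}
    for ds in (allo, bg_full, bg_bal):
        ds.records.to_csv(OUT / f"dataset_{ds.label}.tsv", sep="\t",
                          index=False)
        reports[ds.label] = composition_summary(ds, corpus.documents,
                                                corpus.compounds)
        class_distribution(ds, "L2").to_csv(
            OUT / f"l2_distribution_{ds.label}.tsv", sep="\t", index=False)
        print(f"{ds.label}: {len(ds.records)} records, "
              f"{reports[ds.label]['n_targets']} targets, "
              f"{reports[ds.label]['n_compounds']} compounds")
    with open(OUT / "composition.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    print("balanced background capped at allosteric per-L2 counts:",
          len(bg_bal.records) <= len(allo.records))


if __name__ == "__main__":
    main()
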