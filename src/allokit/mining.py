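"""Corpus partitioning, dataset assembly and background balancing.

The mining stage turns a document/activity corpus into analysis-ready
sets: documents are split into allosteric and background partitions by
case-insensitive whole-word keyword search over titles and abstracts;
within each document only the primary target (the target with the most
bioactivity annotations) is kept; duplicate (compound, target) records
are collapsed preferring higher-quality measurement types (Ki/Kd over
IC50/EC50 over other numeric over comment-only); and a balanced
background set is drawn per L2 target class, capped at the allosteric
set's per-class record counts.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioactivity import normalize_table

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_QUALITY_ORDER",
    "DataSet",
    "classify_documents",
    "select_primary_target",
    "assemble_set",
    "balance_background",
    "composition_summary",
    "class_distribution",
]

#: Measurement-quality tiers, best first (lower tier index wins).
DEFAULT_QUALITY_ORDER = ["Ki", "Kd", "IC50", "EC50", "other-numeric",
                         "comment-only"]
_TIER = {"Ki": 0, "Kd": 0, "IC50": 1, "EC50": 1, "other-numeric": 2,
         "comment-only": 3}


@dataclass
class DataSet:
    label: str  # allosteric | non_allosteric_full | non_allosteric_balanced
    records: pd.DataFrame  # activities joined to target class path


def classify_documents(documents: pd.DataFrame, keywords: list
                       ) -> tuple[list, list]:
    """Split doc_ids into (allosteric, background) by keyword search.

    A document is allosteric iff at least one keyword matches its title
    or abstract case-insensitively at word boundaries; multi-word
    keywords are matched as phrases.  Documents missing both title and
    abstract go to the background with a logged warning.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    pattern = re.compile(
        r"\b(?:" + "|".join(re.escape(k) for k in sorted(keywords)) + r")\b",
        re.IGNORECASE,
    )
    allosteric, background = [], []
    for row in documents.itertuples(index=False):
        title = "" if pd.isna(row.title) else str(row.title)
        abstract = "" if pd.isna(row.abstract) else str(row.abstract)
        if not title and not abstract:
            logger.warning("document %s has neither title nor abstract; "
                           "assigned to background", row.doc_id)
            background.append(row.doc_id)
        elif pattern.search(title) or pattern.search(abstract):
            allosteric.append(row.doc_id)
        else:
            background.append(row.doc_id)
    return allosteric, background


def select_primary_target(doc_records: pd.DataFrame) -> str:
    """Target with the most records in one document; ties break to the
    lexicographically smallest target_id."""
    if len(doc_records) == 0:
        raise ValueError("cannot select a primary target from zero records")
    counts = doc_records.groupby("target_id").size()
    best = counts.max()
    return sorted(counts[counts == best].index)[0]


def assemble_set(doc_ids, activities: pd.DataFrame, targets: pd.DataFrame,
                 label: str = "dataset",
                 quality_order: list | None = None) -> DataSet:
    """Primary-target records for the given documents, deduplicated.

    One record survives per (compound_id, target_id): the highest quality
    tier wins, then the larger pActivity within the tier, then the
    first-seen activity_id.  Qualified (>/<) records stay in the set but
    carry no pActivity and classify as "other" downstream.
    """
    if quality_order is None:
        # default tiers: Ki=Kd > IC50=EC50 > other-numeric > comment-only
        tier = dict(_TIER)
    else:
        tier = {t: i for i, t in enumerate(quality_order)}
    doc_ids = set(doc_ids)
    sub = activities[activities["doc_id"].isin(doc_ids)].copy()

    # primary target per document
    keep_frames = []
    for doc_id, grp in sub.groupby("doc_id", sort=True):
        primary = select_primary_target(grp)
        keep_frames.append(grp[grp["target_id"] == primary])
    if keep_frames:
        kept = pd.concat(keep_frames, ignore_index=True)
    else:
        kept = sub.iloc[0:0].copy()

    kept = normalize_table(kept)
    kept["_tier"] = kept["standard_type"].map(
        lambda t: tier.get(t, len(tier)))
    kept["_p"] = kept["pactivity"].fillna(-np.inf)
    kept = kept.sort_values(["compound_id", "target_id", "_tier", "_p",
                             "activity_id"],
                            ascending=[True, True, True, False, True],
                            kind="mergesort")
    kept = kept.drop_duplicates(["compound_id", "target_id"], keep="first")
    kept = kept.drop(columns=["_tier", "_p"]).reset_index(drop=True)

    kept = kept.merge(targets[["target_id", "l1", "l2"]], on="target_id",
                      how="left")
    for col in ("l1", "l2"):
        kept[col] = kept[col].fillna("Undefined").replace("", "Undefined")
    return DataSet(label=label, records=kept)


def balance_background(full_background: DataSet, allosteric: DataSet,
                       seed: int) -> DataSet:
    """Per-L2-class subsample of the background, capped at the allosteric
    set's class sizes; seeded and reproducible."""
    rng = np.random.default_rng(seed)
    allo_counts = allosteric.records.groupby("l2").size()
    frames = []
    bg = full_background.records
    for l2 in sorted(allo_counts.index):
        pool = bg[bg["l2"] == l2]
        n = min(int(allo_counts[l2]), len(pool))
        if n > 0:
            idx = rng.choice(len(pool), size=n, replace=False)
            frames.append(pool.iloc[np.sort(idx)])
    records = (pd.concat(frames, ignore_index=True) if frames
               else bg.iloc[0:0].copy())
    return DataSet(label="non_allosteric_balanced", records=records)


def composition_summary(dataset: DataSet, documents: pd.DataFrame,
                        compounds: pd.DataFrame) -> dict:
    """Composition report: document/datapoint/assay/target/compound counts
    with assay-type and molecule-type percentages."""
    rec = dataset.records
    if len(rec) == 0:
        return {"label": dataset.label, "n_documents": 0, "n_datapoints": 0,
                "assay_type_pct": {}, "n_targets": 0, "n_l1_classes": 0,
                "n_l2_classes": 0, "n_compounds": 0, "molecule_type_pct": {},
                "year_range": (None, None)}
    doc_ids = rec["doc_id"].unique()
    years = documents.set_index("doc_id").loc[doc_ids, "year"]
    assay_pct = (rec["assay_type"].value_counts(normalize=True) * 100).round(1)
    cmp_ids = rec["compound_id"].unique()
    mol_types = compounds.set_index("compound_id").loc[cmp_ids,
                                                       "molecule_type"]
    mol_pct = (mol_types.value_counts(normalize=True) * 100).round(1)
    return {
        "label": dataset.label,
        "n_documents": int(len(doc_ids)),
        "n_datapoints": int(len(rec)),
        "assay_type_pct": assay_pct.to_dict(),
        "n_targets": int(rec["target_id"].nunique()),
        "n_l1_classes": int(rec["l1"].nunique()),
        "n_l2_classes": int(rec["l2"].nunique()),
        "n_compounds": int(len(cmp_ids)),
        "molecule_type_pct": mol_pct.to_dict(),
        "year_range": (int(years.min()), int(years.max())),
    }


def class_distribution(dataset: DataSet, level: str = "L2") -> pd.DataFrame:
    """Record count and fraction per target class at level L1 or L2."""
    col = level.lower()
    if col not in ("l1", "l2"):
        raise ValueError("level must be 'L1' or 'L2'")
    rec = dataset.records
    counts = (rec[col].fillna("Undefined").replace("", "Undefined")
              .value_counts().sort_index())
    out = counts.rename("n_records").to_frame().reset_index(names="class")
    out["fraction"] = out["n_records"] / out["n_records"].sum()
    return out.sort_values("n_records", ascending=False,
                           kind="mergesort").reset_index(drop=True)
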