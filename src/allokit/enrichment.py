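"""Substructure enrichment by normalized-rank quotients.

Circular-fingerprint feature counts are totalled per set
(occurrence-weighted), normalized to frequencies summing to 1 within each
set, and ranked (rank 1 = most frequent, average ranks on ties,
normalized by the number of features in the set).  The enrichment score
of a feature present in both a focal set and the background is

    score = log10(normalized background rank / normalized focal rank)

so positive scores mark features enriched in the focal set.  Features
absent from either input are excluded from scoring and reported in a
side list.
"""

from __future__ import annotations

import math

import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "substructure_frequencies",
    "rank_normalized",
    "enrichment_scores",
    "enrichment_table",
]


def substructure_frequencies(fingerprints_by_set: dict) -> dict:
    """Occurrence-weighted feature counts and normalized frequencies per set.

    ``fingerprints_by_set`` maps set name -> {compound_id: {feature: count}}.
    Returns {set name: DataFrame(feature_id, count, frequency)}.
    """
    out = {}
    for name, fps in fingerprints_by_set.items():
        if not fps:
            raise ValueError(f"set {name!r} is empty")
        counts: dict[int, int] = {}
        for fp in fps.values():
            for feat, c in fp.items():
                counts[feat] = counts.get(feat, 0) + c
        total = sum(counts.values())
        df = pd.DataFrame(
            {"feature_id": sorted(counts),
             "count": [counts[f] for f in sorted(counts)]})
        df["frequency"] = df["count"] / total
        out[name] = df
    return out


def rank_normalized(freq_table: pd.DataFrame) -> pd.Series:
    """feature_id -> normalized rank; rank 1 = most frequent, average-rank
    ties, divided by the number of features (so values lie in (0, 1])."""
    if len(freq_table) == 0:
        raise ValueError("cannot rank an empty frequency table")
    ranks = rankdata(-freq_table["frequency"].to_numpy(), method="average")
    return pd.Series(ranks / len(freq_table),
                     index=freq_table["feature_id"].to_numpy(),
                     name="normalized_rank")


def enrichment_scores(set_ranks: pd.Series, background_ranks: pd.Series
                      ) -> tuple[pd.DataFrame, list]:
    """Score features present in both inputs; also return the absent list.

    Returns (table sorted descending by score with a final rank column,
    features present in the background but absent from the set).
    """
    common = [f for f in set_ranks.index if f in background_ranks.index]
    absent = [f for f in background_ranks.index if f not in set_ranks.index]
    rows = [
        {"feature_id": f,
         "set_rank": set_ranks[f],
         "background_rank": background_ranks[f],
         "score": math.log10(background_ranks[f] / set_ranks[f])}
        for f in common
    ]
    table = pd.DataFrame(rows, columns=["feature_id", "set_rank",
                                        "background_rank", "score"])
    table = table.sort_values(["score", "feature_id"],
                              ascending=[False, True],
                              kind="mergesort").reset_index(drop=True)
    table["final_rank"] = range(1, len(table) + 1)
    return table, absent


def enrichment_table(allosteric_fps: dict, background_fps: dict
                     ) -> dict:
    """End-to-end enrichment for a two-set corpus.

    The background frequency pool is the union of both sets' occurrence
    counts.  Returns {"allosteric": table, "non_allosteric": table,
    "absent": {...}}.
    """
    merged: dict = {}
    for cid, fp in {**background_fps, **allosteric_fps}.items():
        merged[cid] = fp
    freqs = substructure_frequencies({
        "allosteric": allosteric_fps,
        "non_allosteric": background_fps,
        "background": merged,
    })
    ranks = {name: rank_normalized(tbl) for name, tbl in freqs.items()}
    allo_tbl, allo_absent = enrichment_scores(ranks["allosteric"],
                                              ranks["background"])
    non_tbl, non_absent = enrichment_scores(ranks["non_allosteric"],
                                            ranks["background"])
    return {"allosteric": allo_tbl, "non_allosteric": non_tbl,
            "absent": {"allosteric": allo_absent,
                       "non_allosteric": non_absent},
            "frequencies": freqs}
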