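"""Keyword partition, primary-target selection, deduplication, balancing."""

import numpy as np
import pandas as pd
import pytest

from allokit.mining import (DataSet, assemble_set, balance_background,
                            class_distribution, classify_documents,
                            composition_summary, select_primary_target)


def docs(*rows):
    return pd.DataFrame(rows, columns=["doc_id", "year", "title", "abstract"])


class TestClassifyDocuments:
    def test_keyword_in_abstract(self):
        d = docs(("D1", 2001, "study", "a positive allosteric modulator"),
                 ("D2", 2002, "kinase inhibitors", "crystallographic study"))
        allo, bg = classify_documents(d, ["allosteric"])
        assert allo == ["D1"] and bg == ["D2"]

    def test_title_only_match(self):
        d = docs(("D1", 2001, "Allosterism in GPCRs", ""))
        allo, _ = classify_documents(d, ["allosterism"])
        assert allo == ["D1"]

    def test_word_boundary_no_substring_match(self):
        d = docs(("D1", 2001, "t", "allosterically modulated"))
        allo, bg = classify_documents(d, ["allosteric"])
        assert allo == [] and bg == ["D1"]  # inflection needs its own entry

    def test_phrase_keywords_match_as_phrases(self):
        d = docs(("D1", 2001, "t", "a negative allosteric modulator site"),
                 ("D2", 2001, "t", "negative results for the modulator"))
        allo, bg = classify_documents(d, ["negative allosteric modulator"])
        assert allo == ["D1"] and bg == ["D2"]

    def test_case_insensitive(self):
        d = docs(("D1", 2001, "ALLOSTERIC binding", ""))
        allo, _ = classify_documents(d, ["allosteric"])
        assert allo == ["D1"]

    def test_missing_text_goes_to_background(self):
        d = docs(("D1", 2001, None, None))
        allo, bg = classify_documents(d, ["allosteric"])
        assert bg == ["D1"]

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            classify_documents(docs(("D1", 2001, "t", "a")), [])


class TestPrimaryTarget:
    def test_majority_and_tie_break(self):
        df = pd.DataFrame({"target_id": ["T1"] * 5 + ["T2"] * 3})
        assert select_primary_target(df) == "T1"
        tie = pd.DataFrame({"target_id": ["T2"] * 4 + ["T1"] * 4})
        assert select_primary_target(tie) == "T1"
        single = pd.DataFrame({"target_id": ["T9"]})
        assert select_primary_target(single) == "T9"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_primary_target(pd.DataFrame({"target_id": []}))


class TestAssembleSet:
    def test_quality_preference_ki_over_ic50(self, toy_activities,
                                             toy_targets):
        ds = assemble_set(["D1"], toy_activities, toy_targets)
        c1 = ds.records[ds.records["compound_id"] == "C1"]
        assert list(c1["standard_type"]) == ["Ki"]

    def test_within_tier_higher_potency_wins(self, toy_activities,
                                             toy_targets):
        ds = assemble_set(["D1"], toy_activities, toy_targets)
        c2 = ds.records[ds.records["compound_id"] == "C2"]
        assert c2["pactivity"].iloc[0] == pytest.approx(8.0)  # 10 nM record

    def test_decoy_target_records_excluded(self, toy_activities,
                                           toy_targets):
        ds = assemble_set(["D1"], toy_activities, toy_targets)
        assert "T2" not in set(ds.records["target_id"])

    def test_one_record_per_compound_target(self, study_corpus, study_sets):
        rec = study_sets["allosteric"].records
        assert not rec.duplicated(["compound_id", "target_id"]).any()

    def test_idempotent(self, toy_activities, toy_targets):
        once = assemble_set(["D1"], toy_activities, toy_targets)
        again = assemble_set(["D1"], once.records[toy_activities.columns],
                             toy_targets)
        pd.testing.assert_frame_equal(
            once.records.reset_index(drop=True),
            again.records.reset_index(drop=True))


class TestBalanceBackground:
    def _sets(self, allo_l2, bg_l2):
        def ds(label, l2s):
            n = len(l2s)
            return DataSet(label, pd.DataFrame({
                "activity_id": [f"{label}{i}" for i in range(n)],
                "compound_id": [f"c{label}{i}" for i in range(n)],
                "target_id": "T", "doc_id": "D", "l1": "x", "l2": l2s}))
        return ds("allo", allo_l2), ds("bg", bg_l2)

    def test_sampling_caps(self):
        allo, bg = self._sets(["7TM1"] * 100 + ["LGIC"] * 50,
                              ["7TM1"] * 1000 + ["LGIC"] * 30
                              + ["Protease"] * 99)
        out = balance_background(bg, allo, seed=0)
        counts = out.records["l2"].value_counts()
        assert counts["7TM1"] == 100
        assert counts["LGIC"] == 30  # capped at availability
        assert "Protease" not in counts  # absent from allosteric set

    def test_seed_reproducibility(self):
        allo, bg = self._sets(["7TM1"] * 10, ["7TM1"] * 100)
        a = balance_background(bg, allo, seed=1).records
        b = balance_background(bg, allo, seed=1).records
        c = balance_background(bg, allo, seed=2).records
        pd.testing.assert_frame_equal(a, b)
        assert not a["activity_id"].equals(c["activity_id"])
        assert len(a) == len(c)  # per-class counts seed-invariant

    def test_never_exceeds_allosteric_counts(self, study_sets):
        allo_counts = study_sets["allosteric"].records.groupby("l2").size()
        bal_counts = study_sets["background_balanced"].records.groupby(
            "l2").size()
        for l2, n in bal_counts.items():
            assert n <= allo_counts[l2]
        assert len(study_sets["background_balanced"].records) <= \
            len(study_sets["allosteric"].records)


class TestReports:
    def test_composition_percentages(self, toy_targets):
        act = pd.DataFrame({
            "activity_id": [f"A{i}" for i in range(20)],
            "doc_id": "D1", "target_id": "T1",
            "compound_id": [f"C{i}" for i in range(20)],
            "assay_type": ["binding"] * 10 + ["functional"] * 10,
            "standard_type": "Ki", "standard_value": 10.0,
            "standard_units": "nM", "qualifier": "=", "activity_comment": "",
        })
        documents = pd.DataFrame({"doc_id": ["D1"], "year": [2005],
                                  "title": "t", "abstract": "a"})
        compounds = pd.DataFrame({
            "compound_id": [f"C{i}" for i in range(20)],
            "smiles": "CCO",
            "molecule_type": ["small molecule"] * 19 + ["biological"]})
        ds = assemble_set(["D1"], act, toy_targets)
        report = composition_summary(ds, documents, compounds)
        assert report["assay_type_pct"]["binding"] == pytest.approx(50.0)
        assert report["molecule_type_pct"]["small molecule"] == \
            pytest.approx(95.0)
        assert report["year_range"] == (2005, 2005)

    def test_composition_matches_brute_recount(self, study_corpus,
                                               study_sets):
        ds = study_sets["allosteric"]
        report = composition_summary(ds, study_corpus.documents,
                                     study_corpus.compounds)
        assert report["n_datapoints"] == len(ds.records)
        assert report["n_documents"] == ds.records["doc_id"].nunique()
        assert report["n_targets"] == ds.records["target_id"].nunique()
        assert sum(report["assay_type_pct"].values()) == pytest.approx(
            100.0, abs=1.0)

    def test_class_distribution_fractions(self):
        ds = DataSet("x", pd.DataFrame({
            "l1": ["A"] * 4, "l2": ["7TM1", "7TM1", "7TM1", "Kinase"]}))
        out = class_distribution(ds, "L2")
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out.iloc[0]["class"] == "7TM1"
        assert out.iloc[0]["fraction"] == pytest.approx(0.75)

    def test_missing_l2_counted_as_undefined(self):
        ds = DataSet("x", pd.DataFrame({"l1": ["A"], "l2": [""]}))
        out = class_distribution(ds, "L2")
        assert list(out["class"]) == ["Undefined"]
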