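import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from allokit.mining import assemble_set, balance_background, classify_documents
from allokit.pipeline import describe_compounds
from allokit.synthetic import GeneratorConfig, generate_corpus

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_corpus():
    """Small seeded corpus for structural tests (fast)."""
    return generate_corpus(GeneratorConfig(seed=11, n_documents=60))


@pytest.fixture(scope="session")
def study_corpus():
    """Default-condition corpus, large enough for recovery checks
    (>=2,000 activities)."""
    return generate_corpus(GeneratorConfig(seed=11, n_documents=300))


@pytest.fixture(scope="session")
def study_sets(study_corpus):
    """Mined allosteric set, balanced background, and descriptor table."""
    corpus = study_corpus
    allo_docs, bg_docs = classify_documents(
        corpus.documents, GeneratorConfig().keyword_list)
    allo = assemble_set(allo_docs, corpus.activities, corpus.targets,
                        label="allosteric")
    bg_full = assemble_set(bg_docs, corpus.activities, corpus.targets,
                           label="non_allosteric_full")
    bg_bal = balance_background(bg_full, allo, seed=3)
    used = set(allo.records["compound_id"]) | set(
        bg_bal.records["compound_id"])
    desc = describe_compounds(
        corpus.compounds[corpus.compounds["compound_id"].isin(used)])
    return {"allosteric": allo, "background_full": bg_full,
            "background_balanced": bg_bal, "descriptors": desc}


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def toy_activities():
    """Hand-written activity records exercising every quality tier."""
    return pd.DataFrame([
        # compound C1 on T1: Ki and IC50 at the same concentration
        dict(activity_id="A1", doc_id="D1", target_id="T1",
             compound_id="C1", assay_type="binding", standard_type="Ki",
             standard_value=10.0, standard_units="nM", qualifier="=",
             activity_comment=""),
        dict(activity_id="A2", doc_id="D1", target_id="T1",
             compound_id="C1", assay_type="binding", standard_type="IC50",
             standard_value=10.0, standard_units="nM", qualifier="=",
             activity_comment=""),
        # compound C2 on T1: two Ki values, 1 uM and 10 nM
        dict(activity_id="A3", doc_id="D1", target_id="T1",
             compound_id="C2", assay_type="binding", standard_type="Ki",
             standard_value=1.0, standard_units="uM", qualifier="=",
             activity_comment=""),
        dict(activity_id="A4", doc_id="D1", target_id="T1",
             compound_id="C2", assay_type="binding", standard_type="Ki",
             standard_value=10.0, standard_units="nM", qualifier="=",
             activity_comment=""),
        # decoy-target record in a T1-primary document
        dict(activity_id="A5", doc_id="D1", target_id="T2",
             compound_id="C3", assay_type="functional",
             standard_type="EC50", standard_value=50.0,
             standard_units="nM", qualifier="=", activity_comment=""),
        # comment-only record
        dict(activity_id="A6", doc_id="D1", target_id="T1",
             compound_id="C4", assay_type="binding",
             standard_type="comment-only", standard_value=np.nan,
             standard_units="", qualifier="=", activity_comment="active"),
    ])


@pytest.fixture()
def toy_targets():
    return pd.DataFrame([
        dict(target_id="T1", accession="P00001", l1="Enzyme", l2="Kinase"),
        dict(target_id="T2", accession="P00002", l1="Enzyme", l2="Protease"),
    ])
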