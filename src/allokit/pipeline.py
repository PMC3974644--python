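"""End-to-end orchestration: simulate -> mine -> describe -> profile ->
enrich -> model -> report.

Every stage writes its tables (plain TSV, stable column order) before the
next stage starts; a run manifest records the config snapshot, per-stage
row counts and output hashes so that reruns under identical seeds can be
verified to be byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioactivity, classify, enrichment, fingerprints, mining
from .descriptors import DescriptorVector, compute_descriptors, standardize
from .synthetic import GeneratorConfig, SyntheticCorpus, generate_corpus

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "describe_compounds",
    "profile_dataset",
    "descriptor_comparison",
    "feature_matrix",
]


class PipelineError(RuntimeError):
    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    input_dir: str | None = None  # pre-existing corpus tables; else simulate
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    keywords: list | None = None  # defaults to the generator's list
    activity_threshold: float = bioactivity.ACTIVITY_THRESHOLD
    tanimoto_threshold: float = 0.6
    train_fraction: float = 0.7
    n_trees: int = 500
    seed: int = 0
    ternary: bool = False  # add the allosteric-biological third class

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw:
            gen = raw.pop("generator")
            if "compounds_per_document" in gen:
                gen["compounds_per_document"] = tuple(
                    gen["compounds_per_document"])
            raw["generator"] = GeneratorConfig(**gen)
        return cls(**raw)


def describe_compounds(compounds: pd.DataFrame) -> pd.DataFrame:
    """Standardize every compound and compute the descriptor panel.

    Unparseable structures are dropped with a logged count.  Returns one
    row per compound, stable column order.
    """
    rows, failed = [], 0
    for rec in compounds.itertuples(index=False):
        try:
            mol = standardize(rec.smiles, rec.compound_id)
        except Exception:
            failed += 1
            continue
        vec = compute_descriptors(mol, molecule_class=rec.molecule_type)
        row = {"compound_id": rec.compound_id}
        row.update(vec.as_dict())
        rows.append(row)
    if failed:
        logger.warning("descriptor stage dropped %d unparseable compounds",
                       failed)
    cols = ["compound_id"] + [f for f in DescriptorVector.numeric_fields()] \
        + ["molecule_class"]
    return pd.DataFrame(rows, columns=cols)


def profile_dataset(dataset: mining.DataSet, descriptors: pd.DataFrame
                    ) -> pd.DataFrame:
    """Table-2-style median (MAD) panel: pActivity, efficiency indices,
    promiscuity counts and activity-class percentages for one set."""
    rec = dataset.records.merge(descriptors, on="compound_id", how="inner")
    values: dict[str, list] = {k: [] for k in
                               ["Activity", "LE", "BEI", "SEI", "NBEI",
                                "NSEI", "nBEI", "mBEI"]}
    for row in rec.itertuples(index=False):
        p = row.pactivity
        if p is None or not np.isfinite(p):
            continue
        values["Activity"].append(p)
        npol = round((row.nitrogen_frac + row.oxygen_frac)
                     * _total_atoms(row))
        idx = bioactivity.efficiency_indices(
            p, int(row.heavy_atoms), float(row.mw), float(row.psa),
            int(npol))
        for key, val in idx.as_dict().items():
            if val is not None:
                values[key].append(val)

    prom = [bioactivity.promiscuity(g)
            for _, g in rec.groupby("compound_id", sort=True)]
    values["Targets Annotated"] = [p.targets_annotated for p in prom]
    values["Targets Active"] = [p.targets_active for p in prom]
    values["Targets Inactive"] = [p.targets_inactive for p in prom]
    values["Targets Other"] = [p.targets_other for p in prom]

    rows = []
    for metric, vals in values.items():
        if vals:
            med, mad = bioactivity.median_mad(vals)
            rows.append({"metric": metric, "median": med, "mad": mad,
                         "n": len(vals)})
    class_pct = rec["activity_class"].value_counts(normalize=True) * 100
    for cls in ("active", "inactive", "other"):
        rows.append({"metric": f"{cls.capitalize()} (%)",
                     "median": float(class_pct.get(cls, 0.0)),
                     "mad": np.nan, "n": len(rec)})
    return pd.DataFrame(rows)


def _total_atoms(row) -> float:
    # carbon_frac etc. are fractions of all atoms incl. implicit H; recover
    # the total from the hydrogen fraction and heavy-atom count.
    h_frac = row.hydrogen_frac
    return row.heavy_atoms / (1.0 - h_frac) if h_frac < 1.0 else row.heavy_atoms


def descriptor_comparison(allosteric_desc: pd.DataFrame,
                          background_desc: pd.DataFrame) -> pd.DataFrame:
    """Per-descriptor mean and SD for both sets with display scaling.

    Descriptors with large natural scales are additionally reported
    divided by 10 (e.g. logP) or 1000 (e.g. molecular weight) so all
    properties plot within one order of magnitude.
    """
    if len(allosteric_desc) == 0 or len(background_desc) == 0:
        raise ValueError("descriptor comparison requires two non-empty sets")
    scale = {"mw": 1000.0, "psa": 1000.0, "heavy_atoms": 100.0,
             "logp": 10.0, "logd": 10.0, "solubility": 10.0,
             "hba": 10.0, "hbd": 10.0, "n_rings": 10.0, "n_chains": 10.0,
             "n_chain_assemblies": 10.0, "n_halogens": 10.0,
             "sp2_carbons": 100.0, "sp3_carbons": 100.0,
             "n_terminal_rotomers": 10.0}
    rows = []
    for colname in DescriptorVector.numeric_fields():
        a = pd.to_numeric(allosteric_desc[colname], errors="coerce")
        b = pd.to_numeric(background_desc[colname], errors="coerce")
        s = scale.get(colname, 1.0)
        rows.append({
            "descriptor": colname,
            "allosteric_mean": a.mean(), "allosteric_sd": a.std(),
            "background_mean": b.mean(), "background_sd": b.std(),
            "display_scale": s,
            "allosteric_scaled": a.mean() / s,
            "background_scaled": b.mean() / s,
        })
    return pd.DataFrame(rows)


def feature_matrix(dataset: mining.DataSet, descriptors: pd.DataFrame,
                   label: str, *, ternary: bool = False
                   ) -> tuple[pd.DataFrame, pd.Series]:
    """Descriptor feature matrix + labels for one set's records.

    With ``ternary`` the biological compounds of an allosteric set form
    the class "allosteric_biological".
    """
    rec = dataset.records.merge(descriptors, on="compound_id", how="inner")
    cols = [c for c in DescriptorVector.numeric_fields()
            if c not in ("lipinski_pass", "is_zwitterion")]
    x = rec[cols].astype(float).copy()
    x["lipinski_pass"] = rec["lipinski_pass"].astype(float)
    x["is_zwitterion"] = rec["is_zwitterion"].astype(float)
    y = pd.Series([label] * len(rec), index=x.index, name="label")
    if ternary and label == "allosteric":
        bio = (rec["molecule_class"] != "small molecule").to_numpy()
        y = y.mask(pd.Series(bio, index=y.index), "allosteric_biological")
    return x, y


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {**{k: v for k, v in vars(config).items()
                              if k != "generator"},
                           "generator": vars(config.generator).copy()},
                "stages": {}}
    t0 = time.time()

    def stage_done(name, tables):
        manifest["stages"][name] = {
            "rows": {k: int(len(v)) for k, v in tables.items()},
            "seconds": round(time.time() - t0, 2),
        }

    # --- simulate (or load) ----------------------------------------------
    if config.input_dir is not None:
        indir = Path(config.input_dir)
        if not indir.exists():
            raise PipelineError("simulate", f"input directory not found: {indir}")
        corpus = SyntheticCorpus.read(indir)
    else:
        corpus = generate_corpus(config.generator)
    corpus.write(outdir / "corpus")
    stage_done("simulate", {"documents": corpus.documents,
                            "activities": corpus.activities,
                            "compounds": corpus.compounds})

    # --- mine -------------------------------------------------------------
    keywords = config.keywords or config.generator.keyword_list
    allo_docs, bg_docs = mining.classify_documents(corpus.documents, keywords)
    if not allo_docs:
        raise PipelineError("mine", "no allosteric documents retrieved")
    allo_set = mining.assemble_set(allo_docs, corpus.activities,
                                   corpus.targets, label="allosteric")
    bg_full = mining.assemble_set(bg_docs, corpus.activities, corpus.targets,
                                  label="non_allosteric_full")
    bg_bal = mining.balance_background(bg_full, allo_set, seed=config.seed)
    for ds in (allo_set, bg_full, bg_bal):
        out = ds.records.copy()
        out["set_label"] = ds.label
        out.to_csv(outdir / f"dataset_{ds.label}.tsv", sep="\t", index=False)
    pd.DataFrame({"doc_id": allo_docs}).to_csv(
        outdir / "partition_allosteric_docs.tsv", sep="\t", index=False)
    stage_done("mine", {"allosteric": allo_set.records,
                        "non_allosteric_full": bg_full.records,
                        "non_allosteric_balanced": bg_bal.records})

    # --- describe ---------------------------------------------------------
    used = set(allo_set.records["compound_id"]) | set(
        bg_bal.records["compound_id"])
    desc = describe_compounds(
        corpus.compounds[corpus.compounds["compound_id"].isin(used)])
    desc.to_csv(outdir / "descriptors.tsv", sep="\t", index=False)
    stage_done("describe", {"descriptors": desc})

    # --- profile ----------------------------------------------------------
    profiles = {}
    for ds in (allo_set, bg_bal):
        prof = profile_dataset(ds, desc)
        prof.to_csv(outdir / f"profile_{ds.label}.tsv", sep="\t", index=False)
        profiles[ds.label] = prof
    comparison = descriptor_comparison(
        desc[desc["compound_id"].isin(set(allo_set.records["compound_id"]))],
        desc[desc["compound_id"].isin(set(bg_bal.records["compound_id"]))])
    comparison.to_csv(outdir / "descriptor_comparison.tsv", sep="\t",
                      index=False)
    stage_done("profile", {"comparison": comparison, **profiles})

    # --- enrich -----------------------------------------------------------
    mols = {}
    for rec in corpus.compounds.itertuples(index=False):
        if rec.compound_id in used:
            try:
                mols[rec.compound_id] = standardize(rec.smiles)
            except Exception:
                continue
    fps = fingerprints.fingerprint_table(mols)
    allo_fps = {c: fps[c] for c in allo_set.records["compound_id"]
                if c in fps}
    bg_fps = {c: fps[c] for c in bg_bal.records["compound_id"] if c in fps}
    enr = enrichment.enrichment_table(allo_fps, bg_fps)
    enr["allosteric"].to_csv(outdir / "enrichment_allosteric.tsv", sep="\t",
                             index=False)
    enr["non_allosteric"].to_csv(outdir / "enrichment_non_allosteric.tsv",
                                 sep="\t", index=False)
    stage_done("enrich", {"allosteric": enr["allosteric"],
                          "non_allosteric": enr["non_allosteric"]})

    # --- model ------------------------------------------------------------
    xa, ya = feature_matrix(allo_set, desc, "allosteric",
                            ternary=config.ternary)
    xb, yb = feature_matrix(bg_bal, desc, "non_allosteric")
    x = pd.concat([xa, xb], ignore_index=True)
    y = pd.concat([ya, yb], ignore_index=True)
    report = classify.run_model(x, y, label="L0",
                                train_fraction=config.train_fraction,
                                n_trees=config.n_trees, seed=config.seed)
    report.importance.to_csv(outdir / "importance.tsv", sep="\t", index=False)
    with open(outdir / "model_report.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
    stage_done("model", {"features": x})

    # --- report -----------------------------------------------------------
    manifest["output_hashes"] = {
        p.name: _hash_file(p) for p in sorted(outdir.rglob("*.tsv"))
    }
    manifest["model"] = report.as_dict()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
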