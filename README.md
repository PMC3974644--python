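# allokit

Profiling and classification of allosteric versus non-allosteric ligands
over ChEMBL-style bioactivity corpora.

Allosteric modulators act through a binding site distinct from a
protein's natural (orthosteric) ligand site. Corpus-scale comparisons of
ligands annotated as allosteric against the non-allosteric background
show systematic differences: allosteric compounds tend to be smaller,
more lipophilic and more rigid, bind with lower absolute potency but
similar ligand efficiency, and can be told apart from background ligands
by a classifier over simple physicochemical descriptors. `allokit`
implements that whole analysis as a reusable, tested pipeline for
computational chemists and chemoinformaticians:

* **Corpus mining** — whole-word keyword partition of documents by
  title/abstract, primary-target selection per document (by annotation
  frequency), quality-aware deduplication (Ki/Kd preferred over
  IC50/EC50 over other numeric over comment-only), and a per-L2-class
  balanced background set.
* **Chemistry** — salt stripping and rule-based pH 7.4 protonation, a
  physicochemical descriptor panel including the rigidity index

  R = (f_arom + (1 − f_rot) + f_aliph-ring + (1 − f_single) + f_double
  + f_triple + f_bridge) / 7

  over heavy-atom bond fractions (benzene 3/7, cyclohexane 2/7), the
  Lipinski rule-of-five pass with zero violations, pharmacophore-typed
  circular fingerprints (FCFP-style, diameter 6), Laplacian-corrected
  Bayesian selection into a fixed 512-bit string, and deterministic
  leader clustering on Tanimoto similarity.
* **Bioactivity** — pActivity = −log10 of the molar Ki/Kd/IC50/EC50,
  an active/inactive cutoff at 6 log units (1 µM), the ligand efficiency
  panel LE = 1.37·pA/HA, BEI = pA/(MW/1000), SEI = pA/(PSA/100),
  NBEI = pA/HA, NSEI = pA/NPOL, nBEI = pA + log10(HA),
  mBEI = pA + log10(MW), promiscuity counts, and median (MAD) summaries.
* **Substructure enrichment** — occurrence-weighted feature frequencies
  normalized per set, average-rank ties, and the enrichment score
  log10(normalized background rank / normalized set rank).
* **Classification** — random forests (500 trees, √p features per
  split) with stratified 70/30 external validation, out-of-bag ROC,
  permutation/Gini importances with Pareto-front feature selection, and
  the binary and three-class Matthews correlation coefficient; the
  three-class MCC uses the product of correct counts minus the product
  of per-class miss totals over the cube root of all nine pairwise sums,
  and ternary recall/precision can be rescaled (1/3 → 0.5) onto the
  binary range.
* **Synthetic corpus generator** — a seeded generator of the four
  ChEMBL-like tables (documents, targets, compounds, activities) plus a
  ground-truth table, with two property-shifted small-molecule fragment
  grammars, peptide-like biologicals, potency anchored to Laplace
  (median 5.96, MAD 1.02) vs (6.66, 1.17) log units, planted keywords
  and a planted aromatic motif, so every downstream stage can be tested
  against known truth without any database download.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic corpus (400 documents, 30% allosteric):

```
python analysis/01_simulate_corpus.py
python analysis/02_mine_datasets.py
python analysis/03_compute_descriptors.py
python analysis/04_profile_bioactivity.py
python analysis/05_compare_descriptors.py
python analysis/06_enrich_substructures.py
python analysis/07_train_classifiers.py
```

which prints, among other things:

```
keyword partition: 120 allosteric documents, 280 background
median pActivity (MAD): allosteric 6.01 (±1.01) vs background 6.74 (±1.12)
rigidity_index: allosteric 0.312 vs background 0.132
planted motif (c1cc(C(F)(F)F)sc1): best enrichment rank 1 of 1145
binary: external MCC 0.925, sens 0.97, spec 0.96, AUC 0.997
```

Reading: the keyword search recovers the planted document partition; the
recovered set medians sit at the generator's potency anchors (difference
≈ −0.7 log units); the allosteric population is measurably more rigid;
the planted trifluoromethyl-thiophene motif tops the substructure
enrichment ranking; and the external 70/30 validation of the balanced
random-forest classifier separates the two ligand populations with MCC
0.93. All tables land under `results/analysis/`.

The same pipeline is available as a library (`allokit.pipeline.run_pipeline`)
and a CLI (`allokit simulate`, `allokit run-all`).

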