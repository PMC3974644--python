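# Methods

This note documents the models, conventions and design choices behind
`allokit`, in the spirit of a package methods appendix. Nothing here
states a result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Corpus model and mining

A corpus is four tab-separated tables mirroring a ChEMBL-style export:
documents (id, year, title, abstract), targets (id, accession, L1/L2
protein-family labels), compounds (id, SMILES, molecule type) and
activities (document/target/compound links, assay type, standard type,
value, units, qualifier, comment).

**Keyword partition.** A document is allosteric iff at least one keyword
matches its title or abstract, case-insensitively, at word boundaries;
multi-word keywords match as phrases. Word-boundary matching means
inflections ("allosterically") must be separate list entries — this
avoids double-counting stems while keeping the list auditable. Documents
with neither title nor abstract fall to the background with a warning.

**Primary target and deduplication.** Within each document, the target
with the most activity records is primary (ties: lexicographically
smallest id, for determinism). Only primary-target records are kept. One
record survives per (compound, target): quality tiers Ki=Kd > IC50=EC50
> other numeric > comment-only; within a tier the larger pActivity wins;
remaining ties go to the first-seen activity id. Qualified values (">",
"<") stay in the set but carry no pActivity and classify as "other".

**Balanced background.** For each L2 class present in the allosteric
set, `min(n_allosteric_class, n_background_class)` background records
are sampled without replacement, seeded. This is an exact-count capped
scheme rather than a "random percentage": per-class counts are then
seed-invariant and Table-style composition reports are reproducible.

## Compound standardization

Standardization keeps the largest fragment (salt stripping, via RDKit's
largest-fragment chooser) and applies a fixed SMARTS rule list
approximating pH 7.4: carboxylic, sulfonic and phosphorus oxyacid O–H
deprotonated; tetrazole N–H deprotonated; aliphatic amines (not amides,
anilines or amidine-adjacent) and amidine/guanidine sp2 nitrogens
protonated. A rule list was chosen over pKa prediction for
reproducibility; molecules outside these rules keep their input charge
state.

## Descriptor panel

Denominator conventions (these make every fraction well-defined):

* **atom fractions** (element fractions, H-bond donor/acceptor
  fractions, charge-sign fractions, stereoatom fraction) divide by all
  atoms *including implicit hydrogens* — so a hydrogen fraction exists
  and element fractions over {C, H, N, O, S, other} sum to 1;
* **bond fractions** (single/double/triple/aromatic/ring/aliphatic-ring/
  bridge/rotatable) divide by bonds between heavy atoms; aromatic bonds
  are not counted as single bonds; "bridge" bonds belong to two or more
  smallest rings; a single-atom molecule has all bond fractions 0.

The rigidity index is the seven-term composite
`(f_arom + (1−f_rot) + f_aliph_ring + (1−f_single) + f_double + f_triple
+ f_bridge)/7`, in [0, 1]; benzene scores 3/7, cyclohexane 2/7, and a
bondless molecule scores the 2/7 floor.

Consensus properties (logP, logD, solubility) are arithmetic means over
a registry of estimators, defaulting to one open estimator each: Crippen
logP; a logD(7.4) proxy (Crippen logP shifted −1 per ionized center);
ESOL log-solubility. The registry accepts additional estimators, which
is how multi-calculator consensus values are reproduced when more
calculators are available.

Topology counts are defined in-package: `n_chains` = connected
components of non-ring heavy atoms; `n_chain_assemblies` = connected
components of the acyclic-bond graph (ring atoms may be endpoints);
`n_terminal_rotomers` = terminal sp3 heavy atoms attached by an acyclic
single bond to an atom with further heavy neighbors (this descriptor has
no standard published definition; the one above is this package's).
`psa_frac` uses the Labute approximate surface area as the total-surface
proxy, clipped to [0, 1]. 3D-dependent descriptors (SASA, volume,
average bond length) and proprietary drug-likeness scores are not in the
default panel; the estimator registry is the extension point.

Lipinski pass allows zero violations with inclusive boundaries
(MW ≤ 500, logP ≤ 5, HBD ≤ 5, HBA ≤ 10).

## Fingerprints, selection, clustering

Fingerprints are circular environments to radius 3 (diameter 6) whose
starting atom invariants are pharmacophore feature classes (donor,
acceptor, positively/negatively ionizable, aromatic, halogen) — the
FCFP-style variant — computed with RDKit's feature-invariant Morgan
generator, so feature ids are stable across runs.

Bayesian 512-bit selection ranks features by the absolute
Laplacian-corrected class log-odds `log10(P_corr(c|f)/p_c)` with
`P_corr = (n_fc + 1)/(n_f + 1/p_c)`, keeps the top 512 (all, if fewer),
and encodes compounds as presence bits in rank order. Ties break by
feature id.

Clustering is leader-style (Butina) on Tanimoto similarity of feature
*sets*: centroids in order of descending neighbor count, ties by
compound id. It is implemented in-package to pin down that ordering
rule exactly; the test suite cross-checks the resulting partitions
against RDKit's Butina implementation.

## Bioactivity normalization and efficiency indices

pActivity = −log10(molar value) for unqualified Ki/Kd/IC50/EC50 records;
everything else gets its class from the comment lexicon or "other".
The active/inactive boundary is 6 log units, with pActivity = 6 counting
as active ("better than micromolar" read inclusively). MAD is the
unscaled median absolute deviation (no 1.4826 consistency factor),
matching how median (MAD) pairs are conventionally reported in this
analysis. LE uses 1.37 ≈ 2.303·RT kcal/mol at ~300 K; NPOL is the
nitrogen + oxygen atom count. `nBEI − pActivity = log10(HA)` and
`mBEI − pActivity = log10(MW)` hold identically and are asserted to
1e-9.

## Enrichment scoring

Feature counts are occurrence-weighted (per-compound counts summed) and
normalized per set to frequencies summing to 1. Ranks (1 = most
frequent, average on ties) are normalized by the number of features in
that set. The score is `log10(bg_rank_norm / set_rank_norm)`, log base
10, oriented so positive means enriched in the focal set. The background
pool is the union of both sets' counts. Features absent from a set are
excluded from scoring (no pseudo-rank) and reported separately. Because
the score depends only on ranks, it is invariant to duplicating every
compound.

## Classifiers and validation

Random forests: 500 trees, √p features per split, no class weighting
(sets are balanced upstream), out-of-bag scores enabled. The external
validation is a stratified 70/30 split. Feature matrices for corpus-wide
models use the descriptor panel only; fingerprint bits are reserved for
congeneric (target-specific) sets, where chemical series share enough
substructure for bits to generalize.

Permutation importance is the mean accuracy drop over 10 seeded
permutations per feature, measured on the held-out partition (a
held-out-set score drop rather than strictly per-tree out-of-bag drops,
which the underlying forest implementation does not expose publicly);
Gini importance is the forest's impurity importance. Class correlation
is the Pearson correlation between a feature and the indicator of the
allosteric class; its sign assigns the feature to a class. The reported
top-3 per class come from the Pareto front over (permutation importance,
|correlation|), front members first, then by importance.

The binary MCC is `(AA·BB − AB·BA)/√((AA+BA)(AA+AB)(BB+BA)(BB+AB))`;
any zero denominator yields 0 by convention. The three-class MCC is
`(AA·BB·CC − AX·BX·CX) / cbrt(Π (d + m))` over the nine pairings of
diagonal counts d ∈ {AA, BB, CC} with miss totals m ∈ {AX, BX, CX}.
This is the unique reading of the verbal "cube root of all possible sums
of correct and incorrect predictions" that (a) reduces to the binary
four-sum form for two classes and (b) equals exactly 1 for every
strictly diagonal matrix; the exact-1 anchor is enforced by integer
cube-root detection. Note the product numerator is negative for a
uniform (fully random) 3×3 matrix — the 0-for-random anchor is a binary
property and is only asserted there; the uniform-matrix value is pinned
as a regression value. A covariance-based multiclass MCC (the R_K
statistic) is provided as a config-switchable cross-check; the two agree
at the +1 anchor and differ away from it. Ternary recall/precision can
be rescaled affinely with anchors 1/3 → 0.5 and 1 → 1 for side-by-side
display with binary models.

## Synthetic corpus generator

The generator defines the study conditions; its defaults are fixed:

| parameter | default | rationale |
|---|---|---|
| n_documents | 400 | ≈6,700 activities, ample for median/MAD recovery |
| allosteric_fraction | 0.3 | balanced enough for stratified models |
| potency (allosteric) | Laplace median 5.96, MAD 1.02 log units | literature anchor for the allosteric set |
| potency (background) | Laplace median 6.66, MAD 1.17 log units | literature anchor for the background |
| assay types | 82/17/1 vs 86/13/1 binding/functional/other | composition anchors |
| biological_fraction | 0.04 | both sets carry a few percent biologicals |
| compounds_per_document | 8–16 | typical medicinal-chemistry series size |
| property_shift | 1.0 | full grammar separation (the dial's top) |
| motif_fraction | 0.3 | planted motif lands in the discriminating frequency band of the rank-quotient score |

Potencies are Laplace-distributed because the Laplace MAD is `b·ln 2`,
so (median, MAD) summaries recover the configured anchors directly —
set-level medians differ by ≈ −0.70 log units by construction.

The two small-molecule populations are built from a shared fragment
vocabulary with strongly shifted weights: the allosteric grammar is
dominated by aromatic/heteroaromatic rings, halogens and rigid linkers
in 1–3 fragment assemblies; the background grammar by aliphatic chains,
ethers, amides and polar terminals in 3–6 fragment assemblies. Sharing
the vocabulary (rather than using disjoint pools) mirrors real corpora,
where individual circular features occur in both classes and only their
frequencies differ; it also means the planted
trifluoromethyl-thiophene motif is the only population-exclusive
substructure family, so enrichment recovery has a well-defined truth.
`property_shift` interpolates per molecule between the population
grammar and the even mixture of both pools: at 0 the populations are
chemically identical (a classifier should score MCC ≈ 0), at 1 they are
fully shifted. Biologicals are amide-backbone oligomers of 9–15
residues drawn from seven side chains (MW typically >1,000).

Each document gets one primary target plus a decoy target receiving a
minority of records (primary-target selection is therefore nontrivial),
and ~15% of compounds get a second same-target record of a different
measurement type (deduplication is therefore exercised). Allosteric
documents receive exactly one planted keyword sentence; the background
word bank contains no keyword, so the partition ground truth is exact.

What the generator does *not* emulate: real SAR series and scaffold
hopping, realistic abstracts, inter-target chemotype structure,
activity cliffs, census-accurate class distributions, assay noise
correlated with chemistry. Passing recovery tests therefore shows the
pipeline's machinery is correct on planted structure, not that the
literature-scale effect sizes would be reproduced from a live database.

## Problem sizes in the tests

The test suite runs the recovery checks on a 300-document corpus
(≈5,000 activities, ≈2,700 descriptor rows) with 300-tree forests, and
the pipeline determinism checks on 40–60-document corpora — sizes chosen
so the full suite exercises every stage end to end while staying quick
on a single CPU. The analysis scripts use the 400-document default.

## Known limitations

* The ternary corpus-level model labels only allosteric-set biologicals
  as the third class; background peptides keep the non-allosteric label
  and are chemically indistinguishable from them, so third-class recall
  (and hence the ternary MCC) is structurally limited at corpus level.
  The mode matches case-study settings, where the background is all
  small-molecule.
* pH 7.4 protonation is rule-based, not a pKa model; zwitterion
  detection follows the rules, not measured pKa values.
* The descriptor panel covers the documented subset of a larger
  historical panel; 3D and proprietary descriptors are extension points,
  not defaults.
* Enrichment scores are rank-based with no significance testing, by
  design.
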