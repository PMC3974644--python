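"""Pharmacophore-typed circular fingerprints and operations on them.

Fingerprints are FCFP-style: circular (Morgan) environments of radius up
to 3 (diameter 6) whose starting atom invariants are pharmacophore
feature classes (donor, acceptor, positively/negatively ionizable,
aromatic, halogen) rather than element identities.  Feature identifiers
are the stable RDKit environment hashes, so identical structures always
yield identical feature mappings.

On top of the sparse feature maps this module provides:

* a Laplacian-corrected naive-Bayes feature ranking that compresses the
  open-ended feature space into a fixed-length (default 512) bitstring;
* Tanimoto similarity over feature sets and deterministic leader
  (Butina-style) clustering.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "fingerprint",
    "fingerprint_table",
    "tanimoto",
    "select_features_bayesian",
    "encode_bits",
    "cluster_compounds",
]

_GENERATOR_CACHE: dict[int, object] = {}


def _generator(radius: int):
    if radius not in _GENERATOR_CACHE:
        _GENERATOR_CACHE[radius] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
    return _GENERATOR_CACHE[radius]


def fingerprint(mol: Chem.Mol, radius: int = 3) -> dict[int, int]:
    """Sparse {feature_id: occurrence count} map for one structure."""
    fp = _generator(radius).GetSparseCountFingerprint(mol)
    return dict(fp.GetNonzeroElements())


def fingerprint_table(mols: dict, radius: int = 3) -> dict:
    """Fingerprints for a {compound_id: Mol} mapping."""
    return {cid: fingerprint(mol, radius) for cid, mol in mols.items()}


def tanimoto(fp_a: dict, fp_b: dict) -> float:
    """Tanimoto similarity of two feature *sets* (presence-based)."""
    a, b = set(fp_a), set(fp_b)
    union = len(a | b)
    return len(a & b) / union if union else 1.0


def select_features_bayesian(fingerprints: dict, labels: dict,
                             n_bits: int = 512):
    """Rank features by Laplacian-corrected class log-odds; keep top n_bits.

    For each feature f with total count n_f of which n_f,c fall in class c
    (class prior p_c), the corrected class probability is

        P_corr(c|f) = (n_f,c + 1) / (n_f + 1/p_c)

    and the feature score is log10(P_corr / p_c) for the first class
    (alphabetically); features discriminating either class strongly get
    large |score|.  Ties in |score| break by feature id for determinism.

    Returns (ordered feature id list, {compound_id: bit array}).
    """
    classes = sorted(set(labels.values()))
    if len(classes) < 2:
        raise ValueError("Bayesian feature selection requires >=2 classes")
    focal = classes[0]
    n_total = len(labels)
    n_focal = sum(1 for v in labels.values() if v == focal)
    prior = n_focal / n_total

    count_all: dict[int, int] = {}
    count_focal: dict[int, int] = {}
    for cid, fp in fingerprints.items():
        is_focal = labels[cid] == focal
        for feat in fp:
            count_all[feat] = count_all.get(feat, 0) + 1
            if is_focal:
                count_focal[feat] = count_focal.get(feat, 0) + 1

    scores = {}
    for feat, n_f in count_all.items():
        p_corr = (count_focal.get(feat, 0) + 1.0) / (n_f + 1.0 / prior)
        scores[feat] = math.log10(p_corr / prior)
    ordered = sorted(scores, key=lambda f: (-abs(scores[f]), f))[:n_bits]
    bits = encode_bits(fingerprints, ordered)
    return ordered, bits


def encode_bits(fingerprints: dict, feature_order: list) -> dict:
    """Presence bit vectors over a fixed feature list."""
    index = {f: i for i, f in enumerate(feature_order)}
    out = {}
    for cid, fp in fingerprints.items():
        vec = np.zeros(len(feature_order), dtype=np.int8)
        for feat in fp:
            if feat in index:
                vec[index[feat]] = 1
        out[cid] = vec
    return out


def cluster_compounds(fingerprints: dict, similarity_threshold: float = 0.6
                      ) -> pd.Series:
    """Deterministic leader (Butina-style) clustering on Tanimoto similarity.

    Compounds are taken as cluster centroids in order of descending
    neighbor count (ties by compound id); every compound within the
    similarity threshold of a centroid joins that centroid's cluster and
    is removed from further consideration.

    Returns a Series mapping compound_id -> cluster index (0-based,
    in centroid-selection order).
    """
    ids = sorted(fingerprints)
    if not ids:
        return pd.Series(dtype=int)
    n = len(ids)
    sims = {}
    neighbors = {cid: set() for cid in ids}
    for i in range(n):
        for j in range(i + 1, n):
            s = tanimoto(fingerprints[ids[i]], fingerprints[ids[j]])
            if s >= similarity_threshold:
                neighbors[ids[i]].add(ids[j])
                neighbors[ids[j]].add(ids[i])

    unassigned = set(ids)
    assignment = {}
    cluster = 0
    while unassigned:
        centroid = min(unassigned,
                       key=lambda c: (-len(neighbors[c] & unassigned), c))
        members = (neighbors[centroid] & unassigned) | {centroid}
        for m in members:
            assignment[m] = cluster
        unassigned -= members
        cluster += 1
    return pd.Series(assignment).sort_index()
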