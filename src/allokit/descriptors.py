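"""Structure standardization and the physicochemical descriptor panel.

Structures are salt-stripped to their largest organic fragment and
protonated by a fixed rule list approximating pH 7.4 (carboxylic,
sulfonic and phosphorus oxyacids deprotonated; aliphatic amines,
amidines and guanidines protonated).  The descriptor panel covers size,
lipophilicity (consensus over registered estimators), polarity, atom and
bond composition fractions, ring/chain topology, charge state, the
rigidity index and the Lipinski rule-of-five pass flag.

Denominator conventions: atom fractions are over all atoms including
implicit hydrogens; bond fractions are over bonds between heavy atoms.
The rigidity index is

    (AromaticBondsFrac + (1 - RotatableBondsFrac) + AliphaticRingBondsFrac
     + (1 - SingleBondsFrac) + DoubleBondsFrac + TripleBondsFrac
     + BridgeBondsFrac) / 7

where "single" means single-order non-aromatic bonds and "bridge" means
bonds shared by two or more smallest rings.  Benzene scores 3/7,
cyclohexane 2/7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "StructureError",
    "DescriptorVector",
    "standardize",
    "compute_descriptors",
    "rigidity_index",
    "lipinski_pass",
    "default_estimators",
    "esol_log_solubility",
]


class StructureError(ValueError):
    def __init__(self, message, compound_id=None):
        super().__init__(message)
        self.compound_id = compound_id


# ---------------------------------------------------------------------------
# Standardization

_LARGEST = rdMolStandardize.LargestFragmentChooser()

# (SMARTS, atom index within match, charge delta) applied in order; each
# rule fires on every match.  Deliberately small and auditable rather than
# a pKa model.
_PH74_RULES = [
    # carboxylic acid -> carboxylate
    ("[CX3](=O)[OX2H1]", 2, -1),
    # sulfonic / sulfinic acid O-H
    ("[SX4](=O)(=O)[OX2H1]", 3, -1),
    # phosphate / phosphonate first O-H
    ("[PX4](=O)[OX2H1]", 2, -1),
    # tetrazole N-H (acidic, pKa ~4.9)
    ("c1nnn[nH]1", 4, -1),
    # aliphatic primary/secondary/tertiary amine (not amide, not aromatic,
    # not adjacent to carbonyl or aromatic ring)
    ("[NX3;H2,H1,H0;!$(NC=[O,S,N]);!$(Na);!$(N[a]);!$(N=*);!$([N+])]", 0, +1),
    # amidine / guanidine sp2 nitrogen
    ("[NX2;$(N=C[N;!$(NC=O)])]", 0, +1),
]
_PH74_PATTERNS = [(Chem.MolFromSmarts(s), idx, dq) for s, idx, dq in _PH74_RULES]


def standardize(smiles: str, compound_id=None) -> Chem.Mol:
    """Parse, keep the largest organic fragment, apply pH-7.4 charge rules.

    Returns an RDKit Mol with a stable canonical SMILES (available via
    ``Chem.MolToSmiles``).  Raises :class:`StructureError` on unparseable
    input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureError(f"unparseable SMILES: {smiles!r}", compound_id)
    mol = _LARGEST.choose(mol)
    rw = Chem.RWMol(mol)
    for pattern, idx, dq in _PH74_PATTERNS:
        if pattern is None:
            continue
        for match in rw.GetSubstructMatches(pattern):
            atom = rw.GetAtomWithIdx(match[idx])
            if dq < 0 and atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs()
                                          + atom.GetNumImplicitHs() - 1))
                atom.SetNoImplicit(True)
            elif dq > 0 and atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


# ---------------------------------------------------------------------------
# Consensus property estimators

def esol_log_solubility(mol: Chem.Mol) -> float:
    """ESOL (Delaney 2004) estimated log aqueous solubility (log mol/L)."""
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    heavy = mol.GetNumHeavyAtoms()
    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    arom = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = arom / heavy if heavy else 0.0
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rot - 0.74 * ap


def _logd_crippen(mol: Chem.Mol) -> float:
    """Crude logD(7.4): Crippen logP shifted down per ionized center."""
    logp = Crippen.MolLogP(mol)
    ionized = sum(1 for a in mol.GetAtoms() if a.GetFormalCharge() != 0)
    return logp - 1.0 * ionized


def default_estimators() -> dict:
    """Default property-estimator registry (one open estimator each)."""
    return {
        "logp": [Crippen.MolLogP],
        "logd": [_logd_crippen],
        "solubility": [esol_log_solubility],
    }


def _consensus(mol, estimators, name):
    fns = estimators.get(name, [])
    if not fns:
        raise ValueError(f"no registered estimators for consensus property {name!r}")
    return float(sum(fn(mol) for fn in fns)) / len(fns)


# ---------------------------------------------------------------------------
# Descriptor panel

@dataclass
class DescriptorVector:
    mw: float
    heavy_atoms: int
    logp: float
    logd: float
    solubility: float
    psa: float
    psa_frac: float
    hbd: int
    hba: int
    hbd_frac: float
    hba_frac: float
    carbon_frac: float
    hydrogen_frac: float
    nitrogen_frac: float
    oxygen_frac: float
    sulphur_frac: float
    heteroatom_frac: float
    n_halogens: int
    sp2_carbons: int
    sp3_carbons: int
    sp2_carbon_frac: float
    sp3_carbon_frac: float
    single_bond_frac: float
    double_bond_frac: float
    triple_bond_frac: float
    aromatic_bond_frac: float
    ring_bond_frac: float
    aliphatic_ring_bond_frac: float
    bridge_bond_frac: float
    rotatable_bond_frac: float
    n_rings: int
    n_chains: int
    n_chain_assemblies: int
    n_terminal_rotomers: int
    stereoatom_frac: float
    positive_atom_frac: float
    negative_atom_frac: float
    formal_charge: int
    is_zwitterion: bool
    rigidity_index: float
    lipinski_pass: bool
    molecule_class: str = "small molecule"

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @staticmethod
    def numeric_fields() -> list[str]:
        skip = {"molecule_class"}
        return [f.name for f in dc_fields(DescriptorVector) if f.name not in skip]


def rigidity_index(aromatic_frac: float, rotatable_frac: float,
                   aliphatic_ring_frac: float, single_frac: float,
                   double_frac: float, triple_frac: float,
                   bridge_frac: float) -> float:
    """Seven-term bond-fraction composite estimating conformational rigidity."""
    terms = (aromatic_frac, rotatable_frac, aliphatic_ring_frac, single_frac,
             double_frac, triple_frac, bridge_frac)
    for t in terms:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"bond fraction outside [0,1]: {t}")
    return (aromatic_frac + (1.0 - rotatable_frac) + aliphatic_ring_frac
            + (1.0 - single_frac) + double_frac + triple_frac
            + bridge_frac) / 7.0


def lipinski_pass(mw: float, logp: float, hbd: int, hba: int) -> bool:
    """Rule-of-five with zero violations allowed (inclusive boundaries)."""
    return mw <= 500.0 and logp <= 5.0 and hbd <= 5 and hba <= 10


def _heavy_bonds(mol):
    return [b for b in mol.GetBonds()
            if b.GetBeginAtom().GetAtomicNum() > 1
            and b.GetEndAtom().GetAtomicNum() > 1]


def _bridge_bond_count(mol) -> int:
    """Bonds belonging to >=2 smallest rings (fused/bridged ring bonds)."""
    ri = mol.GetRingInfo()
    membership = {}
    for ring in ri.BondRings():
        for bidx in ring:
            membership[bidx] = membership.get(bidx, 0) + 1
    return sum(1 for v in membership.values() if v >= 2)


def _chain_components(mol) -> tuple[int, int]:
    """(n_chains, n_chain_assemblies).

    n_chains: connected components of the subgraph induced by non-ring
    heavy atoms.  n_chain_assemblies: connected components of the graph
    whose edges are non-ring heavy-heavy bonds (ring atoms may serve as
    endpoints), i.e. chain systems that may link several rings.
    """
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    nonring = {i for i in heavy if not mol.GetAtomWithIdx(i).IsInRing()}

    def components(nodes, edges):
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u, v in edges:
            parent[find(u)] = find(v)
        return len({find(n) for n in nodes})

    chain_edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in _heavy_bonds(mol)
        if b.GetBeginAtomIdx() in nonring and b.GetEndAtomIdx() in nonring
    ]
    n_chains = components(nonring, chain_edges) if nonring else 0

    assembly_edges = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in _heavy_bonds(mol)
        if not b.IsInRing()
    ]
    assembly_nodes = {i for e in assembly_edges for i in e}
    n_assemblies = components(assembly_nodes, assembly_edges) if assembly_nodes else 0
    return n_chains, n_assemblies


def _terminal_rotomers(mol) -> int:
    """Terminal sp3 heavy atoms attached by an acyclic single bond to an
    atom with further heavy neighbors (freely spinning terminal groups)."""
    count = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() <= 1 or atom.GetDegree() != 1:
            continue
        if atom.GetHybridization() != Chem.HybridizationType.SP3:
            continue
        bond = atom.GetBonds()[0]
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        other = bond.GetOtherAtom(atom)
        if other.GetDegree() >= 2:
            count += 1
    return count


_HALOGENS = {9, 17, 35, 53, 85}


def compute_descriptors(mol: Chem.Mol, estimators: dict | None = None,
                        molecule_class: str = "small molecule") -> DescriptorVector:
    """Full descriptor panel for a standardized structure."""
    if estimators is None:
        estimators = default_estimators()

    heavy = mol.GetNumHeavyAtoms()
    n_h = sum(a.GetTotalNumHs() for a in mol.GetAtoms())
    total_atoms = heavy + n_h

    def atom_frac(n):
        return n / total_atoms if total_atoms else 0.0

    elem = {"C": 0, "N": 0, "O": 0, "S": 0}
    n_halogens = 0
    sp2_c = sp3_c = 0
    n_pos = n_neg = 0
    n_stereo = 0
    for a in mol.GetAtoms():
        sym = a.GetSymbol()
        if sym in elem:
            elem[sym] += 1
        if a.GetAtomicNum() in _HALOGENS:
            n_halogens += 1
        if sym == "C":
            if a.GetHybridization() == Chem.HybridizationType.SP2:
                sp2_c += 1
            elif a.GetHybridization() == Chem.HybridizationType.SP3:
                sp3_c += 1
        q = a.GetFormalCharge()
        if q > 0:
            n_pos += 1
        elif q < 0:
            n_neg += 1
        if a.GetChiralTag() != Chem.ChiralType.CHI_UNSPECIFIED:
            n_stereo += 1

    hbonds = _heavy_bonds(mol)
    n_hb = len(hbonds)

    def bond_frac(n):
        return n / n_hb if n_hb else 0.0

    n_single = sum(1 for b in hbonds
                   if b.GetBondType() == Chem.BondType.SINGLE
                   and not b.GetIsAromatic())
    n_double = sum(1 for b in hbonds
                   if b.GetBondType() == Chem.BondType.DOUBLE)
    n_triple = sum(1 for b in hbonds
                   if b.GetBondType() == Chem.BondType.TRIPLE)
    n_aromatic = sum(1 for b in hbonds if b.GetIsAromatic())
    n_ring = sum(1 for b in hbonds if b.IsInRing())
    n_aliph_ring = sum(1 for b in hbonds
                       if b.IsInRing() and not b.GetIsAromatic())
    n_bridge = _bridge_bond_count(mol)
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(mol)

    mw = Descriptors.MolWt(mol)
    psa = rdMolDescriptors.CalcTPSA(mol)
    surface_proxy = rdMolDescriptors.CalcLabuteASA(mol)
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = rdMolDescriptors.CalcNumHBA(mol)
    logp = _consensus(mol, estimators, "logp")
    logd = _consensus(mol, estimators, "logd")
    solubility = _consensus(mol, estimators, "solubility")

    rigidity = rigidity_index(
        bond_frac(n_aromatic), min(1.0, bond_frac(n_rot)),
        bond_frac(n_aliph_ring), bond_frac(n_single),
        bond_frac(n_double), bond_frac(n_triple), bond_frac(n_bridge),
    )
    n_chains, n_assemblies = _chain_components(mol)
    n_carbons = elem["C"]

    return DescriptorVector(
        mw=mw,
        heavy_atoms=heavy,
        logp=logp,
        logd=logd,
        solubility=solubility,
        psa=psa,
        psa_frac=min(1.0, psa / surface_proxy) if surface_proxy > 0 else 0.0,
        hbd=hbd,
        hba=hba,
        hbd_frac=atom_frac(hbd),
        hba_frac=atom_frac(hba),
        carbon_frac=atom_frac(elem["C"]),
        hydrogen_frac=atom_frac(n_h),
        nitrogen_frac=atom_frac(elem["N"]),
        oxygen_frac=atom_frac(elem["O"]),
        sulphur_frac=atom_frac(elem["S"]),
        heteroatom_frac=atom_frac(heavy - elem["C"]),
        n_halogens=n_halogens,
        sp2_carbons=sp2_c,
        sp3_carbons=sp3_c,
        sp2_carbon_frac=sp2_c / n_carbons if n_carbons else 0.0,
        sp3_carbon_frac=sp3_c / n_carbons if n_carbons else 0.0,
        single_bond_frac=bond_frac(n_single),
        double_bond_frac=bond_frac(n_double),
        triple_bond_frac=bond_frac(n_triple),
        aromatic_bond_frac=bond_frac(n_aromatic),
        ring_bond_frac=bond_frac(n_ring),
        aliphatic_ring_bond_frac=bond_frac(n_aliph_ring),
        bridge_bond_frac=bond_frac(n_bridge),
        rotatable_bond_frac=min(1.0, bond_frac(n_rot)),
        n_rings=rdMolDescriptors.CalcNumRings(mol),
        n_chains=n_chains,
        n_chain_assemblies=n_assemblies,
        n_terminal_rotomers=_terminal_rotomers(mol),
        stereoatom_frac=atom_frac(n_stereo),
        positive_atom_frac=atom_frac(n_pos),
        negative_atom_frac=atom_frac(n_neg),
        formal_charge=Chem.GetFormalCharge(mol),
        is_zwitterion=(n_pos > 0 and n_neg > 0),
        rigidity_index=rigidity,
        lipinski_pass=lipinski_pass(mw, logp, hbd, hba),
        molecule_class=molecule_class,
    )
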