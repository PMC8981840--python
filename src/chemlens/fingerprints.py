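"""Molecular fingerprints with feature-to-atom maps.

Beyond the bit vector itself, every operation here records, for each set
feature, *which atoms represent it*. For Morgan (circular) fingerprints a
feature is a hashed atom environment: the atom set of one occurrence is the
center atom plus all atoms within the environment radius. For MACCS keys a
feature is a substructure pattern: the atom sets are its matches. These maps
are what allows per-feature attribution scores (e.g. SHAP values) to be
spread back onto atoms.

Folding collisions (several environments hashing to one bit) are accepted;
a collided bit's atom map is the union of the occurrence lists of all
colliding environments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.MACCSkeys import smartsPatts

logger = logging.getLogger(__name__)

DEFAULT_N_BITS = 256
DEFAULT_RADIUS = 5
MACCS_N_KEYS = 166


@dataclass
class FingerprintResult:
    """A fingerprint plus the atom sets behind each set feature.

    ``feature_atoms[f]`` is a list of frozensets of atom indices, one per
    occurrence of feature ``f``; in counts mode ``bits[f]`` equals the
    number of occurrences.
    """

    bits: np.ndarray
    feature_atoms: dict[int, list[frozenset[int]]] = field(default_factory=dict)
    n_atoms: int = 0
    counts: bool = False

    @property
    def n_bits(self) -> int:
        return len(self.bits)

    def atom_union(self, feature: int) -> frozenset[int]:
        """Union of all occurrence atom sets of one feature."""
        sets = self.feature_atoms.get(feature, [])
        out: set[int] = set()
        for s in sets:
            out |= s
        return frozenset(out)


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


def _environment_atoms(mol: Chem.Mol, center: int, radius: int) -> frozenset[int]:
    """Atoms of one Morgan environment: the center plus all atoms within
    ``radius`` bonds along the environment's bond paths."""
    if radius == 0:
        return frozenset({center})
    bond_ids = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, center)
    atoms = {center}
    for bid in bond_ids:
        bond = mol.GetBondWithIdx(bid)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return frozenset(atoms)


def morgan_fingerprint(
    smiles: str,
    n_bits: int = DEFAULT_N_BITS,
    radius: int = DEFAULT_RADIUS,
    counts: bool = False,
) -> FingerprintResult:
    """Folded Morgan (circular) fingerprint with per-bit atom environments.

    Parameters follow the dataset default: 256 bits, radius 5, binary.
    """
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    mol = _mol_from_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    if counts:
        fp = gen.GetCountFingerprint(mol, additionalOutput=ao)
        bits = np.zeros(n_bits, dtype=int)
        for k, v in fp.GetNonzeroElements().items():
            bits[k] = v
    else:
        fp = gen.GetFingerprint(mol, additionalOutput=ao)
        bits = np.zeros(n_bits, dtype=int)
        bits[list(fp.GetOnBits())] = 1
    feature_atoms: dict[int, list[frozenset[int]]] = {}
    for bit, occurrences in ao.GetBitInfoMap().items():
        feature_atoms[bit] = [_environment_atoms(mol, a, r) for a, r in occurrences]
    return FingerprintResult(bits=bits, feature_atoms=feature_atoms,
                             n_atoms=mol.GetNumHeavyAtoms(), counts=counts)


def maccs_keys(smiles: str) -> FingerprintResult:
    """166 MACCS structural keys with per-key substructure matches.

    RDKit's raw vector has 167 positions with index 0 unused; here feature
    index ``j`` (0-based) corresponds to MACCS key ``j + 1``. Keys without a
    SMARTS definition (count-based special keys) contribute no atoms and are
    logged.
    """
    mol = _mol_from_smiles(smiles)
    raw = MACCSkeys.GenMACCSKeys(mol)
    bits = np.zeros(MACCS_N_KEYS, dtype=int)
    feature_atoms: dict[int, list[frozenset[int]]] = {}
    for on in raw.GetOnBits():
        j = on - 1  # raw index 0 is unused
        bits[j] = 1
        smarts, _min_count = smartsPatts[on]
        if smarts == "?":
            logger.debug("MACCS key %d has no substructure definition; no atom map", on)
            feature_atoms[j] = []
            continue
        patt = Chem.MolFromSmarts(smarts)
        matches = mol.GetSubstructMatches(patt, uniquify=True)
        feature_atoms[j] = [frozenset(m) for m in matches]
    return FingerprintResult(bits=bits, feature_atoms=feature_atoms,
                             n_atoms=mol.GetNumHeavyAtoms(), counts=False)


def concat_features(a: FingerprintResult, b: FingerprintResult) -> FingerprintResult:
    """Concatenate two fingerprints of the same molecule; features of ``b``
    are offset by ``a.n_bits``."""
    if a.n_atoms and b.n_atoms and a.n_atoms != b.n_atoms:
        raise ValueError("fingerprints describe molecules with different atom counts")
    bits = np.concatenate([a.bits, b.bits])
    feature_atoms = {f: list(sets) for f, sets in a.feature_atoms.items()}
    offset = a.n_bits
    for f, sets in b.feature_atoms.items():
        feature_atoms[f + offset] = list(sets)
    return FingerprintResult(bits=bits, feature_atoms=feature_atoms,
                             n_atoms=max(a.n_atoms, b.n_atoms),
                             counts=a.counts or b.counts)
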