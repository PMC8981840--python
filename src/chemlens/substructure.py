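"""Maximum common substructures, substructure filtering and depiction
alignment.

The MCS of a compound list is the largest connected substructure shared by
all of them, compared by element and bond order with ring bonds required to
match ring bonds by default. Substructure filters take a SMILES fragment
(not SMARTS) as the query, matching the tool's table-filter semantics.
Alignment lays every matching molecule out so the shared substructure sits
on identical 2D coordinates, making the differences stand out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDepictor, rdFMCS

logger = logging.getLogger(__name__)

DEFAULT_MCS_TIMEOUT_S = 5.0


class QueryError(ValueError):
    """The substructure query string could not be parsed."""


@dataclass
class McsResult:
    """An MCS pattern plus where it matches in each input compound."""

    pattern: str  # SMARTS
    atom_matches: list[list[tuple[int, ...]]] = field(default_factory=list)
    num_atoms: int = 0
    num_bonds: int = 0
    completed: bool = True

    @property
    def query_mol(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.pattern)
        if q is None:
            raise QueryError(f"stored MCS pattern is not valid SMARTS: {self.pattern!r}")
        return q


def _parse_all(smiles_list: list[str]) -> list[Chem.Mol]:
    mols = []
    for s in smiles_list:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {s!r}")
        mols.append(mol)
    return mols


def mcs(
    smiles_list: list[str],
    timeout_s: float = DEFAULT_MCS_TIMEOUT_S,
    ring_matches_ring_only: bool = True,
) -> McsResult:
    """Maximum common connected substructure of all input molecules.

    Atoms are compared by element, bonds by bond order. On timeout the best
    substructure found so far is returned with ``completed=False``. A
    single-molecule input returns that molecule's full graph.
    """
    if not smiles_list:
        raise ValueError("empty SMILES list")
    mols = _parse_all(smiles_list)
    if len(mols) == 1:
        mol = mols[0]
        pattern = Chem.MolToSmarts(mol)
        query = Chem.MolFromSmarts(pattern)
        matches = [list(mol.GetSubstructMatches(query, uniquify=True))]
        return McsResult(pattern=pattern, atom_matches=matches,
                         num_atoms=mol.GetNumAtoms(), num_bonds=mol.GetNumBonds())
    res = rdFMCS.FindMCS(
        mols,
        timeout=max(1, int(round(timeout_s))),
        ringMatchesRingOnly=ring_matches_ring_only,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
    )
    pattern = res.smartsString
    query = Chem.MolFromSmarts(pattern) if pattern else None
    atom_matches: list[list[tuple[int, ...]]] = []
    for mol in mols:
        if query is None:
            atom_matches.append([])
        else:
            atom_matches.append(list(mol.GetSubstructMatches(query, uniquify=True)))
    return McsResult(pattern=pattern, atom_matches=atom_matches,
                     num_atoms=res.numAtoms if res.numAtoms > 0 else 0,
                     num_bonds=res.numBonds if res.numBonds > 0 else 0,
                     completed=not res.canceled)


def _parse_query(query: str) -> Chem.Mol:
    """Parse a substructure query given as a SMILES fragment."""
    if not isinstance(query, str) or not query.strip():
        raise QueryError("empty substructure query")
    qmol = Chem.MolFromSmiles(query)
    if qmol is None:
        raise QueryError(f"unparseable substructure query: {query!r}")
    return qmol


def contains_substructure(smiles: str, query: str) -> tuple[bool, list[tuple[int, ...]]]:
    """Whether the query fragment occurs in the molecule, with all matches.

    Raises :class:`QueryError` for a bad query (distinct from a molecule
    parse error, which raises ``ValueError``).
    """
    qmol = _parse_query(query)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    matches = list(mol.GetSubstructMatches(qmol, uniquify=True))
    return bool(matches), matches


def filter_by_substructure(table, query: str):
    """Rows of the table whose molecule contains the query fragment, in the
    original order. The query is validated once up front."""
    _parse_query(query)
    keep = [i for i, rec in enumerate(table.records)
            if contains_substructure(rec.smiles, query)[0]]
    return table.subset(keep)


@dataclass
class AlignmentResult:
    """2D depiction coordinates per molecule after template alignment."""

    coords: list[np.ndarray | None]
    unaligned: list[int] = field(default_factory=list)


def align_to_template(smiles_list: list[str], template: McsResult) -> AlignmentResult:
    """Lay out each molecule so the template substructure sits on shared
    coordinates.

    Molecules that do not match the template are reported in ``unaligned``
    (their coords entry is a plain unconstrained depiction), not fatal.
    """
    query = template.query_mol
    rdDepictor.Compute2DCoords(query)
    coords: list[np.ndarray | None] = []
    unaligned: list[int] = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        try:
            AllChem.GenerateDepictionMatching2DStructure(mol, query)
        except Exception:
            logger.warning("molecule %d does not match the template; left unaligned", i)
            rdDepictor.Compute2DCoords(mol)
            unaligned.append(i)
        conf = mol.GetConformer()
        xy = np.array([[conf.GetAtomPosition(a).x, conf.GetAtomPosition(a).y]
                       for a in range(mol.GetNumAtoms())])
        coords.append(xy)
    return AlignmentResult(coords=coords, unaligned=unaligned)
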