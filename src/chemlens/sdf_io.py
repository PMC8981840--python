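"""Reading, validating, transforming and writing SDF datasets.

An SDF (V2000) file carries one molecule block per compound plus named data
items. This module maps those files onto two in-memory containers:

``CompoundRecord``
    one molecule with its compound-level scalar properties and its
    atom-level score vectors (one value per heavy atom).

``CompoundTable``
    an ordered collection of records that can be flattened to a pandas
    DataFrame (one row per record) plus column-group metadata and a
    serialized atom-level store kept out of the flat table.

Conventions
-----------
* A data item whose name starts with ``atom.`` holds an atom-level vector:
  a comma/semicolon/whitespace-separated list of decimals, one per heavy
  atom in connection-table order.
* A data item named ``fingerprint`` holds a molecular fingerprint as an
  integer list; the flat table expands it to ``fingerprint_0 ...
  fingerprint_{L-1}``.
* Data items named ``x`` and ``y`` are precomputed 2D projection
  coordinates.
* Explicit hydrogens are removed at parse time; atom counts and attribution
  vectors refer to heavy atoms only.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

#: reserved prefix marking an SDF data item as an atom-level vector
ATOM_PROP_PREFIX = "atom."
#: data item name holding the fingerprint vector
FINGERPRINT_KEY = "fingerprint"
#: data item names holding precomputed projection coordinates
COORD_KEYS = ("x", "y")

_LIST_SPLIT = re.compile(r"[,;\s]+")
_FLOAT_FMT = "%.12g"


class SdfValidationError(ValueError):
    """A record violates a dataset invariant (e.g. atom-vector length)."""


class NamingCollisionError(ValueError):
    """Flat-table expansion would produce duplicate column names."""


def _format_float(v: float) -> str:
    return _FLOAT_FMT % float(v)


def _parse_scalar(text: str) -> Any:
    """Parse a data-item value as float when possible, else keep the string."""
    try:
        return float(text)
    except ValueError:
        return text


def _parse_number_list(text: str) -> np.ndarray:
    parts = [p for p in _LIST_SPLIT.split(text.strip()) if p]
    return np.asarray([float(p) for p in parts], dtype=float)


@dataclass
class CompoundRecord:
    """One compound: structure, scalar properties and atom-level vectors."""

    mol: Chem.Mol
    smiles: str
    compound_props: dict[str, Any] = field(default_factory=dict)
    atom_props: dict[str, np.ndarray] = field(default_factory=dict)
    fingerprint: np.ndarray | None = None
    coords2d: tuple[float, float] | None = None

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    def validate(self, index: int | None = None) -> None:
        """Check the record invariants; raise :class:`SdfValidationError`."""
        n = self.num_heavy_atoms
        where = f"record {index}" if index is not None else "record"
        for name, vec in self.atom_props.items():
            if len(vec) != n:
                raise SdfValidationError(
                    f"{where}: atom property {ATOM_PROP_PREFIX}{name!s} has "
                    f"{len(vec)} values but the molecule has {n} heavy atoms"
                )
        reparsed = Chem.MolFromSmiles(self.smiles)
        if reparsed is None or reparsed.GetNumHeavyAtoms() != n:
            raise SdfValidationError(f"{where}: SMILES does not re-parse to {n} heavy atoms")

    def copy(self) -> "CompoundRecord":
        return CompoundRecord(
            mol=Chem.Mol(self.mol),
            smiles=self.smiles,
            compound_props=dict(self.compound_props),
            atom_props={k: np.array(v, copy=True) for k, v in self.atom_props.items()},
            fingerprint=None if self.fingerprint is None else np.array(self.fingerprint, copy=True),
            coords2d=self.coords2d,
        )


@dataclass
class CompoundTable:
    """Ordered collection of :class:`CompoundRecord` with projection registry."""

    records: list[CompoundRecord] = field(default_factory=list)
    skipped: int = 0
    projections: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def fingerprint_length(self) -> int | None:
        """Dataset-wide declared fingerprint length, or None if absent."""
        lengths = {len(r.fingerprint) for r in self.records if r.fingerprint is not None}
        if not lengths:
            return None
        if len(lengths) > 1:
            raise SdfValidationError(f"inconsistent fingerprint lengths: {sorted(lengths)}")
        return lengths.pop()

    @property
    def has_fingerprints(self) -> bool:
        return any(r.fingerprint is not None for r in self.records)

    def validate(self) -> None:
        for i, rec in enumerate(self.records):
            rec.validate(i)
        self.fingerprint_length  # raises on inconsistency

    def subset(self, indices: Iterable[int]) -> "CompoundTable":
        recs = [self.records[i].copy() for i in indices]
        return CompoundTable(records=recs)

    def copy(self) -> "CompoundTable":
        t = CompoundTable(records=[r.copy() for r in self.records], skipped=self.skipped)
        t.projections = dict(self.projections)
        return t


def record_from_mol(mol: Chem.Mol, index: int | None = None) -> CompoundRecord:
    """Build a validated record from a parsed molecule with data items."""
    mol = Chem.RemoveHs(mol)
    rec = CompoundRecord(mol=mol, smiles=Chem.MolToSmiles(mol))
    coords: dict[str, float] = {}
    for name in mol.GetPropNames():
        raw = mol.GetProp(name)
        if name.startswith(ATOM_PROP_PREFIX):
            rec.atom_props[name[len(ATOM_PROP_PREFIX):]] = _parse_number_list(raw)
        elif name == FINGERPRINT_KEY:
            rec.fingerprint = _parse_number_list(raw).astype(int)
        elif name in COORD_KEYS:
            coords[name] = float(raw)
        else:
            rec.compound_props[name] = _parse_scalar(raw)
    if len(coords) == 2:
        rec.coords2d = (coords["x"], coords["y"])
    rec.validate(index)
    return rec


def read_sdf(path: str | Path) -> CompoundTable:
    """Read a V2000 SDF file into a :class:`CompoundTable`.

    Molecule blocks that fail RDKit sanitization are skipped with a logged
    warning and counted in ``table.skipped``; an atom-level vector whose
    length does not match the heavy-atom count raises
    :class:`SdfValidationError` naming the record and property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    table = CompoundTable()
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("skipping unparseable molecule block %d in %s", i, path)
            table.skipped += 1
            continue
        table.records.append(record_from_mol(mol, index=len(table.records)))
    if table.skipped:
        logger.warning("%d molecule block(s) skipped in %s", table.skipped, path)
    table.fingerprint_length  # raises if inconsistent
    return table


def write_sdf(table: CompoundTable, path: str | Path) -> Path:
    """Write the table as a V2000 SDF encoding all properties.

    Atom-level vectors are written under the ``atom.`` prefix as
    comma-separated decimals; output is byte-stable for identical input.
    """
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for rec in table.records:
            mol = Chem.Mol(rec.mol)
            for name, value in rec.compound_props.items():
                mol.SetProp(name, _format_float(value) if isinstance(value, float) else str(value))
            if rec.fingerprint is not None:
                mol.SetProp(FINGERPRINT_KEY, ",".join(str(int(v)) for v in rec.fingerprint))
            if rec.coords2d is not None:
                mol.SetProp("x", _format_float(rec.coords2d[0]))
                mol.SetProp("y", _format_float(rec.coords2d[1]))
            for name, vec in rec.atom_props.items():
                mol.SetProp(ATOM_PROP_PREFIX + name, ",".join(_format_float(v) for v in vec))
            writer.write(mol)
    finally:
        writer.close()
    return path


def to_flat_table(table: CompoundTable) -> tuple[pd.DataFrame, dict[str, list[str]], dict]:
    """Flatten to (DataFrame, column-group metadata, atom store).

    Scalar compound properties become columns; the fingerprint expands to
    ``fingerprint_0 .. fingerprint_{L-1}``; atom-level vectors are excluded
    from the flat table and returned in the serialized atom store (one entry
    per record, in row order). Raises :class:`NamingCollisionError` if the
    expansion collides with an existing column name.
    """
    rows: list[dict[str, Any]] = []
    groups: dict[str, list[str]] = {}
    fp_len = table.fingerprint_length
    fp_cols = [f"{FINGERPRINT_KEY}_{i}" for i in range(fp_len)] if fp_len else []
    atom_store: dict = {"records": []}
    prop_cols: list[str] = []
    for rec in table.records:
        row: dict[str, Any] = {"smiles": rec.smiles}
        for name, value in rec.compound_props.items():
            if name in fp_cols or name in COORD_KEYS:
                raise NamingCollisionError(f"property column {name!r} collides with a reserved column")
            row[name] = value
            if name not in prop_cols:
                prop_cols.append(name)
        if rec.fingerprint is not None:
            row.update(zip(fp_cols, (int(v) for v in rec.fingerprint)))
        if rec.coords2d is not None:
            row["x"], row["y"] = rec.coords2d
        rows.append(row)
        atom_store["records"].append({name: [float(v) for v in vec] for name, vec in rec.atom_props.items()})
    df = pd.DataFrame(rows)
    groups["smiles"] = ["smiles"]
    if prop_cols:
        groups["properties"] = prop_cols
    if fp_cols and any(c in df.columns for c in fp_cols):
        groups[FINGERPRINT_KEY] = fp_cols
    if "x" in df.columns and "y" in df.columns:
        groups["projection"] = ["x", "y"]
    return df, groups, atom_store


def write_flat_table(table: CompoundTable, basepath: str | Path) -> dict[str, Path]:
    """Persist the flat form: ``<base>.csv`` + ``<base>.groups.json`` sidecar
    + ``<base>.atoms.json`` atom store. Returns the written paths."""
    basepath = Path(basepath)
    df, groups, atom_store = to_flat_table(table)
    paths = {
        "table": basepath.with_suffix(".csv"),
        "groups": basepath.with_suffix(".groups.json"),
        "atoms": basepath.with_suffix(".atoms.json"),
    }
    df.to_csv(paths["table"], index=False)
    paths["groups"].write_text(json.dumps(groups, indent=1))
    paths["atoms"].write_text(json.dumps(atom_store))
    return paths


def read_atom_store(path: str | Path) -> list[dict[str, np.ndarray]]:
    """Read a persisted atom store back to per-record vector maps."""
    data = json.loads(Path(path).read_text())
    return [{k: np.asarray(v, dtype=float) for k, v in entry.items()} for entry in data["records"]]


def augment_fingerprints(table: CompoundTable, n_bits: int = 256, radius: int = 5) -> CompoundTable:
    """Add default fingerprints when the dataset provides none.

    The default is the 256-bit binary Morgan fingerprint at radius 5.
    Datasets that already carry a fingerprint group are returned unchanged
    (the operation is idempotent). Modifies and returns ``table``.
    """
    from .fingerprints import morgan_fingerprint

    if table.has_fingerprints:
        return table
    for i, rec in enumerate(table.records):
        try:
            rec.fingerprint = morgan_fingerprint(rec.smiles, n_bits=n_bits, radius=radius).bits
        except ValueError as exc:
            raise SdfValidationError(f"record {i}: {exc}") from exc
    return table


def from_smiles_table(df: pd.DataFrame, smiles_column: str = "smiles") -> CompoundTable:
    """Build a table from a DataFrame of SMILES + scalar properties.

    Unparseable SMILES rows are skipped with a warning, mirroring
    :func:`read_sdf`.
    """
    table = CompoundTable()
    for i, row in df.iterrows():
        mol = Chem.MolFromSmiles(str(row[smiles_column]))
        if mol is None:
            logger.warning("skipping unparseable SMILES at row %s", i)
            table.skipped += 1
            continue
        rec = CompoundRecord(mol=mol, smiles=Chem.MolToSmiles(mol))
        for col, value in row.items():
            if col != smiles_column and pd.notna(value):
                rec.compound_props[col] = value
        table.records.append(rec)
    return table
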