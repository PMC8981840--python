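"""2D structure depiction with MCS and attribution overlays.

Four list-processing modes mirror the rendering endpoints of the analysis
back-end:

``list``
    one plain structure image per compound;
``mcs_single``
    a single image of the maximum common substructure of the list;
``mcs_highlight``
    one image per compound with the MCS atoms and bonds highlighted in
    bold;
``attribution``
    one image per compound with its per-atom attribution overlaid as a
    smooth colored field — green where the score pushes the prediction up,
    magenta where it pushes it down — with iso-contour lines showing the
    magnitude.

The attribution overlay builds a 2D scalar field as a sum of Gaussian
kernels centered on the atom depiction coordinates and weighted by the atom
scores; kernel width is 0.4 x the median bond length of the depiction, and
contour lines are drawn at +/-{0.25, 0.5, 0.75} of the maximum absolute
field value. Normalization is per compound by default; pass a shared
``max_abs`` for cross-compound comparison on one scale. All renders are
byte-deterministic for identical inputs.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from rdkit import Chem
from rdkit.Chem import rdDepictor
from rdkit.Chem.Draw import rdMolDraw2D

from .attributions import AtomAttribution
from .sdf_io import CompoundTable
from .substructure import McsResult, mcs

GREEN = (0, 160, 70)
MAGENTA = (200, 0, 200)
HIGHLIGHT = (1.0, 0.55, 0.2)  # rdkit rgb triple for MCS highlights
CONTOUR_LEVELS = (0.25, 0.5, 0.75)
KERNEL_BOND_FRACTION = 0.4
DEFAULT_SIZE = 300
MAX_OVERLAY_ALPHA = 110  # out of 255, at |field| = max

RENDER_MODES = ("list", "mcs_single", "mcs_highlight", "attribution")


@dataclass
class RenderRequest:
    """What to render and how."""

    smiles_list: list[str]
    mode: str = "list"
    attribution_name: str | None = None
    image_size: int = DEFAULT_SIZE
    align: bool = False

    def __post_init__(self):
        if self.mode not in RENDER_MODES:
            raise ValueError(f"unknown render mode {self.mode!r}; one of {RENDER_MODES}")
        if self.mode == "attribution" and not self.attribution_name:
            raise ValueError("attribution mode requires attribution_name")


def color_for_score(score: float) -> str:
    """Sign-to-color rule of the attribution overlay: positive scores are
    green, negative magenta, zero neutral."""
    if not math.isfinite(score):
        raise ValueError(f"non-finite score: {score!r}")
    if score > 0:
        return "green"
    if score < 0:
        return "magenta"
    return "neutral"


def _prepare_mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    rdDepictor.Compute2DCoords(mol)
    return mol


def _draw(mol: Chem.Mol, size: int,
          highlight_atoms=None, highlight_bonds=None) -> rdMolDraw2D.MolDraw2DCairo:
    drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
    opts = drawer.drawOptions()
    opts.highlightBondWidthMultiplier = 16  # bold highlight, per-bond emphasis
    kwargs = {}
    if highlight_atoms:
        kwargs["highlightAtoms"] = list(highlight_atoms)
        kwargs["highlightAtomColors"] = {a: HIGHLIGHT for a in highlight_atoms}
    if highlight_bonds:
        kwargs["highlightBonds"] = list(highlight_bonds)
        kwargs["highlightBondColors"] = {b: HIGHLIGHT for b in highlight_bonds}
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol, **kwargs)
    drawer.FinishDrawing()
    return drawer


def _png(image: Image.Image) -> bytes:
    buf = io.BytesIO()
    image.save(buf, format="PNG")
    return buf.getvalue()


def render_structure(smiles: str, size: int = DEFAULT_SIZE) -> bytes:
    """PNG image of the 2D structure. Deterministic bytes per input."""
    mol = _prepare_mol(smiles)
    drawer = _draw(mol, size)
    return _png(Image.open(io.BytesIO(drawer.GetDrawingText())).convert("RGBA"))


def mcs_highlight_spec(smiles_list: list[str],
                       result: McsResult | None = None) -> list[tuple[list[int], list[int]]]:
    """Per-molecule (atom indices, bond indices) to highlight for the MCS.

    Uses the first substructure match per molecule; the atom sets equal the
    MCS matcher's output, which makes the highlight choice directly
    testable.
    """
    if result is None:
        result = mcs(smiles_list)
    query = result.query_mol if result.pattern else None
    spec = []
    for smi, matches in zip(smiles_list, result.atom_matches):
        mol = Chem.MolFromSmiles(smi)
        if not matches or query is None:
            spec.append(([], []))
            continue
        atoms = list(matches[0])
        atom_set = set(atoms)
        bonds = [b.GetIdx() for b in mol.GetBonds()
                 if b.GetBeginAtomIdx() in atom_set and b.GetEndAtomIdx() in atom_set]
        # keep only bonds that exist in the pattern (avoid highlighting
        # molecule bonds between matched atoms that the MCS lacks)
        qbonds = {frozenset((matches[0][qb.GetBeginAtomIdx()], matches[0][qb.GetEndAtomIdx()]))
                  for qb in query.GetBonds()}
        bonds = [b for b in bonds
                 if frozenset((mol.GetBondWithIdx(b).GetBeginAtomIdx(),
                               mol.GetBondWithIdx(b).GetEndAtomIdx())) in qbonds]
        spec.append((atoms, bonds))
    return spec


def _atom_draw_coords(mol: Chem.Mol, drawer: rdMolDraw2D.MolDraw2DCairo) -> np.ndarray:
    pts = [drawer.GetDrawCoords(i) for i in range(mol.GetNumAtoms())]
    return np.array([[p.x, p.y] for p in pts], dtype=float)


def attribution_field(smiles: str, values: np.ndarray, size: int = DEFAULT_SIZE,
                      kernel_fraction: float = KERNEL_BOND_FRACTION):
    """The overlay's scalar field and its sign masks, for inspection.

    Returns ``(field, positive_mask, negative_mask, base_png_bytes)`` where
    ``field`` is a ``size x size`` array (row-major, image orientation).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    values = np.asarray(values, dtype=float)
    if len(values) != mol.GetNumAtoms():
        raise ValueError(
            f"attribution has {len(values)} values but molecule has "
            f"{mol.GetNumAtoms()} heavy atoms"
        )
    # canonical SMILES round trip so the overlay is equivariant under atom
    # relabeling: the same molecule written in any atom order yields the
    # same picture once the score vector is permuted along
    canonical = Chem.MolToSmiles(mol)
    output_order = list(map(int, json.loads(mol.GetProp("_smilesAtomOutputOrder"))))
    mol = Chem.MolFromSmiles(canonical)
    values = values[output_order]
    rdDepictor.Compute2DCoords(mol)
    drawer = _draw(mol, size)
    centers = _atom_draw_coords(mol, drawer)
    bond_px = [np.linalg.norm(centers[b.GetBeginAtomIdx()] - centers[b.GetEndAtomIdx()])
               for b in mol.GetBonds()]
    sigma = kernel_fraction * (np.median(bond_px) if bond_px else size / 10.0)
    yy, xx = np.mgrid[0:size, 0:size]
    field = np.zeros((size, size), dtype=float)
    for (cx, cy), v in zip(centers, values):
        if v == 0.0:
            continue
        field += v * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma ** 2))
    tol = 1e-12 * max(1.0, np.abs(values).max(initial=0.0))
    return field, field > tol, field < -tol, drawer.GetDrawingText()


def render_attribution(smiles: str, aa: AtomAttribution, size: int = DEFAULT_SIZE,
                       max_abs: float | None = None) -> bytes:
    """Structure depiction with the attribution field overlaid.

    Positive regions are filled green, negative magenta, with opacity
    proportional to |field| and contour lines at fixed fractions of the
    maximum absolute value (of this compound, unless a shared ``max_abs``
    is given).
    """
    from skimage import measure

    field, pos, neg, base_png = attribution_field(smiles, aa.values, size=size)
    base = Image.open(io.BytesIO(base_png)).convert("RGBA")
    peak = float(np.abs(field).max()) if max_abs is None else float(max_abs)
    if peak <= 0.0:
        return _png(base)
    overlay = np.zeros((size, size, 4), dtype=np.uint8)
    alpha = np.clip(np.abs(field) / peak, 0.0, 1.0) * MAX_OVERLAY_ALPHA
    for mask, color in ((pos, GREEN), (neg, MAGENTA)):
        overlay[mask, 0] = color[0]
        overlay[mask, 1] = color[1]
        overlay[mask, 2] = color[2]
        overlay[mask, 3] = alpha[mask].astype(np.uint8)
    overlay_img = Image.fromarray(overlay, mode="RGBA")
    draw = ImageDraw.Draw(overlay_img)
    for frac in CONTOUR_LEVELS:
        for level, color in ((frac * peak, GREEN), (-frac * peak, MAGENTA)):
            for contour in measure.find_contours(field, level):
                pts = [(float(c), float(r)) for r, c in contour]
                if len(pts) > 1:
                    draw.line(pts, fill=color + (255,), width=1)
    return _png(Image.alpha_composite(base, overlay_img))


def render_list(req: RenderRequest, table: CompoundTable | None = None):
    """Execute a render request; returns a list of PNG byte strings, or a
    single PNG for ``mcs_single``.

    ``attribution`` mode reads the named atom property from the table's
    records (matched by SMILES order with the request list).
    """
    if req.mode == "list":
        return [render_structure(s, req.image_size) for s in req.smiles_list]
    if req.mode == "mcs_single":
        result = mcs(req.smiles_list)
        if not result.pattern:
            raise ValueError("molecules share no common substructure to depict")
        qmol = Chem.Mol(result.query_mol)
        rdDepictor.Compute2DCoords(qmol)
        drawer = rdMolDraw2D.MolDraw2DCairo(req.image_size, req.image_size)
        drawer.DrawMolecule(qmol)
        drawer.FinishDrawing()
        return _png(Image.open(io.BytesIO(drawer.GetDrawingText())).convert("RGBA"))
    if req.mode == "mcs_highlight":
        result = mcs(req.smiles_list)
        spec = mcs_highlight_spec(req.smiles_list, result)
        images = []
        for smi, (atoms, bonds) in zip(req.smiles_list, spec):
            mol = _prepare_mol(smi)
            drawer = _draw(mol, req.image_size, highlight_atoms=atoms, highlight_bonds=bonds)
            images.append(_png(Image.open(io.BytesIO(drawer.GetDrawingText())).convert("RGBA")))
        return images
    # attribution mode
    if table is None:
        raise ValueError("attribution mode requires the compound table")
    by_smiles = {rec.smiles: rec for rec in table.records}
    images = []
    for smi in req.smiles_list:
        canonical = Chem.CanonSmiles(smi)
        rec = by_smiles.get(canonical)
        if rec is None or req.attribution_name not in rec.atom_props:
            raise KeyError(
                f"compound {smi!r} has no stored atom property {req.attribution_name!r}"
            )
        aa = AtomAttribution(values=rec.atom_props[req.attribution_name],
                             name=req.attribution_name)
        images.append(render_attribution(rec.smiles, aa, size=req.image_size))
    return images
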