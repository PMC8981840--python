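"""Synthetic SDF datasets with known ground truth.

Molecules are built by decorating a set of scaffold templates with
substituent fragments, which guarantees chemically valid SMILES without any
valence repair. Each dataset carries synthetic "measured" and "predicted"
compound scalars, optional fingerprints, and optional per-feature
attribution scores drawn from a sparse linear score model:

    score[f] = (w[f] + jitter) * [bit f set]

with a dataset-wide weight vector ``w`` (sparse Gaussian). Because the
score model is known, the generator can tabulate the exact expected
per-atom attributions and conservation sums by its own independent
summation, giving every downstream module an oracle to test against.

``make_two_group_dataset`` plants two groups with disjoint scaffold
chemistry and group-specific weight vectors, so both fingerprint space and
explanation space separate the groups — the ground truth for projection and
clustering tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .fingerprints import DEFAULT_N_BITS, DEFAULT_RADIUS, FingerprintResult, morgan_fingerprint
from .sdf_io import CompoundRecord, CompoundTable, write_sdf

AROMATIC_TEMPLATES = [
    "c1ccc({R})cc1",          # benzene
    "c1ccnc({R})c1",          # pyridine
    "c1ccc2cc({R})ccc2c1",    # naphthalene
    "c1csc({R})c1",           # thiophene
]
ALIPHATIC_TEMPLATES = [
    "C1CCC({R})CC1",          # cyclohexane
    "C1CC({R})OC1",           # tetrahydrofuran
    "C1CC({R})NC1",           # pyrrolidine
    "C1CC({R})CC1",           # cyclopentane
]
APOLAR_SUBSTITUENTS = ["C", "CC", "CCC", "C(C)C", "Cl", "Br", "F", "C(F)(F)F"]
POLAR_SUBSTITUENTS = ["O", "N", "OC", "NC", "OCC", "NCC", "C(=O)O", "C(=O)N"]

DEFAULT_SCAFFOLDS = AROMATIC_TEMPLATES + ALIPHATIC_TEMPLATES


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; generation is a pure function
    of this spec."""

    n_compounds: int = 20
    seed: int = 0
    scaffold_set: list[str] = field(default_factory=lambda: list(DEFAULT_SCAFFOLDS))
    substituents: list[str] = field(default_factory=lambda: APOLAR_SUBSTITUENTS + POLAR_SUBSTITUENTS)
    with_attributions: bool = True
    with_coords: bool = False
    with_fingerprints: bool = True
    score_sparsity: float = 0.5
    score_scale: float = 1.0
    score_jitter: float = 0.02
    n_bits: int = DEFAULT_N_BITS
    radius: int = DEFAULT_RADIUS


@dataclass
class FixtureTruth:
    """Ground truth recorded during generation."""

    fingerprints: list[FingerprintResult]
    feature_scores: np.ndarray  # n x L, zero where the bit is zero
    atom_attributions: list[np.ndarray]  # expected per-atom sums
    conservation_sums: np.ndarray  # sum_f score[f] * |atom-union(f)| per compound
    labels: np.ndarray | None = None  # planted group labels, if any


@dataclass
class FixtureResult:
    table: CompoundTable
    truth: FixtureTruth


def _decorate(template: str, substituent: str) -> str:
    return template.replace("{R}", substituent)


def _expected_atom_attribution(fp: FingerprintResult, scores: np.ndarray) -> np.ndarray:
    """Independent per-atom summation over the feature-membership table."""
    values = np.zeros(fp.n_atoms)
    for f in range(fp.n_bits):
        if fp.bits[f] == 0 or scores[f] == 0.0:
            continue
        union: set[int] = set()
        for occ in fp.feature_atoms.get(f, []):
            union.update(occ)
        for j in union:
            values[j] += scores[f]
    return values


def _conservation_sum(fp: FingerprintResult, scores: np.ndarray) -> float:
    total = 0.0
    for f in range(fp.n_bits):
        if fp.bits[f] == 0 or scores[f] == 0.0:
            continue
        union: set[int] = set()
        for occ in fp.feature_atoms.get(f, []):
            union.update(occ)
        total += scores[f] * len(union)
    return total


def _build_records(spec: FixtureSpec, rng: np.random.Generator,
                   templates: list[str], substituents: list[str],
                   n: int, weights: np.ndarray,
                   prop_base: float) -> tuple[list[CompoundRecord], list[FingerprintResult],
                                              list[np.ndarray]]:
    records, fps, scores_rows = [], [], []
    for _ in range(n):
        template = templates[int(rng.integers(len(templates)))]
        sub = substituents[int(rng.integers(len(substituents)))]
        smiles = _decorate(template, sub)
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"scaffold decoration produced invalid SMILES: {smiles}"
        rec = CompoundRecord(mol=mol, smiles=Chem.MolToSmiles(mol))
        measured = prop_base + float(rng.normal(0.0, 1.0))
        rec.compound_props["measured"] = measured
        rec.compound_props["predicted"] = measured + float(rng.normal(0.0, 0.1))
        fp = morgan_fingerprint(rec.smiles, n_bits=spec.n_bits, radius=spec.radius)
        if spec.with_fingerprints:
            rec.fingerprint = fp.bits
        scores = np.zeros(spec.n_bits)
        if spec.with_attributions:
            on = fp.bits != 0
            jitter = rng.normal(0.0, spec.score_jitter, spec.n_bits)
            scores[on] = weights[on] + jitter[on]
            rec.atom_props["shap"] = _expected_atom_attribution(fp, scores)
        records.append(rec)
        fps.append(fp)
        scores_rows.append(scores)
    return records, fps, scores_rows


def _sparse_weights(rng: np.random.Generator, n_bits: int, sparsity: float,
                    scale: float) -> np.ndarray:
    mask = rng.random(n_bits) >= sparsity
    return rng.normal(0.0, scale, n_bits) * mask


def generate(spec: FixtureSpec) -> FixtureResult:
    """Generate one synthetic dataset per the spec (deterministic)."""
    if not spec.scaffold_set:
        raise ValueError("empty scaffold set")
    if spec.n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    rng = np.random.default_rng(spec.seed)
    weights = _sparse_weights(rng, spec.n_bits, spec.score_sparsity, spec.score_scale)
    records, fps, scores_rows = _build_records(
        spec, rng, spec.scaffold_set, spec.substituents, spec.n_compounds,
        weights, prop_base=0.0)
    table = CompoundTable(records=records)
    if spec.with_coords:
        for rec, (x, y) in zip(records, rng.uniform(0.0, 1.0, size=(len(records), 2))):
            rec.coords2d = (float(x), float(y))
    scores = np.vstack(scores_rows)
    truth = FixtureTruth(
        fingerprints=fps,
        feature_scores=scores,
        atom_attributions=[_expected_atom_attribution(fp, s) for fp, s in zip(fps, scores)],
        conservation_sums=np.array([_conservation_sum(fp, s) for fp, s in zip(fps, scores)]),
    )
    return FixtureResult(table=table, truth=truth)


def make_two_group_dataset(n_per_group: int, seed: int = 0,
                           spec: FixtureSpec | None = None) -> FixtureResult:
    """Two scaffold families with disjoint substituent chemistry.

    Group 0 is aromatic scaffolds with apolar substituents, group 1
    aliphatic scaffolds with polar substituents; each group has its own
    sparse weight vector, so explanation similarity separates the groups as
    well as fingerprint similarity does.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    w0 = _sparse_weights(rng, spec.n_bits, spec.score_sparsity, spec.score_scale)
    w1 = _sparse_weights(rng, spec.n_bits, spec.score_sparsity, spec.score_scale)
    rec0, fp0, s0 = _build_records(spec, rng, AROMATIC_TEMPLATES, APOLAR_SUBSTITUENTS,
                                   n_per_group, w0, prop_base=-2.0)
    rec1, fp1, s1 = _build_records(spec, rng, ALIPHATIC_TEMPLATES, POLAR_SUBSTITUENTS,
                                   n_per_group, w1, prop_base=2.0)
    table = CompoundTable(records=rec0 + rec1)
    fps = fp0 + fp1
    scores = np.vstack(s0 + s1)
    truth = FixtureTruth(
        fingerprints=fps,
        feature_scores=scores,
        atom_attributions=[_expected_atom_attribution(fp, s) for fp, s in zip(fps, scores)],
        conservation_sums=np.array([_conservation_sum(fp, s) for fp, s in zip(fps, scores)]),
        labels=np.array([0] * n_per_group + [1] * n_per_group),
    )
    return FixtureResult(table=table, truth=truth)


def write_fixture(result: FixtureResult, basepath: str | Path) -> dict[str, Path]:
    """Persist a fixture: SDF plus truth CSVs (feature scores, expected atom
    attributions, conservation sums, labels when planted)."""
    basepath = Path(basepath)
    paths = {"sdf": basepath.with_suffix(".sdf")}
    write_sdf(result.table, paths["sdf"])
    truth = result.truth
    paths["scores"] = basepath.with_suffix(".scores.csv")
    pd.DataFrame(truth.feature_scores).to_csv(paths["scores"], index=False)
    paths["conservation"] = basepath.with_suffix(".conservation.csv")
    df = pd.DataFrame({"conservation_sum": truth.conservation_sums})
    if truth.labels is not None:
        df["group"] = truth.labels
    df.to_csv(paths["conservation"], index=False)
    return paths
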