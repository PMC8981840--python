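"""Mapping per-feature attribution scores onto atoms.

Feature-attribution methods such as SHAP explain a prediction as one score
per input feature — here, per fingerprint feature. Chemists reason about
atoms, not hashed bits, so each feature's score is spread onto the atoms
that represent that feature and summed per atom: for atom ``j``,

    value[j] = sum over features f (bit set, score nonzero, j in atoms(f))
               of score[f]

Each feature's score is added once per atom in the *union* of its
occurrence sets, not once per occurrence; this keeps the map linear in the
feature scores and avoids double-counting overlapping occurrences of the
same feature. A ``per_occurrence`` mode is available for sensitivity
analysis. Scores carry the units of the explained target, and so do the
resulting atom attributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fingerprints import FingerprintResult
from .sdf_io import CompoundRecord

logger = logging.getLogger(__name__)


@dataclass
class FeatureAttribution:
    """One score per fingerprint feature for one explained output."""

    scores: np.ndarray
    target_name: str = "prediction"
    units: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class AtomAttribution:
    """One score per heavy atom."""

    values: np.ndarray
    name: str = "attribution"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class ConservationReport:
    """Result of checking that per-atom sums match the feature-side total."""

    atom_sum: float
    feature_sum: float
    tolerance: float
    passed: bool = field(init=False)

    def __post_init__(self):
        self.passed = abs(self.atom_sum - self.feature_sum) <= self.tolerance


def map_features_to_atoms(
    fp: FingerprintResult,
    fa: FeatureAttribution,
    mode: str = "union",
    name: str | None = None,
) -> AtomAttribution:
    """Aggregate feature scores into one score per atom.

    Only features whose fingerprint value is nonzero contribute; a nonzero
    score on a zero feature is ignored with a warning (it cannot be placed
    on any atoms). ``mode`` is ``"union"`` (default; score added once per
    atom in the union of the feature's occurrence sets) or
    ``"per_occurrence"`` (added once per occurrence containing the atom).
    """
    if len(fa.scores) != fp.n_bits:
        raise ValueError(
            f"score vector length {len(fa.scores)} does not match fingerprint length {fp.n_bits}"
        )
    if mode not in ("union", "per_occurrence"):
        raise ValueError(f"unknown mode {mode!r}")
    values = np.zeros(fp.n_atoms, dtype=float)
    stray = [f for f in np.nonzero(np.abs(fa.scores) > 1e-12)[0] if fp.bits[f] == 0]
    if stray:
        logger.warning(
            "%d nonzero score(s) on zero fingerprint features ignored (first: %d)",
            len(stray), stray[0],
        )
    for f in np.nonzero(fp.bits)[0]:
        s = fa.scores[f]
        if s == 0.0:
            continue
        if mode == "union":
            for j in fp.atom_union(int(f)):
                values[j] += s
        else:
            for occurrence in fp.feature_atoms.get(int(f), []):
                for j in occurrence:
                    values[j] += s
    return AtomAttribution(values=values, name=name or fa.target_name)


def conservation_check(
    fp: FingerprintResult,
    fa: FeatureAttribution,
    aa: AtomAttribution,
    tolerance: float = 1e-9,
) -> ConservationReport:
    """Verify that the atom-side total equals the feature-side total.

    For the union mapping, summing the atom vector must give
    ``sum_f score[f] * |atom-union(f)|`` over contributing features — a
    direct corollary of the mapping definition, useful as an integrity
    check after I/O round trips.
    """
    feature_sum = 0.0
    for f in np.nonzero(fp.bits)[0]:
        if fa.scores[f] != 0.0:
            feature_sum += fa.scores[f] * len(fp.atom_union(int(f)))
    return ConservationReport(atom_sum=float(aa.values.sum()),
                              feature_sum=float(feature_sum),
                              tolerance=tolerance)


def attach_attribution(
    record: CompoundRecord,
    aa: AtomAttribution,
    overwrite: bool = False,
) -> CompoundRecord:
    """Store an atom attribution on a record as atom property ``atom.<name>``.

    Overwriting an existing name requires ``overwrite=True``.
    """
    if len(aa.values) != record.num_heavy_atoms:
        raise ValueError(
            f"attribution has {len(aa.values)} values but molecule has "
            f"{record.num_heavy_atoms} heavy atoms"
        )
    if aa.name in record.atom_props and not overwrite:
        raise ValueError(f"atom property {aa.name!r} already exists (pass overwrite=True)")
    record.atom_props[aa.name] = np.array(aa.values, copy=True)
    return record
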