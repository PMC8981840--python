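# Methods

This note documents the models and procedures implemented in `chemlens`,
the parameter choices that matter, what the synthetic data generator does
and does not emulate, and the numerical conventions pinned for
reproducibility.

## Data model and SDF conventions

A dataset is an ordered list of compounds, each with a structure, scalar
compound-level properties, and optional atom-level vectors (one real value
per heavy atom, in connection-table order). On disk this is a V2000 SDF
with three reserved data-item conventions:

* `atom.<name>` — an atom-level vector as a comma/semicolon/whitespace
  separated decimal list. The `atom.` prefix is this package's convention;
  it is self-describing and V2000-safe.
* `fingerprint` — an integer list holding the fingerprint vector.
* `x`, `y` — precomputed 2D projection coordinates.

Explicit hydrogens are removed at parse time; all atom counts, fingerprint
environments and attribution vectors refer to heavy atoms only, matching
standard depiction and fingerprint conventions. Unparseable molecule
blocks are skipped with a logged warning rather than aborting the load —
large screening files routinely contain a few bad records — while an
atom-level vector of the wrong length is treated as a hard validation
error, because silently mis-aligned attributions are worse than a failed
load.

The flat form of a dataset is a CSV (one row per compound, fingerprint
expanded to `fingerprint_0…fingerprint_{L-1}`) plus a JSON sidecar naming
the column groups and a JSON atom store holding the atom-level vectors,
which cannot live in a rectangular table because their length varies per
compound. Floats are serialized with 12 significant digits, giving
round-trip errors well below the 1e-9 tolerance asserted in tests.

## Fingerprints and feature→atom maps

The default fingerprint — added automatically whenever a dataset provides
none — is the 256-bit binary Morgan fingerprint with radius 5. Each set
bit records its generating environments as atom sets (center atom plus all
atoms within the environment radius); folding collisions are accepted, and
a collided bit maps to the union of the occurrence lists of all colliding
environments, since a score attached to that bit cannot be split between
them. Chirality flags are not hashed (achiral default). MACCS keys are
exposed as 166 features (RDKit's unused index 0 dropped; feature *j* is
key *j*+1) with per-key substructure matches as the atom sets; the few
count-based keys without a SMARTS definition contribute no atoms and are
logged. Concatenation offsets the second fingerprint's feature indices so
combined Morgan+MACCS feature vectors keep a well-defined atom map.

## Attribution mapping

Feature scores are spread onto atoms by summation: atom *j* receives the
score of every nonzero feature whose atom set contains *j*. Two readings
of "the atoms that represent a feature" are possible for features that
occur more than once; the default adds each feature's score **once per
atom in the union of its occurrences**, which keeps the map linear in the
bit-level scores and avoids double-counting overlapping occurrences of the
same feature. The alternative (`per_occurrence`) is available for
sensitivity analysis. Scores on features whose fingerprint value is zero
are ignored with a warning when they exceed 1e-12 — they have no atom set
to land on. The conservation identity
Σ_j a_j = Σ_f φ_f·|atoms(f)| follows directly from the union rule and is
exposed as a checkable report (tolerance 1e-9).

## Embeddings

UMAP produces all 2D embeddings; defaults are n_neighbors = 15 (clamped to
n−1 for small datasets), min_dist = 0.1, and a fixed default seed of 42 so
CLI runs are reproducible without flags. Standardization, when requested,
scales each column to zero mean and unit **population** variance (the
n-denominator; immaterial at realistic n but pinned for exact tests), with
constant columns mapped to zeros under a warning. Datasets with neither
coordinates nor a computed projection can be given uniform random positions
in the unit square from the run seed.

Explanation space uses the Spearman rank correlation ρ between
per-compound feature-score rows and the distance d = 1 − ρ (range [0, 2])
with UMAP's precomputed metric. 1 − ρ is the simplest monotone distance
derived from a correlation; neither (1−ρ)/2 nor √(1−ρ) changes the
neighborhood structure that UMAP consumes, so only 1 − ρ is implemented.
A score row with zero variance has no defined ranks-correlation; its
off-diagonal entries are set to ρ = 0 (d = 1) with a warning rather than
propagating NaNs.

## Grouping

HDBSCAN (scikit-learn implementation) clusters the 2D coordinates; points
outside any dense region get the label −1 and non-noise labels are
renumbered contiguously in order of first appearance. The default
`min_cluster_size = max(5, n // 100)` keeps small datasets from
fragmenting while scaling weakly with n; it is exposed everywhere. A
cluster's report comprises its member count and the members' MCS, the same
summary a grouped compound column would show.

## Substructures

The MCS is the largest common **connected** substructure with atoms
compared by element and bonds by bond order; ring bonds are required to
match ring bonds by default (so an open chain never "summarizes" a ring
system), and each call is bounded by a 5 s timeout returning the
best-so-far with a `completed` flag. All options are exposed. When several
co-optimal MCSs exist, the bond-maximizing deterministic search order of
the underlying matcher decides; re-running is reproducible. Substructure
filter queries are parsed as SMILES fragments with default aromaticity
perception (the query language users type is SMILES, not SMARTS), and
filtering preserves row order. Template alignment lays out the template
pattern once and constrains each matching molecule's depiction to it, so
matched atoms coincide across the list; non-matching molecules are
reported as unaligned and depicted freely instead of failing the batch.

## Depiction

Rendering uses the Cairo backend at 300×300 px by default (PNG out;
deterministic bytes for identical inputs). The attribution overlay builds
a scalar field as a sum of isotropic Gaussian kernels at the atom
depiction positions, weighted by the atom scores, with kernel width
σ = 0.4 × the median bond length in pixel coordinates — wide enough to
read as a region, narrow enough not to bleed across the molecule. Positive
field regions are filled green and negative magenta with opacity
proportional to |field|, and iso-contour lines are drawn at ±{0.25, 0.5,
0.75} of the maximum |field|. Normalization is per compound by default so
each molecule is legible in isolation; a shared `max_abs` can be passed to
compare several compounds on one scale. The exact kernel fraction and
contour levels are conventions of this package, pinned so renders are
byte-stable under test. The overlay path canonicalizes the atom order (via
a canonical-SMILES round trip, permuting the score vector along), which
makes the picture invariant to how the input SMILES happens to be written.

## Synthetic data generator

Fixtures are built by decorating scaffold templates (benzene, pyridine,
naphthalene, thiophene; cyclohexane, THF, pyrrolidine, cyclopentane) with
substituent fragments at a fixed attachment point — template decoration
guarantees valid chemistry without a valence-repair pass. Each compound
gets a synthetic measured value (unit-variance Gaussian around a scaffold
family baseline) and a prediction (measured + Gaussian noise, σ = 0.1),
emulating a well-fitted model. Feature scores follow a sparse linear
model: a dataset-wide weight vector (50 % of features zeroed, remaining
weights standard normal) evaluated on each compound's set bits plus a
small per-compound jitter (σ = 0.02), so compounds sharing scaffold
chemistry have rank-similar score vectors. The two-group dataset uses
disjoint scaffold/substituent families *and* independent weight vectors,
so fingerprint space and explanation space both separate the groups.

Because the generator records feature memberships and computes expected
atom attributions by its own summation loop, it provides exact oracles for
the mapping, conservation, projection and clustering tests. What it does
**not** emulate: realistic activity distributions, activity cliffs,
measurement heteroscedasticity, fingerprint collisions at production bit
widths beyond what 256 bits produces, or SHAP vectors from a real model
(whose scores are not linear in the bits). Passing tests therefore
demonstrate correctness of the machinery, not performance claims about any
particular model or assay.

Problem sizes in the test and acceptance runs (500 compounds for the
projection contract, 100 for conservation and for planted-group recovery
across 5 seeds, 30 for round trips, 8-molecule panel for brute-force MCS)
were chosen as the smallest sizes at which each property is
non-trivially exercised at desk scale.

## Known limitations

* V3000 SDF, reaction files and 3D conformers are out of scope; files are
  read eagerly (no streaming for multi-GB inputs).
* Only UMAP and HDBSCAN are offered for projection and clustering;
  precomputed coordinates or labels can be supplied in the SDF instead.
* Disconnected MCS and fuzzy (MCES) matching are not implemented.
* Attribution scores are consumed, never computed: explaining a model
  (SHAP, CAM, …) happens upstream.
* Aggregating attributions across compounds is deliberately left out; the
  per-compound overlay with an optional shared scale is the supported
  comparison mechanism.
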