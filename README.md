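# chemlens

A headless Python library and CLI for exploring chemical datasets that
carry model predictions and atom-level XAI attributions.

Modern QSAR/property models are usually explained at the level of their
input features — for a fingerprint-based model, one SHAP value per hashed
fingerprint bit. Chemists, however, reason about atoms and substructures.
`chemlens` bridges that gap for anyone analyzing such models (medicinal and
computational chemists, ML practitioners in drug discovery): it ingests SDF
datasets, maps feature-level attribution scores back onto atoms, embeds
both chemical space and *explanation* space into 2D, groups compounds,
summarizes groups by their maximum common substructure, and renders
structure depictions with attribution overlays.

## The core computations

**Feature→atom attribution mapping.** A folded Morgan fingerprint assigns
each set bit *f* a collection of atom environments. Given feature scores
φ_f (e.g. tree-SHAP values, in the units of the predicted target), the
attribution of atom *j* is

    a_j = Σ_{f : x_f ≠ 0, j ∈ atoms(f)} φ_f

where atoms(f) is the union of the atom sets of all occurrences of feature
*f* (including hash collisions). The map is linear in φ and satisfies the
conservation identity Σ_j a_j = Σ_f φ_f·|atoms(f)|, which the package
checks automatically.

**Explanation-space embedding.** Compounds are compared by the Spearman
rank correlation ρ of their feature-score vectors; the distance d = 1 − ρ
feeds a UMAP embedding with a precomputed metric, so compounds whose
predictions are explained *similarly* cluster together — typically more
informative than Tanimoto similarity of the fingerprints themselves.
Chemical-space embeddings (UMAP on fingerprints, latent vectors or
descriptors, optionally standardized to zero mean/unit variance) and
HDBSCAN grouping of any 2D embedding complete the picture.

**Structure rendering.** Four modes: plain image lists, a single image of
the maximum common substructure (MCS), per-compound images with the MCS
highlighted in bold, and attribution overlays where positive atom scores
are shaded green and negative magenta, with iso-contour lines encoding
magnitude.

## Worked example

A synthetic dataset with two planted scaffold families (aromatic/apolar
vs. aliphatic/polar), projected, clustered, filtered and summarized:

```bash
chemlens fixtures --n 40 --seed 1 --two-group --out demo
chemlens project --in demo.sdf --attrs fingerprint --seed 0 --name chemspace --out projected.sdf
chemlens cluster --in projected.sdf --min-cluster-size 8 --out clustered.sdf
chemlens filter  --in clustered.sdf --query c1ccccc1 --out aromatic.sdf
chemlens mcs     --in aromatic.sdf
```

prints

```
80 compounds -> demo.sdf
projection 'chemspace' (80 x 2) -> projected.sdf
3 cluster(s) -> clustered.sdf
14/80 compounds match -> aromatic.sdf
[#6]1:&@[#6]:&@[#6]:&@[#6]:&@[#6]:&@[#6]:&@1  (6 atoms, 6 bonds, completed=True)
```

`demo.sdf` holds 80 compounds (40 per group) with fingerprints, synthetic
measured/predicted values and per-atom attribution vectors (`atom.shap`
data items). The projection writes one (x, y) pair per compound; HDBSCAN
finds the dense groups in that plane (here three: the planted families
split along scaffold subtypes at this cluster size); the substructure
filter keeps the 14 benzene-containing compounds, whose MCS is — as it
should be — the benzene ring itself. `chemlens render --mode attribution
--attribution shap --out-dir imgs` then draws each compound with its
green/magenta attribution overlay.

The same steps are available as library functions (`chemlens.generate`,
`project`, `project_explanations`, `cluster`, `filter_by_substructure`,
`mcs`, `render_list`); see `docs/methods.md` for the underlying models and
parameter choices.

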