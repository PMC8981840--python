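import numpy as np
import pytest
from rdkit import Chem
from sklearn.metrics import silhouette_score

from chemlens import (
    project,
    project_explanations,
    spearman_distances,
    standardize,
)
from chemlens.sdf_io import CompoundRecord, CompoundTable

from _oracles import spearman_rho_oracle


def _blob_table(n_per_blob=50, n_features=8, sd=0.01, sep=10.0, seed=0):
    """Two tight blobs in feature space, stored as compound properties."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((2, n_features))
    centers[1, :] = sep / np.sqrt(n_features)
    records, labels = [], []
    for g in range(2):
        for _ in range(n_per_blob):
            rec = CompoundRecord(mol=Chem.MolFromSmiles("C"), smiles="C")
            x = centers[g] + rng.normal(0.0, sd, n_features)
            rec.compound_props.update({f"p{i}": float(v) for i, v in enumerate(x)})
            records.append(rec)
            labels.append(g)
    return CompoundTable(records=records), np.array(labels)


def test_standardize_closed_form():
    out = standardize(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(out[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-3)


def test_standardize_constant_column_maps_to_zeros(caplog):
    with caplog.at_level("WARNING"):
        out = standardize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
    np.testing.assert_array_equal(out[:, 0], np.zeros(3))
    assert any("constant" in r.message for r in caplog.records)


def test_standardize_is_idempotent():
    rng = np.random.default_rng(0)
    X = rng.normal(2.0, 3.0, (20, 4))
    once = standardize(X)
    np.testing.assert_allclose(standardize(once), once, atol=1e-9)
    assert np.allclose(once.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(once.std(axis=0), 1.0, atol=1e-12)


def test_standardize_rejects_single_row():
    with pytest.raises(ValueError):
        standardize(np.ones((1, 3)))


def test_spearman_duplicated_row_has_zero_distance():
    S = np.array([[1.0, 5.0, 3.0, 2.0], [1.0, 5.0, 3.0, 2.0], [9.0, 1.0, 4.0, 4.0]])
    dm = spearman_distances(S)
    assert dm.rho[0, 1] == pytest.approx(1.0)
    assert dm.dist[0, 1] == pytest.approx(0.0)


def test_spearman_reversed_ranks_give_distance_two():
    dm = spearman_distances(np.array([[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0]]))
    assert dm.rho[0, 1] == pytest.approx(-1.0)
    assert dm.dist[0, 1] == pytest.approx(2.0)


def test_spearman_matrix_invariants_and_oracle_agreement():
    rng = np.random.default_rng(7)
    for _ in range(5):
        S = rng.normal(size=(5, 6))
        dm = spearman_distances(S)
        np.testing.assert_allclose(dm.rho, dm.rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.rho), 1.0, atol=1e-12)
        np.testing.assert_allclose(dm.dist, 1.0 - dm.rho, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.dist), 0.0, atol=1e-12)
        np.testing.assert_allclose(dm.rho, spearman_rho_oracle(S), atol=1e-9)


def test_spearman_zero_variance_row_gets_unit_distance(caplog):
    S = np.array([[2.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 4.0], [4.0, 1.0, 2.0, 3.0]])
    with caplog.at_level("WARNING"):
        dm = spearman_distances(S)
    assert dm.rho[0, 1] == 0.0 and dm.dist[0, 1] == 1.0
    assert dm.rho[0, 0] == 1.0 and dm.dist[0, 0] == 0.0
    assert any("zero-variance" in r.message for r in caplog.records)


def test_projection_shape_registry_and_determinism():
    table, _ = _blob_table(n_per_blob=10, seed=1)
    r1 = project(table, attribute_groups=["properties"], seed=0, name="a")
    assert r1.coords.shape == (20, 2)
    assert np.isfinite(r1.coords).all()
    assert table.projections["a"] is r1
    table2, _ = _blob_table(n_per_blob=10, seed=1)
    r2 = project(table2, attribute_groups=["properties"], seed=0, name="a")
    np.testing.assert_array_equal(r1.coords, r2.coords)
    with pytest.raises(ValueError, match="already stored"):
        project(table, attribute_groups=["properties"], seed=0, name="a")


def test_projection_separates_planted_blobs():
    table, labels = _blob_table(n_per_blob=50, sd=0.01, sep=10.0, seed=0)
    result = project(table, attribute_groups=["properties"], seed=0, name="blobs")
    assert silhouette_score(result.coords, labels) > 0.5


def test_projection_input_validation():
    table, _ = _blob_table(n_per_blob=2)
    table.records = table.records[:3]
    with pytest.raises(ValueError, match="at least 4"):
        project(table, attribute_groups=["properties"], name="tiny")
    full, _ = _blob_table(n_per_blob=5)
    full.records[0].compound_props["tag"] = "not-a-number"
    with pytest.raises(TypeError, match="non-numeric"):
        project(full, attribute_groups=["properties"], name="bad")


def test_explanation_projection_groups_similar_score_rows():
    rng = np.random.default_rng(0)
    base = rng.normal(size=(2, 30))
    rows = np.vstack([base[i // 20] + rng.normal(0.0, 1e-3, 30) for i in range(40)])
    table, _ = _blob_table(n_per_blob=20, seed=5)
    result = project_explanations(table, rows, seed=0, name="expl")
    assert result.coords.shape == (40, 2)
    a, b = result.coords[:20], result.coords[20:]
    between = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
    within = np.mean([np.linalg.norm(g - g.mean(axis=0), axis=1).mean() for g in (a, b)])
    assert between > within


def test_explanation_projection_checks_row_alignment():
    table, _ = _blob_table(n_per_blob=5)
    with pytest.raises(ValueError, match="rows"):
        project_explanations(table, np.zeros((3, 10)), name="misaligned")
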