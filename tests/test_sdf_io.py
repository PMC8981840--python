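import numpy as np
import pytest
from rdkit import Chem

from chemlens import (
    CompoundRecord,
    FixtureSpec,
    SdfValidationError,
    augment_fingerprints,
    from_smiles_table,
    generate,
    read_sdf,
    to_flat_table,
    write_flat_table,
    write_sdf,
)
from chemlens.sdf_io import read_atom_store
import pandas as pd


def _make_sdf_text(smiles: str, props: dict[str, str]) -> str:
    mol = Chem.MolFromSmiles(smiles)
    block = Chem.MolToMolBlock(mol)
    items = "".join(f">  <{k}>\n{v}\n\n" for k, v in props.items())
    return block + items + "$$$$\n"


def test_read_preserves_record_count_and_order(small_fixture, tmp_path):
    path = write_sdf(small_fixture.table, tmp_path / "d.sdf")
    table = read_sdf(path)
    assert len(table) == len(small_fixture.table)
    assert table.smiles == small_fixture.table.smiles


def test_atom_property_length_mismatch_names_record_and_property(tmp_path):
    text = _make_sdf_text("CCCCCC", {"atom.shap": "0.1,0.2,0.3,0.4,0.5"})
    path = tmp_path / "bad.sdf"
    path.write_text(text)
    with pytest.raises(SdfValidationError, match=r"record 0.*atom\.shap.*5 values.*6 heavy"):
        read_sdf(path)


def test_unparseable_block_is_skipped_with_count(tmp_path):
    good = _make_sdf_text("CCO", {"p": "1.0"})
    bad = good.replace("C   0", "Xx  0", 1)  # corrupt one atom symbol
    path = tmp_path / "mix.sdf"
    path.write_text(good + bad + good)
    table = read_sdf(path)
    assert len(table) == 2
    assert table.skipped == 1


def test_round_trip_identity(small_fixture, tmp_path):
    p1 = write_sdf(small_fixture.table, tmp_path / "a.sdf")
    t1 = read_sdf(p1)
    p2 = write_sdf(t1, tmp_path / "b.sdf")
    t2 = read_sdf(p2)
    assert t1.smiles == t2.smiles == small_fixture.table.smiles
    for r0, r1 in zip(small_fixture.table.records, t2.records):
        for k, v in r0.compound_props.items():
            assert r1.compound_props[k] == pytest.approx(v, abs=1e-9)
        for k, v in r0.atom_props.items():
            np.testing.assert_allclose(r1.atom_props[k], v, atol=1e-9)
        np.testing.assert_array_equal(r1.fingerprint, r0.fingerprint)


def test_write_is_byte_stable(small_fixture, tmp_path):
    p1 = write_sdf(small_fixture.table, tmp_path / "a.sdf")
    p2 = write_sdf(small_fixture.table, tmp_path / "b.sdf")
    assert p1.read_bytes() == p2.read_bytes()


def test_flat_table_expansion_and_groups(small_fixture):
    df, groups, atom_store = to_flat_table(small_fixture.table)
    L = small_fixture.table.fingerprint_length
    assert groups["fingerprint"] == [f"fingerprint_{i}" for i in range(L)]
    assert {"measured", "predicted"} <= set(groups["properties"])
    assert len(df) == len(small_fixture.table)
    assert df["smiles"].tolist() == small_fixture.table.smiles  # row order
    # atom-level vectors are excluded from the flat table, kept in the store
    assert not any(c.startswith("atom.") or c == "shap" for c in df.columns)
    assert len(atom_store["records"]) == len(df)


def test_precomputed_coords_become_projection_group():
    res = generate(FixtureSpec(n_compounds=5, seed=1, with_coords=True))
    df, groups, _ = to_flat_table(res.table)
    assert groups["projection"] == ["x", "y"]
    assert df["x"].notna().all()


def test_atom_store_round_trips_losslessly(small_fixture, tmp_path):
    paths = write_flat_table(small_fixture.table, tmp_path / "flat")
    store = read_atom_store(paths["atoms"])
    for rec, entry in zip(small_fixture.table.records, store):
        for name, vec in rec.atom_props.items():
            np.testing.assert_allclose(entry[name], vec, atol=1e-9)


def test_augment_adds_256_bit_fingerprints_when_absent():
    res = generate(FixtureSpec(n_compounds=6, seed=2, with_fingerprints=False,
                               with_attributions=False))
    assert not res.table.has_fingerprints
    augment_fingerprints(res.table)
    assert all(len(r.fingerprint) == 256 for r in res.table.records)
    assert all(set(np.unique(r.fingerprint)) <= {0, 1} for r in res.table.records)


def test_augment_leaves_existing_fingerprints_untouched():
    res = generate(FixtureSpec(n_compounds=4, seed=2, n_bits=2048))
    before = [r.fingerprint.copy() for r in res.table.records]
    augment_fingerprints(res.table)
    for b, r in zip(before, res.table.records):
        np.testing.assert_array_equal(r.fingerprint, b)
        assert len(r.fingerprint) == 2048


def test_augment_is_idempotent_and_deterministic():
    res = generate(FixtureSpec(n_compounds=6, seed=4, with_fingerprints=False,
                               with_attributions=False))
    augment_fingerprints(res.table)
    once = [r.fingerprint.copy() for r in res.table.records]
    augment_fingerprints(res.table)
    for a, r in zip(once, res.table.records):
        np.testing.assert_array_equal(r.fingerprint, a)
    # identical SMILES get identical fingerprints
    by_smiles = {}
    for r in res.table.records:
        if r.smiles in by_smiles:
            np.testing.assert_array_equal(r.fingerprint, by_smiles[r.smiles])
        by_smiles[r.smiles] = r.fingerprint


def test_from_smiles_table_skips_bad_rows():
    df = pd.DataFrame({"smiles": ["CCO", "not_a_smiles", "c1ccccc1"], "pred": [1.0, 2.0, 3.0]})
    table = from_smiles_table(df)
    assert len(table) == 2
    assert table.skipped == 1
    assert table.records[0].compound_props["pred"] == 1.0


def test_record_validation_rejects_wrong_length_vector():
    rec = CompoundRecord(mol=Chem.MolFromSmiles("CCO"), smiles="CCO")
    rec.atom_props["q"] = np.array([1.0, 2.0])
    with pytest.raises(SdfValidationError):
        rec.validate(0)
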