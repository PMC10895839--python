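"""Data model, curation pipeline, splits, and I/O round trips."""

import numpy as np
import pytest

from rxnmvp.chem_data import (
    ConfigError, DatasetIOError, Molecule, Reaction, ReactionDataset,
    ReactionParseError, SplitError, ValidityError,
    attach_conformers, canonicalize_reaction, deduplicate_dataset,
    etkdg_embedder, filter_by_yield, load_dataset, parse_reaction_smiles,
    split_by_component, stratified_split, write_dataset,
)


def rxn(text, y=None, rid="r"):
    return parse_reaction_smiles(text, yield_pct=y, record_id=rid)


# -- parsing ----------------------------------------------------------------

def test_parse_reaction_smiles_roles():
    r = rxn("CCO.CC(=O)O>[H+]>CCOC(C)=O")
    assert [m.smiles for m in r.reactants] == ["CCO", "CC(=O)O"]
    assert [m.smiles for m in r.agents] == ["[H+]"]
    assert [m.smiles for m in r.products] == ["CCOC(C)=O"]


def test_parse_empty_agents_field():
    assert rxn("CCO>>CC=O").agents == ()


@pytest.mark.parametrize("bad", ["CCO>CC=O", "CCO>>CC=O>C", ">>CCO", "CCO>>",
                                 "X#Q>>CCO"])
def test_parse_errors(bad):
    with pytest.raises(ReactionParseError):
        rxn(bad)


def test_canonicalize_sorts_roles_and_is_idempotent():
    r = rxn("OCC.CC(=O)O>>CCOC(C)=O")   # OCC canonicalizes to CCO
    c = canonicalize_reaction(r)
    assert [m.smiles for m in c.reactants] == ["CC(=O)O", "CCO"]
    assert canonicalize_reaction(c) == c


# -- dedup ------------------------------------------------------------------

def test_dedup_collapses_permuted_reactants_and_prefers_yield():
    d = ReactionDataset([
        rxn("CCO.CCN>>CCOC", rid="a"),
        rxn("CCN.CCO>>CCOC", y=80.0, rid="b"),
        rxn("CCBr>>CCO", rid="c"),
    ])
    out, report = deduplicate_dataset(d)
    assert len(out) == 2
    kept = {r.record_id for r in out.records}
    assert kept == {"b", "c"}          # the yielded duplicate wins
    assert report.stage_counts == {"input": 3, "after_dedup": 2}


def test_dedup_idempotent(small_dataset):
    once, _ = deduplicate_dataset(small_dataset)
    twice, _ = deduplicate_dataset(once)
    assert once == twice


# -- conformers -------------------------------------------------------------

def test_attach_conformers_all_embed_and_deterministic():
    d = ReactionDataset([rxn("CCO>>CC=O", rid="a"), rxn("CCBr.CCN>>CCOC", rid="b")])
    out1, rep = attach_conformers(d, seed=3)
    out2, _ = attach_conformers(d, seed=3)
    assert len(out1) == 2 and not rep.dropped
    assert all(r.has_conformers() for r in out1.records)
    assert out1 == out2                 # bit-identical coordinates


def test_attach_conformers_drops_failures_with_reason():
    def flaky(smiles, seed):
        return None if smiles == "CCN" else etkdg_embedder(smiles, seed)

    d = ReactionDataset([rxn("CCO>>CC=O", rid="ok"), rxn("CCN>>CCO", rid="bad")])
    out, rep = attach_conformers(d, embedder=flaky, seed=0)
    assert [r.record_id for r in out.records] == ["ok"]
    assert rep.dropped[0]["record_id"] == "bad"
    assert "CCN" in rep.dropped[0]["reason"]


# -- yield filter -----------------------------------------------------------

def test_filter_by_yield_validity_rule():
    d = ReactionDataset([
        rxn("CCO>>CC=O", y=85.0, rid="a"),
        rxn("CCN>>CCO", y=120.0, rid="b"),
        rxn("CCBr>>CCO", rid="c"),
        rxn("CCCl>>CCO", y=30.0, rid="d"),
        rxn("CCI>>CCO", y=0.0, rid="e"),
    ])
    out, rep = filter_by_yield(d)
    assert {r.record_id for r in out.records} == {"a", "d"}
    assert len(rep.dropped) == 3


def test_filter_by_yield_low_fraction_count():
    records = [rxn("CCO>>CC=O", y=float(y), rid=f"r{i}")
               for i, y in enumerate(np.linspace(1, 49, 100))]
    d = ReactionDataset(records)
    out, _ = filter_by_yield(d, low_cut=50.0, low_fraction=0.5, seed=1)
    assert len(out) == 50
    out2, _ = filter_by_yield(d, low_cut=50.0, low_fraction=0.5, seed=1)
    assert out == out2
    full, _ = filter_by_yield(d, low_cut=50.0, low_fraction=1.0)
    assert len(full) == 100


def test_filter_by_yield_bad_fraction():
    d = ReactionDataset([rxn("CCO>>CC=O", y=50.0)])
    with pytest.raises(ConfigError):
        filter_by_yield(d, low_fraction=1.5)


# -- splits -----------------------------------------------------------------

def test_stratified_split_exact_small_case():
    records = [rxn("CCO>>CC=O", y=float(5 * i + 2), rid=f"r{i}") for i in range(20)]
    d = stratified_split(ReactionDataset(records), (18, 1, 1), n_bins=10, seed=0)
    counts = {s: list(d.split_labels.values()).count(s) for s in ("train", "valid", "test")}
    assert counts == {"train": 18, "valid": 1, "test": 1}


def test_stratified_split_per_bin_proportions():
    rng = np.random.default_rng(0)
    records = [rxn("CCO>>CC=O", y=float(y), rid=f"r{i}")
               for i, y in enumerate(rng.uniform(0.5, 100, 2000))]
    d = stratified_split(ReactionDataset(records), (18, 1, 1), n_bins=10, seed=7)
    labels = d.split_labels
    counts = {s: list(labels.values()).count(s) for s in ("train", "valid", "test")}
    assert counts["train"] + counts["valid"] + counts["test"] == 2000
    assert abs(counts["test"] - 100) <= 1 and abs(counts["valid"] - 100) <= 1
    # per-bin: test fraction 0.05 within one record of each bin's quota
    for b in range(10):
        in_bin = [r for r in records if 10 * b <= (r.yield_pct if r.yield_pct < 100 else 99.9) < 10 * (b + 1)]
        n_test = sum(labels[r.record_id] == "test" for r in in_bin)
        assert abs(n_test - 0.05 * len(in_bin)) <= 1.0


def test_stratified_split_seeded_reproducible():
    records = [rxn("CCO>>CC=O", y=float(i % 100 + 0.5), rid=f"r{i}") for i in range(200)]
    d1 = stratified_split(ReactionDataset(records), seed=3)
    d2 = stratified_split(ReactionDataset(records), seed=3)
    assert d1.split_labels == d2.split_labels


def test_stratified_split_degenerate_ratio_and_too_few():
    records = [rxn("CCO>>CC=O", y=50.0, rid=f"r{i}") for i in range(5)]
    d = stratified_split(ReactionDataset(records), (1, 0, 0))
    assert set(d.split_labels.values()) == {"train"}
    with pytest.raises(SplitError):
        stratified_split(ReactionDataset(records[:2]), (18, 1, 1))


def test_split_by_component_zero_leakage():
    ligand = "c1ccncc1"
    records = [rxn(f"CCO.{ligand}>>CCOC", rid=f"with{i}") for i in range(4)]
    records += [rxn("CCO.CCN>>CCOC", rid=f"without{i}") for i in range(6)]
    d = split_by_component(ReactionDataset(records), [ligand], role="reactants")
    labels = d.split_labels
    assert list(labels.values()).count("test") == 4
    for rec in d.records:
        present = any(m.smiles == ligand for m in rec.molecules())
        assert labels[rec.record_id] == ("test" if present else "train")


def test_split_by_component_absent_smiles_errors():
    d = ReactionDataset([rxn("CCO>>CC=O", rid="a")])
    with pytest.raises(SplitError, match="CCCCO"):
        split_by_component(d, ["CCCCO"])


# -- I/O --------------------------------------------------------------------

def test_csv_round_trip_with_conformers_and_splits(tmp_path):
    d = ReactionDataset([
        rxn("CCO.CCN>>CCOC", y=77.5, rid="a"),
        rxn("CCBr>>CCO", y=12.0, rid="b"),
    ])
    d, _ = attach_conformers(d, seed=5)
    d = stratified_split(d, (1, 0, 1), n_bins=2, seed=0)
    path = tmp_path / "data.csv"
    write_dataset(d, path, format="csv")
    loaded = load_dataset(path, format="csv")
    assert loaded == d


def test_smiles_lines_round_trip(tmp_path):
    d = ReactionDataset([rxn("CCO>>CC=O", rid="line-1"), rxn("CCN.CCO>>CCOC", rid="line-2")])
    path = tmp_path / "data.smi"
    write_dataset(d, path, format="smiles")
    loaded = load_dataset(path, format="smiles")
    assert [r.reaction_smiles() for r in loaded.records] == [r.reaction_smiles() for r in d.records]


def test_csv_missing_yield_column_in_supervised_mode(tmp_path):
    path = tmp_path / "data.csv"
    path.write_text("record_id,reaction_smiles\na,CCO>>CC=O\n")
    with pytest.raises(DatasetIOError, match="yield_pct"):
        load_dataset(path, format="csv", supervised=True)


def test_molecule_coord_shape_validation():
    with pytest.raises(ValidityError):
        Molecule("CCO", ("C", "C", "O"), np.zeros((2, 3)))
    with pytest.raises(ValidityError):
        Molecule("CCO", ("C", "C", "O"), np.full((3, 3), np.nan))
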