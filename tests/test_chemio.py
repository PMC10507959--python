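"""Compound parsing, featurization, tokenization, dataset I/O, fixtures."""

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from molpath import chemio
from molpath.chemio import (
    ATOM_FEATURE_DIM,
    DatasetFormatError,
    LabelVector,
    Molecule,
    SmilesParseError,
    SmilesTokenizer,
    TokenizationError,
    atom_features,
    canonicalize_smiles,
    generate_fixture_dataset,
    read_dataset,
    smiles_to_graph,
    tokenize_smiles,
)


class TestCanonicalization:
    def test_matches_toolkit_and_is_idempotent(self):
        out = canonicalize_smiles("OCC")
        assert out == Chem.MolToSmiles(Chem.MolFromSmiles("OCC"))
        assert canonicalize_smiles(out) == out

    def test_kekulized_and_aromatic_benzene_agree(self):
        assert canonicalize_smiles("C1=CC=CC=C1") == canonicalize_smiles("c1ccccc1")

    @pytest.mark.parametrize("bad", ["", "not-a-smiles", "C(("])
    def test_parse_error_names_input(self, bad):
        with pytest.raises(SmilesParseError):
            canonicalize_smiles(bad)


class TestAtomFeatures:
    def test_methane_carbon(self):
        mol = Molecule.from_smiles("C")
        fv = atom_features(mol, 0)
        assert fv.degree_onehot.argmax() == 0
        assert fv.num_h_onehot.argmax() == 4
        assert fv.formal_charge == 0
        assert not fv.in_ring and not fv.aromatic
        assert len(fv.vector) == ATOM_FEATURE_DIM

    def test_benzene_atoms_aromatic_ring_degree2(self):
        mol = Molecule.from_smiles("c1ccccc1")
        for i in range(6):
            fv = atom_features(mol, i)
            assert fv.aromatic and fv.in_ring
            assert fv.degree_onehot.argmax() == 2

    def test_ethanol_oxygen(self):
        mol = Molecule.from_smiles("CCO")
        fv = atom_features(mol, 2)  # parser order: C, C, O
        assert fv.symbol_onehot.argmax() == chemio.ELEMENT_VOCAB.index("O")
        assert fv.num_h_onehot.argmax() == 1
        assert fv.degree_onehot.argmax() == 1

    def test_onehot_blocks_sum_to_one(self):
        mol = Molecule.from_smiles("C[C@H](N)C(=O)[O-]")
        for i in range(mol.n_atoms):
            fv = atom_features(mol, i)
            for block in (fv.symbol_onehot, fv.degree_onehot, fv.num_h_onehot,
                          fv.implicit_valence_onehot, fv.chiral_onehot):
                assert block.sum() == 1.0

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            atom_features(Molecule.from_smiles("C"), 1)


class TestMolecularGraph:
    @pytest.mark.parametrize(
        "smiles,n_nodes,n_edges",
        [("CCO", 3, 4), ("c1ccccc1", 6, 12), ("[Na+].[Cl-]", 2, 0)],
    )
    def test_node_and_edge_counts(self, smiles, n_nodes, n_edges):
        g = smiles_to_graph(Molecule.from_smiles(smiles))
        assert g.n_nodes == n_nodes
        assert len(g.edges) == n_edges
        assert g.node_features.shape == (n_nodes, ATOM_FEATURE_DIM)

    def test_every_edge_has_its_reverse(self, fixture_dataset):
        for mol, _ in fixture_dataset:
            g = smiles_to_graph(mol)
            edge_set = set(g.edges)
            assert all((j, i) in edge_set for i, j in edge_set)
            assert all(0 <= i < g.n_nodes and 0 <= j < g.n_nodes for i, j in g.edges)

    def test_feature_dim_constant_across_dataset(self, fixture_dataset):
        dims = {smiles_to_graph(mol).node_features.shape[1] for mol, _ in fixture_dataset}
        assert dims == {ATOM_FEATURE_DIM}


class TestTokenizer:
    def test_character_count_and_padding(self):
        seq = tokenize_smiles("CCO", max_len=8)
        assert seq.true_length == 3
        assert (seq.token_ids[3:] == 0).all()
        assert (seq.token_ids[:3] != 0).all()

    def test_two_character_elements_are_single_tokens(self):
        seq = tokenize_smiles("CCl", max_len=8)
        assert seq.true_length == 2
        tok = SmilesTokenizer()
        assert tok.split("CCl") == ["C", "Cl"]
        assert tok.split("C%12CC%12") == ["C", "%12", "C", "C", "%12"]
        assert tok.split("[C@@H](O)Br") == ["[C@@H]", "(", "O", ")", "Br"]

    def test_exact_length_boundary_accepted(self):
        seq = tokenize_smiles("CCCC", max_len=4)
        assert seq.true_length == 4

    def test_overlength_raises(self):
        with pytest.raises(TokenizationError, match="max_len"):
            tokenize_smiles("CCCCC", max_len=4)

    def test_unknown_token_named_in_error(self):
        tok = SmilesTokenizer(tokens=["C", "O"])
        with pytest.raises(TokenizationError, match="'N'"):
            tok.tokenize("CNO", max_len=8)

    def test_round_trip_on_fixture_smiles(self, fixture_dataset, fitted_tokenizer):
        for s in fixture_dataset.smiles:
            seq = fitted_tokenizer.tokenize(s)
            assert fitted_tokenizer.detokenize(seq) == s

    def test_vocabulary_id_tracks_vocabulary(self):
        a, b = SmilesTokenizer(), SmilesTokenizer(tokens=["C", "O"])
        assert a.vocabulary_id != b.vocabulary_id


class TestReadDataset:
    def write(self, tmp_path, rows, header="smiles,labels"):
        p = tmp_path / "ds.csv"
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    def test_multi_label_row(self, tmp_path):
        ds = read_dataset(self.write(tmp_path, ["CCO,0;5"]), label_count=18)
        bits = ds.records[0][1].bits
        assert bits[0] == 1 and bits[5] == 1 and bits.sum() == 2

    def test_out_of_range_label_reports_line(self, tmp_path):
        p = self.write(tmp_path, ["CCO,3", "CCC,17"])
        with pytest.raises(DatasetFormatError, match="line 3"):
            read_dataset(p, label_count=11)

    def test_empty_label_field_flagged(self, tmp_path):
        ds = read_dataset(self.write(tmp_path, ["CCO,"]), label_count=5)
        assert ds.records[0][1].bits.sum() == 0
        assert ds.load_report.empty_label_rows == [2]

    def test_bad_smiles_reports_line(self, tmp_path):
        p = self.write(tmp_path, ["CCO,1", "xyz((,2"])
        with pytest.raises(DatasetFormatError, match="line 3"):
            read_dataset(p, label_count=5)
        ds = read_dataset(p, label_count=5, on_error="skip")
        assert len(ds) == 1
        assert ds.load_report.rejected[0][0] == 3

    def test_duplicates_merged_by_canonical_smiles(self, tmp_path):
        ds = read_dataset(self.write(tmp_path, ["CCO,0", "OCC,2"]), label_count=5)
        assert len(ds) == 1
        assert ds.records[0][1].indices == [0, 2]
        with pytest.raises(DatasetFormatError, match="duplicate"):
            read_dataset(self.write(tmp_path, ["CCO,0", "OCC,2"]), label_count=5,
                         duplicates="error")

    def test_missing_column(self, tmp_path):
        p = self.write(tmp_path, ["CCO"], header="smiles")
        with pytest.raises(DatasetFormatError, match="labels"):
            read_dataset(p, label_count=5)

    def test_csv_round_trip(self, tmp_path, fixture_dataset):
        p = tmp_path / "round.csv"
        fixture_dataset.to_csv(p)
        back = read_dataset(p, label_count=fixture_dataset.label_count)
        assert np.array_equal(back.label_matrix, fixture_dataset.label_matrix)
        assert [m.canonical_smiles for m, _ in back] == [
            m.canonical_smiles for m, _ in fixture_dataset
        ]


class TestFixtureGenerator:
    def test_deterministic_and_seed_sensitive(self, tmp_path):
        a = generate_fixture_dataset(50, 5, seed=1)
        b = generate_fixture_dataset(50, 5, seed=1)
        c = generate_fixture_dataset(50, 5, seed=2)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa)
        b.to_csv(pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.smiles != c.smiles

    def test_all_smiles_valid_and_unique(self):
        ds = generate_fixture_dataset(100, 8, seed=3)
        canon = [canonicalize_smiles(s) for s in ds.smiles]
        assert len(set(canon)) == 100

    def test_multi_label_rows_present(self):
        ds = generate_fixture_dataset(200, 8, seed=4, multi_label_fraction=0.5)
        assert (ds.label_matrix.sum(axis=1) >= 2).mean() > 0.2

    def test_precondition(self):
        with pytest.raises(ValueError):
            generate_fixture_dataset(3, 5, seed=1)

    def test_label_marginals_follow_configured_distribution(self):
        """Chi-square goodness of fit of per-label marginals at n=5000.

        With m label draws per row (m = 1, 2, 3 with probabilities 0.7,
        0.21, 0.09 at the default multi-label fraction 0.3) drawn with
        replacement from weights w, P(bit_l) = E_m[1 - (1 - w_l)^m].
        """
        n, L = 5000, 6
        ds = generate_fixture_dataset(n, L, seed=9)
        w = 0.85 ** np.arange(L)
        w = w / w.sum()
        p_m = {1: 0.7, 2: 0.3 * 0.7, 3: 0.3 * 0.3}
        p_bit = sum(pm * (1.0 - (1.0 - w) ** m) for m, pm in p_m.items())
        observed = ds.label_matrix.sum(axis=0)
        expected = n * p_bit
        chi2 = (((observed - expected) ** 2) / expected
                + ((n - observed - (n - expected)) ** 2) / (n - expected)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=L)

    def test_structural_labels_flag_marker_substructures(self):
        ds = generate_fixture_dataset(30, 5, seed=6, structural_labels=True)
        # positive labels must correspond to a present marker fragment
        for mol, labels in ds:
            for idx in labels.indices:
                marker = Chem.MolFromSmiles(chemio.MARKER_DECORATIONS[idx])
                assert mol.rdkit_mol.HasSubstructMatch(marker)


class TestLabelVector:
    def test_from_indices_and_range_check(self):
        lv = LabelVector.from_indices([0, 2], ("0", "1", "2"))
        assert lv.indices == [0, 2]
        with pytest.raises(ValueError):
            LabelVector.from_indices([3], ("0", "1", "2"))
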