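"""Network contracts: attention, propagation, pooling, fusion, prediction."""

import numpy as np
import pytest

from conftest import tiny_model_config
from molpath.chemio import Molecule, MolecularGraph, smiles_to_graph
from molpath.model import (
    AttentionParams,
    Batch,
    LabelProbabilities,
    ModelConfig,
    PathwayModel,
    attention_coefficients,
    encode_dataset,
    global_pool,
    graph_transformer_layer,
    load_checkpoint,
    save_checkpoint,
    threshold_predict,
)


def random_heads(n_heads, head_dim, in_dim, seed=0):
    rng = np.random.default_rng(seed)
    return [
        AttentionParams(
            W_q=rng.normal(size=(head_dim, in_dim)),
            W_k=rng.normal(size=(head_dim, in_dim)),
            W_v=rng.normal(size=(head_dim, in_dim)),
            W_l=rng.normal(size=(head_dim, in_dim)),
            head_index=c,
        )
        for c in range(n_heads)
    ]


def path_graph(node_features: np.ndarray) -> MolecularGraph:
    """A synthetic path graph over arbitrary feature rows."""
    n = node_features.shape[0]
    edges = []
    for i in range(n - 1):
        edges += [(i, i + 1), (i + 1, i)]
    mol = Molecule.from_smiles("C" * max(n, 1))
    return MolecularGraph(node_features=node_features, edges=tuple(edges), molecule=mol)


def oracle_layer(graph: MolecularGraph, heads) -> np.ndarray:
    """Naive double-loop implementation of the propagation equations."""
    X = graph.node_features
    n, d = X.shape
    per_head = []
    for hp in heads:
        out = np.zeros((n, hp.head_dim))
        for i in range(n):
            out[i] = hp.W_l @ X[i]
            nbrs = [j for (j, t) in graph.edges if t == i]
            if nbrs:
                scores = np.array([(hp.W_q @ X[i]) @ (hp.W_k @ X[j]) for j in nbrs]) / np.sqrt(d)
                e = np.exp(scores - scores.max())
                alpha = e / e.sum()
                for a, j in zip(alpha, nbrs):
                    out[i] += a * (hp.W_v @ X[j])
        per_head.append(out)
    return np.hstack(per_head)


class TestAttentionCoefficients:
    def test_single_neighbor_gives_one(self):
        g = smiles_to_graph(Molecule.from_smiles("CO"))
        (params,) = random_heads(1, 4, g.node_features.shape[1])
        alpha = attention_coefficients(g, 0, params)
        assert alpha.shape == (1,)
        assert alpha[0] == pytest.approx(1.0)

    def test_identical_neighbors_split_evenly(self):
        # central CH2 of propane: both neighbours are equivalent CH3 carbons
        g = smiles_to_graph(Molecule.from_smiles("CCC"))
        (params,) = random_heads(1, 4, g.node_features.shape[1])
        alpha = attention_coefficients(g, 1, params)
        assert np.allclose(alpha, [0.5, 0.5])

    def test_matches_direct_softmax_on_four_neighbors(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 6))
        star = MolecularGraph(
            node_features=X,
            edges=tuple((j, 0) for j in range(1, 5)) + tuple((0, j) for j in range(1, 5)),
            molecule=Molecule.from_smiles("CC(C)(C)C"),
        )
        (params,) = random_heads(1, 3, 6, seed=8)
        alpha = attention_coefficients(star, 0, params)
        q = params.W_q @ X[0]
        scores = np.array([q @ (params.W_k @ X[j]) for j in range(1, 5)]) / np.sqrt(6)
        expected = np.exp(scores) / np.exp(scores).sum()
        assert np.allclose(alpha, expected, atol=1e-12)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-6)

    def test_isolated_node_yields_empty(self):
        g = smiles_to_graph(Molecule.from_smiles("[Na+].[Cl-]"))
        (params,) = random_heads(1, 4, g.node_features.shape[1])
        assert attention_coefficients(g, 0, params).size == 0


class TestGraphTransformerLayer:
    def test_isolated_node_keeps_self_term_only(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(1, 4))
        g = MolecularGraph(node_features=X, edges=(), molecule=Molecule.from_smiles("C"))
        (hp,) = random_heads(1, 3, 4)
        out = graph_transformer_layer(g, [hp])
        assert np.allclose(out[0], hp.W_l @ X[0], atol=1e-12)

    def test_single_edge_attention_is_unity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2, 4))
        g = path_graph(X)
        (hp,) = random_heads(1, 3, 4)
        out = graph_transformer_layer(g, [hp])
        assert np.allclose(out[0], hp.W_l @ X[0] + hp.W_v @ X[1], atol=1e-10)
        assert np.allclose(out[1], hp.W_l @ X[1] + hp.W_v @ X[0], atol=1e-10)

    def test_matches_double_loop_oracle_on_path_graph(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 6))
        g = path_graph(X)
        heads = random_heads(2, 4, 6, seed=4)
        out = graph_transformer_layer(g, heads)
        assert out.shape == (5, 8)  # C x head_dim
        assert np.allclose(out, oracle_layer(g, heads), atol=1e-6)

    def test_matches_oracle_on_real_molecules(self):
        for smiles in ("CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O"):
            g = smiles_to_graph(Molecule.from_smiles(smiles))
            heads = random_heads(3, 5, g.node_features.shape[1], seed=6)
            assert np.allclose(graph_transformer_layer(g, heads), oracle_layer(g, heads), atol=1e-6)


class TestGlobalPool:
    def test_single_node_duplicates_row(self):
        v = np.array([[1.0, -2.0, 3.0]])
        assert np.allclose(global_pool(v), [1, -2, 3, 1, -2, 3])

    def test_mean_and_max_blocks(self):
        out = global_pool(np.array([[1.0, 3.0], [3.0, 1.0]]))
        assert np.allclose(out, [2, 2, 3, 3])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        m = rng.normal(size=(10, 4))
        shuffled = m[rng.permutation(10)]
        assert np.allclose(global_pool(m), global_pool(shuffled))

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            global_pool(np.zeros((0, 3)))


class TestBlocks:
    def test_branch_vectors_are_2000d_by_default(self, fitted_tokenizer):
        model = PathwayModel(ModelConfig(label_count=5, seed=0), tokenizer=fitted_tokenizer)
        mol = Molecule.from_smiles("COc1ccccc1O")
        v1 = model.block1_forward(smiles_to_graph(mol))
        v2 = model.block2_forward(fitted_tokenizer.tokenize(mol.smiles))
        assert v1.shape == (2000,)
        assert v2.shape == (2000,)
        assert model.fused_dim == 4000

    def test_block_outputs_deterministic(self, tiny_model, fitted_tokenizer):
        g = smiles_to_graph(Molecule.from_smiles("CCO"))
        assert np.array_equal(tiny_model.block1_forward(g), tiny_model.block1_forward(g))
        seq = fitted_tokenizer.tokenize("CCO")
        assert np.array_equal(tiny_model.block2_forward(seq), tiny_model.block2_forward(seq))

    def test_block1_invariant_to_atom_relabeling(self, tiny_model):
        g = smiles_to_graph(Molecule.from_smiles("CC(=O)Oc1ccccc1C(=O)O"))
        rng = np.random.default_rng(11)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        permuted = MolecularGraph(
            node_features=g.node_features[perm],
            edges=tuple((int(inv[i]), int(inv[j])) for i, j in g.edges),
            molecule=g.molecule,
        )
        v_orig = tiny_model.block1_forward(g)
        v_perm = tiny_model.block1_forward(permuted)
        assert np.abs(v_orig - v_perm).max() < 1e-8

    def test_distinct_smiles_give_distinct_text_vectors(self, tiny_model, fitted_tokenizer, fixture_dataset):
        vecs = [tiny_model.block2_forward(fitted_tokenizer.tokenize(s)) for s in fixture_dataset.smiles[:8]]
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                assert not np.allclose(vecs[i], vecs[j])


class TestFusionAndPrediction:
    def test_fused_vector_length_4000_default(self, fitted_tokenizer):
        model = PathwayModel(ModelConfig(label_count=3, seed=1), tokenizer=fitted_tokenizer)
        probs = model.fusion_forward(np.ones(2000), np.ones(2000))
        assert isinstance(probs, LabelProbabilities)
        assert probs.probs.shape == (3,)

    def test_zero_output_weights_give_half_probabilities(self, tiny_model):
        tiny_model.output.weight.data[:] = 0.0
        tiny_model.output.bias.data[:] = 0.0
        probs = tiny_model.fusion_forward(np.ones(32), np.ones(32))
        assert np.allclose(probs.probs, 0.5)

    def test_dimension_mismatch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.fusion_forward(np.ones(10), np.ones(10))

    def test_inference_deterministic_despite_dropout_config(self, tiny_model, fixture_dataset):
        smiles = fixture_dataset.smiles[:3]
        assert np.array_equal(tiny_model.predict_proba(smiles), tiny_model.predict_proba(smiles))

    def test_whole_model_invariant_to_atom_relabeling(self, tiny_model, fitted_tokenizer):
        mol = Molecule.from_smiles("COc1ccc(CC(N)C(=O)O)cc1")
        g = smiles_to_graph(mol)
        seq = fitted_tokenizer.tokenize(mol.smiles)
        rng = np.random.default_rng(13)
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)

        def probs_for(graph):
            ea = graph.edge_array
            batch = Batch(graph.node_features, ea[0], ea[1],
                          np.zeros(graph.n_nodes, dtype=np.intp), 1,
                          seq.token_ids[None, :], np.array([seq.true_length]))
            tiny_model.eval()
            from molpath import nn
            with nn.no_grad():
                return tiny_model(batch).data[0]

        permuted = MolecularGraph(
            node_features=g.node_features[perm],
            edges=tuple((int(inv[i]), int(inv[j])) for i, j in g.edges),
            molecule=mol,
        )
        assert np.abs(probs_for(g) - probs_for(permuted)).max() < 1e-5


class TestThresholdPredict:
    def test_definition(self):
        assert np.array_equal(threshold_predict(np.array([0.6, 0.4, 0.9]), 0.5), [1, 0, 1])

    def test_tie_predicts_membership(self):
        assert np.array_equal(threshold_predict(np.array([0.5, 0.5]), 0.5), [1, 1])

    def test_all_below_threshold_allowed(self):
        assert threshold_predict(np.array([0.1, 0.2]), 0.5).sum() == 0

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            threshold_predict(np.array([0.5]), 1.0)


class TestConfigValidation:
    def test_both_blocks_disabled_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(label_count=3, use_block1=False, use_block2=False)

    def test_threshold_range(self):
        with pytest.raises(ValueError):
            ModelConfig(label_count=3, threshold=0.0)

    def test_branch_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(label_count=3, graph_out_dim=100, text_out_dim=200)


class TestAblations:
    @pytest.mark.parametrize("switch", ["use_block1", "use_block2", "use_fusion_cnn"])
    def test_ablated_models_still_predict(self, fitted_tokenizer, switch):
        cfg = tiny_model_config(**{switch: False})
        model = PathwayModel(cfg, tokenizer=fitted_tokenizer)
        probs = model.predict_proba(["CCO"])
        assert probs.shape == (1, 5)
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_single_branch_fusion_width(self, fitted_tokenizer):
        cfg = tiny_model_config(use_block2=False)
        model = PathwayModel(cfg, tokenizer=fitted_tokenizer)
        assert model.fused_dim == cfg.graph_out_dim


class TestCheckpoint:
    def test_round_trip_reproduces_predictions(self, tmp_path, tiny_model, fixture_dataset):
        p = tmp_path / "model.npz"
        save_checkpoint(tiny_model, p)
        restored = load_checkpoint(p)
        smiles = fixture_dataset.smiles[:4]
        assert np.array_equal(restored.predict_proba(smiles), tiny_model.predict_proba(smiles))
        assert restored.label_names == tiny_model.label_names
        assert restored.tokenizer.tokens == tiny_model.tokenizer.tokens


class TestEncodeDataset:
    def test_collate_shapes(self, fixture_dataset, fitted_tokenizer):
        enc = encode_dataset(fixture_dataset, fitted_tokenizer)
        batch = enc.collate([0, 1, 2])
        assert batch.n_graphs == 3
        assert batch.node_features.shape[0] == batch.node_graph.shape[0]
        assert batch.token_ids.shape[0] == 3
        assert (batch.src < batch.node_features.shape[0]).all()
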