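"""The hybrid pathway-prediction network.

Two branches encode a compound in parallel:

* **Block1** (graph branch): stacked graph-transformer layers in which each
  atom attends over its bonded neighbours with multi-head Query/Key/Value
  attention, followed by parallel global mean and max pooling and a fully
  connected layer, yielding a 2000-dimensional molecule vector.
* **Block2** (text branch): a learned character-level embedding of the
  SMILES string, a 1-D convolution, a 1-D max-pooling layer and a fully
  connected layer, also yielding 2000 dimensions.

The two vectors are concatenated to 4000 dimensions, passed through a small
1-D CNN and a dropout layer, and a final fully connected layer emits one
independent sigmoid probability per pathway. Prediction thresholds the
probabilities at 0.5 (ties predict membership). Ablation switches can drop
either branch or the fusion CNN.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .chemio import (
    ATOM_FEATURE_DIM,
    LabeledDataset,
    MolecularGraph,
    Molecule,
    SmilesTokenizer,
    TokenSequence,
    smiles_to_graph,
)


@dataclass(frozen=True)
class AttentionParams:
    """Per-head attention weights: query, key, value and self projections."""

    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray
    W_l: np.ndarray
    head_index: int = 0

    def __post_init__(self):
        shapes = {m.shape for m in (self.W_q, self.W_k, self.W_v, self.W_l)}
        if len(shapes) != 1:
            raise ValueError(f"attention matrices must share one shape, got {shapes}")

    @property
    def head_dim(self) -> int:
        return self.W_q.shape[0]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The 2000-dimensional per-branch output and the 0.5 decision threshold
    are structural constants of the method; the remaining sizes are free
    choices recorded here so a checkpoint fully describes its network.
    """

    label_count: int
    n_graph_layers: int = 3
    n_heads: int = 4
    head_dim: int = 64
    graph_out_dim: int = 2000
    text_embed_dim: int = 64
    conv_channels: int = 64
    conv_kernel: int = 3
    text_out_dim: int = 2000
    fusion_channels: int = 16
    fusion_kernel: int = 3
    fusion_pool: int = 8
    fusion_dropout: float = 0.2
    threshold: float = 0.5
    use_block1: bool = True
    use_block2: bool = True
    use_fusion_cnn: bool = True
    max_len: int = 256
    seed: int = 0

    def __post_init__(self):
        if not (self.use_block1 or self.use_block2):
            raise ValueError("at least one of use_block1/use_block2 must be enabled")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1): {self.threshold}")
        if self.use_block1 and self.use_block2 and self.graph_out_dim != self.text_out_dim:
            raise ValueError("graph_out_dim and text_out_dim must match when both blocks are enabled")
        if self.label_count < 1:
            raise ValueError("label_count must be >= 1")
        for name in ("n_graph_layers", "n_heads", "head_dim", "graph_out_dim", "text_embed_dim",
                     "conv_channels", "conv_kernel", "fusion_channels", "fusion_kernel", "fusion_pool"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.fusion_dropout < 1.0:
            raise ValueError("fusion_dropout must be in [0, 1)")


@dataclass(frozen=True)
class LabelProbabilities:
    """Independent per-pathway sigmoid probabilities (no sum-to-one)."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if ((p < 0) | (p > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "probs", p)


def threshold_predict(probs: LabelProbabilities | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Multi-hot prediction: bit p is 1 iff prob[p] >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1): {threshold}")
    p = probs.probs if isinstance(probs, LabelProbabilities) else np.asarray(probs)
    return (p >= threshold).astype(np.int8)


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------


@dataclass
class Batch:
    """Several molecular graphs packed into one disjoint-union graph plus a
    padded token matrix for the text branch."""

    node_features: np.ndarray  # (total_nodes, d)
    src: np.ndarray            # (E,) source node of each directed edge
    dst: np.ndarray            # (E,) target node of each directed edge
    node_graph: np.ndarray     # (total_nodes,) graph id per node
    n_graphs: int
    token_ids: np.ndarray      # (B, max_len)
    lengths: np.ndarray        # (B,)


@dataclass
class EncodedDataset:
    """Featurized cache of a dataset: graphs, tokens and the label matrix."""

    graphs: list[MolecularGraph]
    token_ids: np.ndarray
    lengths: np.ndarray
    labels: np.ndarray
    smiles: list[str]

    def __len__(self) -> int:
        return len(self.graphs)

    def collate(self, indices) -> Batch:
        indices = np.asarray(indices, dtype=np.intp)
        graphs = [self.graphs[i] for i in indices]
        feats = np.concatenate([g.node_features for g in graphs], axis=0)
        src_parts, dst_parts, node_graph = [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            ea = g.edge_array
            src_parts.append(ea[0] + offset)
            dst_parts.append(ea[1] + offset)
            node_graph.append(np.full(g.n_nodes, gi, dtype=np.intp))
            offset += g.n_nodes
        return Batch(
            node_features=feats,
            src=np.concatenate(src_parts),
            dst=np.concatenate(dst_parts),
            node_graph=np.concatenate(node_graph),
            n_graphs=len(graphs),
            token_ids=self.token_ids[indices],
            lengths=self.lengths[indices],
        )


def encode_dataset(
    dataset: LabeledDataset,
    tokenizer: SmilesTokenizer,
    max_len: int | None = None,
    min_len: int = 8,
) -> EncodedDataset:
    """Featurize every record once. Token sequences are padded to the
    longest sequence in the dataset (at least ``min_len``), capped by the
    tokenizer's ``max_len``."""
    graphs = [smiles_to_graph(mol) for mol, _ in dataset]
    split_lengths = [len(tokenizer.split(s)) for s in dataset.smiles]
    if max_len is None:
        max_len = min(max(max(split_lengths, default=1), min_len), tokenizer.max_len)
    seqs = [tokenizer.tokenize(s, max_len=max_len) for s in dataset.smiles]
    return EncodedDataset(
        graphs=graphs,
        token_ids=np.stack([s.token_ids for s in seqs]),
        lengths=np.array([s.true_length for s in seqs], dtype=np.intp),
        labels=dataset.label_matrix.astype(np.float64),
        smiles=list(dataset.smiles),
    )


# ---------------------------------------------------------------------------
# Network modules
# ---------------------------------------------------------------------------


class _AttentionHead(nn.Module):
    def __init__(self, in_dim: int, head_dim: int, rng: np.random.Generator):
        self.W_q = nn.Parameter(nn.layers.glorot(rng, (head_dim, in_dim), in_dim, head_dim))
        self.W_k = nn.Parameter(nn.layers.glorot(rng, (head_dim, in_dim), in_dim, head_dim))
        self.W_v = nn.Parameter(nn.layers.glorot(rng, (head_dim, in_dim), in_dim, head_dim))
        self.W_l = nn.Parameter(nn.layers.glorot(rng, (head_dim, in_dim), in_dim, head_dim))


class GraphTransformerLayer(nn.Module):
    """One propagation step: for each head c,
    x'_{c,i} = W_l x_i + sum_{j in N(i)} alpha_{c,i,j} W_v x_j, where alpha is
    the softmax over N(i) of (W_q x_i)^T (W_k x_j) / sqrt(d); the per-head
    results are concatenated. Isolated atoms keep only the self term."""

    def __init__(self, in_dim: int, n_heads: int, head_dim: int, rng: np.random.Generator):
        self.in_dim = in_dim
        self.heads = [_AttentionHead(in_dim, head_dim, rng) for _ in range(n_heads)]

    def __call__(self, x: nn.Tensor, src: np.ndarray, dst: np.ndarray, n_nodes: int) -> nn.Tensor:
        outs = []
        scale = 1.0 / np.sqrt(self.in_dim)  # d is the input feature dimension
        for head in self.heads:
            q = nn.matmul(x, _transpose(head.W_q))
            k = nn.matmul(x, _transpose(head.W_k))
            v = nn.matmul(x, _transpose(head.W_v))
            self_term = nn.matmul(x, _transpose(head.W_l))
            if len(src):
                scores = nn.mul(nn.tsum(nn.mul(nn.gather_rows(q, dst), nn.gather_rows(k, src)), axis=1), scale)
                alpha = nn.segment_softmax(scores, dst, n_nodes)
                msg = nn.mul(nn.reshape(alpha, (-1, 1)), nn.gather_rows(v, src))
                agg = nn.segment_sum(msg, dst, n_nodes)
                outs.append(nn.add(self_term, agg))
            else:
                outs.append(self_term)
        return nn.concat(outs, axis=1)


def _transpose(p: nn.Parameter) -> nn.Tensor:
    return nn.Tensor(p.data.T, requires_grad=True, parents=(p,), backward=lambda g: p._accumulate(g.T))


def attention_coefficients(graph: MolecularGraph, node_i: int, params: AttentionParams) -> np.ndarray:
    """Attention coefficients of node i over its neighbours N(i), in edge
    order; softmax-normalised to sum to 1. Empty for isolated atoms."""
    neighbors = graph.neighbors(node_i)
    if not neighbors:
        return np.zeros(0)
    d = graph.node_features.shape[1]
    q = params.W_q @ graph.node_features[node_i]
    scores = np.array([q @ (params.W_k @ graph.node_features[j]) for j in neighbors]) / np.sqrt(d)
    e = np.exp(scores - scores.max())
    return e / e.sum()


def graph_transformer_layer(graph: MolecularGraph, heads: list[AttentionParams]) -> np.ndarray:
    """Apply one graph-transformer layer with the given per-head weights to
    a single molecular graph; returns the (n, C*head_dim) updated features."""
    rng = np.random.default_rng(0)
    layer = GraphTransformerLayer(graph.node_features.shape[1], len(heads), heads[0].head_dim, rng)
    for module_head, p in zip(layer.heads, heads):
        module_head.W_q.data = np.asarray(p.W_q, dtype=np.float64)
        module_head.W_k.data = np.asarray(p.W_k, dtype=np.float64)
        module_head.W_v.data = np.asarray(p.W_v, dtype=np.float64)
        module_head.W_l.data = np.asarray(p.W_l, dtype=np.float64)
    ea = graph.edge_array
    with nn.no_grad():
        out = layer(nn.Tensor(graph.node_features), ea[0], ea[1], graph.n_nodes)
    return out.data


def global_pool(node_features: np.ndarray) -> np.ndarray:
    """Graph readout: concatenation of columnwise mean and columnwise max.
    Permutation-invariant by construction."""
    node_features = np.asarray(node_features, dtype=float)
    if node_features.ndim != 2 or node_features.shape[0] < 1:
        raise ValueError("global_pool requires a non-empty (n, h) matrix")
    return np.concatenate([node_features.mean(axis=0), node_features.max(axis=0)])


class Block1(nn.Module):
    """Graph branch: stacked graph-transformer layers, mean/max readout, FC."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        dims = [ATOM_FEATURE_DIM] + [config.n_heads * config.head_dim] * config.n_graph_layers
        self.layers = [
            GraphTransformerLayer(dims[i], config.n_heads, config.head_dim, rng)
            for i in range(config.n_graph_layers)
        ]
        self.fc = nn.Linear(2 * dims[-1], config.graph_out_dim, rng)

    def __call__(self, batch: Batch) -> nn.Tensor:
        x = nn.Tensor(batch.node_features)
        for layer in self.layers:
            x = nn.relu(layer(x, batch.src, batch.dst, batch.node_features.shape[0]))
        counts = np.bincount(batch.node_graph, minlength=batch.n_graphs).astype(np.float64)
        mean_pool = nn.mul(
            nn.segment_sum(x, batch.node_graph, batch.n_graphs),
            nn.Tensor(1.0 / counts[:, None]),
        )
        max_pool = nn.segment_max(x, batch.node_graph, batch.n_graphs)
        pooled = nn.concat([mean_pool, max_pool], axis=1)
        return nn.relu(self.fc(pooled))


class Block2(nn.Module):
    """Text branch: token embedding, Conv1D, masked global max Pool1D, FC."""

    def __init__(self, config: ModelConfig, vocab_size: int, rng: np.random.Generator):
        self.embedding = nn.Embedding(vocab_size, config.text_embed_dim, rng)
        self.conv = nn.Conv1d(config.text_embed_dim, config.conv_channels, config.conv_kernel, rng)
        self.fc = nn.Linear(config.conv_channels, config.text_out_dim, rng)
        self.kernel = config.conv_kernel

    def __call__(self, token_ids: np.ndarray, lengths: np.ndarray) -> nn.Tensor:
        if (lengths < 1).any():
            raise ValueError("sequence of only padding")
        emb = self.embedding(token_ids)
        h = nn.relu(self.conv(emb))
        n_pos = h.data.shape[1]
        # windows that extend past the real tokens are masked out of the max
        valid = np.arange(n_pos)[None, :] < np.maximum(lengths - self.kernel + 1, 1)[:, None]
        h = nn.add(h, nn.Tensor(np.where(valid, 0.0, -1e30)[:, :, None]))
        pooled = nn.reshape(nn.maxpool1d(h, window=n_pos), (h.data.shape[0], -1))
        return nn.relu(self.fc(pooled))


class PathwayModel(nn.Module):
    """The full two-branch network with fusion head and sigmoid output.

    Parameter groups — ``block1``, ``block2``, ``fusion`` (the fusion CNN)
    and ``output`` (the last FC layer) — are the units of transfer-learning
    freezing.
    """

    def __init__(self, config: ModelConfig, tokenizer: SmilesTokenizer | None = None,
                 label_names: tuple[str, ...] | None = None):
        self.config = config
        self.tokenizer = tokenizer if tokenizer is not None else SmilesTokenizer(max_len=config.max_len)
        self.label_names = tuple(label_names) if label_names is not None else tuple(
            str(i) for i in range(config.label_count)
        )
        if len(self.label_names) != config.label_count:
            raise ValueError("label_names length must equal label_count")
        rng = np.random.default_rng(config.seed)
        self.block1 = Block1(config, rng) if config.use_block1 else None
        self.block2 = Block2(config, self.tokenizer.vocab_size, rng) if config.use_block2 else None
        fused_dim = (config.graph_out_dim if config.use_block1 else 0) + (
            config.text_out_dim if config.use_block2 else 0
        )
        self.fused_dim = fused_dim
        if config.use_fusion_cnn:
            self.fusion_conv = nn.Conv1d(1, config.fusion_channels, config.fusion_kernel, rng)
            conv_out = fused_dim - config.fusion_kernel + 1
            self.fusion_out_dim = (conv_out // config.fusion_pool) * config.fusion_channels
        else:
            self.fusion_conv = None
            self.fusion_out_dim = fused_dim
        self.dropout = nn.Dropout(config.fusion_dropout, np.random.default_rng([config.seed, 1]))
        self.output = nn.Linear(self.fusion_out_dim, config.label_count, rng)

    # -- forward -----------------------------------------------------------

    def branch_vectors(self, batch: Batch) -> list[nn.Tensor]:
        vecs = []
        if self.block1 is not None:
            vecs.append(self.block1(batch))
        if self.block2 is not None:
            vecs.append(self.block2(batch.token_ids, batch.lengths))
        return vecs

    def fuse(self, fused: nn.Tensor) -> nn.Tensor:
        """Fusion CNN + dropout + last FC + sigmoid on the concatenated vector."""
        if self.fusion_conv is not None:
            h = nn.reshape(fused, (fused.data.shape[0], self.fused_dim, 1))
            h = nn.relu(self.fusion_conv(h))
            h = nn.maxpool1d(h, window=self.config.fusion_pool)
            h = nn.reshape(h, (fused.data.shape[0], -1))
        else:
            h = fused
        h = self.dropout(h)
        return nn.sigmoid(self.output(h))

    def __call__(self, batch: Batch) -> nn.Tensor:
        vecs = self.branch_vectors(batch)
        fused = vecs[0] if len(vecs) == 1 else nn.concat(vecs, axis=1)
        return self.fuse(fused)

    # -- single-molecule functional surface --------------------------------

    def _single_batch(self, molecule: Molecule) -> Batch:
        graph = smiles_to_graph(molecule)
        seq = self.tokenizer.tokenize(molecule.smiles, max_len=None)
        ea = graph.edge_array
        return Batch(
            node_features=graph.node_features,
            src=ea[0],
            dst=ea[1],
            node_graph=np.zeros(graph.n_nodes, dtype=np.intp),
            n_graphs=1,
            token_ids=seq.token_ids[None, :],
            lengths=np.array([seq.true_length], dtype=np.intp),
        )

    def block1_forward(self, graph: MolecularGraph) -> np.ndarray:
        """Graph-branch molecule vector (length graph_out_dim)."""
        if self.block1 is None:
            raise ValueError("Block1 is disabled in this configuration")
        ea = graph.edge_array
        batch = Batch(graph.node_features, ea[0], ea[1],
                      np.zeros(graph.n_nodes, dtype=np.intp), 1,
                      np.zeros((1, 1), dtype=np.intp), np.ones(1, dtype=np.intp))
        was_training = self.training
        self.eval()
        with nn.no_grad():
            out = self.block1(batch)
        self.train(was_training)
        return out.data[0]

    def block2_forward(self, tokens: TokenSequence) -> np.ndarray:
        """Text-branch molecule vector (length text_out_dim)."""
        if self.block2 is None:
            raise ValueError("Block2 is disabled in this configuration")
        was_training = self.training
        self.eval()
        with nn.no_grad():
            out = self.block2(tokens.token_ids[None, :], np.array([tokens.true_length]))
        self.train(was_training)
        return out.data[0]

    def fusion_forward(self, v1: np.ndarray | None, v2: np.ndarray | None) -> LabelProbabilities:
        """Fuse branch vectors into per-pathway probabilities (inference)."""
        vecs = [np.asarray(v) for v in (v1, v2) if v is not None]
        fused = np.concatenate(vecs)
        if fused.shape[0] != self.fused_dim:
            raise ValueError(f"fused vector has length {fused.shape[0]}, expected {self.fused_dim}")
        was_training = self.training
        self.eval()
        with nn.no_grad():
            probs = self.fuse(nn.Tensor(fused[None, :]))
        self.train(was_training)
        return LabelProbabilities(probs.data[0])

    # -- prediction --------------------------------------------------------

    def predict_proba(self, smiles_list: list[str]) -> np.ndarray:
        """Per-pathway probabilities for a list of SMILES (inference mode)."""
        mols = [Molecule.from_smiles(s) for s in smiles_list]
        was_training = self.training
        self.eval()
        rows = []
        with nn.no_grad():
            for mol in mols:
                rows.append(self(self._single_batch(mol)).data[0])
        self.train(was_training)
        return np.stack(rows)

    def predict(self, smiles_list: list[str]) -> np.ndarray:
        return threshold_predict(self.predict_proba(smiles_list), self.config.threshold)

    def parameter_groups(self) -> dict[str, list[tuple[str, nn.Parameter]]]:
        groups: dict[str, list[tuple[str, nn.Parameter]]] = {
            "block1": [], "block2": [], "fusion": [], "output": []
        }
        for name, p in self.named_parameters():
            root = name.split(".")[0]
            if root == "block1":
                groups["block1"].append((name, p))
            elif root == "block2":
                groups["block2"].append((name, p))
            elif root == "fusion_conv":
                groups["fusion"].append((name, p))
            elif root == "output":
                groups["output"].append((name, p))
        return groups

    def replace_output_layer(self, new_label_count: int, label_names: tuple[str, ...] | None = None,
                             seed: int | None = None) -> None:
        """Swap the last FC layer for a fresh one of a new width (the only
        architectural change needed to move the model to a new task)."""
        rng = np.random.default_rng(seed if seed is not None else [self.config.seed, 2])
        self.output = nn.Linear(self.fusion_out_dim, new_label_count, rng)
        self.config.label_count = new_label_count
        self.label_names = tuple(label_names) if label_names is not None else tuple(
            str(i) for i in range(new_label_count)
        )


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: PathwayModel, path: str | Path) -> None:
    """Serialize weights plus config, label names and tokenizer vocabulary,
    so predictions are reproducible from the file alone."""
    meta = {
        "config": asdict(model.config),
        "label_names": list(model.label_names),
        "tokenizer_tokens": model.tokenizer.tokens[1:],  # pad token implicit
        "tokenizer_max_len": model.tokenizer.max_len,
    }
    np.savez(path, __meta__=np.array(json.dumps(meta)), **model.state_dict())


def load_checkpoint(path: str | Path) -> PathwayModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(**meta["config"])
    tokenizer = SmilesTokenizer(tokens=meta["tokenizer_tokens"], max_len=meta["tokenizer_max_len"])
    model = PathwayModel(config, tokenizer=tokenizer, label_names=tuple(meta["label_names"]))
    model.load_state_dict(state)
    return model
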