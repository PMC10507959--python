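"""Training, cross-validation and transfer learning.

The workflow mirrors a two-stage protocol: the model is pre-trained on a
large source dataset (learning rate 3e-4), the best cross-validation fold
is kept, the output layer is swapped for the target label space, and the
model is fine-tuned at a reduced learning rate (1e-4) under one of five
layer-freezing strategies. Frozen parameter groups are simply withheld from
the optimiser, so their tensors remain bitwise unchanged.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import KFold

from . import nn
from .chemio import LabeledDataset, SmilesTokenizer
from .evaluation import MetricsReport, metrics_report, summarize_folds
from .model import EncodedDataset, ModelConfig, PathwayModel, encode_dataset, threshold_predict

PRETRAIN_LR = 3e-4
FINETUNE_LR = 1e-4
_LOSS_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = PRETRAIN_LR
    epochs: int = 50
    batch_size: int = 32
    k_folds: int = 5
    seed: int = 0
    optimizer_name: str = "adam"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.optimizer_name != "adam":
            raise ValueError(f"unsupported optimizer: {self.optimizer_name!r}")


@dataclass
class TrainingHistory:
    """Per-epoch losses for a single run, or per-fold records for CV."""

    per_epoch_loss: list[float] = field(default_factory=list)
    fold_metrics: list[MetricsReport] = field(default_factory=list)
    fold_losses: list[list[float]] = field(default_factory=list)
    models: list[PathwayModel] = field(default_factory=list, repr=False)

    def summary(self) -> dict[str, dict[str, float]]:
        if not self.fold_metrics:
            raise ValueError("no fold metrics recorded")
        return summarize_folds(self.fold_metrics)


@dataclass(frozen=True)
class TransferStrategy:
    """A named layer-freezing scheme; the output layer is always trainable
    (it is replaced for the new task and never frozen)."""

    name: str
    frozen_groups: frozenset[str]


STRATEGIES: dict[str, TransferStrategy] = {
    "entire_model_frozen": TransferStrategy("entire_model_frozen", frozenset({"block1", "block2", "fusion"})),
    "block1_frozen": TransferStrategy("block1_frozen", frozenset({"block1"})),
    "block2_frozen": TransferStrategy("block2_frozen", frozenset({"block2"})),
    "block1_block2_frozen": TransferStrategy("block1_block2_frozen", frozenset({"block1", "block2"})),
    "no_module_frozen": TransferStrategy("no_module_frozen", frozenset()),
}


def get_strategy(name: str) -> TransferStrategy:
    if name not in STRATEGIES:
        raise ValueError(f"unknown transfer strategy {name!r}; options: {sorted(STRATEGIES)}")
    return STRATEGIES[name]


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def multilabel_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean binary cross-entropy over the batch x label matrix."""
    probs = np.asarray(probs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs targets {targets.shape}")
    if not np.isin(targets, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")
    p = np.clip(probs, 1e-12, 1.0 - 1e-12)
    # exact zero when probs equal targets: clipped terms vanish identically
    with np.errstate(divide="ignore", invalid="ignore"):
        per_cell = -(targets * np.log(p) + (1.0 - targets) * np.log(1.0 - p))
    per_cell = np.where(probs == targets, 0.0, per_cell)
    return float(per_cell.mean())


def _engine_loss(probs: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    term = nn.add(
        nn.mul(nn.Tensor(targets), nn.log(nn.add(probs, _LOSS_EPS))),
        nn.mul(nn.Tensor(1.0 - targets), nn.log(nn.add(nn.mul(probs, -1.0), 1.0 + _LOSS_EPS))),
    )
    return nn.mul(nn.tmean(term), -1.0)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def kfold_split(dataset: LabeledDataset | int, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition: disjoint validation sets covering all
    records, sizes differing by at most one; deterministic per seed."""
    n = dataset if isinstance(dataset, int) else len(dataset)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds dataset size {n}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2**32 - 1))
    return [(train, val) for train, val in kf.split(np.arange(n))]


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def extend_vocabulary(model: PathwayModel, smiles_list) -> int:
    """Grow the tokenizer (and embedding rows) to cover a new corpus.

    Returns the number of tokens added. New rows are randomly initialised;
    they belong to the block2 parameter group and obey its freeze state.
    """
    old = model.tokenizer.vocab_size
    model.tokenizer.fit(smiles_list)
    added = model.tokenizer.vocab_size - old
    if added and model.block2 is not None:
        rng = np.random.default_rng([model.config.seed, 3])
        extra = rng.normal(0.0, 0.05, size=(added, model.config.text_embed_dim))
        emb = model.block2.embedding.weight
        emb.data = np.concatenate([emb.data, extra], axis=0)
    return added


def _trainable_params(model: PathwayModel, frozen_groups: frozenset[str]) -> list[nn.Parameter]:
    params: list[nn.Parameter] = []
    for group, named in model.parameter_groups().items():
        if group in frozen_groups:
            continue
        params.extend(p for _, p in named)
    return params


def predict_encoded(model: PathwayModel, enc: EncodedDataset, indices=None, batch_size: int = 64) -> np.ndarray:
    """Probabilities for (a subset of) an encoded dataset, in index order."""
    indices = np.arange(len(enc)) if indices is None else np.asarray(indices, dtype=np.intp)
    was_training = model.training
    model.eval()
    rows = []
    with nn.no_grad():
        for start in range(0, len(indices), batch_size):
            batch = enc.collate(indices[start : start + batch_size])
            rows.append(model(batch).data)
    model.train(was_training)
    return np.concatenate(rows, axis=0)


def evaluate_model(model: PathwayModel, dataset: LabeledDataset) -> MetricsReport:
    """Threshold predictions on a dataset and report micro metrics."""
    enc = encode_dataset(dataset, model.tokenizer)
    probs = predict_encoded(model, enc)
    pred = threshold_predict(probs, model.config.threshold)
    return metrics_report(pred, dataset.label_matrix)


def train_model(
    dataset: LabeledDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    model: PathwayModel | None = None,
    frozen_groups: frozenset[str] = frozenset(),
) -> tuple[PathwayModel, TrainingHistory]:
    """Train (or continue training) on a dataset; returns the model and its
    per-epoch loss history. Aborts with a diagnostic if the loss becomes
    non-finite."""
    if model_config.label_count != dataset.label_count:
        raise ValueError(
            f"model expects {model_config.label_count} labels, dataset has {dataset.label_count}"
        )
    if model is None:
        tokenizer = SmilesTokenizer(max_len=model_config.max_len).fit(dataset.smiles)
        model = PathwayModel(model_config, tokenizer=tokenizer, label_names=dataset.label_names)
    else:
        if model.config.label_count != dataset.label_count:
            raise ValueError(
                f"model expects {model.config.label_count} labels, dataset has {dataset.label_count}"
            )
        extend_vocabulary(model, dataset.smiles)
    enc = encode_dataset(dataset, model.tokenizer)
    params = _trainable_params(model, frozen_groups)
    if not params:
        raise ValueError("all parameter groups frozen: nothing to train")
    optimizer = nn.Adam(params, lr=train_config.learning_rate)
    shuffler = np.random.default_rng([train_config.seed, 17])
    history = TrainingHistory()
    model.train(True)
    n = len(enc)
    for epoch in range(train_config.epochs):
        order = shuffler.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            batch = enc.collate(idx)
            probs = model(batch)
            loss = _engine_loss(probs, enc.labels[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(f"non-finite loss at epoch {epoch}: {value}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_losses.append(value)
        history.per_epoch_loss.append(float(np.mean(epoch_losses)))
    model.eval()
    return model, history


def cross_validate(
    dataset: LabeledDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> TrainingHistory:
    """k-fold cross-validation: one fresh model per fold, each evaluated on
    its held-out split; fold models and reports are kept so the best fold
    can be selected for transfer."""
    folds = kfold_split(dataset, train_config.k_folds, train_config.seed)
    history = TrainingHistory()
    for fold_idx, (train_idx, val_idx) in enumerate(folds):
        fold_model_config = replace(model_config, seed=model_config.seed + fold_idx)
        fold_train_config = replace(train_config, seed=train_config.seed + fold_idx)
        train_ds = dataset.subset(train_idx, name=f"{dataset.name}/fold{fold_idx}-train")
        val_ds = dataset.subset(val_idx, name=f"{dataset.name}/fold{fold_idx}-val")
        model, run = train_model(train_ds, fold_model_config, fold_train_config)
        # the tokenizer was fitted on the training split only; cover the
        # validation split's tokens before evaluating
        extend_vocabulary(model, val_ds.smiles)
        report = evaluate_model(model, val_ds)
        history.fold_losses.append(run.per_epoch_loss)
        history.fold_metrics.append(report)
        history.models.append(model)
    return history


def select_best_model(history: TrainingHistory) -> int:
    """Fold index with the highest validation accuracy; ties go to the
    lowest index."""
    if not history.fold_metrics:
        raise ValueError("empty history: no folds completed")
    accuracies = [r.accuracy for r in history.fold_metrics]
    return int(np.argmax(accuracies))


# ---------------------------------------------------------------------------
# Transfer learning
# ---------------------------------------------------------------------------


def apply_transfer_strategy(
    model: PathwayModel,
    strategy: TransferStrategy | str,
    new_label_count: int,
    label_names: tuple[str, ...] | None = None,
) -> PathwayModel:
    """Prepare a pre-trained model for fine-tuning: deep-copy it, swap the
    output layer to the new label width, and record the freezing scheme on
    the copy (``model.transfer_strategy``). The source model is untouched."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    elif strategy.name not in STRATEGIES:
        raise ValueError(f"unknown transfer strategy {strategy.name!r}")
    clone_config = copy.deepcopy(model.config)
    clone = PathwayModel(clone_config, tokenizer=SmilesTokenizer(model.tokenizer.tokens[1:], model.tokenizer.max_len),
                         label_names=model.label_names)
    clone.load_state_dict(model.state_dict())
    clone.replace_output_layer(new_label_count, label_names=label_names)
    clone.transfer_strategy = strategy
    return clone


def finetune(
    model: PathwayModel,
    dataset: LabeledDataset,
    train_config: TrainConfig | None = None,
) -> tuple[PathwayModel, TrainingHistory]:
    """Fine-tune a transfer-prepared model at the reduced learning rate.
    Parameters in the strategy's frozen groups receive no updates."""
    strategy = getattr(model, "transfer_strategy", None)
    if strategy is None:
        raise ValueError("model was not prepared by apply_transfer_strategy")
    if train_config is None:
        train_config = TrainConfig(learning_rate=FINETUNE_LR)
    return train_model(dataset, model.config, train_config, model=model,
                       frozen_groups=strategy.frozen_groups)
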