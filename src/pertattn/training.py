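"""Control pairing, condition-level splits and the training loop.

Splits are made at *condition* granularity: all cells of a perturbation
condition land in exactly one of train/validation/test, which turns
evaluation into an out-of-distribution task over unseen conditions.  Test
conditions are labeled by how many of their perturbed genes were
individually perturbed in the training conditions ("seen s/m").

Training pairs every perturbed cell with a uniformly sampled control cell
(once, as a preprocessing step), then minimizes the combined autofocus +
direction-aware loss with Adam over shuffled mini-batches.  The parameters
with the best validation loss are returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor, no_grad
from .go_graph import WeightedGeneGraph
from .io import (Condition, EmbeddingTable, ExpressionMatrix, GeneIndex,
                 format_condition, parse_condition)
from .model import Model, ModelConfig, init_model
from .sgconv import normalize_adjacency


@dataclass
class PairedSample:
    """A perturbed cell paired with a sampled control cell."""

    control: np.ndarray
    target: np.ndarray
    condition: Condition


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")


@dataclass
class SplitSpec:
    """Disjoint condition partitions plus generalization-class labels."""

    train: list[Condition]
    val: list[Condition]
    test: list[Condition]
    class_of: dict[Condition, str] = field(default_factory=dict)

    def __post_init__(self):
        parts = [set(self.train), set(self.val), set(self.test)]
        if (parts[0] & parts[1]) or (parts[0] & parts[2]) or (parts[1] & parts[2]):
            raise ValueError("split partitions overlap at condition level")
        missing = [c for c in self.test if c not in self.class_of]
        if missing:
            raise ValueError(f"{len(missing)} test conditions lack class labels")

    def train_genes(self) -> set[int]:
        return {g for c in self.train for g in c.genes}

    def to_json(self, genes: GeneIndex) -> str:
        return json.dumps({
            "train": [format_condition(c, genes) for c in self.train],
            "val": [format_condition(c, genes) for c in self.val],
            "test": [format_condition(c, genes) for c in self.test],
            "class_of": {format_condition(c, genes): lab
                         for c, lab in self.class_of.items()},
        }, indent=1)

    @classmethod
    def from_json(cls, text: str, genes: GeneIndex) -> "SplitSpec":
        raw = json.loads(text)
        parse = lambda s: parse_condition(s, genes)
        return cls(train=[parse(s) for s in raw["train"]],
                   val=[parse(s) for s in raw["val"]],
                   test=[parse(s) for s in raw["test"]],
                   class_of={parse(s): lab for s, lab in raw["class_of"].items()})


def pair_controls(data: ExpressionMatrix, seed: int) -> list[PairedSample]:
    """Pair each perturbed cell with a control drawn uniformly w/ replacement."""
    ctrl_rows = np.nonzero(data.control_mask())[0]
    if ctrl_rows.size == 0:
        raise ValueError("dataset has no control cells")
    pert_rows = np.nonzero(~data.control_mask())[0]
    rng = np.random.default_rng(seed)
    picks = ctrl_rows[rng.integers(0, ctrl_rows.size, size=pert_rows.size)]
    return [PairedSample(control=data.values[ci], target=data.values[pi],
                         condition=data.conditions[pi])
            for pi, ci in zip(pert_rows, picks)]


def classify_condition(c: Condition, train_genes: set[int]) -> str:
    """Generalization class of a test condition: 'seen s/m'."""
    if c.m not in (1, 2):
        raise ValueError(f"generalization classes are defined for m in {{1,2}}, "
                         f"got m={c.m}")
    s = len(set(c.genes) & train_genes)
    return f"seen {s}/{c.m}"


def make_split(conditions: list[Condition], fractions=(0.75, 0.10, 0.15),
               seed: int = 0) -> SplitSpec:
    """Random condition-level split; floor each partition, remainder to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if any(c.is_control for c in conditions):
        raise ValueError("control conditions cannot be split")
    conditions = sorted(set(conditions), key=lambda c: c.genes)
    n = len(conditions)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train += n - n_train - n_val - n_test
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(f"a partition would be empty for {n} conditions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [conditions[i] for i in order]
    train = shuffled[:n_train]
    val = shuffled[n_train:n_train + n_val]
    test = shuffled[n_train + n_val:]
    genes = {g for c in train for g in c.genes}
    class_of = {c: classify_condition(c, genes) for c in test}
    return SplitSpec(train, val, test, class_of)


def make_combo_holdout_split(conditions: list[Condition], n_test: int = 4,
                             n_val: int = 2, seed: int = 0) -> SplitSpec:
    """Hold out two-gene conditions for validation and test.

    Every other condition — in particular every single-gene condition —
    stays in train, so the held-out combinations probe how well the model
    composes individually observed perturbations ("seen 2/2" when both
    genes are perturbed somewhere in train).  Using combinations for the
    validation set matters: checkpoint selection then tracks the
    combination-generalization task instead of the unlearnable effects of
    never-perturbed genes.
    """
    doubles = sorted({c for c in conditions if c.m == 2}, key=lambda c: c.genes)
    if len(doubles) < n_test + n_val:
        raise ValueError(
            f"need {n_test + n_val} two-gene conditions, have {len(doubles)}")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(doubles), size=n_test + n_val, replace=False)
    test = [doubles[i] for i in pick[:n_test]]
    val = [doubles[i] for i in pick[n_test:]]
    held = set(test) | set(val)
    train = [c for c in sorted(set(conditions), key=lambda c: c.genes)
             if c not in held]
    if not train:
        raise ValueError("holding out the combinations empties the train set")
    genes = {g for c in train for g in c.genes}
    class_of = {c: classify_condition(c, genes) for c in test}
    return SplitSpec(train, val, test, class_of)


@dataclass
class TrainResult:
    model: Model
    history: pd.DataFrame   # columns: epoch, train_loss, val_loss
    best_epoch: int


def _batch_loss(model: Model, z_uniq: np.ndarray, cond_idx: np.ndarray,
                x: np.ndarray, y: np.ndarray, ctrl_mean: np.ndarray,
                go_prop, aug_prop, training: bool) -> tuple[Tensor, float]:
    """Differentiable autofocus term + (constant) direction term.

    The direction term is piecewise constant in the parameters, so it is
    reported in the loss value but contributes no gradient.
    """
    cfg = model.config
    shifts = model.forward_shifts(z_uniq, go_prop, aug_prop, training)  # (C,K)
    pred = shifts.take_rows(cond_idx) + Tensor(x)                       # (B,K)
    autofocus = ((pred - Tensor(y)).abs() ** (2.0 + cfg.gamma)).mean()
    direction = cfg.lambda_dir * np.mean(
        (np.sign(y - ctrl_mean) - np.sign(pred.data - ctrl_mean)) ** 2)
    return autofocus, float(autofocus.item() + direction)


def _stack_conditions(samples: list[PairedSample], n_genes: int):
    """Unique-condition indicators plus per-sample condition indices."""
    uniq: dict[Condition, int] = {}
    for s in samples:
        uniq.setdefault(s.condition, len(uniq))
    z = np.zeros((len(uniq), n_genes))
    for c, i in uniq.items():
        z[i] = c.indicator(n_genes)
    idx = np.array([uniq[s.condition] for s in samples], dtype=np.intp)
    x = np.stack([s.control for s in samples])
    y = np.stack([s.target for s in samples])
    return z, idx, x, y


def train(data: ExpressionMatrix, go_graph: WeightedGeneGraph,
          aug_graph: WeightedGeneGraph, split: SplitSpec,
          mconfig: ModelConfig, tconfig: TrainConfig,
          embeddings: EmbeddingTable | None = None) -> TrainResult:
    """Fit the model on the split's train conditions; select by val loss."""
    if go_graph.n_nodes != data.n_genes or aug_graph.n_nodes != data.n_genes:
        raise ValueError("graphs and dataset cover different gene sets")
    if not split.train:
        raise ValueError("empty train partition")
    if mconfig.n_genes != data.n_genes:
        raise ValueError("model config n_genes does not match the dataset")

    rng = np.random.default_rng(tconfig.seed)
    sub = np.random.SeedSequence(tconfig.seed).generate_state(3) % (2 ** 31)
    pairs = pair_controls(data, int(sub[0]))
    train_set = set(split.train)
    val_set = set(split.val)
    train_pairs = [p for p in pairs if p.condition in train_set]
    val_pairs = [p for p in pairs if p.condition in val_set]
    if not train_pairs:
        raise ValueError("no training cells for the train conditions")

    go_prop = normalize_adjacency(go_graph, mconfig.hops)
    aug_prop = normalize_adjacency(aug_graph, mconfig.hops)
    ctrl_mean = data.values[data.control_mask()].mean(axis=0)

    model = init_model(mconfig, embeddings, seed=int(sub[1]))
    model.gene_names = list(data.gene_index.names)
    opt = Adam(model.parameters(), lr=tconfig.learning_rate)

    zv, iv, xv, yv = (_stack_conditions(val_pairs, data.n_genes)
                      if val_pairs else (None,) * 4)
    order = np.arange(len(train_pairs))
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    for epoch in range(1, tconfig.epochs + 1):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, order.size, tconfig.batch_size):
            batch = [train_pairs[i] for i in order[start:start + tconfig.batch_size]]
            z, idx, x, y = _stack_conditions(batch, data.n_genes)
            opt.zero_grad()
            autofocus, total = _batch_loss(model, z, idx, x, y, ctrl_mean,
                                           go_prop, aug_prop, training=True)
            autofocus.backward()
            opt.step()
            epoch_losses.append(total)
        train_loss = float(np.mean(epoch_losses))
        if val_pairs:
            with no_grad():
                _, val_loss = _batch_loss(model, zv, iv, xv, yv, ctrl_mean,
                                          go_prop, aug_prop, training=False)
        else:
            val_loss = train_loss
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
    model.load_state_dict(best_state)
    frame = pd.DataFrame(history)
    return TrainResult(model=model, history=frame, best_epoch=best_epoch)
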