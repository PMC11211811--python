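"""The perturbation-response network.

The model maps a perturbation condition ``c`` (a set of perturbed genes) to
a predicted per-gene expression shift ``g(c)`` of length K, which is added
to a sampled control cell to give the post-perturbation prediction.  Two
encoders feed a gene-specific decoder:

* **PertWeight** — nonuniform global effects.  Gene embeddings are
  propagated through the GO similarity graph by SGConv operators into
  queries, keys and values of a multi-head attention; the value rows are
  masked by the 0/1 perturbation indicators, so each gene's encoding is a
  learned, weighted sum of the perturbed genes' effect vectors, plus a
  general-effect term that sums the perturbed genes' propagated rows.
  This encoder is additive over the perturbed genes (before the output
  projections).

* **PertLocal** — localized disturbance.  Indicator embeddings are biased
  by a nonadditive (NA) modulation ``1 + beta (m-1) tanh(K_NA z)`` — the
  identity whenever a single gene is perturbed — added to a gene base
  embedding, and propagated through the fully connected augmented GO graph.
  This is the only component that can express nonadditive co-effects of
  multi-gene perturbations.

The decoder applies a shared feed-forward map followed by a per-gene linear
read-out, ``g_k = w_k^T f5(h_k^PW + h_k^PL) + b_k``: no cross-gene layer,
so each gene's shift depends only on its own row of the summed encodings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, no_grad, parameter, softmax
from .io import Condition, EmbeddingTable
from .sgconv import Propagator

_BN_EPS = 1e-5
_LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyper-parameters (defaults follow the reference setup)."""

    n_genes: int
    d_embed: int = 200      # gene embedding width D_e (Gene2Vec width)
    d_hidden: int = 64      # network hidden size D
    n_heads: int = 2        # attention heads H
    d_qk: int = 64          # query/key head width (d_q = d_k)
    d_v: int = 64           # value head width
    d_p: int = 64           # general-effect projection width D_p
    d_b: int = 64           # local-encoder SGConv width D_b
    hops: int = 1           # SGConv hop count t
    alpha: float = 0.75     # augmented-graph virtual-edge factor
    beta: float = 0.05      # NA-bias strength
    gamma: float = 1.0      # autofocus loss exponent offset
    lambda_dir: float = 0.1 # direction-aware loss weight

    def __post_init__(self):
        for name in ("n_genes", "d_embed", "d_hidden", "n_heads",
                     "d_qk", "d_v", "d_p", "d_b"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if not (0 <= self.beta < 1):
            raise ValueError("beta must be in [0, 1)")
        if self.hops < 0:
            raise ValueError("hops must be >= 0")


class _Linear:
    """y = x W + b."""

    def __init__(self, rng, d_in: int, d_out: int, prefix: str):
        self.w = parameter(None, rng, (d_in, d_out), 1.0 / np.sqrt(d_in))
        self.b = parameter(np.zeros(d_out))
        self.prefix = prefix

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def params(self):
        return {f"{self.prefix}.w": self.w, f"{self.prefix}.b": self.b}


class _LayerNorm:
    """Normalize the last axis, with learnable gain/bias."""

    def __init__(self, d: int, prefix: str):
        self.gain = parameter(np.ones(d))
        self.bias = parameter(np.zeros(d))
        self.prefix = prefix

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + _LN_EPS).sqrt() * self.gain + self.bias

    def params(self):
        return {f"{self.prefix}.gain": self.gain, f"{self.prefix}.bias": self.bias}


class _BatchNorm:
    """Per-feature normalization over the gene axis of a (C, K, D) encoding.

    Training mode uses each condition's own gene-axis statistics and updates
    running statistics; evaluation mode uses the stored running statistics,
    making the forward pass deterministic given the parameters.
    """

    def __init__(self, d: int, prefix: str, momentum: float = 0.1):
        self.gain = parameter(np.ones(d))
        self.bias = parameter(np.zeros(d))
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.prefix = prefix

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=-2, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=-2, keepdims=True)
            batch_axes = tuple(range(mu.data.ndim - 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.mean(axis=batch_axes))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.mean(axis=batch_axes))
            return (x - mu) / (var + _BN_EPS).sqrt() * self.gain + self.bias
        xhat = (x - Tensor(self.running_mean)) \
            * Tensor(1.0 / np.sqrt(self.running_var + _BN_EPS))
        return xhat * self.gain + self.bias

    def params(self):
        return {f"{self.prefix}.gain": self.gain, f"{self.prefix}.bias": self.bias}

    def stats(self):
        return {f"{self.prefix}.running_mean": self.running_mean,
                f"{self.prefix}.running_var": self.running_var}


class Model:
    """All trainable state of the perturbation-response network."""

    def __init__(self, config: ModelConfig, embeddings: EmbeddingTable | None,
                 seed: int):
        cfg = config
        if embeddings is not None and embeddings.d_e != cfg.d_embed:
            raise ValueError(
                f"embedding width {embeddings.d_e} does not match d_embed "
                f"{cfg.d_embed}")
        rng = np.random.default_rng(seed)
        k, de = cfg.n_genes, cfg.d_embed
        emb_scale = 1.0 / np.sqrt(de)

        def gene_embedding():
            if embeddings is not None:
                return parameter(embeddings.matrix)
            return parameter(None, rng, (k, de), emb_scale)

        # PertWeight: weight/pert embeddings, four SGConv projections, f1/f2
        self.e_w = gene_embedding()
        self.e_p = gene_embedding()
        self.t_q = parameter(None, rng, (de, cfg.n_heads * cfg.d_qk), emb_scale)
        self.t_k = parameter(None, rng, (de, cfg.n_heads * cfg.d_qk), emb_scale)
        self.t_v = parameter(None, rng, (de, cfg.n_heads * cfg.d_v), emb_scale)
        self.t_p = parameter(None, rng, (de, cfg.d_p), emb_scale)
        self.f1 = _Linear(rng, cfg.n_heads * cfg.d_v, cfg.d_hidden, "f1")
        self.f1_ln = _LayerNorm(cfg.d_hidden, "f1_ln")
        self.f2 = _Linear(rng, cfg.d_p, cfg.d_hidden, "f2")
        self.f2_ln = _LayerNorm(cfg.d_hidden, "f2_ln")

        # PertLocal: base/indicator embeddings, NA-bias weight, SGConv, f3/f4
        self.e_g = gene_embedding()
        self.e_z = parameter(None, rng, (2, de), emb_scale)
        self.k_na = parameter(None, rng, (de, k), 1.0 / np.sqrt(k))
        self.t_b = parameter(None, rng, (de, cfg.d_b), emb_scale)
        self.f3 = _Linear(rng, cfg.d_b, cfg.d_hidden, "f3")
        self.f3_bn = _BatchNorm(cfg.d_hidden, "f3_bn")
        self.f4 = _Linear(rng, de, cfg.d_hidden, "f4")
        self.f4_bn = _BatchNorm(cfg.d_hidden, "f4_bn")

        # decoder: shared feed-forward f5 then per-gene linear read-out
        d = cfg.d_hidden
        self.f5_w1 = parameter(None, rng, (d, d), 1.0 / np.sqrt(d))
        self.f5_b1 = parameter(np.zeros(d))
        self.f5_w2 = parameter(None, rng, (d, d), 1.0 / np.sqrt(d))
        self.f5_b2 = parameter(np.zeros(d))
        self.dec_w = parameter(None, rng, (k, d), 1.0 / np.sqrt(d))
        self.dec_b = parameter(np.zeros(k))

        self.config = cfg
        self.gene_names: list[str] | None = None

    # -- parameter bookkeeping ------------------------------------------------

    def _named_params(self) -> dict[str, Tensor]:
        out = {"e_w": self.e_w, "e_p": self.e_p, "t_q": self.t_q,
               "t_k": self.t_k, "t_v": self.t_v, "t_p": self.t_p,
               "e_g": self.e_g, "e_z": self.e_z, "k_na": self.k_na,
               "t_b": self.t_b, "f5_w1": self.f5_w1, "f5_b1": self.f5_b1,
               "f5_w2": self.f5_w2, "f5_b2": self.f5_b2,
               "dec_w": self.dec_w, "dec_b": self.dec_b}
        for layer in (self.f1, self.f1_ln, self.f2, self.f2_ln,
                      self.f3, self.f3_bn, self.f4, self.f4_bn):
            out.update(layer.params())
        return out

    def parameters(self) -> list[Tensor]:
        return list(self._named_params().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self._named_params().items()}
        for bn in (self.f3_bn, self.f4_bn):
            state.update({name: arr.copy() for name, arr in bn.stats().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self._named_params().items():
            p.data = np.array(state[name], dtype=np.float64, copy=True)
        self.f3_bn.running_mean = np.array(state["f3_bn.running_mean"], copy=True)
        self.f3_bn.running_var = np.array(state["f3_bn.running_var"], copy=True)
        self.f4_bn.running_mean = np.array(state["f4_bn.running_mean"], copy=True)
        self.f4_bn.running_var = np.array(state["f4_bn.running_var"], copy=True)

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        """Write a checkpoint directory: config JSON + parameter blob."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {"config": asdict(self.config), "gene_names": self.gene_names}
        (path / "config.json").write_text(json.dumps(meta, indent=1))
        np.savez(path / "params.npz", **self.state_dict())

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        model = cls(ModelConfig(**meta["config"]), None, seed=0)
        with np.load(path / "params.npz") as blob:
            model.load_state_dict({name: blob[name] for name in blob.files})
        model.gene_names = meta.get("gene_names")
        return model

    # -- differentiable forward pieces (batched over conditions) --------------

    def _propagate(self, s: np.ndarray, x: Tensor, hops: int) -> Tensor:
        st = Tensor(s)
        for _ in range(hops):
            x = st @ x
        return x

    def _pertweight_batch(self, z: np.ndarray, go_prop: Propagator):
        """PertWeight for a (C, K) indicator batch.

        Returns (h_pw, h_mha, sum_p) with shapes (C, K, D), (C, K, H*d_v)
        and (C, D_p); the last two are the pre-projection parts.
        """
        cfg = self.config
        k, h, dqk, dv = cfg.n_genes, cfg.n_heads, cfg.d_qk, cfg.d_v
        c = z.shape[0]
        zt = Tensor(z)

        pre_w = self._propagate(go_prop.s, self.e_w, go_prop.hops)
        pre_p = self._propagate(go_prop.s, self.e_p, go_prop.hops)
        q = (pre_w @ self.t_q).reshape(k, h, dqk).transpose(1, 0, 2)   # (H,K,dq)
        key = (pre_w @ self.t_k).reshape(k, h, dqk).transpose(1, 0, 2)
        v = (pre_p @ self.t_v).reshape(k, h, dv).transpose(1, 0, 2)    # (H,K,dv)
        p = pre_p @ self.t_p                                           # (K,Dp)

        scores = (q @ key.swapaxes(-1, -2)) * (1.0 / np.sqrt(dqk))     # (H,K,K)
        attn = softmax(scores, axis=-1)
        v_masked = zt.reshape(c, 1, k, 1) * v                          # (C,H,K,dv)
        h_mha = (attn @ v_masked).transpose(0, 2, 1, 3).reshape(c, k, h * dv)
        sum_p = zt @ p                                                 # (C,Dp)
        h_pw = (self.f1_ln(self.f1(h_mha))
                + self.f2_ln(self.f2(sum_p)).reshape(c, 1, cfg.d_hidden))
        aux = {"attention": attn, "v_masked": v_masked,
               "h_mha": h_mha, "sum_p": sum_p}
        return h_pw, aux

    def _na_bias_batch(self, z: np.ndarray, beta: float):
        """Indicator embedding with NA-bias for a (C, K) indicator batch.

        Returns (e_z_biased, e_z_plain), both (C, K, D_e).
        """
        cfg = self.config
        c, k = z.shape
        zt = Tensor(z)
        m = z.sum(axis=1)                                    # (C,)
        ez0 = self.e_z.take_rows([0]).reshape(1, 1, cfg.d_embed)
        ez1 = self.e_z.take_rows([1]).reshape(1, 1, cfg.d_embed)
        z3 = zt.reshape(c, k, 1)
        e_z = (1.0 - z3) * ez0 + z3 * ez1                    # (C,K,De)
        act = (zt @ self.k_na.swapaxes(0, 1)).tanh()         # (C,De)
        mod = 1.0 + Tensor(beta * (m - 1.0)).reshape(c, 1) * act
        return e_z * mod.reshape(c, 1, cfg.d_embed), e_z

    def _pertlocal_batch(self, z: np.ndarray, aug_prop: Propagator,
                         training: bool):
        """PertLocal for a (C, K) indicator batch -> (C, K, D)."""
        cfg = self.config
        e_z_biased, e_z = self._na_bias_batch(z, cfg.beta)
        k, de = cfg.n_genes, cfg.d_embed
        base = self.e_g.reshape(1, k, de) + e_z_biased
        sgc = self._propagate(aug_prop.s, base, aug_prop.hops) @ self.t_b
        h3 = self.f3_bn(self.f3(sgc), training)
        h4 = self.f4_bn(self.f4(e_z), training)
        return h3 + h4

    def _decode_batch(self, h: Tensor) -> Tensor:
        """Per-gene read-out of a (C, K, D) encoding -> (C, K) shifts."""
        hidden = ((h @ self.f5_w1 + self.f5_b1).relu() @ self.f5_w2 + self.f5_b2)
        return (hidden * self.dec_w.reshape((1,) + self.dec_w.shape)).sum(axis=-1) \
            + self.dec_b

    def forward_shifts(self, z_batch: np.ndarray, go_prop: Propagator,
                       aug_prop: Propagator, training: bool = False) -> Tensor:
        """Predicted expression shifts for a (C, K) batch of indicators."""
        h_pw, _ = self._pertweight_batch(z_batch, go_prop)
        h_pl = self._pertlocal_batch(z_batch, aug_prop, training)
        return self._decode_batch(h_pw + h_pl)


def init_model(config: ModelConfig, embeddings: EmbeddingTable | None = None,
               seed: int = 0) -> Model:
    """Create a model; embeddings (when given) initialize e_w, e_p and e_g."""
    return Model(config, embeddings, seed)


# -- single-condition operations (thin wrappers over the batched path) --------

def _as_indicator(z, n_genes: int) -> np.ndarray:
    if isinstance(z, Condition):
        return z.indicator(n_genes)
    z = np.asarray(z, dtype=np.float64)
    if z.shape != (n_genes,):
        raise ValueError(f"indicator must have length {n_genes}")
    return z


def pertweight_forward(z, model: Model, go_prop: Propagator,
                       return_parts: bool = False):
    """PertWeight encoding (K x D) for one condition.

    With ``return_parts`` also returns a dict of intermediates: the
    per-head attention matrices (H, K, K), the masked value tensor, the
    pre-projection attention output H_MHA (K x H*d_v) and the summed
    general-effect vector (D_p,).
    """
    zb = _as_indicator(z, model.config.n_genes)[None, :]
    with no_grad():
        h_pw, aux = model._pertweight_batch(zb, go_prop)
    if return_parts:
        parts = {"attention": aux["attention"].data,
                 "v_masked": aux["v_masked"].data[0],
                 "h_mha": aux["h_mha"].data[0],
                 "sum_p": aux["sum_p"].data[0]}
        return h_pw.data[0], parts
    return h_pw.data[0]


def na_bias(z, model: Model, beta: float | None = None) -> np.ndarray:
    """NA-biased indicator embedding E'_z (K x D_e) for one condition."""
    beta = model.config.beta if beta is None else beta
    zb = _as_indicator(z, model.config.n_genes)[None, :]
    with no_grad():
        biased, _ = model._na_bias_batch(zb, beta)
    return biased.data[0]


def pertlocal_forward(z, model: Model, aug_prop: Propagator,
                      training: bool = False) -> np.ndarray:
    """PertLocal encoding (K x D) for one condition."""
    zb = _as_indicator(z, model.config.n_genes)[None, :]
    if training:
        h_pl = model._pertlocal_batch(zb, aug_prop, True)
        return h_pl.data[0]
    with no_grad():
        h_pl = model._pertlocal_batch(zb, aug_prop, False)
    return h_pl.data[0]


def decode(h_pw: np.ndarray, h_pl: np.ndarray, model: Model) -> np.ndarray:
    """Per-gene decoding of summed encodings into a length-K shift."""
    h = np.asarray(h_pw) + np.asarray(h_pl)
    if h.shape != (model.config.n_genes, model.config.d_hidden):
        raise ValueError("encoding shape does not match the model")
    with no_grad():
        out = model._decode_batch(Tensor(h[None]))
    return out.data[0]


def predict(c: Condition, control_cell: np.ndarray, model: Model,
            go_prop: Propagator, aug_prop: Propagator) -> np.ndarray:
    """Predicted post-perturbation expression: shift(c) + control cell."""
    control_cell = np.asarray(control_cell, dtype=np.float64)
    if not np.all(np.isfinite(control_cell)):
        raise ValueError("control cell contains non-finite values")
    return predict_shift(c, model, go_prop, aug_prop) + control_cell


def predict_shift(c: Condition, model: Model, go_prop: Propagator,
                  aug_prop: Propagator) -> np.ndarray:
    """Predicted expression shift g(c) (length K, evaluation mode)."""
    zb = _as_indicator(c, model.config.n_genes)[None, :]
    with no_grad():
        out = model.forward_shifts(zb, go_prop, aug_prop, training=False)
    return out.data[0]


def combined_loss(pred: np.ndarray, truth: np.ndarray, ctrl_mean: np.ndarray,
                  gamma: float = 1.0, lambda_dir: float = 0.1) -> float:
    """Autofocus plus direction-aware loss.

    ``mean |pred - truth|^(2+gamma)`` plus ``lambda_dir`` times the mean
    squared difference of the shift signs relative to the control mean
    (sign(0) = 0, so a zero shift mismatches any nonzero one).
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    autofocus = np.mean(np.abs(pred - truth) ** (2.0 + gamma))
    direction = np.mean(
        (np.sign(truth - ctrl_mean) - np.sign(pred - ctrl_mean)) ** 2)
    return float(autofocus + lambda_dir * direction)
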