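"""Synthetic perturb-seq generator with known ground truth.

Emulates the structure of pooled CRISPR screens with single-cell readout:
control cells around a baseline expression profile, single-gene conditions
that shift a sparse set of genes, and two-gene conditions whose shift is
the sum of the single shifts plus, for a configurable fraction of pairs, a
nonadditive interaction component.  Noise is Gaussian on the log-expression
scale (the model and every metric operate on log-normalized values, so
count-level noise would add complexity without exercising anything).

Genes are organized into latent modules.  A matching synthetic GO
annotation table gives genes of the same module extra shared terms, and
perturbation effects concentrate on the perturbed gene's module, so the
ontology graph genuinely carries signal about which genes respond.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .io import Condition, ExpressionMatrix, GeneIndex


@dataclass
class SyntheticSpec:
    """Generator settings; defaults define the package's reference fixture."""

    k_genes: int = 60
    n_terms: int = 120
    terms_per_gene: tuple[int, int] = (4, 10)
    n_modules: int = 6
    n_single: int = 30
    n_double: int = 16
    cells_per_condition: int = 50
    n_control_cells: int = 200
    effect_scale: float = 1.0        # typical |delta| of a perturbed gene
    effect_sparsity: float = 0.15    # fraction of genes a perturbation touches
    interaction_fraction: float = 0.25
    interaction_scale: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("k_genes", "n_terms", "n_modules", "n_single", "n_double",
                     "cells_per_condition", "n_control_cells"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("effect_sparsity", "interaction_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_terms < self.terms_per_gene[1]:
            raise ValueError("n_terms must cover the terms_per_gene range")
        if self.n_single > self.k_genes:
            raise ValueError("cannot perturb more genes than the panel has")

    def gene_names(self) -> list[str]:
        width = len(str(self.k_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.k_genes)]

    def module_of(self, gene: int) -> int:
        """Deterministic block assignment of genes to latent modules."""
        return gene * self.n_modules // self.k_genes


@dataclass
class GroundTruth:
    """The generator's bookkeeping: true shifts for every condition."""

    baseline: np.ndarray
    single_effects: dict[int, np.ndarray]
    pair_effects: dict[Condition, np.ndarray]
    interactions: dict[Condition, np.ndarray] = field(default_factory=dict)

    def conditions(self) -> list[Condition]:
        singles = [Condition([g]) for g in self.single_effects]
        return singles + list(self.pair_effects)


def true_shift(gt: GroundTruth, c: Condition) -> np.ndarray:
    """The generator's true expression shift for condition ``c``."""
    if c.is_control:
        return np.zeros_like(gt.baseline)
    if c.m == 1:
        g = c.genes[0]
        if g not in gt.single_effects:
            raise KeyError(f"gene {g} was not perturbed by the generator")
        return gt.single_effects[g].copy()
    if c in gt.pair_effects:
        return gt.pair_effects[c].copy()
    raise KeyError(f"condition {c} unknown to the generator")


def simulate_annotations(spec: SyntheticSpec) -> dict[str, set[str]]:
    """Seeded synthetic GO annotations with module block structure.

    Half the term vocabulary is split into per-module pools; each gene
    draws most of its terms from its module's pool and the rest from the
    shared remainder, so within-module Jaccard similarity exceeds
    between-module similarity.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    terms = [f"T{i:04d}" for i in range(spec.n_terms)]
    pool_size = max(1, spec.n_terms // (2 * spec.n_modules))
    pools = [terms[m * pool_size:(m + 1) * pool_size]
             for m in range(spec.n_modules)]
    shared = terms[spec.n_modules * pool_size:]
    lo, hi = spec.terms_per_gene
    table: dict[str, set[str]] = {}
    for gene, name in enumerate(spec.gene_names()):
        n = int(rng.integers(lo, hi + 1))
        pool = pools[spec.module_of(gene)]
        n_mod = min(len(pool), max(1, int(round(0.6 * n))))
        picked = set(rng.choice(pool, size=n_mod, replace=False))
        n_shared = min(len(shared), n - n_mod)
        if n_shared > 0:
            picked |= set(rng.choice(shared, size=n_shared, replace=False))
        table[name] = picked
    return table


def _single_effect(rng, spec: SyntheticSpec, gene: int) -> np.ndarray:
    """Sparse shift concentrated on the perturbed gene's module."""
    k = spec.k_genes
    n_affected = max(2, int(round(spec.effect_sparsity * k)))
    weights = np.ones(k)
    modules = np.array([spec.module_of(g) for g in range(k)])
    weights[modules == spec.module_of(gene)] = 4.0
    weights[gene] = 0.0
    weights /= weights.sum()
    others = rng.choice(k, size=n_affected - 1, replace=False, p=weights)
    delta = np.zeros(k)
    delta[others] = rng.normal(0.0, spec.effect_scale, size=others.size)
    # the perturbed gene itself drops (knockdown-like)
    delta[gene] = -spec.effect_scale * rng.uniform(0.5, 1.5)
    return delta


def simulate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate an expression matrix plus its generating ground truth."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 1)))
    k = spec.k_genes
    genes = GeneIndex(spec.gene_names())
    baseline = rng.uniform(0.5, 5.0, size=k)

    perturbed = rng.choice(k, size=spec.n_single, replace=False)
    single_effects = {int(g): _single_effect(rng, spec, int(g))
                      for g in perturbed}

    max_pairs = spec.n_single * (spec.n_single - 1) // 2
    if spec.n_double > max_pairs:
        raise ValueError("n_double exceeds the number of available pairs")
    pair_pool = [(int(perturbed[i]), int(perturbed[j]))
                 for i in range(spec.n_single)
                 for j in range(i + 1, spec.n_single)]
    chosen = rng.choice(len(pair_pool), size=spec.n_double, replace=False)
    n_interacting = int(round(spec.interaction_fraction * spec.n_double))
    pair_effects: dict[Condition, np.ndarray] = {}
    interactions: dict[Condition, np.ndarray] = {}
    for rank, pick in enumerate(chosen):
        i, j = pair_pool[pick]
        cond = Condition([i, j])
        additive = single_effects[i] + single_effects[j]
        inter = np.zeros(k)
        if rank < n_interacting:
            support = np.unique(np.concatenate([
                np.nonzero(single_effects[i])[0],
                np.nonzero(single_effects[j])[0]]))
            n_sup = max(1, support.size // 2)
            hit = rng.choice(support, size=n_sup, replace=False)
            inter[hit] = rng.normal(0.0, spec.interaction_scale, size=n_sup)
        pair_effects[cond] = additive + inter
        interactions[cond] = inter
    gt = GroundTruth(baseline, single_effects, pair_effects, interactions)

    conditions: list[Condition] = []
    blocks: list[np.ndarray] = []

    def add_block(cond: Condition, n_cells: int):
        shift = true_shift(gt, cond)
        noise = rng.normal(0.0, spec.noise_sd, size=(n_cells, k))
        blocks.append(baseline + shift + noise)
        conditions.extend([cond] * n_cells)

    add_block(Condition(), spec.n_control_cells)
    for g in sorted(single_effects):
        add_block(Condition([g]), spec.cells_per_condition)
    for cond in sorted(pair_effects, key=lambda c: c.genes):
        add_block(cond, spec.cells_per_condition)

    data = ExpressionMatrix(np.vstack(blocks), conditions, genes)
    return data, gt


def ground_truth_to_json(gt: GroundTruth, genes: GeneIndex) -> str:
    """Serialize ground truth (gene names as keys, '+'-joined for pairs)."""
    return json.dumps({
        "baseline": list(gt.baseline),
        "single_effects": {genes.names[g]: list(v)
                           for g, v in gt.single_effects.items()},
        "pair_effects": {"+".join(genes.names[g] for g in c.genes): list(v)
                         for c, v in gt.pair_effects.items()},
        "interactions": {"+".join(genes.names[g] for g in c.genes): list(v)
                         for c, v in gt.interactions.items()},
    })


def ground_truth_from_json(text: str, genes: GeneIndex) -> GroundTruth:
    raw = json.loads(text)

    def cond(s):
        return Condition([genes.index(n) for n in s.split("+")])

    return GroundTruth(
        baseline=np.array(raw["baseline"]),
        single_effects={genes.index(n): np.array(v)
                        for n, v in raw["single_effects"].items()},
        pair_effects={cond(s): np.array(v)
                      for s, v in raw["pair_effects"].items()},
        interactions={cond(s): np.array(v)
                      for s, v in raw["interactions"].items()},
    )
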