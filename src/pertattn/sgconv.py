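"""Simplified graph convolution (SGC) over weighted gene graphs.

A t-hop SGConv is a single linear operator: node features are propagated t
times through the symmetrically normalized adjacency with self-loops,

    S = D̃^{-1/2} (A + I) D̃^{-1/2},   D̃ = diag(rowsum(A + I)),

then projected once, ``SGC_{t,T}(A, E) = S^t E T``.  There are no
nonlinearities or biases between hops; those live in the downstream
feed-forward layers.  Dense K x K propagation is used throughout (the gene
panels this package targets are at most a few thousand genes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .go_graph import WeightedGeneGraph


@dataclass
class Propagator:
    """Normalized dense propagation matrix S plus the hop count t."""

    s: np.ndarray
    hops: int = 1

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=np.float64)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise ValueError("propagator matrix must be square")
        if self.hops < 0:
            raise ValueError("hop count must be >= 0")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("propagator contains non-finite entries")

    @property
    def n_nodes(self) -> int:
        return self.s.shape[0]

    def power(self) -> np.ndarray:
        """S^t as a dense matrix."""
        return np.linalg.matrix_power(self.s, self.hops)


def normalize_adjacency(g: WeightedGeneGraph, hops: int = 1) -> Propagator:
    """Build S = D̃^{-1/2}(A + I)D̃^{-1/2} from a weighted gene graph."""
    a = g.adjacency()
    a_tilde = a + np.eye(g.n_nodes)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    s = d_inv_sqrt[:, None] * a_tilde * d_inv_sqrt[None, :]
    return Propagator(s, hops)


def sgconv(p: Propagator, e: np.ndarray, t_w: np.ndarray) -> np.ndarray:
    """Evaluate ``S^t E T_w`` (hops = 0 reduces to ``E T_w``)."""
    e = np.asarray(e, dtype=np.float64)
    t_w = np.asarray(t_w, dtype=np.float64)
    if e.ndim != 2 or t_w.ndim != 2:
        raise ValueError("node features and projection must be 2-D")
    if e.shape[0] != p.n_nodes:
        raise ValueError(
            f"features have {e.shape[0]} rows but the graph has {p.n_nodes} nodes")
    if e.shape[1] != t_w.shape[0]:
        raise ValueError(
            f"feature width {e.shape[1]} does not match projection input "
            f"{t_w.shape[0]}")
    x = e
    for _ in range(p.hops):
        x = p.s @ x
    return x @ t_w
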