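"""Gene Ontology similarity graph construction.

Edge weights are the Jaccard similarity of two genes' GO term sets.  The
graph is sparsified by keeping, for each gene, its k highest-weight edges
(k = 20 by default), then taking the union over endpoints so the result is
symmetric.  A second, fully connected "augmented" graph assigns every
missing pair a virtual edge weighing ``alpha`` times the minimum existing
edge weight: the graph-propagated encoder can then learn lightweight,
rather than exactly zero, interactions between ontologically unrelated
genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneIndex


@dataclass
class WeightedGeneGraph:
    """Symmetric weighted gene-gene graph without self-edges.

    Edges are stored once per unordered pair, keyed ``(i, j)`` with
    ``i < j``; all stored weights are positive.
    """

    n_nodes: int
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        for (i, j), w in self.edges.items():
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"invalid edge key ({i}, {j})")
            if not (w > 0):
                raise ValueError(f"edge ({i}, {j}) has non-positive weight {w}")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        key = (i, j) if i < j else (j, i)
        return self.edges.get(key, 0.0)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric adjacency with zero diagonal."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edges.items():
            a[i, j] = w
            a[j, i] = w
        return a

    def min_weight(self) -> float:
        if not self.edges:
            raise ValueError("graph has no edges")
        return min(self.edges.values())


def jaccard_weight(terms_a: set, terms_b: set) -> float:
    """|A ∩ B| / |A ∪ B| for two non-empty annotation term sets."""
    if not terms_a or not terms_b:
        raise ValueError("Jaccard similarity is undefined for empty term sets")
    inter = len(terms_a & terms_b)
    union = len(terms_a | terms_b)
    return inter / union


def build_go_graph(annotations: dict[str, set[str]], genes: GeneIndex,
                   k: int = 20) -> WeightedGeneGraph:
    """All-pairs Jaccard similarities sparsified to each gene's top-k edges.

    Every modeled gene must be annotated.  Ties at the k-th weight are
    broken toward the smaller partner index; an edge survives if it is in
    the top-k of either endpoint.  Zero-weight pairs are never kept.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [name for name in genes if name not in annotations or
               not annotations[name]]
    if missing:
        raise ValueError(f"genes without GO annotations: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    n = len(genes)
    # indicator matrix over the term vocabulary -> vectorized all-pairs Jaccard
    vocab = sorted({t for name in genes for t in annotations[name]})
    t_idx = {t: i for i, t in enumerate(vocab)}
    ind = np.zeros((n, len(vocab)))
    for gi, name in enumerate(genes):
        for t in annotations[name]:
            ind[gi, t_idx[t]] = 1.0
    inter = ind @ ind.T
    sizes = ind.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    sim = inter / union
    np.fill_diagonal(sim, 0.0)

    kept: set[tuple[int, int]] = set()
    for i in range(n):
        partners = np.nonzero(sim[i] > 0)[0]
        if partners.size == 0:
            continue
        order = sorted(partners, key=lambda j: (-sim[i, j], j))
        for j in order[:k]:
            kept.add((i, j) if i < j else (j, i))
    edges = {key: float(sim[key]) for key in kept}
    return WeightedGeneGraph(n, edges)


def augment_graph(g: WeightedGeneGraph, alpha: float = 0.75) -> WeightedGeneGraph:
    """Make ``g`` fully connected with virtual edges of weight alpha * min.

    Existing weights are preserved bit-exactly; every previously missing
    pair receives ``alpha * min{positive weights of g}``.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    virtual = alpha * g.min_weight()   # raises on edgeless input
    edges = dict(g.edges)
    for i in range(g.n_nodes):
        for j in range(i + 1, g.n_nodes):
            if (i, j) not in edges:
                edges[(i, j)] = virtual
    return WeightedGeneGraph(g.n_nodes, edges)


def write_edge_list(g: WeightedGeneGraph, path, genes: GeneIndex) -> None:
    """Write an edge-list TSV (gene_i, gene_j, weight), one pair per line, i<j."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tweight\n")
        for (i, j) in sorted(g.edges):
            fh.write(f"{genes.names[i]}\t{genes.names[j]}\t{g.edges[(i, j)]:.10g}\n")


def read_edge_list(path, genes: GeneIndex) -> WeightedGeneGraph:
    edges: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_i"):
            raise ValueError(f"{path}: missing edge-list header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields")
            i, j = genes.index(fields[0]), genes.index(fields[1])
            if i > j:
                i, j = j, i
            edges[(i, j)] = float(fields[2])
    return WeightedGeneGraph(len(genes), edges)
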