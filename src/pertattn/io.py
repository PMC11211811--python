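"""Readers, writers and core containers for perturb-seq artifacts.

Conditions use the perturb-seq label dialect found throughout public
screens: ``"ctrl"`` for unperturbed cells, ``"GENE+ctrl"`` for single-gene
perturbations and ``"GENE1+GENE2"`` for combinatorial ones.  Expression is
log-normalized and kept dense (cells x genes); the on-disk encodings are a
dense TSV with a gene-name header, or a MatrixMarket triplet with gene/cell
sidecar files.  All readers tolerate CRLF line endings and ``#`` comment
lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CONTROL_TOKEN = "ctrl"


class GeneIndex:
    """Ordered, unique gene identifiers with 0-based index lookup."""

    def __init__(self, names):
        names = list(names)
        if len(names) < 2:
            raise ValueError("a gene index needs at least 2 genes")
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        self.names: list[str] = names
        self._lookup = {name: i for i, name in enumerate(names)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name) -> bool:
        return name in self._lookup

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneIndex) and self.names == other.names

    def index(self, name: str) -> int:
        try:
            return self._lookup[name]
        except KeyError:
            raise KeyError(f"unknown gene: {name!r}") from None


@dataclass(frozen=True)
class Condition:
    """A perturbation condition: the set of perturbed gene indices.

    ``m = 0`` denotes the unperturbed control condition.
    """

    genes: tuple[int, ...]

    def __init__(self, genes=()):
        genes = tuple(sorted(set(int(g) for g in genes)))
        object.__setattr__(self, "genes", genes)

    @property
    def m(self) -> int:
        return len(self.genes)

    @property
    def is_control(self) -> bool:
        return self.m == 0

    def indicator(self, n_genes: int) -> np.ndarray:
        """0/1 indicator vector z over all genes."""
        z = np.zeros(n_genes)
        z[list(self.genes)] = 1.0
        return z


def parse_condition(text: str, genes: GeneIndex) -> Condition:
    """Parse a condition string like ``"ctrl"``, ``"SOX14+ctrl"``, ``"FOXA1+HOXB9"``."""
    if not text or not text.strip():
        raise ValueError("empty condition string")
    tokens = [t.strip() for t in text.strip().split("+")]
    tokens = [t for t in tokens if t != CONTROL_TOKEN]
    indices = []
    for tok in tokens:
        if tok not in genes:
            raise KeyError(f"condition {text!r} names unknown gene {tok!r}")
        indices.append(genes.index(tok))
    if len(set(indices)) != len(indices):
        raise ValueError(f"condition {text!r} repeats a gene")
    return Condition(indices)


def format_condition(c: Condition, genes: GeneIndex) -> str:
    """Inverse of :func:`parse_condition` (names joined in gene-index order)."""
    if c.is_control:
        return CONTROL_TOKEN
    names = [genes.names[i] for i in c.genes]
    if c.m == 1:
        return f"{names[0]}+{CONTROL_TOKEN}"
    return "+".join(names)


@dataclass
class ExpressionMatrix:
    """Log-normalized expression (cells x genes) with per-cell conditions."""

    values: np.ndarray
    conditions: list[Condition]
    gene_index: GeneIndex
    cell_ids: list[str] = field(default=None)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (cells x genes)")
        n, k = self.values.shape
        if k != len(self.gene_index):
            raise ValueError(
                f"matrix has {k} genes but gene index has {len(self.gene_index)}")
        if len(self.conditions) != n:
            raise ValueError(
                f"{n} cells but {len(self.conditions)} condition labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        for c in self.conditions:
            if c.genes and c.genes[-1] >= k:
                raise ValueError("condition names a gene outside the gene index")
        if not any(c.is_control for c in self.conditions):
            raise ValueError("dataset has no control cells")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(n)]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def control_mask(self) -> np.ndarray:
        return np.array([c.is_control for c in self.conditions])

    def cells_of(self, c: Condition) -> np.ndarray:
        """Row indices of the cells measured under condition ``c``."""
        return np.array([i for i, ci in enumerate(self.conditions) if ci == c],
                        dtype=np.intp)

    def unique_conditions(self, include_control: bool = False) -> list[Condition]:
        seen = {}
        for c in self.conditions:
            if c.is_control and not include_control:
                continue
            seen.setdefault(c, None)
        return list(seen)

    def condition_mean(self, c: Condition) -> np.ndarray:
        rows = self.cells_of(c)
        if rows.size == 0:
            raise ValueError("condition has no cells")
        return self.values[rows].mean(axis=0)


@dataclass
class EmbeddingTable:
    """Per-gene real-valued embedding rows aligned to a GeneIndex."""

    gene_index: GeneIndex
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape[0] != len(self.gene_index):
            raise ValueError("embedding rows do not match the gene index")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("embedding table contains non-finite values")

    @property
    def d_e(self) -> int:
        return self.matrix.shape[1]


def _read_lines(path):
    with open(path, "r", newline=None) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_expression(matrix_path, cells_path=None, genes_path=None) -> ExpressionMatrix:
    """Load an expression matrix from dense TSV or MatrixMarket triplet.

    Dense TSV: header row of gene names, one row of floats per cell;
    ``cells_path`` supplies the per-cell conditions (columns: cell_id,
    condition).  MatrixMarket: ``matrix_path`` ends in ``.mtx`` and both
    ``genes_path`` (one gene name per line) and ``cells_path`` are required;
    the matrix is cells x genes.
    """
    if str(matrix_path).endswith(".mtx"):
        if genes_path is None or cells_path is None:
            raise ValueError("MatrixMarket input needs genes_path and cells_path")
        values = scipy.io.mmread(matrix_path)
        if scipy.sparse.issparse(values):
            values = values.toarray()
        values = np.asarray(values, dtype=np.float64)
        gene_names = [line.split("\t")[0] for _, line in _read_lines(genes_path)]
        genes = GeneIndex(gene_names)
    else:
        if cells_path is None:
            raise ValueError("dense TSV input needs cells_path")
        frame = pd.read_csv(matrix_path, sep="\t", comment="#")
        genes = GeneIndex(list(frame.columns))
        values = frame.to_numpy(dtype=np.float64)
    if np.isnan(values).any():
        raise ValueError(f"{matrix_path}: matrix contains NaN values")

    cells = pd.read_csv(cells_path, sep="\t", comment="#")
    if "condition" not in cells.columns:
        raise ValueError(f"{cells_path}: missing 'condition' column")
    if len(cells) != values.shape[0]:
        raise ValueError(
            f"matrix has {values.shape[0]} cells but {cells_path} lists {len(cells)}")
    if values.shape[1] != len(genes):
        raise ValueError(
            f"matrix has {values.shape[1]} genes but gene list has {len(genes)}")
    conditions = [parse_condition(str(s), genes) for s in cells["condition"]]
    cell_ids = [str(s) for s in cells["cell_id"]] if "cell_id" in cells.columns else None
    return ExpressionMatrix(values, conditions, genes, cell_ids)


def write_expression(data: ExpressionMatrix, matrix_path, cells_path,
                     genes_path=None, fmt: str = "tsv") -> None:
    """Write an ExpressionMatrix in either on-disk encoding (``tsv``/``mtx``)."""
    cells = pd.DataFrame({
        "cell_id": data.cell_ids,
        "condition": [format_condition(c, data.gene_index) for c in data.conditions],
    })
    cells.to_csv(cells_path, sep="\t", index=False)
    if fmt == "tsv":
        frame = pd.DataFrame(data.values, columns=data.gene_index.names)
        frame.to_csv(matrix_path, sep="\t", index=False, float_format="%.10g")
    elif fmt == "mtx":
        if genes_path is None:
            raise ValueError("mtx output needs genes_path")
        scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(data.values))
        with open(genes_path, "w") as fh:
            for name in data.gene_index.names:
                fh.write(name + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_embeddings(path, genes: GeneIndex, d_e: int = 200,
                    seed: int = 0) -> EmbeddingTable:
    """Load Gene2Vec-style embeddings: ``gene v1 ... v_{d_e}`` per line.

    Genes absent from the file receive seeded N(0, 1/d_e) rows so the table
    always covers the full gene index; the draw order follows the gene
    index, making the result deterministic given (file, seed).
    """
    vectors: dict[str, np.ndarray] = {}
    for lineno, line in _read_lines(path):
        parts = line.split()
        if len(parts) != d_e + 1:
            raise ValueError(
                f"{path}:{lineno}: expected 1 name + {d_e} floats, got "
                f"{len(parts)} fields")
        try:
            vec = np.array([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        vectors[parts[0]] = vec
    rng = np.random.default_rng(seed)
    matrix = np.empty((len(genes), d_e))
    for i, name in enumerate(genes):
        if name in vectors:
            matrix[i] = vectors[name]
        else:
            matrix[i] = rng.normal(0.0, 1.0 / np.sqrt(d_e), size=d_e)
    return EmbeddingTable(genes, matrix)


def read_annotations(path) -> dict[str, set[str]]:
    """Load a 2-column (gene_id, term_id) TSV into gene -> term-set."""
    terms: dict[str, set[str]] = {}
    n_lines = 0
    for lineno, line in _read_lines(path):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}")
        gene, term = fields[0].strip(), fields[1].strip()
        terms.setdefault(gene, set()).add(term)
        n_lines += 1
    if n_lines == 0:
        raise ValueError(f"{path}: empty annotation table")
    return terms


def write_annotations(terms: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in terms:
            for term in sorted(terms[gene]):
                fh.write(f"{gene}\t{term}\n")
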