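"""Reading, writing and normalising interaction networks and annotations.

Networks arrive as plain-text adjacency lists (``gene_a<TAB>gene_b<TAB>weight``,
one edge per line, weights in [0, 1], ``#`` comments allowed). A gene-index
file (one external id per line; the line number is the 0-based index) fixes
the node count *n* and the ordering shared by every network, so that feature
blocks from different networks stay aligned gene-by-gene.

Internally a :class:`WeightedGraph` holds a sparse symmetric adjacency matrix
over the shared index; :func:`to_transition` column-normalises it into the
Markov transition matrix used by the random-walk diffusion, where entry
``M[i, j]`` is the probability of stepping from gene *j* to gene *i*.
Annotations are a binary gene x label matrix; GO-style hierarchies are
handled by :func:`propagate_labels`, which closes each gene's label set over
the ancestor relation of a DAG.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "WeightedGraph",
    "TransitionMatrix",
    "LabelMatrix",
    "load_gene_index",
    "gene_index_checksum",
    "load_network",
    "symmetrize",
    "to_transition",
    "load_annotations",
    "load_dag",
    "propagate_labels",
    "write_gene_index",
    "write_network",
    "write_annotations",
]


class NetworkFormatError(ValueError):
    """Raised for malformed adjacency-list / annotation input."""


@dataclass
class WeightedGraph:
    """Weighted undirected interaction network over a fixed gene index.

    Parameters
    ----------
    adjacency
        ``n x n`` sparse matrix of edge confidences in [0, 1]. May be
        directed until :func:`symmetrize` is applied.
    id_map
        External gene id -> 0-based index. Genes absent from the edge file
        are isolated nodes; they are kept so all networks share one index.
    """

    adjacency: sp.csr_matrix
    id_map: Mapping[str, int] = field(default_factory=dict)
    name: str = ""
    n_duplicates: int = 0
    n_skipped: int = 0

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Undirected edge count (each pair counted once)."""
        a = sp.triu(self.adjacency.maximum(self.adjacency.T), k=0)
        return int(a.nnz)

    def edges(self) -> Iterable[tuple[int, int, float]]:
        coo = self.adjacency.tocoo()
        return zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist())

    def is_symmetric(self) -> bool:
        diff = self.adjacency - self.adjacency.T
        return diff.nnz == 0 or np.abs(diff.data).max() == 0.0


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix of a weighted network.

    ``M[i, j] = A[i, j] / sum_i' A[i', j]`` for columns with positive weight;
    columns of zero-degree (dangling) nodes are all-zero and their indices
    recorded in :attr:`dangling` so the diffusion can redirect their mass to
    the restart distribution.
    """

    M: sp.csr_matrix
    dangling: frozenset[int]

    @property
    def n(self) -> int:
        return self.M.shape[0]


@dataclass
class LabelMatrix:
    """Binary multi-label annotation matrix (genes x labels).

    Labels are not mutually exclusive; a gene may carry any number of labels
    including zero (such genes are excluded from training folds but still
    receive predictions).
    """

    Y: np.ndarray
    label_names: list[str]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_labels(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# loading


def load_gene_index(path: str | Path) -> dict[str, int]:
    """Read a gene-index file (one id per line; line number = index)."""
    id_map: dict[str, int] = {}
    for line in Path(path).read_text().splitlines():
        gid = line.strip()
        if not gid or gid.startswith("#"):
            continue
        if gid in id_map:
            raise NetworkFormatError(f"duplicate gene id {gid!r} in index")
        id_map[gid] = len(id_map)
    return id_map


def gene_index_checksum(id_map: Mapping[str, int]) -> str:
    """Stable sha256 of the index ordering, used to detect stale artifacts."""
    ordered = sorted(id_map, key=id_map.__getitem__)
    return hashlib.sha256("\n".join(ordered).encode()).hexdigest()


def load_network(
    path: str | Path,
    id_map: Mapping[str, int],
    *,
    strict: bool = True,
    name: str | None = None,
) -> WeightedGraph:
    """Parse a whitespace-delimited adjacency list into a :class:`WeightedGraph`.

    Duplicate (i, j) entries are merged by maximum weight (a conservative
    confidence merge) and counted in ``n_duplicates``. In strict mode (the
    default) an unknown gene id aborts with its line number; in lenient mode
    such lines are skipped and counted, which risks silently mis-aligning
    networks and is therefore opt-in.
    """
    n = len(id_map)
    weights: dict[tuple[int, int], float] = {}
    n_dup = 0
    n_skip = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 'gene_a gene_b weight', got {line!r}"
            )
        ga, gb, ws = parts
        try:
            w = float(ws)
        except ValueError as exc:
            raise NetworkFormatError(f"{path}:{lineno}: bad weight {ws!r}") from exc
        if not 0.0 <= w <= 1.0:
            raise NetworkFormatError(
                f"{path}:{lineno}: weight {w} outside [0, 1]"
            )
        if ga not in id_map or gb not in id_map:
            missing = ga if ga not in id_map else gb
            if strict:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown gene id {missing!r}"
                )
            n_skip += 1
            continue
        key = (id_map[ga], id_map[gb])
        if key in weights:
            n_dup += 1
            weights[key] = max(weights[key], w)
        else:
            weights[key] = w
    if weights:
        rows, cols = zip(*weights)
        data = [weights[k] for k in weights]
        adj = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    else:
        adj = sp.csr_matrix((n, n))
    return WeightedGraph(
        adjacency=adj,
        id_map=dict(id_map),
        name=name or Path(path).stem,
        n_duplicates=n_dup,
        n_skipped=n_skip,
    )


def from_adjacency(
    adj: sp.spmatrix | np.ndarray,
    id_map: Mapping[str, int] | None = None,
    name: str = "",
) -> WeightedGraph:
    """Wrap an adjacency matrix (dense or sparse) as a :class:`WeightedGraph`."""
    adj = sp.csr_matrix(adj)
    if id_map is None:
        id_map = {f"g{i}": i for i in range(adj.shape[0])}
    return WeightedGraph(adjacency=adj, id_map=dict(id_map), name=name)


# ---------------------------------------------------------------------------
# normalisation


def symmetrize(g: WeightedGraph) -> WeightedGraph:
    """Make the network undirected, resolving (i,j)/(j,i) conflicts by max.

    Idempotent: applying it to an already-symmetric graph is a no-op.
    """
    sym = g.adjacency.maximum(g.adjacency.T).tocsr()
    return WeightedGraph(
        adjacency=sym,
        id_map=g.id_map,
        name=g.name,
        n_duplicates=g.n_duplicates,
        n_skipped=g.n_skipped,
    )


def to_transition(g: WeightedGraph) -> TransitionMatrix:
    """Column-normalise the adjacency into a transition matrix.

    Requires a symmetric graph (apply :func:`symmetrize` first). Zero-degree
    columns are left all-zero and their node indices reported as dangling;
    downstream diffusion treats mass landing there as restart mass rather
    than inventing a teleportation prior.
    """
    if not g.is_symmetric():
        raise ValueError("to_transition requires a symmetrized graph")
    a = g.adjacency.tocsc(copy=True).astype(float)
    col_sums = np.asarray(a.sum(axis=0)).ravel()
    dangling = frozenset(np.flatnonzero(col_sums == 0).tolist())
    inv = np.zeros_like(col_sums)
    nz = col_sums > 0
    inv[nz] = 1.0 / col_sums[nz]
    m = (a @ sp.diags(inv)).tocsr()
    return TransitionMatrix(M=m, dangling=dangling)


# ---------------------------------------------------------------------------
# annotations


def load_annotations(
    path: str | Path,
    id_map: Mapping[str, int],
    label_set: Sequence[str],
    *,
    strict: bool = True,
) -> LabelMatrix:
    """Read (gene, label) pairs into a binary gene x label matrix.

    Pairs whose label is outside ``label_set`` are dropped (counted); unknown
    gene ids follow the same strict/lenient contract as :func:`load_network`.
    """
    labels = list(label_set)
    label_idx = {name: c for c, name in enumerate(labels)}
    Y = np.zeros((len(id_map), len(labels)), dtype=np.int8)
    n_dropped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 'gene label', got {line!r}"
            )
        gid, lab = parts
        if gid not in id_map:
            if strict:
                raise NetworkFormatError(f"{path}:{lineno}: unknown gene id {gid!r}")
            continue
        if lab not in label_idx:
            n_dropped += 1
            continue
        Y[id_map[gid], label_idx[lab]] = 1
    lm = LabelMatrix(Y=Y, label_names=labels)
    lm.n_dropped = n_dropped  # type: ignore[attr-defined]
    return lm


def load_dag(path: str | Path) -> list[tuple[str, str]]:
    """Read (child, parent) label-hierarchy edges."""
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        child, parent = line.split()
        edges.append((child, parent))
    return edges


def propagate_labels(
    lm: LabelMatrix, dag: Iterable[tuple[str, str]]
) -> LabelMatrix:
    """Close annotations upward over a label hierarchy.

    Edges mean "child is_a/part_of parent": a gene annotated with a label is
    annotated with every ancestor of that label. Monotone (never removes a 1)
    and idempotent. Rejects cyclic hierarchies.
    """
    g = nx.DiGraph()
    g.add_nodes_from(lm.label_names)
    for child, parent in dag:
        if child not in g or parent not in g:
            raise NetworkFormatError(
                f"hierarchy edge ({child}, {parent}) uses an unknown label"
            )
        g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        raise NetworkFormatError("label hierarchy contains a cycle")
    C = lm.n_labels
    idx = {name: c for c, name in enumerate(lm.label_names)}
    # closure[c, a] = 1 iff a is c itself or an ancestor of c
    closure = np.eye(C, dtype=bool)
    for name in lm.label_names:
        for anc in nx.descendants(g, name):  # edges point child -> parent
            closure[idx[name], idx[anc]] = True
    Y = (lm.Y.astype(bool) @ closure).astype(np.int8)
    return LabelMatrix(Y=Y, label_names=list(lm.label_names))


# ---------------------------------------------------------------------------
# writers (used by the synthetic generator and the pipeline)


def write_gene_index(path: str | Path, id_map: Mapping[str, int]) -> None:
    ordered = sorted(id_map, key=id_map.__getitem__)
    Path(path).write_text("\n".join(ordered) + "\n")


def write_network(path: str | Path, g: WeightedGraph) -> None:
    """Write the upper triangle (one line per undirected edge)."""
    rev = {i: gid for gid, i in g.id_map.items()}
    coo = sp.triu(g.adjacency.maximum(g.adjacency.T), k=0).tocoo()
    lines = [
        f"{rev[i]}\t{rev[j]}\t{w:.6g}"
        for i, j, w in zip(coo.row.tolist(), coo.col.tolist(), coo.data.tolist())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_annotations(
    path: str | Path, lm: LabelMatrix, id_map: Mapping[str, int]
) -> None:
    rev = {i: gid for gid, i in id_map.items()}
    rows, cols = np.nonzero(lm.Y)
    lines = [
        f"{rev[int(i)]}\t{lm.label_names[int(c)]}" for i, c in zip(rows, cols)
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
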