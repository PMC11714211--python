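"""Interactome data model, I/O, shortest paths, degree-matched nulls, LCC localization.

The interactome is an undirected, unweighted protein-protein interaction
network over gene symbols.  Everything downstream -- proximity, diffusion,
module localization -- runs on this substrate, so this module also owns the
shared statistical machinery: multi-source hop distances, degree-binned
random gene-set sampling for permutation nulls, and the empirical-P counting
rules used by every screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

__all__ = [
    "GeneSet",
    "PermutationNull",
    "LccResult",
    "InteractomeGraph",
    "load_edge_list",
    "write_edge_list",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "all_pairs_min_distance",
    "sample_degree_matched",
    "lcc_significance",
    "empirical_p",
    "as_rng",
]

#: Sentinel for an undefined Z score (zero-variance permutation null).
UNDEFINED_Z = float("nan")


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Coerce an integer seed (or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols. Membership is exact string match."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def restrict(self, universe: Iterable[str]) -> "GeneSet":
        """Intersect with a universe (typically the graph's node set)."""
        return GeneSet(self.name, self.members & frozenset(universe))


@dataclass
class PermutationNull:
    """Summary of a statistic's permutation null distribution.

    ``samples`` holds the statistic recomputed under each of ``n_perm``
    randomizations; ``mean``/``sd`` are the moments that standardize the
    observed value into a Z score.
    """

    n_perm: int
    samples: np.ndarray
    seed: int | None = None
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (self.n_perm,):
            raise ValueError(
                f"expected {self.n_perm} null samples, got {self.samples.shape}"
            )
        self.mean = float(self.samples.mean())
        self.sd = float(self.samples.std(ddof=0))

    def z(self, observed: float) -> float:
        """Standardize ``observed``; NaN when the null is degenerate (sd=0)."""
        if self.sd == 0.0:
            return UNDEFINED_Z
        return (observed - self.mean) / self.sd


def empirical_p(samples: np.ndarray, observed: float, tail: str) -> float:
    """Permutation P as a plain counting fraction, no smoothing.

    tail:
      * ``"less"``          -- #{sample <  observed} / n
      * ``"less_equal"``    -- #{sample <= observed} / n
      * ``"greater"``       -- #{sample >  observed} / n
      * ``"greater_equal"`` -- #{sample >= observed} / n

    P = 0 is reportable: with n permutations the smallest attainable
    nonzero value is 1/n and no pseudocount is added.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empirical_p needs at least one null sample")
    if tail == "less":
        count = int(np.sum(samples < observed))
    elif tail == "less_equal":
        count = int(np.sum(samples <= observed))
    elif tail == "greater":
        count = int(np.sum(samples > observed))
    elif tail == "greater_equal":
        count = int(np.sum(samples >= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return count / samples.size


@dataclass
class LccResult:
    """Largest-connected-component localization test result."""

    observed_lcc: int
    null: PermutationNull
    z: float
    empirical_p: float


class InteractomeGraph:
    """Undirected labeled interaction graph with cached sparse machinery.

    Invariants: no self-loops, no duplicate edges, every edge endpoint is a
    registered node.  Nodes are gene symbols.  A sorted node order backs the
    CSR adjacency used by the distance and diffusion code, so all array-level
    results are deterministic regardless of insertion order.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        self._g = g
        self._node_list: list[str] = sorted(g.nodes)
        self._index: dict[str, int] = {v: i for i, v in enumerate(self._node_list)}
        self._csr: sp.csr_matrix | None = None
        self._degree_bins: dict[int, tuple[np.ndarray, list[np.ndarray]]] = {}

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "InteractomeGraph":
        return cls(g.edges, g.nodes)

    # -- basic accessors ---------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> list[str]:
        """Node labels in the canonical (sorted) order."""
        return self._node_list

    @property
    def node_set(self) -> set[str]:
        return set(self._node_list)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def number_of_nodes(self) -> int:
        return len(self._node_list)

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def degree(self, v: str) -> int:
        return self._g.degree[v]

    def neighbors(self, v: str) -> list[str]:
        return list(self._g.neighbors(v))

    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted pairs, in deterministic order."""
        return sorted(tuple(sorted(e)) for e in self._g.edges)

    def index_of(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._index[g] for g in genes], dtype=np.intp)

    @property
    def adjacency(self) -> sp.csr_matrix:
        """Symmetric 0/1 CSR adjacency in canonical node order (cached)."""
        if self._csr is None:
            self._csr = nx.to_scipy_sparse_array(
                self._g, nodelist=self._node_list, dtype=np.float64, format="csr"
            )
        return self._csr

    def degree_array(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    # -- degree binning ----------------------------------------------------

    def degree_bins(self, min_bin_size: int = 100):
        """Degree bins for degree-matched sampling.

        Distinct degrees are walked in ascending order, merging adjacent
        degrees until each bin holds at least ``min_bin_size`` nodes; a
        trailing undersized bin is absorbed into its predecessor.  Returns
        ``(bin_of_node, bin_members)`` where ``bin_of_node[i]`` is the bin id
        of node index ``i`` and ``bin_members[b]`` the node indices in bin
        ``b``.  Cached per ``min_bin_size``.
        """
        cached = self._degree_bins.get(min_bin_size)
        if cached is not None:
            return cached
        deg = self.degree_array()
        order = np.argsort(deg, kind="stable")
        n = len(order)
        bin_of_node = np.empty(n, dtype=np.intp)
        bin_members: list[np.ndarray] = []
        start = 0
        while start < n:
            end = max(start + min_bin_size, start + 1)
            # extend to include all nodes sharing the boundary degree
            while end < n and deg[order[end]] == deg[order[end - 1]]:
                end += 1
            end = min(end, n)
            members = order[start:end]
            bin_members.append(members)
            start = end
        if len(bin_members) > 1 and len(bin_members[-1]) < min_bin_size:
            bin_members[-2] = np.concatenate([bin_members[-2], bin_members[-1]])
            bin_members.pop()
        for b, members in enumerate(bin_members):
            bin_of_node[members] = b
        bin_members = [np.sort(m) for m in bin_members]
        self._degree_bins[min_bin_size] = (bin_of_node, bin_members)
        return bin_of_node, bin_members


# -- I/O -------------------------------------------------------------------


def _open_text(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "rt", encoding="utf-8")
    return source


def load_edge_list(
    source: str | Path | TextIO, header: bool = False
) -> InteractomeGraph:
    """Read a two-column gene-symbol edge list (TSV).

    Lines starting with ``#`` are comments.  Self-loops are dropped and
    duplicate edges collapsed; the counts are recorded on the returned
    graph as ``dropped_self_loops`` and ``dropped_duplicates`` attributes.

    Raises ``ValueError`` on an empty file or on a data row with fewer than
    two columns (naming the offending line).
    """
    stream = _open_text(source)
    close = isinstance(source, (str, Path))
    try:
        seen: set[tuple[str, str]] = set()
        edges: list[tuple[str, str]] = []
        n_self = 0
        n_dup = 0
        n_rows = 0
        for lineno, raw in enumerate(stream, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if header:
                header = False
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(
                    f"malformed edge-list row at line {lineno}: {line!r} "
                    "(need two tab-separated gene symbols)"
                )
            a, b = parts[0].strip(), parts[1].strip()
            n_rows += 1
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            edges.append(key)
        if n_rows == 0:
            raise ValueError("empty edge list: no data rows found")
        graph = InteractomeGraph(edges)
        graph.dropped_self_loops = n_self  # type: ignore[attr-defined]
        graph.dropped_duplicates = n_dup  # type: ignore[attr-defined]
        return graph
    finally:
        if close:
            stream.close()


def write_edge_list(graph: InteractomeGraph, dest: str | Path | TextIO) -> None:
    """Write the graph as a two-column TSV in deterministic edge order."""
    stream = _open_text(dest) if not isinstance(dest, (str, Path)) else open(dest, "w")
    close = isinstance(dest, (str, Path))
    try:
        for a, b in graph.edges():
            stream.write(f"{a}\t{b}\n")
    finally:
        if close:
            stream.close()


def read_gmt(source: str | Path | TextIO) -> dict[str, GeneSet]:
    """Read gene sets in GMT format (name, description, members...)."""
    stream = _open_text(source)
    close = isinstance(source, (str, Path))
    try:
        sets: dict[str, GeneSet] = {}
        for raw in stream:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            sets[name] = GeneSet(name, [g for g in parts[2:] if g])
        return sets
    finally:
        if close:
            stream.close()


def write_gmt(sets: Iterable[GeneSet], dest: str | Path) -> None:
    with open(dest, "w") as fh:
        for gs in sets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.name}\t-\t{members}\n")


def read_gene_list(source: str | Path | TextIO, name: str = "genes") -> GeneSet:
    """Read a one-symbol-per-line gene list."""
    stream = _open_text(source)
    close = isinstance(source, (str, Path))
    try:
        genes = [ln.strip() for ln in stream if ln.strip() and not ln.startswith("#")]
        return GeneSet(name, genes)
    finally:
        if close:
            stream.close()


# -- shortest paths --------------------------------------------------------


def min_distance_array(graph: InteractomeGraph, source_idx: np.ndarray) -> np.ndarray:
    """Hop distance from every node to its nearest source (array form).

    Unreachable nodes get ``inf``.  This is the array-level workhorse behind
    :func:`all_pairs_min_distance` and the proximity statistic.
    """
    if source_idx.size == 0:
        raise ValueError("no source nodes present in the graph")
    return dijkstra(
        graph.adjacency, unweighted=True, indices=source_idx, min_only=True
    )


def all_pairs_min_distance(
    graph: InteractomeGraph, sources: GeneSet
) -> dict[str, float]:
    """BFS hop distance from the nearest source, for every node.

    Unreachable nodes map to ``float('inf')``.  Raises if no source is in
    the graph.
    """
    present = [g for g in sources if g in graph]
    if not present:
        raise ValueError(f"none of the source genes {sorted(sources)[:5]}... in graph")
    dist = min_distance_array(graph, graph.index_of(present))
    return {v: float(dist[i]) for i, v in enumerate(graph.nodes)}


# -- degree-matched sampling ----------------------------------------------


def sample_degree_matched_idx(
    graph: InteractomeGraph,
    template_idx: np.ndarray,
    rng: np.random.Generator,
    min_bin_size: int = 100,
) -> np.ndarray:
    """Degree-matched random node indices, distinct, one per template slot."""
    bin_of_node, bin_members = graph.degree_bins(min_bin_size)
    out = np.empty(len(template_idx), dtype=np.intp)
    template_bins = bin_of_node[template_idx]
    for b in np.unique(template_bins):
        slots = np.nonzero(template_bins == b)[0]
        pool = bin_members[b]
        if len(slots) > len(pool):
            raise ValueError(
                f"degree bin {b} holds {len(pool)} nodes but the template "
                f"needs {len(slots)} distinct draws from it; rebuild the "
                f"bins with a larger min_bin_size (coarser binning)"
            )
        out[slots] = rng.choice(pool, size=len(slots), replace=False)
    return out


def sample_degree_matched(
    graph: InteractomeGraph,
    template: GeneSet,
    rng_seed: int | np.random.Generator,
    min_bin_size: int = 100,
) -> GeneSet:
    """Random gene set with a degree distribution matching ``template``.

    Each template gene contributes one draw from its degree bin; draws are
    without replacement within the sample, so the result has ``|template|``
    distinct genes.  Deterministic given the seed.  Template genes must all
    be graph nodes.
    """
    missing = [g for g in template if g not in graph]
    if missing:
        raise ValueError(f"template genes not in graph: {missing[:5]}")
    rng = as_rng(rng_seed)
    idx = sample_degree_matched_idx(
        graph, graph.index_of(sorted(template.members)), rng, min_bin_size
    )
    return GeneSet(f"{template.name}_rand", [graph.nodes[i] for i in idx])


# -- LCC localization ------------------------------------------------------


def _lcc_size(graph: InteractomeGraph, node_idx: np.ndarray) -> int:
    if node_idx.size == 0:
        return 0
    sub = graph.adjacency[node_idx][:, node_idx]
    n_comp, labels = connected_components(sub, directed=False)
    return int(np.bincount(labels).max())


def lcc_significance(
    graph: InteractomeGraph,
    genes: GeneSet,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    min_bin_size: int = 100,
    degree_matched: bool = True,
) -> LccResult:
    """Test whether a gene set is localized (forms a larger connected
    component than chance) in the interactome.

    The null resamples ``n_perm`` random sets of the same size -- degree
    matched by default, uniform when ``degree_matched=False`` -- and the
    empirical P is the fraction of null LCC sizes >= observed.  With a
    degenerate null (sd = 0) the Z is NaN but the empirical P stays valid.
    """
    present = sorted(genes.restrict(graph.nodes).members)
    if len(present) < 2:
        raise ValueError("need at least 2 genes present in the graph")
    idx = graph.index_of(present)
    observed = _lcc_size(graph, idx)
    rng = as_rng(rng_seed)
    samples = np.empty(n_perm, dtype=float)
    n = graph.number_of_nodes()
    for k in range(n_perm):
        if degree_matched:
            rand_idx = sample_degree_matched_idx(graph, idx, rng, min_bin_size)
        else:
            rand_idx = rng.choice(n, size=len(idx), replace=False)
        samples[k] = _lcc_size(graph, rand_idx)
    null = PermutationNull(n_perm=n_perm, samples=samples)
    return LccResult(
        observed_lcc=observed,
        null=null,
        z=null.z(observed),
        empirical_p=empirical_p(samples, observed, "greater_equal"),
    )
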