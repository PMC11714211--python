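"""GO functional similarity between drug targets and the gene module.

Term-level similarity is Wang's topology-based measure: each term's
ancestor DAG is scored with downward-propagated S-values, edge-weighted by
relation type (is_a 0.8, part_of 0.6), and two terms are compared by the
overlap of their weighted ancestor scores.  Gene pairs aggregate term
similarities by best-match averaging (BMA); gene sets aggregate gene-pair
BMAs by a second BMA.  The drug-level FS statistic is the mean of the
set-level similarities over the three namespaces,

    FS = (Sim_BP + Sim_MF + Sim_CC) / 3,

and significance comes from size-matched random gene sets drawn from the
annotated universe, P = #{FS_random > FS}/n_perm.  A drug passes at
FS > 0.6 and P < 0.05.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import obonet

from netscreen.interactome import (
    GeneSet,
    InteractomeGraph,
    PermutationNull,
    as_rng,
    empirical_p,
    sample_degree_matched,
)

__all__ = [
    "NAMESPACES",
    "GoDag",
    "AnnotationMap",
    "FsResult",
    "read_obo",
    "write_obo",
    "read_annotations",
    "wang_term_similarity",
    "bma_gene_similarity",
    "set_similarity",
    "fs_screen",
]

NAMESPACES = ("BP", "MF", "CC")

#: Wang's published edge-contribution constants.
DEFAULT_EDGE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

FS_THRESHOLD = 0.6
P_THRESHOLD = 0.05

_OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
}
_GAF_ASPECT = {"P": "BP", "F": "MF", "C": "CC"}


class GoDag:
    """Ontology DAG with typed child->parent edges and per-type weights.

    Namespaces (BP/MF/CC) are disjoint DAGs; edges never cross namespaces
    and cycles are rejected at construction.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str, str]],
        edge_weights: Mapping[str, float] | None = None,
        names: Mapping[str, str] | None = None,
    ):
        self.namespace: dict[str, str] = dict(terms)
        for t, ns in self.namespace.items():
            if ns not in NAMESPACES:
                raise ValueError(f"term {t}: unknown namespace {ns!r}")
        self.weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
        self.names = dict(names or {})
        self.parents: dict[str, list[tuple[str, str]]] = {t: [] for t in self.namespace}
        self.children: dict[str, list[tuple[str, str]]] = {t: [] for t in self.namespace}
        for child, parent, rel in edges:
            if child not in self.namespace or parent not in self.namespace:
                raise ValueError(f"edge ({child},{parent}) references unknown term")
            if self.namespace[child] != self.namespace[parent]:
                raise ValueError(
                    f"cross-namespace edge {child} ({self.namespace[child]}) -> "
                    f"{parent} ({self.namespace[parent]})"
                )
            if rel not in self.weights:
                raise ValueError(f"edge relation {rel!r} has no contribution weight")
            self.parents[child].append((parent, rel))
            self.children[parent].append((child, rel))
        self._check_acyclic()
        self._sv_cache: dict[str, dict[str, float]] = {}
        self._sim_cache: dict[tuple[str, str], float] = {}

    def _check_acyclic(self) -> None:
        indeg = {t: len(self.parents[t]) for t in self.namespace}
        queue = deque(t for t, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            t = queue.popleft()
            seen += 1
            for child, _ in self.children[t]:
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self.namespace):
            raise ValueError("ontology contains a cycle")

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def __len__(self) -> int:
        return len(self.namespace)

    def terms(self, ns: str | None = None) -> list[str]:
        if ns is None:
            return sorted(self.namespace)
        return sorted(t for t, n in self.namespace.items() if n == ns)

    def roots(self, ns: str | None = None) -> list[str]:
        return [t for t in self.terms(ns) if not self.parents[t]]

    def svalues(self, term: str) -> dict[str, float]:
        """Wang S-values over the term's ancestor DAG (term included).

        S(term) = 1; for an ancestor a, S(a) = max over in-DAG children c of
        w(c->a) * S(c).  Cached per term.
        """
        cached = self._sv_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.namespace:
            raise KeyError(f"unknown term {term!r}")
        # ancestor closure
        closure = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p, _ in self.parents[t]:
                if p not in closure:
                    closure.add(p)
                    stack.append(p)
        # topological order: process a node once all in-closure children done
        indeg = {
            t: sum(1 for c, _ in self.children[t] if c in closure) for t in closure
        }
        sv = {term: 1.0}
        queue = deque([term])
        while queue:
            t = queue.popleft()
            for p, rel in self.parents[t]:
                cand = self.weights[rel] * sv[t]
                if cand > sv.get(p, 0.0):
                    sv[p] = cand
                indeg[p] -= 1
                if indeg[p] == 0:
                    queue.append(p)
        self._sv_cache[term] = sv
        return sv


def wang_term_similarity(dag: GoDag, t1: str, t2: str) -> float:
    """Wang semantic similarity between two terms of one namespace.

    sim = sum over shared DAG terms of (S1 + S2) / (SV1 + SV2), a symmetric
    score in [0, 1]; sim(t, t) = 1.  Cross-namespace pairs are refused.
    """
    for t in (t1, t2):
        if t not in dag:
            raise KeyError(f"unknown term {t!r}")
    if dag.namespace[t1] != dag.namespace[t2]:
        raise ValueError(
            f"cross-namespace comparison: {t1} is {dag.namespace[t1]}, "
            f"{t2} is {dag.namespace[t2]}"
        )
    key = (t1, t2) if t1 <= t2 else (t2, t1)
    cached = dag._sim_cache.get(key)
    if cached is not None:
        return cached
    sv1 = dag.svalues(t1)
    sv2 = dag.svalues(t2)
    common = sv1.keys() & sv2.keys()
    num = sum(sv1[t] + sv2[t] for t in common)
    sim = num / (sum(sv1.values()) + sum(sv2.values()))
    dag._sim_cache[key] = sim
    return sim


class AnnotationMap:
    """Gene -> GO term sets, held per namespace.

    Ancestor propagation is implicit: Wang similarity scores ancestor
    overlap at comparison time, so only direct annotations are stored.
    """

    def __init__(self, dag: GoDag, pairs: Iterable[tuple[str, str]] = ()):
        self._dag = dag
        self._by_ns: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
        self._bma_cache: dict[tuple[str, str, str], float | None] = {}
        for gene, term in pairs:
            self.annotate(gene, term)

    def annotate(self, gene: str, term: str) -> None:
        if term not in self._dag:
            raise KeyError(f"annotation references unknown term {term!r}")
        ns = self._dag.namespace[term]
        self._by_ns[ns].setdefault(gene, set()).add(term)

    def terms(self, gene: str, ns: str) -> frozenset[str]:
        return frozenset(self._by_ns[ns].get(gene, ()))

    def annotated_genes(self, ns: str | None = None) -> set[str]:
        if ns is not None:
            return set(self._by_ns[ns])
        out: set[str] = set()
        for d in self._by_ns.values():
            out |= d.keys()
        return out

    def pairs(self) -> list[tuple[str, str]]:
        """(gene, term) pairs in deterministic order, for serialization."""
        out = []
        for ns in NAMESPACES:
            for gene, terms in self._by_ns[ns].items():
                out.extend((gene, t) for t in terms)
        return sorted(out)


def _bma(matrix: np.ndarray) -> float:
    """Best-match average of a pairwise similarity matrix."""
    return float((matrix.max(axis=1).mean() + matrix.max(axis=0).mean()) / 2.0)


def bma_gene_similarity(
    dag: GoDag, annot: AnnotationMap, g1: str, g2: str, ns: str
) -> float | None:
    """Best-match-average Wang similarity between two genes in a namespace.

    Returns ``None`` (not 0) when either gene lacks annotation in the
    namespace -- missing annotation is not evidence of dissimilarity.
    """
    key = (ns, g1, g2) if g1 <= g2 else (ns, g2, g1)
    if key in annot._bma_cache:
        return annot._bma_cache[key]
    t1 = sorted(annot.terms(g1, ns))
    t2 = sorted(annot.terms(g2, ns))
    if not t1 or not t2:
        annot._bma_cache[key] = None
        return None
    m = np.array([[wang_term_similarity(dag, a, b) for b in t2] for a in t1])
    val = _bma(m)
    annot._bma_cache[key] = val
    return val


def set_similarity(
    dag: GoDag,
    annot: AnnotationMap,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    ns: str,
) -> float | None:
    """Set-vs-set similarity in one namespace: BMA over the gene-pair BMA
    matrix, restricted to genes annotated in the namespace.  ``None`` when
    either side has no annotated gene."""
    a = sorted(g for g in genes_a if annot.terms(g, ns))
    b = sorted(g for g in genes_b if annot.terms(g, ns))
    if not a or not b:
        return None
    m = np.array([[bma_gene_similarity(dag, annot, ga, gb, ns) for gb in b] for ga in a])
    return _bma(m)


@dataclass
class FsResult:
    """Per-drug functional-similarity screen result.

    ``sim_bp``/``sim_mf``/``sim_cc`` are ``None`` when a namespace has no
    annotated gene on one side; ``fs`` is the mean of the available ones.
    """

    drug_id: str
    fs: float
    sim_bp: float | None
    sim_mf: float | None
    sim_cc: float | None
    null: PermutationNull
    p: float

    @property
    def passes(self) -> bool:
        """Candidate rule: FS > 0.6 and P < 0.05, both required."""
        return self.fs > FS_THRESHOLD and self.p < P_THRESHOLD


def _fs_value(
    dag: GoDag, annot: AnnotationMap, genes_a, genes_b
) -> tuple[float | None, dict[str, float | None]]:
    per_ns = {
        ns: set_similarity(dag, annot, genes_a, genes_b, ns) for ns in NAMESPACES
    }
    avail = [v for v in per_ns.values() if v is not None]
    fs = float(np.mean(avail)) if avail else None
    return fs, per_ns


def fs_screen(
    dag: GoDag,
    annot: AnnotationMap,
    targets: GeneSet,
    module: GeneSet,
    n_perm: int = 1000,
    rng_seed: int | np.random.Generator = 0,
    null: str = "annotated",
    graph: InteractomeGraph | None = None,
    drug_id: str = "",
) -> FsResult:
    """Functional-similarity screen of one drug's targets against the module.

    The null redraws ``n_perm`` random gene lists, size-matched to the
    drug's annotated target count, holding the module fixed.  By default
    (``null="annotated"``) the lists are drawn uniformly from the annotated
    gene universe -- annotation coverage, not degree, is the confounder for
    a semantic statistic; ``null="degree_matched"`` (requires ``graph``)
    instead degree-matches the lists on the interactome.
    """
    if null not in ("annotated", "degree_matched"):
        raise ValueError(f"unknown null mode {null!r}")
    universe = sorted(annot.annotated_genes())
    module_genes = sorted(module.members)
    target_genes = sorted(t for t in targets.members if t in set(universe))
    fs, per_ns = _fs_value(dag, annot, target_genes, module_genes)
    if fs is None:
        raise ValueError(
            "no namespace has annotated genes on both sides; FS undefined"
        )
    rng = as_rng(rng_seed)
    n_t = len(target_genes)
    samples = np.empty(n_perm)
    if null == "degree_matched":
        if graph is None:
            raise ValueError("degree_matched null requires the interactome graph")
        template = GeneSet("targets", [g for g in target_genes if g in graph])
        if not template.members:
            raise ValueError("no annotated target is a graph node")
    for k in range(n_perm):
        if null == "annotated":
            rand = [universe[i] for i in rng.choice(len(universe), n_t, replace=False)]
        else:
            rand = sorted(sample_degree_matched(graph, template, rng).members)
        fs_rand, _ = _fs_value(dag, annot, sorted(rand), module_genes)
        samples[k] = fs_rand if fs_rand is not None else 0.0
    null_summary = PermutationNull(n_perm=n_perm, samples=samples)
    return FsResult(
        drug_id=drug_id,
        fs=fs,
        sim_bp=per_ns["BP"],
        sim_mf=per_ns["MF"],
        sim_cc=per_ns["CC"],
        null=null_summary,
        p=empirical_p(samples, fs, "greater"),
    )


# -- I/O -------------------------------------------------------------------


def read_obo(
    path: str | Path, edge_weights: Mapping[str, float] | None = None
) -> GoDag:
    """Read an OBO 1.2 ontology into a :class:`GoDag`.

    Keeps ``is_a`` and ``relationship: part_of`` edges; obsolete terms are
    skipped; other relationship types are ignored with a warning count.
    """
    g = obonet.read_obo(path)
    weights = dict(edge_weights or DEFAULT_EDGE_WEIGHTS)
    terms: dict[str, str] = {}
    names: dict[str, str] = {}
    for t, data in g.nodes(data=True):
        ns_raw = data.get("namespace")
        if ns_raw is None or ns_raw not in _OBO_NAMESPACE:
            raise ValueError(f"term {t} has no recognized namespace: {ns_raw!r}")
        terms[t] = _OBO_NAMESPACE[ns_raw]
        if "name" in data:
            names[t] = data["name"]
    edges: list[tuple[str, str, str]] = []
    skipped = 0
    for child, parent, rel in g.edges(keys=True):
        if rel in weights:
            edges.append((child, parent, rel))
        else:
            skipped += 1
    if skipped:
        warnings.warn(
            f"ignored {skipped} ontology edges with unweighted relation types",
            RuntimeWarning,
        )
    return GoDag(terms, edges, edge_weights=weights, names=names)


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Write the DAG as a minimal OBO 1.2 document (round-trips via obonet)."""
    ns_long = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in dag.terms():
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.names.get(term, term)}\n")
            fh.write(f"namespace: {ns_long[dag.namespace[term]]}\n")
            for parent, rel in sorted(dag.parents[term]):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")


def read_annotations(
    source: str | Path,
    dag: GoDag,
    fmt: str = "auto",
    include_iea: bool = True,
) -> AnnotationMap:
    """Read gene -> GO annotations from GAF 2.x or a two-column TSV.

    GAF rows with a NOT qualifier are dropped; IEA evidence is kept by
    default (``include_iea=False`` excludes it).  Annotations to terms
    absent from the DAG are dropped with a warning count.
    """
    path = Path(source)
    if fmt == "auto":
        fmt = "gaf" if path.suffix in (".gaf",) else "tsv"
    pairs: list[tuple[str, str]] = []
    unknown = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            cols = line.split("\t")
            if fmt == "gaf":
                if len(cols) < 9:
                    raise ValueError(f"malformed GAF row: {line!r}")
                qualifier, gene, term, evidence = cols[3], cols[2], cols[4], cols[6]
                if "NOT" in qualifier.split("|"):
                    continue
                if not include_iea and evidence == "IEA":
                    continue
            else:
                if len(cols) < 2:
                    raise ValueError(f"malformed annotation row: {line!r}")
                gene, term = cols[0], cols[1]
            if term not in dag:
                unknown += 1
                continue
            pairs.append((gene, term))
    if unknown:
        warnings.warn(
            f"dropped {unknown} annotations to terms absent from the ontology",
            RuntimeWarning,
        )
    return AnnotationMap(dag, pairs)


def write_annotations(annot: AnnotationMap, path: str | Path) -> None:
    """Write annotations as a two-column gene<TAB>term TSV."""
    with open(path, "w") as fh:
        for gene, term in annot.pairs():
            fh.write(f"{gene}\t{term}\n")
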