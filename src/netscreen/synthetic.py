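"""Synthetic fixtures with known planted structure.

Real inputs to a network-medicine screen -- the compiled interactome, a
curated drug-target library, GO, a tissue expression atlas -- are large,
version-dependent downloads.  This module generates small stand-ins with
planted ground truth so every statistic in the package can be exercised
and validated end-to-end: a scale-free interactome with a dense module
around a seed gene, drugs with graded target overlap with that module, a
three-namespace ontology whose designated subtree co-annotates the module,
and an expression matrix with planted tissue-specific genes.  Identical
spec + seed always yields the identical fixture, and every fixture
serializes to the package's external text formats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from netscreen.funcsim import AnnotationMap, GoDag, NAMESPACES, write_annotations, write_obo
from netscreen.interactome import GeneSet, InteractomeGraph, write_edge_list
from netscreen.screening import DrugTargetLibrary, derive_seed, write_drug_library
from netscreen.tissue import ExpressionMatrix

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_interactome",
    "make_drug_library",
    "make_ontology_and_annotations",
    "make_expression",
    "make_all",
    "write_fixture",
]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study system.

    The interactome is a preferential-attachment (scale-free) graph; the
    planted module's induced edge density is raised to
    ``planted_density_boost`` times the background density -- the same order
    of enrichment real disease modules show over genome-scale interactomes
    (a ~200-gene module with a few thousand internal edges sits roughly
    50-60x above background).  Because a propagation-derived module is the
    seed's immediate network vicinity, the seed gene is additionally wired
    to a ``seed_attachment`` fraction of the planted members.  Drug target
    sets overlap the planted module
    by a configured fraction: fully for planted drugs, not at all for
    decoys, with the remainder degree-matched outside the module.
    """

    n_nodes: int = 1000
    attachment: int = 3
    background: str = "ba"              # "ba" scale-free | "er" Erdos-Renyi
    planted_module_size: int = 25
    planted_density_boost: float = 55.0
    seed_attachment: float = 0.9
    n_drugs: int = 50
    n_planted_drugs: int = 3
    targets_per_drug: int = 4
    overlap_planted: float = 1.0
    overlap_decoy: float = 0.0
    ontology_depth: int = 4
    ontology_branching: int = 3
    part_of_fraction: float = 0.2
    terms_per_gene: int = 3
    n_expr_genes: int = 300
    n_tissues: int = 30
    expression_fold: float = 8.0
    n_specific_genes: int = 20
    expression_sigma: float = 0.25
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_module_size >= self.n_nodes:
            raise ValueError("planted module must be smaller than the graph")
        for frac in (self.overlap_planted, self.overlap_decoy):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap fractions must be in [0,1]")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.ontology_depth < 2 or self.ontology_branching < 2:
            raise ValueError("ontology needs depth >= 2 and branching >= 2")


def _gene(i: int) -> str:
    return f"G{i:04d}"


def make_interactome(spec: FixtureSpec) -> tuple[InteractomeGraph, GeneSet, str]:
    """Background graph with a planted dense module around a seed gene.

    Returns ``(graph, planted_set, seed_gene)``.  Extra edges are added
    uniformly among planted non-edges until the induced density reaches
    ``planted_density_boost`` times the background density (capped at a
    clique).  The seed gene is a planted member.  An ``"er"`` background is
    reduced to its largest connected component so distances stay finite.
    """
    rng = np.random.default_rng(derive_seed(spec.master_seed, "interactome"))
    nx_seed = derive_seed(spec.master_seed, "background")
    if spec.background == "ba":
        g = nx.barabasi_albert_graph(spec.n_nodes, spec.attachment, seed=nx_seed)
    elif spec.background == "er":
        p = 2.0 * spec.attachment / (spec.n_nodes - 1)
        g = nx.gnp_random_graph(spec.n_nodes, p, seed=nx_seed)
        lcc = max(nx.connected_components(g), key=len)
        g = g.subgraph(lcc).copy()
    else:
        raise ValueError(f"unknown background {spec.background!r}")
    g = nx.relabel_nodes(g, {v: _gene(v) for v in g.nodes})
    node_list = sorted(g.nodes)
    planted = sorted(
        node_list[i]
        for i in rng.choice(len(node_list), spec.planted_module_size, replace=False)
    )
    background_density = 2.0 * g.number_of_edges() / (len(node_list) * (len(node_list) - 1))
    m = len(planted)
    max_edges = m * (m - 1) // 2
    target_density = min(1.0, spec.planted_density_boost * background_density)
    target_edges = min(max_edges, math.ceil(target_density * max_edges))
    have = g.subgraph(planted).number_of_edges()
    if target_edges > max_edges:
        raise ValueError("requested planted density is infeasible")
    non_edges = [
        (planted[i], planted[j])
        for i in range(m)
        for j in range(i + 1, m)
        if not g.has_edge(planted[i], planted[j])
    ]
    n_add = max(0, target_edges - have)
    if n_add > 0:
        chosen = rng.choice(len(non_edges), size=n_add, replace=False)
        g.add_edges_from(non_edges[i] for i in chosen)
    # the seed is the most module-internal member: a seed whose edges are
    # dominated by its own module, as for a propagation-derived module
    planted_set_now = set(planted)
    seed_gene = min(
        planted, key=lambda v: (sum(1 for u in g.neighbors(v) if u not in planted_set_now), v)
    )
    others = [v for v in planted if v != seed_gene and not g.has_edge(seed_gene, v)]
    n_attach = round(spec.seed_attachment * (m - 1)) - (m - 1 - len(others))
    if n_attach > 0:
        for i in rng.choice(len(others), min(n_attach, len(others)), replace=False):
            g.add_edge(seed_gene, others[i])
    return InteractomeGraph.from_networkx(g), GeneSet("planted_module", planted), seed_gene


def make_drug_library(
    graph: InteractomeGraph, planted: GeneSet, spec: FixtureSpec
) -> tuple[DrugTargetLibrary, dict[str, bool]]:
    """Drug library with graded module overlap plus ground-truth labels.

    Planted drugs take ``overlap_planted`` of their targets inside the
    planted module; decoys take ``overlap_decoy``.  Off-module targets are
    degree-matched to module members but drawn outside the module, so
    decoys are degree-fair negatives.  A drug's truth label is
    ``overlap >= 0.5``.
    """
    rng = np.random.default_rng(derive_seed(spec.master_seed, "drugs"))
    planted_nodes = sorted(planted.restrict(graph.nodes).members)
    if not planted_nodes:
        raise ValueError("planted module has no graph node")
    planted_set = set(planted_nodes)
    bin_of_node, bin_members = graph.degree_bins(min_bin_size=100)
    outside_bins = [
        np.array([i for i in members if graph.nodes[i] not in planted_set])
        for members in bin_members
    ]

    def sample_outside(n: int, exclude: set[str]) -> list[str]:
        # degree-match to random module members, drawing outside the module
        out: list[str] = []
        taken = set(exclude)
        for _ in range(n):
            template = planted_nodes[int(rng.integers(len(planted_nodes)))]
            b = bin_of_node[graph.index_of([template])[0]]
            pool = [graph.nodes[i] for i in outside_bins[b] if graph.nodes[i] not in taken]
            if not pool:
                raise ValueError(
                    f"degree bin {b} has no unused node outside the planted module"
                )
            pick = pool[int(rng.integers(len(pool)))]
            out.append(pick)
            taken.add(pick)
        return out

    targets: dict[str, GeneSet] = {}
    labels: dict[str, bool] = {}
    t = spec.targets_per_drug
    for d in range(spec.n_drugs):
        is_planted = d < spec.n_planted_drugs
        overlap = spec.overlap_planted if is_planted else spec.overlap_decoy
        n_in = round(overlap * t)
        drug = f"DRUG_{'P' if is_planted else 'D'}{d:03d}"
        inside = [
            planted_nodes[i] for i in rng.choice(len(planted_nodes), n_in, replace=False)
        ]
        outside = sample_outside(t - n_in, set(inside))
        targets[drug] = GeneSet(drug, inside + outside)
        labels[drug] = overlap >= 0.5
    return DrugTargetLibrary(targets=targets), labels


def _build_namespace_tree(
    ns: str, depth: int, branching: int, part_of_fraction: float, rng: np.random.Generator
) -> tuple[dict[str, str], list[tuple[str, str, str]], list[str]]:
    """One namespace tree of the given depth/branching.

    Returns (terms, edges, designated_subtree_terms); the designated
    subtree is the first depth-1 child and all its descendants.
    """
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"{ns}:{counter:07d}"

    root = new_term()
    terms = {root: ns}
    edges: list[tuple[str, str, str]] = []
    levels = [[root]]
    for _ in range(depth - 1):
        nxt = []
        for parent in levels[-1]:
            for _ in range(branching):
                child = new_term()
                terms[child] = ns
                rel = "part_of" if rng.random() < part_of_fraction else "is_a"
                edges.append((child, parent, rel))
                nxt.append(child)
        levels.append(nxt)
    designated_root = levels[1][0]
    designated = [designated_root]
    frontier = [designated_root]
    child_map: dict[str, list[str]] = {}
    for c, p, _ in edges:
        child_map.setdefault(p, []).append(c)
    while frontier:
        t = frontier.pop()
        for c in child_map.get(t, []):
            designated.append(c)
            frontier.append(c)
    return terms, edges, sorted(designated)


def make_ontology_and_annotations(
    spec: FixtureSpec, genes: list[str], planted: GeneSet
) -> tuple[GoDag, AnnotationMap]:
    """Three-namespace ontology with module genes co-annotated to one subtree.

    Each namespace is a rooted tree of the configured depth and branching
    with a ``part_of_fraction`` mixture of edge types.  Planted-module
    genes draw their terms from the namespace's designated subtree (so they
    are functionally coherent); all other genes draw uniformly from the
    namespace's non-root terms.
    """
    rng = np.random.default_rng(derive_seed(spec.master_seed, "ontology"))
    all_terms: dict[str, str] = {}
    all_edges: list[tuple[str, str, str]] = []
    designated: dict[str, list[str]] = {}
    non_root: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        terms, edges, desig = _build_namespace_tree(
            ns, spec.ontology_depth, spec.ontology_branching, spec.part_of_fraction, rng
        )
        all_terms.update(terms)
        all_edges.extend(edges)
        designated[ns] = desig
        children = {c for c, _, _ in edges}
        non_root[ns] = sorted(t for t in terms if t in children)
    dag = GoDag(all_terms, all_edges)
    annot = AnnotationMap(dag)
    planted_set = planted.members
    k = spec.terms_per_gene
    for gene in sorted(genes):
        for ns in NAMESPACES:
            pool = designated[ns] if gene in planted_set else non_root[ns]
            n_draw = min(k, len(pool))
            for i in rng.choice(len(pool), n_draw, replace=False):
                annot.annotate(gene, pool[i])
    return dag, annot


def make_expression(spec: FixtureSpec) -> tuple[ExpressionMatrix, GeneSet, str]:
    """Log-normal expression matrix with planted tissue-specific genes.

    Background values are log-normal with scale ``expression_sigma``; the
    first ``n_specific_genes`` genes are multiplied by ``expression_fold``
    in the designated (first) tissue.  Returns
    ``(matrix, truth_genes, designated_tissue)``.
    """
    rng = np.random.default_rng(derive_seed(spec.master_seed, "expression"))
    genes = [f"EG{i:04d}" for i in range(spec.n_expr_genes)]
    tissues = [f"tissue_{j:02d}" for j in range(spec.n_tissues)]
    values = np.exp(rng.normal(0.0, spec.expression_sigma, (len(genes), len(tissues))))
    planted = genes[: spec.n_specific_genes]
    values[: spec.n_specific_genes, 0] *= spec.expression_fold
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=tissues), scale="linear"
    )
    return matrix, GeneSet("tissue_specific_truth", planted), tissues[0]


@dataclass
class Fixture:
    """A complete synthetic study system."""

    spec: FixtureSpec
    graph: InteractomeGraph
    planted_module: GeneSet
    seed_gene: str
    library: DrugTargetLibrary
    drug_labels: dict[str, bool]
    dag: GoDag
    annotations: AnnotationMap
    expression: ExpressionMatrix
    specific_truth: GeneSet
    designated_tissue: str


def make_all(spec: FixtureSpec) -> Fixture:
    """Generate every fixture component from one spec + master seed."""
    graph, planted, seed_gene = make_interactome(spec)
    library, labels = make_drug_library(graph, planted, spec)
    dag, annot = make_ontology_and_annotations(spec, graph.nodes, planted)
    expr, truth, tissue = make_expression(spec)
    return Fixture(
        spec=spec,
        graph=graph,
        planted_module=planted,
        seed_gene=seed_gene,
        library=library,
        drug_labels=labels,
        dag=dag,
        annotations=annot,
        expression=expr,
        specific_truth=truth,
        designated_tissue=tissue,
    )


def write_fixture(fixture: Fixture, out_dir: str | Path) -> None:
    """Serialize the whole fixture to the package's external text formats,
    with truth labels in sidecar TSVs and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_edge_list(fixture.graph, out / "edges.tsv")
    write_drug_library(fixture.library, out / "drug_targets.tsv")
    write_obo(fixture.dag, out / "ontology.obo")
    write_annotations(fixture.annotations, out / "annotations.tsv")
    fixture.expression.write_tsv(out / "expression.tsv")
    with open(out / "planted_module.txt", "w") as fh:
        for gene in sorted(fixture.planted_module.members):
            fh.write(gene + "\n")
    with open(out / "drug_labels.tsv", "w") as fh:
        for drug in sorted(fixture.drug_labels):
            fh.write(f"{drug}\t{int(fixture.drug_labels[drug])}\n")
    with open(out / "tissue_specific_truth.txt", "w") as fh:
        for gene in sorted(fixture.specific_truth.members):
            fh.write(gene + "\n")
    manifest = {
        "spec": asdict(fixture.spec),
        "seed_gene": fixture.seed_gene,
        "designated_tissue": fixture.designated_tissue,
        "n_nodes": fixture.graph.number_of_nodes(),
        "n_edges": fixture.graph.number_of_edges(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
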