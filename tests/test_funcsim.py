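import numpy as np
import pytest

from netscreen.funcsim import (
    AnnotationMap,
    GoDag,
    bma_gene_similarity,
    fs_screen,
    read_annotations,
    read_obo,
    set_similarity,
    wang_term_similarity,
    write_annotations,
    write_obo,
)
from netscreen.interactome import GeneSet


# -- independent oracle: a from-scratch recursive Wang/BMA evaluation -------


def oracle_svalues(dag, term):
    """S-values by plain recursive relaxation (independent of the package's
    worklist implementation)."""
    sv = {term: 1.0}
    changed = True
    while changed:
        changed = False
        for t in list(sv):
            for parent, rel in dag.parents[t]:
                cand = dag.weights[rel] * sv[t]
                if cand > sv.get(parent, 0.0) + 1e-15:
                    sv[parent] = cand
                    changed = True
    return sv


def oracle_wang(dag, t1, t2):
    s1, s2 = oracle_svalues(dag, t1), oracle_svalues(dag, t2)
    common = set(s1) & set(s2)
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))


def oracle_bma(matrix):
    rows = [max(r) for r in matrix]
    cols = [max(c) for c in zip(*matrix)]
    return (sum(rows) / len(rows) + sum(cols) / len(cols)) / 2


def oracle_fs(dag, annot, genes_a, genes_b):
    per_ns = []
    for ns in ("BP", "MF", "CC"):
        a = [g for g in sorted(genes_a) if annot.terms(g, ns)]
        b = [g for g in sorted(genes_b) if annot.terms(g, ns)]
        if not a or not b:
            continue
        m = []
        for ga in a:
            row = []
            for gb in b:
                pair = [
                    [oracle_wang(dag, t1, t2) for t2 in sorted(annot.terms(gb, ns))]
                    for t1 in sorted(annot.terms(ga, ns))
                ]
                row.append(oracle_bma(pair))
            m.append(row)
        per_ns.append(oracle_bma(m))
    return sum(per_ns) / len(per_ns)


class TestWangTermSimilarity:
    def test_self_similarity_is_one(self, tiny_dag):
        for t in ["r", "a", "b"]:
            assert wang_term_similarity(tiny_dag, t, t) == 1.0

    def test_hand_evaluated_siblings(self, tiny_dag):
        # S_a = {a:1, r:0.8}, SV = 1.8 each; sim = (0.8+0.8)/3.6 = 4/9
        assert wang_term_similarity(tiny_dag, "a", "b") == pytest.approx(4.0 / 9.0)

    def test_symmetry(self, tiny_dag):
        assert wang_term_similarity(tiny_dag, "a", "b") == wang_term_similarity(
            tiny_dag, "b", "a"
        )

    def test_cross_namespace_refused(self):
        dag = GoDag({"b1": "BP", "m1": "MF"}, [])
        with pytest.raises(ValueError, match="cross-namespace"):
            wang_term_similarity(dag, "b1", "m1")

    def test_unknown_term_refused(self, tiny_dag):
        with pytest.raises(KeyError):
            wang_term_similarity(tiny_dag, "a", "zzz")

    def test_within_namespace_always_positive(self, tiny_dag):
        assert wang_term_similarity(tiny_dag, "a", "b") > 0.0

    def test_monotone_on_linear_ontology(self):
        chain = ["t0", "t1", "t2", "t3", "t4"]
        dag = GoDag(
            {t: "BP" for t in chain},
            [(chain[i + 1], chain[i], "is_a") for i in range(4)],
        )
        sims = [wang_term_similarity(dag, "t0", t) for t in chain[1:]]
        assert all(a > b for a, b in zip(sims, sims[1:]))

    def test_part_of_weight_lowers_similarity(self):
        base = {"r": "BP", "a": "BP", "b": "BP"}
        isa = GoDag(base, [("a", "r", "is_a"), ("b", "r", "is_a")])
        part = GoDag(base, [("a", "r", "part_of"), ("b", "r", "part_of")])
        assert wang_term_similarity(part, "a", "b") < wang_term_similarity(
            isa, "a", "b"
        )

    def test_matches_recursive_oracle_on_random_dag(self):
        rng = np.random.default_rng(12)
        terms = {f"T{i:02d}": "BP" for i in range(30)}
        ids = sorted(terms)
        edges = []
        for i in range(1, 30):
            n_par = 1 + (rng.random() < 0.3)
            for p in rng.choice(i, min(n_par, i), replace=False):
                rel = "part_of" if rng.random() < 0.25 else "is_a"
                edges.append((ids[i], ids[p], rel))
        dag = GoDag(terms, edges)
        for _ in range(40):
            t1, t2 = (ids[i] for i in rng.choice(30, 2, replace=False))
            assert wang_term_similarity(dag, t1, t2) == pytest.approx(
                oracle_wang(dag, t1, t2), abs=1e-12
            )


class TestBmaGeneSimilarity:
    def test_identical_term_sets_give_one(self, tiny_dag):
        annot = AnnotationMap(tiny_dag, [("g1", "a"), ("g1", "b"), ("g2", "a"), ("g2", "b")])
        assert bma_gene_similarity(tiny_dag, annot, "g1", "g2", "BP") == 1.0

    def test_hand_evaluated_bma(self, tiny_dag):
        # T1={a,b}, T2={a}: (avg(1, 4/9) + 1)/2 = 31/36
        annot = AnnotationMap(tiny_dag, [("g1", "a"), ("g1", "b"), ("g2", "a")])
        assert bma_gene_similarity(tiny_dag, annot, "g1", "g2", "BP") == pytest.approx(
            31.0 / 36.0
        )

    def test_unannotated_gene_is_missing_not_zero(self, tiny_dag):
        annot = AnnotationMap(tiny_dag, [("g1", "a")])
        assert bma_gene_similarity(tiny_dag, annot, "g1", "g2", "BP") is None

    def test_bounded_by_pairwise_extremes(self, small_fixture):
        dag, annot = small_fixture.dag, small_fixture.annotations
        genes = sorted(small_fixture.graph.nodes)[:10]
        for g1, g2 in zip(genes, genes[1:]):
            t1 = sorted(annot.terms(g1, "BP"))
            t2 = sorted(annot.terms(g2, "BP"))
            pairwise = [wang_term_similarity(dag, a, b) for a in t1 for b in t2]
            val = bma_gene_similarity(dag, annot, g1, g2, "BP")
            assert min(pairwise) - 1e-12 <= val <= max(pairwise) + 1e-12


class TestFsScreen:
    def test_targets_equal_module_gives_fs_one_p_zero(self, tiny_dag):
        annot = AnnotationMap(tiny_dag, [(f"g{i}", "a") for i in range(6)])
        genes = GeneSet("s", [f"g{i}" for i in range(3)])
        res = fs_screen(tiny_dag, annot, genes, genes, n_perm=50, rng_seed=0)
        assert res.fs == 1.0
        assert res.p == 0.0  # no null sample can exceed 1.0 strictly

    def test_p_arithmetic_against_injected_null(self):
        from netscreen.interactome import empirical_p

        samples = np.concatenate([np.full(812, 0.9), np.full(188, 0.1)])
        assert empirical_p(samples, 0.5, "greater") == 0.812

    def test_missing_namespace_uses_mean_of_available(self, tiny_dag):
        # tiny_dag has only BP terms: fs must equal sim_bp, not a 3-way mean
        annot = AnnotationMap(tiny_dag, [("g1", "a"), ("g2", "a"), ("g3", "b")])
        res = fs_screen(
            tiny_dag, annot, GeneSet("t", ["g1"]), GeneSet("m", ["g2", "g3"]),
            n_perm=20, rng_seed=1,
        )
        assert res.sim_mf is None and res.sim_cc is None
        assert res.fs == res.sim_bp

    def test_matches_independent_oracle(self, small_fixture):
        fx = small_fixture
        rng = np.random.default_rng(3)
        genes = sorted(fx.graph.nodes)
        a = [genes[i] for i in rng.choice(len(genes), 6, replace=False)]
        b = [genes[i] for i in rng.choice(len(genes), 9, replace=False)]
        per_ns = [
            set_similarity(fx.dag, fx.annotations, a, b, ns)
            for ns in ("BP", "MF", "CC")
        ]
        fs = np.mean([v for v in per_ns if v is not None])
        assert fs == pytest.approx(oracle_fs(fx.dag, fx.annotations, a, b), abs=1e-12)

    def test_gene_order_invariance(self, small_fixture):
        fx = small_fixture
        module = sorted(fx.planted_module.members)[:8]
        t = sorted(fx.graph.nodes)[:5]
        v1 = set_similarity(fx.dag, fx.annotations, t, module, "BP")
        v2 = set_similarity(fx.dag, fx.annotations, reversed(t), reversed(module), "BP")
        assert v1 == v2

    def test_planted_annotations_recovered(self, small_fixture):
        """A drug sharing the module's planted annotations beats its null."""
        fx = small_fixture
        module = fx.planted_module
        res = fs_screen(
            fx.dag, fx.annotations, fx.library["DRUG_P000"], module,
            n_perm=200, rng_seed=5,
        )
        assert res.fs > np.quantile(res.null.samples, 0.95)

    def test_no_annotated_overlap_errors(self, tiny_dag):
        annot = AnnotationMap(tiny_dag, [("g1", "a")])
        with pytest.raises(ValueError, match="no namespace"):
            fs_screen(tiny_dag, annot, GeneSet("t", ["u1"]), GeneSet("m", ["u2"]),
                      n_perm=10, rng_seed=0)


class TestOntologyIO:
    def test_obo_round_trip(self, small_fixture, tmp_path):
        dag = small_fixture.dag
        path = tmp_path / "onto.obo"
        write_obo(dag, path)
        dag2 = read_obo(path)
        assert dag2.namespace == dag.namespace
        for t in dag.terms():
            assert sorted(dag2.parents[t]) == sorted(dag.parents[t])

    def test_gaf_reader_drops_not_and_optionally_iea(self, tiny_dag, tmp_path):
        gaf = tmp_path / "annotations.gaf"
        rows = [
            ["DB", "X1", "geneA", "", "a", "ref", "EXP", "", "P"],
            ["DB", "X2", "geneB", "NOT", "a", "ref", "EXP", "", "P"],
            ["DB", "X3", "geneC", "", "b", "ref", "IEA", "", "P"],
        ]
        gaf.write_text("!gaf-version: 2.2\n" + "\n".join("\t".join(r) for r in rows) + "\n")
        annot = read_annotations(gaf, tiny_dag, fmt="gaf")
        assert annot.terms("geneA", "BP") == {"a"}
        assert not annot.terms("geneB", "BP")  # NOT-qualified dropped
        assert annot.terms("geneC", "BP") == {"b"}  # IEA kept by default
        strict = read_annotations(gaf, tiny_dag, fmt="gaf", include_iea=False)
        assert not strict.terms("geneC", "BP")

    def test_tsv_annotations_round_trip(self, small_fixture, tmp_path):
        annot = small_fixture.annotations
        path = tmp_path / "annot.tsv"
        write_annotations(annot, path)
        again = read_annotations(path, small_fixture.dag, fmt="tsv")
        assert again.pairs() == annot.pairs()
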