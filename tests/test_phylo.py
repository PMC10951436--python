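"""Phylogenetics: progressive MSA, distances, BioNJ, bootstrap, GTR+Gamma
likelihood (with brute-force oracles) and flank extraction."""

import itertools

import numpy as np
import pytest

from tylocus import phylo, sim, util
from tylocus.trees import Node, bipartitions, parse_newick


def random_tree(rng, n):
    nodes = [Node(f"t{i}", float(rng.uniform(0.5, 3))) for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(None, float(rng.uniform(0.5, 3)), children=[a, b]))
    return Node(children=nodes)


def path_distance_matrix(root):
    leaves = root.leaves()
    parent = {}
    for n in root.preorder():
        for c in n.children:
            parent[id(c)] = n
    def up(n):
        out = []
        while id(n) in parent:
            out.append(n)
            n = parent[id(n)]
        return out
    labels = [l.label for l in leaves]
    D = np.zeros((len(leaves),) * 2)
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            if i >= j:
                continue
            pa, pb = up(a), up(b)
            ids_a = {id(x): k for k, x in enumerate(pa)}
            d = 0.0
            for x in pb:
                if id(x) in ids_a:
                    d += sum(y.length for y in pa[: ids_a[id(x)]])
                    break
                d += x.length
            else:  # common ancestor is the root
                d += sum(y.length for y in pa)
            D[i, j] = D[j, i] = d
    return labels, D


class TestMsa:
    def test_identical_pair_gapless(self):
        msa = phylo.progressive_msa([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        assert [s for _, s in msa] == ["ACGTACGT", "ACGTACGT"]

    def test_single_deletion_one_gap_column(self):
        msa = dict(phylo.progressive_msa([("a", "ACGTACGT"), ("b", "ACGACGT")]))
        assert len(msa["a"]) == 8
        assert msa["a"].count("-") == 0 and msa["b"].count("-") == 1

    def test_residue_conservation(self):
        seqs = [("a", "ACGTTGCA"), ("b", "AGGTTGA"), ("c", "ACGTTGCATT")]
        msa = phylo.progressive_msa(seqs)
        orig = dict(seqs)
        for name, row in msa:
            assert row.replace("-", "") == orig[name]
            assert len(row) >= max(len(s) for _, s in seqs)

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError):
            phylo.progressive_msa([("a", "ACGT"), ("a", "ACGT")])


class TestDistances:
    def test_identical_zero(self):
        dm = phylo.distances([("a", "ACGT" * 10), ("b", "ACGT" * 10)])
        assert dm.matrix[0, 1] == 0

    def test_p_distance_definition(self):
        dm = phylo.distances([("a", "A" * 90 + "C" * 10), ("b", "A" * 100)],
                             model="p")
        assert dm.matrix[0, 1] == pytest.approx(0.10)

    def test_jc_closed_form(self):
        dm = phylo.distances([("a", "A" * 90 + "C" * 10), ("b", "A" * 100)],
                             model="JC")
        assert dm.matrix[0, 1] == pytest.approx(0.107326, abs=1e-6)

    def test_complete_deletion_removes_gap_columns(self):
        dm = phylo.distances([("a", "AC-T"), ("b", "ACGT")], model="p")
        assert dm.matrix[0, 1] == 0  # gapped column deleted before counting

    def test_saturation_errors(self):
        with pytest.raises(ValueError, match="saturated"):
            phylo.distances([("a", "AAAA"), ("b", "CCCC")], model="JC")


class TestBioNJ:
    def test_additive_recovery_random_trees(self):
        """On exactly additive matrices BioNJ recovers the generating
        topology and branch lengths (path-sum oracle)."""
        rng = np.random.default_rng(17)
        for _ in range(6):
            n = int(rng.integers(5, 9))
            truth = random_tree(rng, n)
            labels, D = path_distance_matrix(truth)
            rec = phylo.bionj(phylo.DistanceMatrix(labels, D))
            assert bipartitions(rec) == bipartitions(truth)
            labels2, D2 = path_distance_matrix(rec)
            idx = [labels2.index(l) for l in labels]
            assert np.allclose(D2[np.ix_(idx, idx)], D, atol=1e-8)

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = phylo.bionj(phylo.DistanceMatrix(["a", "b", "c"], D))
        lengths = {n.label: n.length for n in tree.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(23)
        truth = random_tree(rng, 6)
        labels, D = path_distance_matrix(truth)
        perm = list(rng.permutation(len(labels)))
        t1 = phylo.bionj(phylo.DistanceMatrix(labels, D))
        t2 = phylo.bionj(phylo.DistanceMatrix(
            [labels[i] for i in perm], D[np.ix_(perm, perm)]))
        assert bipartitions(t1) == bipartitions(t2)

    def test_dendropy_cross_check(self):
        """Independent NJ implementation recovers the same topology."""
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(29)
        truth = random_tree(rng, 7)
        labels, D = path_distance_matrix(truth)
        ours = phylo.bionj(phylo.DistanceMatrix(labels, D))
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(x) for x in D[i])
            for i in range(len(labels)))
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv))
        theirs = parse_newick(pdm.nj_tree().as_string(schema="newick")
                              .replace("[&U]", "").strip())
        assert bipartitions(ours) == bipartitions(theirs)


class TestBootstrap:
    def builder(self, a):
        return phylo.bionj(phylo.distances(a, model="p"))

    def test_deterministic_and_bounded(self):
        rng = np.random.default_rng(31)
        msa = [(f"t{i}", util.random_dna(rng, 200)) for i in range(5)]
        b1 = phylo.bootstrap_support(msa, self.builder, 50, seed=5)
        b2 = phylo.bootstrap_support(msa, self.builder, 50, seed=5)
        s1 = [n.support for n in b1.postorder() if n.support is not None]
        s2 = [n.support for n in b2.postorder() if n.support is not None]
        assert s1 == s2 and all(0 <= s <= 50 for s in s1)

    def test_strong_signal_high_support(self):
        """Two well-separated clades: the internal edge gets >= 95/100."""
        nwk = "((A:0.05,B:0.05):0.5,(C:0.05,D:0.05):0.5);"
        model = sim.StrainEvolutionModel(nwk, {}, seed=6)
        rng = np.random.default_rng(33)
        root = util.random_dna(rng, 2000)
        out = sim.evolve_strains(root, sim.LocusTruth([], None, [], 2000),
                                 model, sim.default_library())
        msa = [(k, v[0]) for k, v in sorted(out.items())]
        tree = phylo.bootstrap_support(msa, self.builder, 100, seed=7)
        supports = [n.support for n in tree.postorder()
                    if n.support is not None]
        assert supports and min(supports) >= 95


class TestLikelihood:
    def brute_force(self, tree, msa, model):
        code = {c: i for i, c in enumerate("ACGT")}
        cols = list(zip(*[s for _, s in msa]))
        names = [n for n, _ in msa]
        cats = model.category_rates()
        leaves = {n.label: n for n in tree.postorder() if n.is_leaf}
        internals = [n for n in tree.postorder()
                     if not n.is_leaf and n is not tree]
        P = {id(n): model.transition_matrices(n.length or 0.0)
             for n in tree.postorder() if n is not tree}
        total = 0.0
        for col in cols:
            obs = dict(zip(names, col))
            site = 0.0
            for c in range(len(cats)):
                for states in itertools.product(range(4),
                                                repeat=len(internals) + 1):
                    root_state = states[0]
                    assign = {id(tree): root_state}
                    for k, n in enumerate(internals):
                        assign[id(n)] = states[k + 1]
                    p = model.freqs[root_state]

                    def down(node, parent_state):
                        nonlocal p
                        for ch in node.children:
                            if ch.is_leaf:
                                p *= P[id(ch)][c][parent_state,
                                                  code[obs[ch.label]]]
                            else:
                                s = assign[id(ch)]
                                p *= P[id(ch)][c][parent_state, s]
                                down(ch, s)

                    down(tree, root_state)
                    site += p
            total += np.log(site / len(cats))
        return total

    def test_pruning_equals_enumeration(self):
        """Felsenstein pruning vs exhaustive internal-state summation on
        4 taxa, random GTR+Gamma parameters."""
        rng = np.random.default_rng(37)
        for _ in range(3):
            msa = [(t, util.random_dna(rng, 12)) for t in "ABCD"]
            model = phylo.GTRModel(rng.uniform(0.5, 2, 6),
                                   rng.dirichlet(np.ones(4) * 10),
                                   alpha=float(rng.uniform(0.3, 2)))
            tree = parse_newick(
                "((A:{:.3f},B:{:.3f}):{:.3f},C:{:.3f},D:{:.3f});".format(
                    *rng.uniform(0.05, 0.5, 5)))
            got = phylo.loglik(tree, msa, model)
            want = self.brute_force(tree, msa, model)
            assert got == pytest.approx(want, rel=1e-8)

    def test_transition_matrix_rows(self):
        model = phylo.GTRModel(np.ones(6), np.array([.1, .2, .3, .4]), 0.5)
        for P in model.transition_matrices(0.7):
            assert np.allclose(P.sum(axis=1), 1, atol=1e-10)
            assert np.all(P >= 0)

    def test_ml_recovers_strong_signal_topology(self):
        nwk = ("(((A:0.3,B:0.3):0.3,(C:0.3,D:0.3):0.3):0.3,"
               "(E:0.3,F:0.3):0.3);")
        truth = parse_newick(nwk)
        model = sim.StrainEvolutionModel(nwk, {}, seed=9)
        rng = np.random.default_rng(41)
        root = util.random_dna(rng, 2000)
        out = sim.evolve_strains(root, sim.LocusTruth([], None, [], 2000),
                                 model, sim.default_library())
        msa = [(k, v[0]) for k, v in sorted(out.items())]
        tree, logl = phylo.ml_tree(msa)
        assert bipartitions(tree) == bipartitions(truth)
        start = phylo.loglik(phylo.bionj(phylo.distances(msa, model="JC")),
                             msa, phylo.default_gtr(msa))
        assert logl >= start


class TestFlankAndRooting:
    def test_flank_concat_matches_truth(self, panel, trnas):
        from tylocus import annotation

        strains, _ = panel
        for name in ("s01", "s03"):
            seq, truth = panel[0][name]
            ann = annotation.annotate_trnas(seq, trnas)
            got = phylo.extract_flank_concat(ann.contig, ann.calls, 1000)
            ls, le = truth.locus_interval()
            want = seq[ls - 1000 : ls] + seq[le : le + 1000]
            assert got == want

    def test_flank_concat_presence_independent(self, panel, trnas):
        """Present vs absent strains on the same background yield highly
        similar concatenated flanks (they differ only by drift)."""
        import edlib

        from tylocus import annotation

        strains, _ = panel
        flanks = {}
        for name in ("s01", "s03"):
            ann = annotation.annotate_trnas(strains[name][0], trnas)
            flanks[name] = phylo.extract_flank_concat(ann.contig, ann.calls, 1000)
        d = edlib.align(flanks["s01"], flanks["s03"], mode="NW")["editDistance"]
        assert d < 0.05 * 2000

    def test_zero_flank_empty(self, root_locus, trnas):
        from tylocus import annotation

        ann = annotation.annotate_trnas(root_locus[0], trnas)
        assert phylo.extract_flank_concat(ann.contig, ann.calls, 0) == ""

    def test_insufficient_flank_names_side(self, root_locus, trnas):
        from tylocus import annotation

        ann = annotation.annotate_trnas(root_locus[0], trnas)
        with pytest.raises(ValueError, match="5' flank"):
            phylo.extract_flank_concat(ann.contig, ann.calls, 10**6)

    def test_root_by_clade_and_monophyly(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rooted = phylo.root_by_clade(t, {"A", "B"})
        assert phylo.is_monophyletic(rooted, {"A", "B"})
        assert phylo.is_monophyletic(rooted, set("ABCD"))
        assert not phylo.is_monophyletic(rooted, {"A", "C"})
        with pytest.raises(ValueError):
            phylo.root_by_clade(t, {"A", "C"})
        single = phylo.root_by_clade(t, {"A"})
        assert phylo.is_monophyletic(single, {"B", "C", "D"})
        with pytest.raises(ValueError):
            phylo.is_monophyletic(rooted, {"Z"})
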