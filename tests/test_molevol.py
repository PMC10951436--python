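"""Codon-model selection analysis: codon alignment, NG86 counting,
GY94/M0 likelihood (brute-force oracle) and fitting."""

import itertools

import numpy as np
import pytest

from tylocus import molevol as me
from tylocus import sim
from tylocus.trees import Node, parse_newick


class TestCodonAlign:
    def test_identical_gapless(self):
        cds = "ATGTTTGGACAATAA"
        aln = me.codon_align([("a", cds), ("b", cds)])
        assert aln.seqs[0] == aln.seqs[1]
        assert "-" not in aln.seqs[0]

    def test_single_codon_deletion_one_gap_run(self):
        a = "ATGTTTGGAGATCAA"
        b = "ATGTTTGATCAA"  # GGA codon removed
        aln = me.codon_align([("a", a), ("b", b)])
        rows = dict(zip(aln.taxa, aln.seqs))
        assert rows["a"].replace("-", "") == a
        gaps = [i for i, c in enumerate(rows["b"]) if c == "-"]
        assert len(gaps) == 3 and gaps == list(range(gaps[0], gaps[0] + 3))
        assert gaps[0] % 3 == 0

    def test_frame_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            me.codon_align([("a", "ATGT")])

    def test_internal_stop_named(self):
        with pytest.raises(ValueError, match="b.*stop"):
            me.codon_align([("a", "ATGTTTAAA"), ("b", "ATGTAAAAA")])


class TestTrim:
    def make(self):
        return me.CodonAlignment(["r", "s"], ["ATGTTTGGA", "ATGTTCGGA"])

    def test_trim_final_codon(self):
        out = me.trim_at_indel(self.make(), "r", 2)
        assert out.ncodons == 2 and not out.trim["noop"]

    def test_noop_past_end(self):
        out = me.trim_at_indel(self.make(), "r", 99)
        assert out.ncodons == 3 and out.trim["noop"]

    def test_reference_tail_gap_free(self):
        aln = me.CodonAlignment(["r", "s"], ["ATGTTT---", "ATGTTCGGA"])
        out = me.trim_at_indel(aln, "r", 2)
        assert "-" not in dict(zip(out.taxa, out.seqs))["r"]

    def test_unknown_taxon(self):
        with pytest.raises(ValueError):
            me.trim_at_indel(self.make(), "zzz", 1)


class TestNeiGojobori:
    def test_identical_undefined(self):
        r = me.nei_gojobori(me.CodonAlignment(["a", "b"], ["ATGTTT"] * 2))
        assert r.undefined and r.ratio is None and r.dn == r.ds == 0

    def test_synonymous_only_ratio_zero(self):
        r = me.nei_gojobori(me.CodonAlignment(["a", "b"], ["TTT", "TTC"]))
        assert r.ds > 0 and r.dn == 0 and r.ratio == 0

    def test_hand_computed_pathway_counts(self):
        """50-codon pair, 1 synonymous + 3 nonsynonymous single-position
        differences; site counts derived by hand from the genetic code:
        TTT/TTC s=1/3 each; GGG s=1; AGG s=2/3; CCC s=1; ACC s=1;
        GAT s=1/3; GTT s=1; filler GGG s=1."""
        a = ["GGG"] * 46 + ["TTT", "GGG", "CCC", "GAT"]
        b = ["GGG"] * 46 + ["TTC", "AGG", "ACC", "GTT"]
        r = me.nei_gojobori(me.CodonAlignment(["a", "b"],
                                              ["".join(a), "".join(b)]))
        S = 46 + 1 / 3 + (1 + 2 / 3) / 2 + 1 + (1 / 3 + 1) / 2
        N = 150 - S
        ps, pn = 1 / S, 3 / N
        ds = -0.75 * np.log(1 - 4 * ps / 3)
        dn = -0.75 * np.log(1 - 4 * pn / 3)
        assert r.ds == pytest.approx(ds, rel=1e-9)
        assert r.dn == pytest.approx(dn, rel=1e-9)
        assert r.ratio == pytest.approx(dn / ds, rel=1e-9)


class TestGY94Loglik:
    def test_zero_branch_single_codon_closed_form(self):
        pi = np.full(61, 1 / 61)
        aln = me.CodonAlignment(["a", "b"], ["ATG", "ATG"])
        tree = Node(children=[Node("a", 0.0), Node("b", 0.0)])
        assert me.gy94_loglik(aln, tree, 1.0, 1.0, pi) == \
            pytest.approx(np.log(1 / 61))

    def test_brute_force_three_taxa(self):
        """Pruning equals exhaustive 61-state summation over the internal
        node, random parameters."""
        rng = np.random.default_rng(51)
        for _ in range(3):
            aln = sim.simulate_codon_alignment(
                "(a:0.2,b:0.3,c:0.1);", float(rng.uniform(0.2, 2)),
                float(rng.uniform(1, 4)), 5, seed=int(rng.integers(100)))
            omega, kappa = float(rng.uniform(0.2, 2)), float(rng.uniform(1, 4))
            pi = rng.dirichlet(np.ones(61) * 50)
            tree = parse_newick("(a:0.2,b:0.3,c:0.1);")
            got = me.gy94_loglik(aln, tree, omega, kappa, pi)
            model = me.GY94(omega, kappa, pi)
            P = {n.label: model.transition_matrix(n.length)
                 for n in tree.children}
            idx = {c: i for i, c in enumerate(me.SENSE_CODONS)}
            rows = {t: r for t, r in zip(aln.taxa, aln.codon_rows())}
            want = 0.0
            for site in range(aln.ncodons):
                s = sum(
                    pi[x] * np.prod([P[t][x, idx[rows[t][site]]]
                                     for t in rows])
                    for x in range(61))
                want += np.log(s)
            assert got == pytest.approx(want, rel=1e-8)

    def test_transition_matrix_stochastic(self):
        model = me.GY94(0.7, 2.0, np.full(61, 1 / 61))
        P = model.transition_matrix(0.5)
        assert np.allclose(P.sum(axis=1), 1, atol=1e-10) and np.all(P >= 0)

    def test_reversibility_rerooting_invariance(self):
        """Under a reversible model the likelihood only depends on the sum
        of branch lengths along a path (pulley principle)."""
        aln = sim.simulate_codon_alignment("(a:0.2,b:0.3);", 0.5, 2.0, 50,
                                           seed=3)
        pi = np.full(61, 1 / 61)
        t1 = Node(children=[Node("a", 0.1), Node("b", 0.4)])
        t2 = Node(children=[Node("a", 0.5), Node("b", 0.0)])
        l1 = me.gy94_loglik(aln, t1, 0.5, 2.0, pi)
        l2 = me.gy94_loglik(aln, t2, 0.5, 2.0, pi)
        assert l1 == pytest.approx(l2, rel=1e-9)


class TestFitM0:
    def test_identical_alignment_unidentifiable(self):
        aln = me.CodonAlignment(["a", "b", "c"], ["ATGTTTGGA"] * 3)
        with pytest.raises(ValueError, match="unidentifiable"):
            me.fit_m0(aln)

    def test_recovery_single_seed(self):
        nwk = ("((t1:0.2,t2:0.2):0.1,(t3:0.2,t4:0.2):0.1,"
               "((t5:0.2,t6:0.2):0.1,(t7:0.2,t8:0.2):0.1):0.1);")
        aln = sim.simulate_codon_alignment(nwk, 0.5, 2.0, 500, seed=7)
        fit = me.fit_m0(aln, parse_newick(nwk))
        assert 0.4 <= fit.omega <= 0.6
        assert fit.converged and fit.ds > 0
        assert fit.dn / fit.ds == pytest.approx(fit.omega, rel=0.05)

    def test_local_optimality_spot_checks(self):
        nwk = "(a:0.3,b:0.2,c:0.4);"
        aln = sim.simulate_codon_alignment(nwk, 0.8, 2.0, 200, seed=11)
        fit = me.fit_m0(aln, parse_newick(nwk))
        for dw in (-0.1, 0.1):
            alt = me.gy94_loglik(aln, fit.tree, fit.omega + dw, fit.kappa,
                                 fit.pi)
            assert fit.logl >= alt

    def test_ng86_and_m0_agree_in_ordering(self):
        nwk = "((a:0.15,b:0.15):0.1,(c:0.15,d:0.15):0.1);"
        om_hat, ng_hat = [], []
        for omega in (0.2, 1.0, 2.0):
            aln = sim.simulate_codon_alignment(nwk, omega, 2.0, 300, seed=13)
            fit = me.fit_m0(aln, parse_newick(nwk))
            ng = me.nei_gojobori(aln)
            om_hat.append(fit.omega)
            ng_hat.append(ng.ratio)
        assert om_hat == sorted(om_hat)
        assert ng_hat == sorted(ng_hat)
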