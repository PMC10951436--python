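"""Synthetic-data generator: haplotype construction, strain evolution,
read and codon-alignment simulation, with independent oracles."""

import edlib
import numpy as np
import pytest

from tylocus import sim, util
from tylocus.molevol import GY94
from tylocus.trees import parse_newick


class TestBuildLocusHaplotype:
    def test_relic_blueprint_marks_deletion_and_downstream_orf(self, library):
        seq, truth = sim.build_locus_haplotype(sim.relic_blueprint(), library,
                                               flank_len=5000, seed=1)
        ty = truth.feature_of_kind("truncated_ty")
        assert ty is not None and ty.strand == "+"
        # the engineered 1 bp deletion is recorded in global coordinates
        assert truth.indels == [(ty.start + 300, -1)]
        # the intact downstream ORF starts with ATG, ends in a stop
        s, e = truth.orf
        assert ty.start < s < e <= ty.end
        orf = seq[s:e]
        assert orf[:3] == "ATG" and orf[-3:] in {"TAA", "TAG", "TGA"}
        assert (e - s) % 3 == 0 and (e - s) // 3 >= 50

    def test_empty_locus_blueprint(self, library, trnas):
        bp = sim.LocusBlueprint([
            sim.BlueprintFeature("flank"),
            sim.BlueprintFeature("trna", "tRNA-Gly", "+"),
            sim.BlueprintFeature("trna", "tRNA-Ser", "-"),
            sim.BlueprintFeature("flank"),
        ])
        seq, truth = sim.build_locus_haplotype(bp, library, flank_len=1000,
                                               seed=5)
        assert len(seq) == 2000 + len(trnas["tRNA-Gly"]) + len(trnas["tRNA-Ser"])
        assert all(f.kind in ("flank", "trna") for f in truth.features)

    def test_deterministic(self, library):
        a = sim.build_locus_haplotype(sim.relic_blueprint(), library, seed=7)
        b = sim.build_locus_haplotype(sim.relic_blueprint(), library, seed=7)
        assert a[0] == b[0]
        assert a[1].features == b[1].features

    def test_invalid_truncation_names_feature(self, library):
        bp = sim.relic_blueprint(truncation=(100, 99999))
        with pytest.raises(ValueError, match="feature 3"):
            sim.build_locus_haplotype(bp, library, seed=0)

    def test_coordinate_closure(self, root_locus):
        seq, truth = root_locus
        prev_end = 0
        for f in truth.features:
            assert 0 <= f.start < f.end <= len(seq)
            assert f.start >= prev_end  # non-overlapping, ordered
            prev_end = f.end


class TestEvolveStrains:
    def test_zero_branch_no_events_is_identity(self, root_locus, library):
        seq, truth = root_locus
        model = sim.StrainEvolutionModel("(a:0.0,b:0.0);", {}, seed=1)
        out = sim.evolve_strains(seq, truth, model, library)
        assert out["a"][0] == seq and out["b"][0] == seq

    def test_deletion_removes_insertion_keeps_trnas(self, root_locus, library):
        seq, truth = root_locus
        model = sim.StrainEvolutionModel(
            "(a:0.001,b:0.001);", {"a": [("delete_locus_insertion",)]}, seed=2)
        out = sim.evolve_strains(seq, truth, model, library)
        aseq, atruth = out["a"]
        assert atruth.feature_of_kind("truncated_ty") is None
        assert len([f for f in atruth.features if f.kind == "trna"]) == 2
        ty = truth.feature_of_kind("truncated_ty")
        assert len(aseq) == len(seq) - ty.length

    def test_gene_conversion_nearest_library_entry(self, root_locus, library):
        """Best-hit subfamily of the converted fragment, recomputed by
        exhaustive alignment against every Ty1 library entry."""
        seq, truth = root_locus
        model = sim.StrainEvolutionModel(
            "(a:0.001,b:0.001);", {"a": [("gene_convert", "Ty101")]}, seed=3)
        out = sim.evolve_strains(seq, truth, model, library)
        aseq, atruth = out["a"]
        frag_feat = atruth.feature_of_kind("truncated_ty")
        assert frag_feat.subfamily == "Ty101"
        frag = aseq[frag_feat.start : frag_feat.end]
        t = frag_feat.truncation
        dists = {
            e.name: edlib.align(frag, e.internal_seq[t[0] : t[1]],
                                mode="NW")["editDistance"]
            for e in library if e.family == "Ty1"
        }
        assert min(dists, key=dists.get) == "Ty101"

    def test_gene_convert_after_deletion_errors(self, root_locus, library):
        seq, truth = root_locus
        model = sim.StrainEvolutionModel(
            "(a:0.0,b:0.0);",
            {"a": [("delete_locus_insertion",), ("gene_convert", "Ty101")]},
            seed=4)
        with pytest.raises(ValueError, match="inapplicable|deleted"):
            sim.evolve_strains(seq, truth, model, library)

    def test_orf_stays_translatable(self, panel):
        from tylocus.molevol import translate

        strains, _ = panel
        for name, (seq, truth) in strains.items():
            if truth.orf is None:
                continue
            s, e = truth.orf
            prot = translate(seq[s:e])
            assert "*" not in prot[:-1] and prot.endswith("*")


class TestSimulateReads:
    def test_zero_coverage_empty(self, root_locus):
        reads, placements = sim.simulate_reads(root_locus[0],
                                               sim.perfect_profile(), 0)
        assert reads == [] and placements == []

    def test_negative_coverage_errors(self, root_locus):
        with pytest.raises(ValueError):
            sim.simulate_reads(root_locus[0], sim.perfect_profile(), -1)

    def test_perfect_reads_are_substrings(self, root_locus):
        genome = root_locus[0]
        reads, placements = sim.simulate_reads(genome, sim.perfect_profile(),
                                               5, seed=6)
        for (rid, seq), (rid2, s, e, strand) in zip(reads, placements):
            assert rid == rid2
            expected = genome[s:e]
            if strand == "-":
                expected = util.revcomp(expected)
            assert seq == expected

    def test_total_bases_near_target(self, root_locus):
        genome = root_locus[0]
        reads, _ = sim.simulate_reads(genome, sim.perfect_profile(), 30, seed=7)
        total = sum(len(s) for _, s in reads)
        target = 30 * len(genome)
        assert target <= total <= target + 2 * np.exp(9.0 + 0.35 ** 2)

    def test_error_rate_matches_profile(self, root_locus):
        """Mean per-base edit distance to the truth interval within +-20%
        of the summed profile rates, measured over >= 100 reads."""
        genome = root_locus[0]
        prof = sim.pacbio_clr_profile()
        reads, placements = sim.simulate_reads(genome, prof, 70, seed=8)
        assert len(reads) >= 100
        rates = []
        for (_, seq), (_, s, e, strand) in zip(reads, placements):
            truth = genome[s:e]
            if strand == "-":
                truth = util.revcomp(truth)
            d = edlib.align(seq, truth, mode="NW")["editDistance"]
            rates.append(d / (e - s))
        expected = prof.mismatch + prof.insertion + prof.deletion
        assert expected * 0.8 <= np.mean(rates) <= expected * 1.2


class TestSimulateCodonAlignment:
    def test_zero_branches_identical(self):
        aln = sim.simulate_codon_alignment("(a:0.0,b:0.0,c:0.0);", 1.0, 2.0,
                                           50, seed=1)
        assert len(set(aln.seqs)) == 1

    def test_seed_reproducible(self):
        a = sim.simulate_codon_alignment("(a:0.2,b:0.3);", 0.5, 2.0, 100, seed=9)
        b = sim.simulate_codon_alignment("(a:0.2,b:0.3);", 0.5, 2.0, 100, seed=9)
        assert a.seqs == b.seqs

    def test_missing_branch_lengths_error(self):
        with pytest.raises(ValueError, match="branch lengths"):
            sim.simulate_codon_alignment("(a,b);", 1.0, 1.0, 10)

    def test_no_stop_codons(self):
        aln = sim.simulate_codon_alignment("(a:0.5,b:0.5);", 2.0, 2.0, 200,
                                           seed=2)
        for row in aln.codon_rows():
            assert not set(row) & {"TAA", "TAG", "TGA"}

    def test_two_taxon_divergence_matches_matrix_exponential(self):
        """Fraction of differing codon sites vs the closed-form expectation
        sum_i pi_i P_ii(t), computed from an independent eigendecomposition."""
        t_total = 0.4
        pi = np.full(61, 1 / 61)
        model = GY94(1.0, 1.0, pi)
        import scipy.linalg

        P = scipy.linalg.expm(model.q * t_total)  # independent of sampler path
        p_same = float(np.sum(pi * np.diag(P)))
        diffs = []
        for rep in range(200):
            aln = sim.simulate_codon_alignment(
                f"(a:{t_total / 2},b:{t_total / 2});", 1.0, 1.0, 500, seed=rep)
            a, b = aln.codon_rows()
            diffs.append(np.mean([x != y for x, y in zip(a, b)]))
        observed = np.mean(diffs)
        se = np.std(diffs) / np.sqrt(len(diffs))
        assert abs(observed - (1 - p_same)) < 5 * se + 1e-3


class TestYamlConfigs:
    def test_blueprint_round_trip(self, library, tmp_path):
        text = """
- kind: flank
- {kind: trna, entry: tRNA-Gly, orient: "+"}
- {kind: truncated_ty, entry: Ty1prime, orient: "+",
   truncation: [1100, 3900], indels: [[300, -1]]}
- {kind: trna, entry: tRNA-Ser, orient: "-"}
- kind: flank
"""
        p = tmp_path / "bp.yaml"
        p.write_text(text)
        bp = sim.load_blueprint(p)
        seq, truth = sim.build_locus_haplotype(bp, library, flank_len=500,
                                               seed=3)
        assert truth.feature_of_kind("truncated_ty") is not None

    def test_profile_round_trip(self, tmp_path):
        p = tmp_path / "prof.yaml"
        p.write_text("platform: ont\nmismatch: 0.04\ninsertion: 0.03\n"
                     "deletion: 0.05\nmin_len: 2000\n")
        prof = sim.load_profile(p)
        assert prof.platform == "ont" and prof.min_len == 2000

    def test_run_config_yaml(self, tmp_path):
        from tylocus import pipeline

        p = tmp_path / "run.yaml"
        p.write_text("seed: 5\ncoverage: 12\nstrains: [s01, s02]\n")
        cfg = pipeline.RunConfig.from_yaml(p)
        assert cfg.seed == 5 and cfg.strains == ("s01", "s02")
        p.write_text("bogus_key: 1\n")
        with pytest.raises(ValueError, match="bogus_key"):
            pipeline.RunConfig.from_yaml(p)
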