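"""End-to-end orchestration: simulate/ingest -> map -> extract ->
assemble (x2) -> QC -> annotate -> classify -> phylogeny -> dN/dS.

Strains failing QC or tRNA annotation are excluded from downstream
cohort stages but kept in the report with their failure reason.  A fixed
seed makes the whole run reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation, assembly, classify, mapping, molevol, phylo, qc, sim, util
from .trees import Node, parse_newick

log = logging.getLogger("tylocus")


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | fastq
    seed: int = 0
    outdir: str | Path | None = None
    coverage: float = 30.0
    profile: str = "pacbio_clr"  # pacbio_clr | ont | perfect
    flank_len: int = 5000
    branch_length: float = 0.004
    tree_method: str = "bionj"  # bionj | ml
    bootstrap_replicates: int = 100
    min_mapq: int = 30
    flank_concat_len: int = 1000
    outgroup: tuple[str, ...] = ("s01", "s02")
    strains: tuple[str, ...] | None = None  # subset filter (simulate mode)
    # fastq-mode inputs
    reads_by_strain: dict[str, str] = field(default_factory=dict)
    reference_fasta: str | None = None
    locus: tuple[int, int] | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in
                               __import__("dataclasses").fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outgroup", "strains", "locus"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class StrainResult:
    strain: str
    status: str = ""
    n_reads: int = 0
    n_locus_reads: int = 0
    contig_olc: str = ""
    contig_sdbg: str = ""
    qc_report: qc.QCReport | None = None
    trna: annotation.TrnaAnnotation | None = None
    fragments: list = field(default_factory=list)
    orf: annotation.OrfCall | None = None
    excluded_flags: list[str] = field(default_factory=list)


@dataclass
class RunReport:
    statuses: dict[str, str]
    strains: dict[str, StrainResult]
    truth_status: dict[str, str] = field(default_factory=dict)
    fragment_tree: Node | None = None
    flank_tree: Node | None = None
    m0: molevol.M0Fit | None = None
    loss_events: int | None = None
    elapsed: dict[str, float] = field(default_factory=dict)


def _profile(name: str) -> sim.ReadProfile:
    return {"pacbio_clr": sim.pacbio_clr_profile,
            "ont": sim.ont_profile,
            "perfect": sim.perfect_profile}[name]()


def process_strain(strain: str, reads: list[tuple[str, str]],
                   ref_index: mapping.MinimizerIndex, reference: str,
                   locus: tuple[int, int], trnas: dict[str, str],
                   library, min_mapq: int = 30) -> StrainResult:
    """Map, extract, dual-assemble, QC and annotate one strain."""
    res = StrainResult(strain, n_reads=len(reads))
    alns = []
    for rid, seq in reads:
        alns.extend(mapping.map_read(rid, seq, ref_index, reference))
    filt = mapping.filter_alignments(alns, min_mapq=min_mapq)
    ids = mapping.extract_locus_reads(filt, locus, ref_len=len(reference))
    locus_reads = [(rid, s) for rid, s in reads if rid in ids]
    res.n_locus_reads = len(locus_reads)
    if not locus_reads:
        res.excluded_flags.append("no locus reads")
        res.status = "excluded"
        return res
    olc = assembly.assemble_olc(locus_reads)
    res.contig_olc = olc.seq
    try:
        sdbg = assembly.assemble_sdbg(locus_reads)
        res.contig_sdbg = sdbg.seq
    except ValueError as exc:
        res.contig_sdbg = ""
        res.excluded_flags.append(f"sdbg assembly failed: {exc}")
    # QC on the polished olc contig (the assembly that advances)
    cov_windows, cov_status = qc.coverage_discrepancy(locus_reads, olc.seq)
    ls, le = locus
    ref_with_flanks = reference[max(0, ls - 2000) : min(len(reference), le + 2000)]
    spans, col_status = qc.collinearity_check(olc.seq, ref_with_flanks,
                                              flank_len=1000)
    report = qc.QCReport(strain, cov_status, cov_windows, col_status, spans)
    if res.contig_sdbg:
        report.concordance, _ = qc.assembler_concordance(olc.seq, res.contig_sdbg)
    res.qc_report = report
    if report.overall == "fail":
        res.excluded_flags.append("QC fail")
    res.trna = annotation.annotate_trnas(olc.seq, trnas)
    if res.trna.excluded:
        res.excluded_flags.extend(res.trna.missing)
    res.fragments = annotation.annotate_ty_fragments(res.trna.contig, library)
    frag = classify.qualifying_fragment(res.fragments)
    if frag is not None:
        ty1 = [e for e in library if e.subfamily == "Ty1prime"]
        ref_coding = ""
        if ty1:
            s, e = ty1[0].orf_interval
            ref_coding = ty1[0].internal_seq[s:e]
        if ref_coding:
            res.orf = annotation.call_orf(
                res.trna.contig[frag.start : frag.end], ref_coding)
    return res


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full workflow; see module docstring for stage order."""
    t0 = time.time()
    elapsed: dict[str, float] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    trnas = sim.default_trnas()
    if config.mode == "simulate":
        strains, library, tree_nwk = sim.build_panel(
            seed=config.seed, branch=config.branch_length,
            flank_len=config.flank_len)
        bp = sim.relic_blueprint()
        reference, ref_truth = sim.build_locus_haplotype(
            bp, library, flank_len=config.flank_len, seed=config.seed)
        locus = ref_truth.locus_interval()
        truth_status = dict(sim.PANEL_TRUTH_STATUS)
        strain_tree = parse_newick(tree_nwk)
        if config.strains:
            strains = {k: v for k, v in strains.items() if k in config.strains}
            truth_status = {k: v for k, v in truth_status.items()
                            if k in config.strains}
        profile = _profile(config.profile)
        reads_by_strain = {}
        for i, (name, (genome, _)) in enumerate(sorted(strains.items())):
            reads, _ = sim.simulate_reads(
                genome, profile, config.coverage,
                seed=(config.seed * 1000 + i) % (2**31), prefix=f"{name}_r")
            reads_by_strain[name] = reads
    elif config.mode == "fastq":
        if not (config.reads_by_strain and config.reference_fasta and config.locus):
            raise ValueError("fastq mode needs reads, reference and locus")
        reference = next(iter(util.read_fasta(config.reference_fasta).values()))
        locus = config.locus
        library = sim.default_library()
        truth_status = {}
        strain_tree = None
        reads_by_strain = {s: util.read_fastq(p)
                           for s, p in config.reads_by_strain.items()}
    else:
        raise ValueError(f"unknown mode {config.mode}")
    elapsed["simulate"] = time.time() - t0

    if not reads_by_strain:
        return RunReport({}, {}, truth_status, elapsed=elapsed)

    ref_index = mapping.index_reference(reference)
    results: dict[str, StrainResult] = {}
    t1 = time.time()
    for name in sorted(reads_by_strain):
        ts = time.time()
        results[name] = process_strain(
            name, reads_by_strain[name], ref_index, reference, locus,
            trnas, library, config.min_mapq)
        log.info("strain %s processed in %.1fs (%d locus reads)", name,
                 time.time() - ts, results[name].n_locus_reads)
        if outdir:
            sdir = outdir / name
            sdir.mkdir(exist_ok=True)
            util.write_fastq(sdir / "reads.fastq", reads_by_strain[name])
            r = results[name]
            if r.contig_olc:
                util.write_fasta(sdir / "contig_olc.fa", {f"{name}_olc": r.contig_olc})
            if r.contig_sdbg:
                util.write_fasta(sdir / "contig_sdbg.fa", {f"{name}_sdbg": r.contig_sdbg})
            if r.qc_report:
                (sdir / "qc.json").write_text(json.dumps(r.qc_report.to_dict(),
                                                         indent=1))
            if r.trna:
                (sdir / "annot.gff3").write_text(annotation.to_gff3(
                    name, r.trna.calls, r.fragments, r.orf))
    elapsed["per_strain"] = time.time() - t1

    # --- cohort stages ------------------------------------------------------
    t2 = time.time()
    fragment_seqs: dict[str, str] = {}
    subfam_hits: dict[str, str] = {}
    for name, r in results.items():
        if r.excluded_flags:
            continue
        frag = classify.qualifying_fragment(r.fragments)
        if frag is not None:
            fragment_seqs[name] = r.trna.contig[frag.start : frag.end]
            subfam_hits[name] = frag.subfamily
    # anchor: the ancestral (reference) fragment
    ref_anchor = "__reference__"
    if config.mode == "simulate":
        ref_frag = ref_truth.feature_of_kind("truncated_ty")
        fragment_seqs[ref_anchor] = reference[ref_frag.start : ref_frag.end]
        subfam_hits[ref_anchor] = "Ty1prime"
    anchor = ref_anchor if ref_anchor in fragment_seqs else \
        (sorted(fragment_seqs)[0] if fragment_seqs else None)
    if anchor is not None and len(fragment_seqs) >= 1:
        frag_result = classify.build_fragment_tree(
            fragment_seqs, subfam_hits, anchor, "Ty1prime",
            replicates=config.bootstrap_replicates, seed=config.seed)
    else:
        frag_result = classify.FragmentTreeResult(None, frozenset(), fallback=True)
    statuses = {}
    status_objs = []
    for name, r in results.items():
        st = classify.call_status(name, r.fragments, r.excluded_flags,
                                  frag_result)
        r.status = st.status
        statuses[name] = st.status
        status_objs.append(st)
    elapsed["classify"] = time.time() - t2

    # flanking-region phylogeny
    t3 = time.time()
    flank_tree = None
    flank_seqs = []
    for name, r in sorted(results.items()):
        if r.excluded_flags or r.trna is None or len(r.trna.calls) < 2:
            continue
        try:
            flank_seqs.append((name, phylo.extract_flank_concat(
                r.trna.contig, r.trna.calls, config.flank_concat_len)))
        except ValueError:
            continue
    if len(flank_seqs) >= 4:
        msa = phylo.progressive_msa(flank_seqs)
        if config.tree_method == "ml":
            flank_tree, _ = phylo.ml_tree(msa)
        else:
            flank_tree = phylo.bootstrap_support(
                msa, lambda a: phylo.bionj(distances_safe(a)),
                replicates=config.bootstrap_replicates, seed=config.seed)
        og = [t for t in config.outgroup if t in {n for n, _ in flank_seqs}]
        if og:
            try:
                flank_tree = phylo.root_by_clade(flank_tree, og)
            except ValueError:
                log.warning("outgroup not monophyletic; tree left unrooted")
    elapsed["phylo"] = time.time() - t3

    # loss parsimony on the true strain tree when available, else inferred
    loss = None
    count_tree = strain_tree if strain_tree is not None else flank_tree
    if count_tree is not None:
        leaf_status = {n: statuses.get(n) for n in count_tree.leaf_labels()
                       if n in statuses}
        if len(leaf_status) == len(count_tree.leaf_labels()) and \
                all(v and v != "excluded" for v in leaf_status.values()):
            loss = loss_event_count(count_tree, leaf_status)

    # dN/dS of the conserved ORF across present strains
    t4 = time.time()
    m0 = None
    cds = []
    for name, r in sorted(results.items()):
        if r.status != "present" or r.orf is None or r.orf.empty:
            continue
        frag = classify.qualifying_fragment(r.fragments)
        seq = r.trna.contig[frag.start + r.orf.start : frag.start + r.orf.end]
        if len(seq) % 3 == 0:
            cds.append((name, seq))
    if len(cds) >= 3:
        try:
            aln = molevol.codon_align(cds)
            m0 = molevol.fit_m0(aln)
        except (ValueError, RuntimeError) as exc:
            log.warning("M0 fit skipped: %s", exc)
    elapsed["molevol"] = time.time() - t4

    report = RunReport(statuses, results, truth_status, frag_result.tree,
                       flank_tree, m0, loss, elapsed)
    if outdir:
        cohort = outdir / "cohort"
        cohort.mkdir(exist_ok=True)
        (cohort / "status.tsv").write_text(classify.status_table(status_objs))
        if frag_result.tree is not None:
            (cohort / "fragment_tree.nwk").write_text(frag_result.tree.to_newick())
        if flank_tree is not None:
            (cohort / "flank_tree.nwk").write_text(flank_tree.to_newick())
        if m0 is not None:
            (cohort / "m0.json").write_text(json.dumps({
                "omega": m0.omega, "kappa": m0.kappa, "logL": m0.logl,
                "dN": m0.dn, "dS": m0.ds, "tree": m0.tree.to_newick()}, indent=1))
    return report


def distances_safe(msa):
    """JC distances, falling back to p-distances on saturation."""
    try:
        return phylo.distances(msa, model="JC")
    except ValueError:
        return phylo.distances(msa, model="p")


def loss_event_count(tree: Node, statuses: dict[str, str]) -> int:
    """Fitch small-parsimony count of state changes given presence at the
    root (each loss/conversion event counts once)."""
    missing = [l for l in tree.leaf_labels() if l not in statuses]
    if missing:
        raise ValueError(f"leaves without status: {missing}")
    changes = 0

    def fitch(node: Node) -> frozenset[str]:
        nonlocal changes
        if node.is_leaf:
            return frozenset([statuses[node.label]])
        sets = [fitch(c) for c in node.children]
        inter = frozenset.intersection(*sets)
        if inter:
            return inter
        changes += 1
        return frozenset.union(*sets)

    root_set = fitch(tree)
    if "present" not in root_set:
        changes += 1
    return changes
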