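"""Locus status calls: present / absent / gene-converted / excluded.

A strain is *present* when it carries a truncated Ty1-family internal
fragment in the forward orientation between the tRNAs whose sequence
falls inside the bona fide clade of the fragment phylogeny; *converted*
when a structurally matching fragment clusters outside that clade (a
different subfamily haplotype occupying the same position); *absent*
when no qualifying fragment exists; *excluded* propagates QC or tRNA
flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation import TyFragment
from .phylo import bionj, bootstrap_support, distances, progressive_msa
from .trees import Node


@dataclass
class LocusStatus:
    strain: str
    status: str  # present | absent | converted | excluded
    evidence: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


@dataclass
class FragmentTreeResult:
    tree: Node | None
    bona_fide_taxa: frozenset[str]
    support: float | None = None  # bootstrap support of the clade edge
    fallback: bool = False  # subfamily best-hit only (too few fragments)


def qualifying_fragment(fragments: list[TyFragment],
                        family: str = "Ty1") -> TyFragment | None:
    """The structural signature of the locus insertion: a truncated
    internal fragment of the target family in forward orientation."""
    hits = [f for f in fragments
            if f.part == "internal" and f.family == family
            and f.completeness == "truncated" and f.strand == "+"]
    return max(hits, key=lambda f: f.length) if hits else None


def build_fragment_tree(fragment_seqs: dict[str, str],
                        subfamily_hits: dict[str, str],
                        reference_taxon: str,
                        canonical_subfamily: str,
                        replicates: int = 100, seed: int = 0
                        ) -> FragmentTreeResult:
    """Phylogeny of all truncated family fragments across strains, and the
    bona fide clade definition.

    The bona fide clade is the maximal clade (bipartition side) containing
    the designated reference taxon's fragment and only fragments whose
    best library hit is the canonical subfamily.  With < 3 fragments no
    tree is built and membership falls back to the subfamily best hit.
    """
    taxa = sorted(fragment_seqs)
    if reference_taxon not in fragment_seqs:
        raise ValueError(f"reference taxon {reference_taxon} has no fragment")
    if len(taxa) < 3:
        bona = frozenset(t for t in taxa
                         if subfamily_hits.get(t) == canonical_subfamily)
        return FragmentTreeResult(None, bona, None, fallback=True)
    msa = progressive_msa([(t, fragment_seqs[t]) for t in taxa])

    def builder(aln):
        return bionj(distances(aln, model="JC"))

    tree = bootstrap_support(msa, builder, replicates=replicates, seed=seed)
    canonical = {t for t in taxa if subfamily_hits.get(t) == canonical_subfamily}
    best: frozenset[str] | None = None
    all_taxa = frozenset(taxa)
    # candidate clades: each bipartition side, single leaves, all taxa
    candidates = [frozenset([t]) for t in taxa] + [all_taxa]
    for node in tree.postorder():
        if node is tree:
            continue
        side = frozenset(node.leaf_labels())
        candidates.append(side)
        candidates.append(all_taxa - side)
    for side in candidates:
        if reference_taxon in side and side <= canonical:
            if best is None or len(side) > len(best):
                best = side
    if best is None:
        best = frozenset([reference_taxon])
    support = None
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        if side == best or side == all_taxa - best:
            support = node.support
    return FragmentTreeResult(tree, best, support)


def call_status(strain: str, fragments: list[TyFragment],
                excluded_flags: list[str],
                fragment_result: FragmentTreeResult) -> LocusStatus:
    """Classify one strain given its annotation and the cohort fragment
    phylogeny."""
    if excluded_flags:
        return LocusStatus(strain, "excluded", notes=list(excluded_flags))
    frag = qualifying_fragment(fragments)
    if frag is None:
        return LocusStatus(strain, "absent")
    in_clade = strain in fragment_result.bona_fide_taxa
    status = "present" if in_clade else "converted"
    return LocusStatus(strain, status, evidence={
        "fragment": (frag.start, frag.end, frag.strand),
        "subfamily": frag.subfamily,
        "identity": frag.identity,
        "in_bona_fide_clade": in_clade,
    })


def status_table(statuses: list[LocusStatus]) -> str:
    lines = ["strain\tstatus\tsubfamily\tnotes"]
    for s in sorted(statuses, key=lambda x: x.strain):
        sub = s.evidence.get("subfamily", "")
        lines.append(f"{s.strain}\t{s.status}\t{sub}\t{';'.join(s.notes)}")
    return "\n".join(lines) + "\n"
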