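"""Annotation of locus assemblies: tRNA genes, Ty/LTR fragments, ORFs.

Annotation is alignment-based throughout: the flanking tRNAs are known a
priori, so a covariance-model scan would be overkill, and the Ty library
is small enough for exhaustive per-entry tiling.  Fragments are found by
exact-seed clustering confirmed with edit-distance alignment against
each library entry, then merged and classified as solo LTR, truncated
element or full-length element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from . import util

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class TrnaCall:
    name: str
    start: int
    end: int
    strand: str
    identity: float


@dataclass
class TyFragment:
    start: int
    end: int
    strand: str
    family: str
    subfamily: str  # "" when best hit is ambiguous (family-only call)
    part: str  # ltr | internal
    completeness: str  # solo_ltr | truncated | full_length
    identity: float
    entry: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfCall:
    start: int = -1
    end: int = -1
    frame: int = -1
    protein_length: int = 0
    premature_stops: list[int] = field(default_factory=list)
    frameshifts: list[int] = field(default_factory=list)
    note: str = ""

    @property
    def empty(self) -> bool:
        return self.start < 0


@dataclass
class TrnaAnnotation:
    calls: list[TrnaCall]
    contig: str  # orientation-normalized
    flipped: bool
    missing: list[str]

    @property
    def excluded(self) -> bool:
        return bool(self.missing)


def find_longest_orf(seq: str, min_codons: int = 50) -> tuple[int, int] | None:
    """Longest ATG..stop ORF (including the stop codon, >= min_codons
    codons) over the three forward frames; half-open interval."""
    best = None
    for frame in range(3):
        start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                if (i + 3 - start) // 3 >= min_codons:
                    if best is None or i + 3 - start > best[1] - best[0]:
                        best = (start, i + 3)
                start = None
    return best


# ---------------------------------------------------------------------------
# tRNA annotation


def _best_hit(query: str, target: str) -> tuple[int, int, str, float] | None:
    """Best full-query local placement of query in target, either strand."""
    best = None
    for strand, q in (("+", query), ("-", util.revcomp(query))):
        res = edlib.align(q, target, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / len(q)
        loc = res["locations"][0]
        if best is None or ident > best[3]:
            best = (loc[0], loc[1] + 1, strand, ident)
    return best


def annotate_trnas(contig: str, trna_refs: dict[str, str],
                   expected: tuple[str, str] = ("tRNA-Gly", "tRNA-Ser"),
                   min_identity: float = 0.90) -> TrnaAnnotation:
    """Locate the flanking tRNAs and normalize assembly orientation.

    The locus convention is 5' tRNA (+ strand) first; if the calls come
    out mirrored the contig is reverse-complemented and re-annotated.
    A missing flanking tRNA sets the exclusion flag instead of raising.
    """
    def scan(seq: str) -> tuple[list[TrnaCall], list[str]]:
        calls, missing = [], []
        for name in expected:
            hit = _best_hit(trna_refs[name], seq)
            if hit is None or hit[3] < min_identity:
                missing.append(name)
                continue
            calls.append(TrnaCall(name, hit[0], hit[1], hit[2], hit[3]))
        return calls, missing

    calls, missing = scan(contig)
    flipped = False
    by_name = {c.name: c for c in calls}
    five = by_name.get(expected[0])
    three = by_name.get(expected[1])
    if five is not None:
        flipped = five.strand == "-"
    elif three is not None:
        flipped = three.strand == "+"
    if flipped:
        contig = util.revcomp(contig)
        calls, missing = scan(contig)
    calls.sort(key=lambda c: c.start)
    if missing:
        missing = [f"missing flanking tRNA: {m}" for m in missing]
    return TrnaAnnotation(calls, contig, flipped, missing)


# ---------------------------------------------------------------------------
# Ty fragment annotation


def _seed_candidates(contig: str, query: str, k: int = 13,
                     max_tpos_gap: int = 400, max_diag_drift: int = 150
                     ) -> list[tuple[int, int, int, int]]:
    """Cluster exact k-mer matches into candidate intervals.

    Returns (contig_start, contig_end, query_start, query_end) per
    cluster; boundaries are seed extremes and get refined by alignment.
    """
    qpos: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        qpos.setdefault(query[i : i + k], []).append(i)
    hits = []
    for t in range(len(contig) - k + 1):
        for qp in qpos.get(contig[t : t + k], ()):  # usually 0 or 1
            hits.append((t, t - qp))
    if not hits:
        return []
    hits.sort()
    clusters = []
    cur = [hits[0]]
    for t, d in hits[1:]:
        if t - cur[-1][0] <= max_tpos_gap and abs(d - np.median([x[1] for x in cur[-5:]])) <= max_diag_drift:
            cur.append((t, d))
        else:
            clusters.append(cur)
            cur = [(t, d)]
    clusters.append(cur)
    out = []
    for cl in clusters:
        ts, te = cl[0][0], cl[-1][0] + k
        qs = min(t - d for t, d in cl)
        qe = max(t - d for t, d in cl) + k
        out.append((ts, te, qs, qe))
    return out


def _refine_candidate(contig: str, query: str, cand, pad: int = 120
                      ) -> tuple[int, int]:
    """Extend a seeded candidate's boundaries by score-trimmed alignment
    of the query flanks (x-drop style): diverged-but-homologous termini
    are recovered while truncation boundaries stay put."""
    from .mapping import _trimmed_extension

    ts, te, qs, qe = cand
    # right extension
    rq = query[qe : qe + pad]
    rt = contig[te : te + pad + 60]
    _, _, tc = _trimmed_extension(rq, rt)
    te += tc
    # left extension (reverse both)
    lq = query[max(0, qs - pad) : qs][::-1]
    lt = contig[max(0, ts - pad - 60) : ts][::-1]
    _, _, tc = _trimmed_extension(lq, lt)
    ts -= tc
    return ts, te


def _fragment_identity(frag: str, part_seq: str, strand: str) -> float:
    q = frag if strand == "+" else util.revcomp(frag)
    res = edlib.align(q, part_seq, mode="HW", task="distance")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(q)


def annotate_ty_fragments(contig: str, library, min_len: int = 40,
                          min_identity: float = 0.55, merge_gap: int = 50,
                          subfamily_margin: float = 0.005
                          ) -> list[TyFragment]:
    """Tile the contig against every library entry's LTR and internal
    sequence on both strands; merge nearby co-oriented hits; classify.

    Subfamily is the best-identity entry, assigned only when it beats the
    runner-up by ``subfamily_margin`` — otherwise the call is family-only,
    which keeps downstream gene-conversion calls conservative.
    """
    raw: list[tuple[str, str, str, int, int, float, str]] = []
    by_family_part: dict[tuple[str, str], list] = {}
    for entry in library:
        for part, seq in (("ltr", entry.ltr_seq), ("internal", entry.internal_seq)):
            if not seq:
                continue
            by_family_part.setdefault((entry.family, part), []).append((entry, seq))
    fragments: list[TyFragment] = []
    for (family, part), entries in sorted(by_family_part.items()):
        intervals: list[tuple[int, int, str]] = []
        for entry, seq in entries:
            for strand in ("+", "-"):
                q = seq if strand == "+" else util.revcomp(seq)
                for cand in _seed_candidates(contig, q):
                    ts, te = _refine_candidate(contig, q, cand)
                    if te - ts >= min_len:
                        intervals.append((ts, te, strand))
        if not intervals:
            continue
        merged = _merge_intervals(intervals, merge_gap)
        for ts, te, strand in merged:
            frag = contig[ts:te]
            scored = sorted(
                ((_fragment_identity(frag, seq, strand), entry)
                 for entry, seq in entries),
                key=lambda t: (-t[0], t[1].name))
            best_id, best_entry = scored[0]
            if best_id < min_identity or te - ts < min_len:
                continue
            if len(scored) > 1 and best_id - scored[1][0] < subfamily_margin:
                subfam = ""
            else:
                subfam = best_entry.subfamily
            fragments.append(TyFragment(ts, te, strand, family, subfam, part,
                                        "truncated", best_id, best_entry.name))
    fragments.sort(key=lambda f: f.start)
    _classify_completeness(fragments, merge_gap)
    return fragments


def _merge_intervals(intervals, gap):
    out = []
    for strand in ("+", "-"):
        ivs = sorted(i for i in intervals if i[2] == strand)
        cur = None
        for ts, te, _ in ivs:
            if cur and ts <= cur[1] + gap:
                cur[1] = max(cur[1], te)
            else:
                if cur:
                    out.append((cur[0], cur[1], strand))
                cur = [ts, te]
        if cur:
            out.append((cur[0], cur[1], strand))
    return out


def _classify_completeness(fragments: list[TyFragment], gap: int) -> None:
    for i, f in enumerate(fragments):
        if f.part != "internal":
            continue
        left = right = False
        for g in fragments:
            if g.part != "ltr" or g.family != f.family or g.strand != f.strand:
                continue
            if 0 <= f.start - g.end <= 2 * gap:
                left = True
                g.completeness = "flanking_ltr"
            elif 0 <= g.start - f.end <= 2 * gap:
                right = True
                g.completeness = "flanking_ltr"
        f.completeness = "full_length" if (left and right) else "truncated"
    for f in fragments:
        if f.part == "ltr" and f.completeness == "truncated":
            f.completeness = "solo_ltr"
        elif f.part == "ltr" and f.completeness == "flanking_ltr":
            # LTR adjacent to an internal of its own family
            neighbour_full = any(
                g.part == "internal" and g.family == f.family
                and g.completeness == "full_length" for g in fragments)
            f.completeness = "full_length" if neighbour_full else "truncated"


# ---------------------------------------------------------------------------
# ORF calling


def call_orf(fragment: str, reference_coding: str, min_codons: int = 50
             ) -> OrfCall:
    """Call the longest forward-frame ORF and relate the fragment to a
    reference coding sequence: net-indel (frameshift) offsets and
    premature in-frame stops upstream of the called ORF."""
    if len(reference_coding) % 3:
        raise ValueError("reference coding sequence not in frame")
    orf = find_longest_orf(fragment, min_codons)
    if orf is None:
        return OrfCall(note=f"no ORF >= {min_codons} codons")
    start, end = orf
    call = OrfCall(start, end, start % 3, (end - start) // 3 - 1)
    # align only the homologous overlap: the fragment usually carries a
    # truncated piece of the reference coding sequence (and extra flanking
    # sequence), so end-to-end alignment would fabricate indels
    span = _anchored_overlap(reference_coding, fragment)
    if span is None:
        call.note = "reference coding sequence did not align"
        return call
    qs, qe, ts, te = span
    res = edlib.align(reference_coding[qs:qe], fragment[ts:te], mode="NW",
                      task="path")
    t, q = ts, qs
    t_anchor = None
    events: list[tuple[int, int]] = []  # (fragment pos, net indel length)
    import re

    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op in "=X":
            if t_anchor is None:
                skip = (-q) % 3  # first reference codon boundary in the run
                if skip < n:
                    t_anchor = t + skip
            t += n
            q += n
        elif op == "I":  # present in reference, absent in fragment
            events.append((t, -n))
            q += n
        elif op == "D":  # extra bases in fragment
            events.append((t, n))
            t += n
    # frameshifts: nearby compensating indels cancel (cluster gap 30 bp)
    i = 0
    while i < len(events):
        j = i
        net = 0
        while j < len(events) and events[j][0] - events[i][0] <= 30:
            net += events[j][1]
            j += 1
        if net % 3:
            call.frameshifts.append(events[i][0])
        i = j
    # premature stops: scan the fragment in the frame set by the upstream
    # reference-aligned region (the frame a ribosome entering from 5'
    # would read), up to the intact ORF start
    if t_anchor is not None:
        for p in range(t_anchor, min(start, len(fragment) - 2) - 2, 3):
            if fragment[p : p + 3] in _STOPS:
                call.premature_stops.append(p)
    return call


def _anchored_overlap(ref: str, frag: str, k: int = 15
                      ) -> tuple[int, int, int, int] | None:
    """Colinear exact-k-mer chain between two sequences; returns the
    spanned (ref_start, ref_end, frag_start, frag_end) or None."""
    import bisect

    pos: dict[str, int] = {}
    dup = set()
    for i in range(len(ref) - k + 1):
        km = ref[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    pairs = sorted((pos[frag[i : i + k]], i)
                   for i in range(len(frag) - k + 1) if frag[i : i + k] in pos)
    if not pairs:
        return None
    # longest chain increasing in the fragment coordinate
    tails: list[int] = []
    tail_pairs: list[tuple[int, int]] = []
    parents: dict[tuple[int, int], tuple[int, int] | None] = {}
    for p in pairs:
        j = bisect.bisect_left(tails, p[1])
        if j == len(tails):
            tails.append(p[1])
            tail_pairs.append(p)
        else:
            tails[j] = p[1]
            tail_pairs[j] = p
        parents[p] = tail_pairs[j - 1] if j > 0 else None
    chain = []
    node = tail_pairs[-1]
    while node is not None:
        chain.append(node)
        node = parents[node]
    chain.reverse()
    (q0, t0), (q1, t1) = chain[0], chain[-1]
    return q0, q1 + k, t0, t1 + k


# ---------------------------------------------------------------------------
# GFF3 output


def to_gff3(seqid: str, trnas: list[TrnaCall], fragments: list[TyFragment],
            orf: OrfCall | None = None) -> str:
    lines = ["##gff-version 3"]
    for c in trnas:
        lines.append("\t".join([
            seqid, "tylocus", "tRNA_gene", str(c.start + 1), str(c.end), ".",
            c.strand, ".", f"ID={c.name};identity={c.identity:.3f}"]))
    for i, f in enumerate(fragments):
        attrs = (f"ID=tyfrag{i};family={f.family};subfamily={f.subfamily}"
                 f";part={f.part};completeness={f.completeness}"
                 f";identity={f.identity:.3f};entry={f.entry}")
        lines.append("\t".join([
            seqid, "tylocus", "LTR_retrotransposon_fragment", str(f.start + 1),
            str(f.end), f"{f.identity:.3f}", f.strand, ".", attrs]))
    if orf is not None and not orf.empty:
        lines.append("\t".join([
            seqid, "tylocus", "ORF", str(orf.start + 1), str(orf.end), ".",
            "+", "0", f"ID=orf;protein_length={orf.protein_length}"]))
    return "\n".join(lines) + "\n"
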