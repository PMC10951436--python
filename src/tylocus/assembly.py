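"""Local assembly of extracted locus reads with two independent algorithms.

``assemble_olc`` is a greedy overlap-layout-consensus assembler: all-vs-all
dovetail overlaps (minimizer screening + edit-distance confirmation),
greedy best-overlap layout, column-vote consensus, then polishing.

``assemble_sdbg`` is a sparse-marker frame assembler: reads above a
minimum length are anchored onto a growing coordinate frame by shared
sparse k-mer markers (hash-thresholded, not windowed minimizers), the
frame is cut into fixed-size bins, the heaviest contiguous bin run is
kept, and a single majority consensus is taken — no polishing, mirroring
the behaviour difference between a polishing and a non-polishing
assembler.

Both return a :class:`ContigAssembly`; determinism follows from fixed
input order and documented tie-breaking (longer overlap first, then
lexicographically smaller read id).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from . import util


@dataclass
class OverlapEdge:
    read_a: str
    read_b: str
    orientation: str  # '+' B same strand as A, '-' reverse
    overlap_len: int
    identity: float
    # offset of A[0] in (oriented) B coordinates; negative = A starts before B
    offset: int
    contained: str | None = None  # id of the contained read, if any


@dataclass
class ContigAssembly:
    seq: str
    depth: np.ndarray
    read_ids: list[str]
    assembler: str  # olc | sdbg
    polish_rounds: int = 0

    def __post_init__(self):
        if len(self.depth) != len(self.seq):
            raise ValueError("depth vector length must equal contig length")

    def header(self) -> str:
        return (f"assembler={self.assembler} rounds={self.polish_rounds} "
                f"reads={len(self.read_ids)}")


# ---------------------------------------------------------------------------
# Overlap computation


def _read_minimizers(reads, k=15, w=10):
    out = {}
    for rid, seq in reads:
        out[rid] = util.minimizers(seq, k, w)
    return out


def compute_overlaps(reads: list[tuple[str, str]], min_overlap: int = 500,
                     min_identity: float = 0.75,
                     k: int = 15, w: int = 10) -> list[OverlapEdge]:
    """All-vs-all candidate overlaps by shared-minimizer screening,
    confirmed by edit-distance dovetail alignment.

    Contained reads are flagged on the edge rather than dropped here.
    """
    if not reads:
        raise ValueError("no reads")
    seqs = dict(reads)
    mins = _read_minimizers(reads, k, w)
    # hash -> [(rid, pos, strand)]
    table: dict[int, list[tuple[str, int, int]]] = {}
    for rid, mm in mins.items():
        for pos, h, strand in mm:
            table.setdefault(h, []).append((rid, pos, strand))
    pair_hits: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    order = {rid: i for i, (rid, _) in enumerate(reads)}
    for h, entries in table.items():
        if len(entries) < 2 or len(entries) > 50:
            continue
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                (ra, pa, sa), (rb, pb, sb) = entries[i], entries[j]
                if ra == rb:
                    continue
                if order[ra] > order[rb]:
                    (ra, pa, sa), (rb, pb, sb) = (rb, pb, sb), (ra, pa, sa)
                pair_hits.setdefault((ra, rb), []).append((pa, pb, sa ^ sb))
    edges = []
    for (ra, rb), hits in sorted(pair_hits.items()):
        if len(hits) < 4:
            continue
        la, lb = len(seqs[ra]), len(seqs[rb])
        fwd = [(pa, pb) for pa, pb, x in hits if x == 0]
        rev = [(pa, lb - pb - k) for pa, pb, x in hits if x == 1]
        orientation, pairs = ("+", fwd) if len(fwd) >= len(rev) else ("-", rev)
        if len(pairs) < 4:
            continue
        b_seq = seqs[rb] if orientation == "+" else util.revcomp(seqs[rb])
        offs = np.array([pb - pa for pa, pb in pairs])
        offset = int(np.median(offs))
        edge = _confirm_overlap(ra, rb, seqs[ra], b_seq, orientation, offset,
                                min_overlap, min_identity)
        if edge is not None:
            edges.append(edge)
    return edges


def _confirm_overlap(ra, rb, a: str, b: str, orientation: str, offset: int,
                     min_overlap: int, min_identity: float) -> OverlapEdge | None:
    """Confirm a candidate overlap. ``offset``: A[i] ~ B[i + offset]."""
    la, lb = len(a), len(b)
    slack = max(100, int(0.2 * min(la, lb) * 0.5))
    a_lo, a_hi = -offset, -offset + lb  # A-coords covered by B
    ov_start = max(0, a_lo)
    ov_end = min(la, a_hi)
    if ov_end - ov_start < min_overlap:
        return None
    contained = None
    if a_lo <= 0 and a_hi >= la:
        contained = ra
    elif a_lo >= 0 and a_hi <= la:
        contained = rb
    # confirm identity on (a capped stretch of) the overlapping A segment
    # inside a padded B window; capping keeps all-vs-all confirmation cheap
    cap = 2000
    mid = (ov_start + ov_end) // 2
    c_start = max(ov_start, mid - cap // 2)
    c_end = min(ov_end, c_start + cap)
    q = a[c_start:c_end]
    b_lo = max(0, c_start + offset - slack)
    b_hi = min(lb, c_end + offset + slack)
    res = edlib.align(q, b[b_lo:b_hi], mode="HW", task="distance")
    if res["editDistance"] < 0:
        return None
    identity = 1.0 - res["editDistance"] / len(q)
    if identity < min_identity:
        return None
    return OverlapEdge(ra, rb, orientation, ov_end - ov_start, identity,
                       offset, contained)


def write_paf(path, edges: list[OverlapEdge], reads: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write("\t".join(map(str, [
                e.read_a, len(reads[e.read_a]), 0, e.overlap_len,
                e.orientation, e.read_b, len(reads[e.read_b]),
                max(0, e.offset), max(0, e.offset) + e.overlap_len,
                int(e.identity * e.overlap_len), e.overlap_len, 255])) + "\n")


# ---------------------------------------------------------------------------
# Column-vote consensus / polishing


def _align_reads(contig: str, reads: list[tuple[str, str]],
                 orientations: dict[str, str] | None = None):
    """Align every read to the contig (cached orientation when known).

    Returns a list of (oriented_seq, target_start, cigar_runs)."""
    out = []
    for rid, seq in reads:
        if orientations is not None and rid in orientations:
            oriented = seq if orientations[rid] == "+" else util.revcomp(seq)
            aln = edlib.align(oriented, contig, mode="HW", task="path")
            if aln["editDistance"] < 0:
                continue
        else:
            aln, oriented = _best_orientation(seq, contig)
            if aln is None:
                continue
            if orientations is not None:
                orientations[rid] = "+" if oriented == seq else "-"
        out.append((oriented, aln["locations"][0][0],
                    list(_iter_cigar(aln["cigar"]))))
    return out


def _refine_windows(contig: str, alignments, base_votes, del_votes,
                    ins_votes, cov, pad: int = 8, min_cov: int = 8) -> str:
    """Local plurality re-vote over read substrings in ambiguous windows.

    Columns where no call has a clear majority (often compensating indel
    clusters that column-wise voting cannot resolve) are grouped into
    short windows; each window is replaced by the most common read-derived
    string spanning it.
    """
    L = len(contig)
    suspicious = np.zeros(L, dtype=bool)
    okcov = cov >= min_cov
    suspicious |= okcov & (del_votes > 0.15 * cov) & (del_votes <= 0.5 * cov)
    for p, counter in ins_votes.items():
        if 0 <= p < L and cov[p] >= min_cov:
            cnt = max(counter.values())
            if 0.15 * cov[p] < cnt <= 0.5 * cov[p]:
                suspicious[p] = True
    if not suspicious.any():
        return contig
    pos = np.where(suspicious)[0]
    max_window = 32
    windows = []
    s = e = pos[0]
    for p in pos[1:]:
        if p - e <= 2 * pad and p - s <= max_window - 2 * pad:
            e = p
        else:
            windows.append((max(0, s - pad), min(L, e + pad + 1)))
            s = e = p
    windows.append((max(0, s - pad), min(L, e + pad + 1)))
    # per-alignment segment tables for contig->read coordinate lookup
    tables = []
    for oriented, t0, runs in alignments:
        t, q = t0, 0
        segs = []  # (t_start, t_end, q_start, op)
        for n, op in runs:
            if op in "=X":
                segs.append((t, t + n, q, op))
                t += n
                q += n
            elif op == "D":
                segs.append((t, t + n, q, op))
                t += n
            else:
                q += n
        tends = np.array([sg[1] for sg in segs])
        tables.append((oriented, t0, t, segs, tends))

    def read_pos(table, tpos):
        oriented, t0, tmax, segs, tends = table
        if not (t0 <= tpos < tmax):
            return None
        i = int(np.searchsorted(tends, tpos, side="right"))
        if i >= len(segs):
            return None
        ts, te, qs, op = segs[i]
        if tpos < ts:
            return qs  # inside a preceding insertion boundary
        return qs + (tpos - ts if op != "D" else 0)

    new_parts = []
    last = 0
    for s, e in windows:
        strings = []
        for table in tables:
            a = read_pos(table, s)
            b = read_pos(table, e - 1)
            if a is None or b is None:
                continue
            strings.append(table[0][a : b + 1])
        if len(strings) >= max(2, min_cov):
            votes = Counter(strings)
            best, cnt = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
            if cnt < 2:
                continue
            if best and best != contig[s:e]:
                new_parts.append(contig[last:s])
                new_parts.append(best)
                last = e
    new_parts.append(contig[last:])
    return "".join(new_parts)



def _run_starts(contig: str) -> np.ndarray:
    """run_starts[i] = start index of the homopolymer run containing i."""
    arr = util.encode(contig)
    starts = np.arange(len(arr))
    same = np.zeros(len(arr), dtype=bool)
    same[1:] = arr[1:] == arr[:-1]
    idx = np.where(~same, starts, 0)
    return np.maximum.accumulate(idx)


def _votes_from_alignments(contig: str, alignments):
    """Column votes over a set of read-to-contig alignments.

    Single-base indel votes are pooled at the start of their homopolymer
    run: otherwise equivalent alignments spread the same event over the
    run and no single column reaches a majority.
    """
    L = len(contig)
    base_votes = np.zeros((L, 4), dtype=np.int32)
    del_votes = np.zeros(L, dtype=np.int32)
    cov = np.zeros(L, dtype=np.int32)
    ins_votes: dict[int, Counter] = {}
    runs = _run_starts(contig)
    for oriented, t0, cigar_runs in alignments:
        t, q = t0, 0
        qcodes = util.encode(oriented)
        for n, op in cigar_runs:
            if op in "=X":
                idx = np.arange(t, t + n)
                np.add.at(base_votes, (idx, qcodes[q : q + n].astype(np.intp)), 1)
                cov[idx] += 1
                t += n
                q += n
            elif op == "D":
                if n == 1:
                    del_votes[runs[t]] += 1
                else:
                    del_votes[t : t + n] += 1
                cov[t : t + n] += 1
                t += n
            elif op == "I":
                ins = oriented[q : q + n]
                p = t
                if n == 1 and 0 < p < L:
                    if contig[p] == ins:
                        p = runs[p]
                    elif contig[p - 1] == ins:
                        p = runs[p - 1]
                ins_votes.setdefault(p, Counter())[ins] += 1
                q += n
    return base_votes, del_votes, ins_votes, cov


def _consensus(contig: str, base_votes, del_votes, ins_votes, cov) -> str:
    """Column plurality with majority-gated indels.

    A deletion wins a column only with > 50% weighted support.  An
    insertion wins with > 50% support, or with > 35% support when it
    dominates every competing insertion at that junction: equivalent
    alignments scatter a true insertion over neighbouring columns, so a
    strict majority systematically misses real single-base insertions
    while spurious ones never approach the 35% floor.
    """
    out = []
    for i in range(len(contig)):
        c = cov[i]
        if i in ins_votes and c > 0:
            seq_counts = ins_votes[i]
            best, cnt = min(seq_counts.items(), key=lambda kv: (-kv[1], kv[0]))
            runner = max((v for k, v in seq_counts.items() if k != best),
                         default=0)
            if cnt > 0.5 * c or (cnt > 0.35 * c and cnt >= 3 * runner):
                out.append(best)
        if c == 0:
            out.append(contig[i])
            continue
        if del_votes[i] > 0.5 * c:
            continue
        out.append("ACGT"[int(np.argmax(base_votes[i]))])
    return "".join(out)


def _vote_pass(contig: str, reads: list[tuple[str, str]],
               orientations: dict[str, str] | None = None
               ) -> tuple[str, np.ndarray]:
    """Remap reads to the contig and take the depth-weighted plurality at
    every column; a deletion or insertion wins only with > 50% support."""
    alignments = _align_reads(contig, reads, orientations)
    votes = _votes_from_alignments(contig, alignments)
    return _consensus(contig, *votes), votes[3]


def _best_orientation(seq: str, contig: str):
    fwd = edlib.align(seq, contig, mode="HW", task="path")
    rc = util.revcomp(seq)
    rev = edlib.align(rc, contig, mode="HW", task="path")
    if fwd["editDistance"] < 0 and rev["editDistance"] < 0:
        return None, seq
    if rev["editDistance"] >= 0 and (fwd["editDistance"] < 0
                                     or rev["editDistance"] < fwd["editDistance"]):
        return rev, rc
    return fwd, seq


def _iter_cigar(cig: str):
    import re

    for n, op in re.findall(r"(\d+)([=XIDM])", cig or ""):
        yield int(n), op


def polish(contig: str, reads: list[tuple[str, str]], rounds: int = 2) -> str:
    """Iteratively replace every column by the depth-weighted plurality
    base/indel; ``rounds=0`` is the identity."""
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    orientations: dict[str, str] = {}
    for _ in range(rounds):
        new, _ = _vote_pass(contig, reads, orientations)
        if new == contig:
            break
        contig = new
    return contig


def read_depth(contig: str, reads: list[tuple[str, str]]) -> np.ndarray:
    _, cov = _vote_pass(contig, reads)
    return cov


# ---------------------------------------------------------------------------
# Greedy OLC assembler


def assemble_olc(reads: list[tuple[str, str]], min_overlap: int = 500,
                 min_identity: float = 0.75, polish_rounds: int = 2,
                 min_tip_depth: int = 4) -> ContigAssembly:
    """Greedy best-overlap layout + column-vote consensus + polishing.

    Contig tips are trimmed to the maximal stretch with read depth >=
    ``min_tip_depth``: below that no column vote is meaningful and tip
    bases are as error-prone as a single raw read."""
    if not reads:
        raise ValueError("no reads")
    seqs = dict(reads)
    if len(reads) == 1:
        rid, seq = reads[0]
        return ContigAssembly(seq, np.ones(len(seq), dtype=np.int32), [rid],
                              "olc", polish_rounds)
    edges = compute_overlaps(reads, min_overlap, min_identity)
    contained = {e.contained for e in edges if e.contained}
    dovetail = [e for e in edges
                if e.contained is None
                and e.read_a not in contained and e.read_b not in contained]
    usable = [(rid, s) for rid, s in reads if rid not in contained]
    if not usable:
        usable = [max(reads, key=lambda r: (len(r[1]), r[0]))]
    # adjacency: per read, overlaps sorted by quality
    adj: dict[str, list[OverlapEdge]] = {}
    for e in dovetail:
        adj.setdefault(e.read_a, []).append(e)
        adj.setdefault(e.read_b, []).append(e)

    def edge_key(e: OverlapEdge):
        return (-e.identity * e.overlap_len, -e.overlap_len,
                min(e.read_a, e.read_b))

    seed = max(usable, key=lambda r: (len(r[1]), r[0]))[0]
    layout: list[tuple[str, str]] = [(seed, "+")]  # (read, orientation)
    used = {seed}

    def oriented_seq(rid: str, orient: str) -> str:
        return seqs[rid] if orient == "+" else util.revcomp(seqs[rid])

    def edge_relative(e: OverlapEdge, rid: str) -> tuple[str, int, str]:
        """Express an edge with ``rid`` as the anchor: returns
        (other, off, ory) such that rid[i] ~ other_oriented(ory)[i + off]
        in rid's stored frame."""
        if e.read_a == rid:
            return e.read_b, e.offset, e.orientation
        la, lb = len(seqs[e.read_a]), len(seqs[e.read_b])
        if e.orientation == "+":
            return e.read_a, -e.offset, "+"
        return e.read_a, la - lb + e.offset, "-"

    def neighbours(rid: str, orient: str, side: str):
        """Unused reads overlapping rid and extending beyond it on `side`
        of the contig frame (rid placed with orientation `orient`)."""
        res = []
        lx = len(seqs[rid])
        for e in adj.get(rid, []):
            other, off, ory = edge_relative(e, rid)
            if other in used:
                continue
            ly = len(seqs[other])
            # other's span in rid's stored coords: [-off, -off + ly)
            start, end = -off, -off + ly
            if orient == "-":
                start, end = lx - end, lx - start
                ory = "+" if ory == "-" else "-"
            ext_left, ext_right = -start, end - lx
            if side == "right" and ext_right > 0:
                res.append((e, other, ory, ext_right))
            elif side == "left" and ext_left > 0:
                res.append((e, other, ory, ext_left))
        res.sort(key=lambda t: edge_key(t[0]))
        return res

    # extend right then left
    for side in ("right", "left"):
        while True:
            rid, orient = layout[-1] if side == "right" else layout[0]
            cands = neighbours(rid, orient, side)
            if not cands:
                break
            _, other, o_orient, _ = cands[0]
            used.add(other)
            if side == "right":
                layout.append((other, o_orient))
            else:
                layout.insert(0, (other, o_orient))
    backbone = oriented_seq(*layout[0])
    for rid, orient in layout[1:]:
        nxt = oriented_seq(rid, orient)
        # locate backbone tail inside the next read to find the junction
        tail = backbone[-min(len(backbone), 2000):]
        res = edlib.align(tail, nxt, mode="HW", task="distance")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        end = res["locations"][0][1] + 1
        if end < len(nxt):
            backbone += nxt[end:]
    orientations: dict[str, str] = {}
    contig, _ = _vote_pass(backbone, reads, orientations)
    for _ in range(polish_rounds):
        new, _ = _vote_pass(contig, reads, orientations)
        if new == contig:
            break
        contig = new
    # resolve ambiguous windows (compensating indel clusters) by local
    # consensus over spanning read substrings
    for _ in range(2):
        alignments = _align_reads(contig, reads, orientations)
        votes = _votes_from_alignments(contig, alignments)
        refined = _refine_windows(contig, alignments, *votes)
        if refined == contig:
            break
        contig = refined
    alignments = _align_reads(contig, reads, orientations)
    _, _, _, cov = _votes_from_alignments(contig, alignments)
    # estimate the residual read error rate: tips are only trimmed for
    # noisy data, where low-depth tips are as error-prone as a raw read
    nerr = sum(sum(n for n, op in runs if op != "=")
               for _, _, runs in alignments)
    nbase = sum(len(o) for o, _, _ in alignments)
    err_rate = nerr / nbase if nbase else 0.0
    if err_rate > 0.01 and len(reads) > 2 * min_tip_depth and len(cov):
        good = np.where(cov >= min_tip_depth)[0]
        if len(good):
            s, e = int(good[0]), int(good[-1]) + 1
            if 0 < s or e < len(contig):
                contig = contig[s:e]
                cov = read_depth(contig, reads)
    return ContigAssembly(contig, cov, [rid for rid, _ in reads], "olc",
                          polish_rounds)


# ---------------------------------------------------------------------------
# Sparse-marker frame assembler


def _sparse_markers(seq: str, k: int = 17, density: int = 8):
    h, strands = util.canonical_kmer_hashes(seq, k)
    thresh = np.uint64(0xFFFFFFFFFFFFFFFF) // np.uint64(density)
    pos = np.nonzero(h < thresh)[0]
    return [(int(p), int(h[p]), int(strands[p])) for p in pos]


def assemble_sdbg(reads: list[tuple[str, str]], k_bin: int = 256,
                  min_len: int = 3000) -> ContigAssembly:
    """Sparse-marker frame assembly with bin-graph trimming.

    Reads shorter than ``min_len`` are discarded up front (raising if
    nothing remains).  The consensus is a single majority vote — the
    contig is intentionally left unpolished.
    """
    reads = [(rid, s) for rid, s in reads if len(s) >= min_len]
    if not reads:
        raise ValueError(f"no reads of length >= {min_len}")
    seqs = dict(reads)
    k = 17
    marks = {rid: _sparse_markers(s, k) for rid, s in reads}
    seed = max(reads, key=lambda r: (len(r[1]), r[0]))[0]
    frame = seqs[seed]
    placements: dict[str, tuple[int, str]] = {seed: (0, "+")}
    for _pass in range(4):
        frame_marks: dict[int, list[int]] = {}
        for p, h, s in _sparse_markers(frame, k):
            frame_marks.setdefault(h, []).append((p, s))
        placed_any = False
        for rid, seq in reads:
            if rid in placements:
                continue
            offs_f, offs_r = [], []
            rlen = len(seq)
            for p, h, s in marks[rid]:
                for fp, fs in frame_marks.get(h, []):
                    if s == fs:
                        offs_f.append(fp - p)
                    else:
                        offs_r.append(fp - (rlen - p - k))
            orient, offs = ("+", offs_f) if len(offs_f) >= len(offs_r) else ("-", offs_r)
            if len(offs) < 5:
                continue
            offs = np.array(offs)
            med = int(np.median(offs))
            if np.mean(np.abs(offs - med) < 200) < 0.5:
                continue
            placements[rid] = (med, orient)
            placed_any = True
            oriented = seq if orient == "+" else util.revcomp(seq)
            if med < 0:
                frame = oriented[: -med] + frame
                placements = {r: (o - med, st) for r, (o, st) in placements.items()}
                placements[rid] = (0, orient)
            end = placements[rid][0] + rlen
            if end > len(frame):
                cut = len(frame) - placements[rid][0]
                frame = frame + oriented[cut:]
        if not placed_any:
            break
    # bin depth over the frame; keep the heaviest contiguous covered run
    nbins = (len(frame) + k_bin - 1) // k_bin
    depth_bins = np.zeros(nbins, dtype=np.int32)
    for rid, (off, orient) in placements.items():
        b0 = max(0, off // k_bin)
        b1 = min(nbins, -(-(off + len(seqs[rid])) // k_bin))  # ceil
        depth_bins[b0:b1] += 1
    best_run, cur = None, None
    for b in range(nbins):
        if depth_bins[b] > 0:
            if cur is None:
                cur = [b, b + 1, int(depth_bins[b])]
            else:
                cur[1] = b + 1
                cur[2] += int(depth_bins[b])
        elif cur is not None:
            if best_run is None or cur[2] > best_run[2]:
                best_run = cur
            cur = None
    if cur is not None and (best_run is None or cur[2] > best_run[2]):
        best_run = cur
    if best_run is None:
        raise ValueError("no covered bins in frame")
    frame = frame[best_run[0] * k_bin : min(len(frame), best_run[1] * k_bin)]
    layout_reads = [(rid, seqs[rid]) for rid in placements]
    consensus, _ = _vote_pass(frame, layout_reads)
    depth = read_depth(consensus, layout_reads)
    return ContigAssembly(consensus, depth, sorted(placements), "sdbg", 0)
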