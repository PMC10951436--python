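"""Long-read mapping against a reference locus.

A compact seed-chain-extend mapper: minimizer index, longest-colinear
chaining of anchors, base-level alignment of each chain with edit-distance
alignment plus score-trimmed tail extension.  Alignment categories follow
SAM semantics (one primary per mapped read; overlapping suboptimal chains
become secondary, disjoint ones supplementary), so the published
"-F 2304 -q 30" filter has a faithful analog here.

The mapping quality is a documented uniqueness score:
``mapq = 60`` with no competing chain, else
``clamp(round(40 * (1 - s2/s1) * min(1, anchors/10)), 0, 60)``
with ``s1``/``s2`` the best and second-best competing chain scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from . import util

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 2, -4, -4, -2


@dataclass
class MinimizerIndex:
    k: int
    w: int
    table: dict[int, list[tuple[int, int]]]
    ref_len: int


@dataclass
class ChainAlignment:
    read_id: str
    ref_id: str
    strand: str  # read strand relative to reference
    read_start: int
    read_end: int  # on the forward read
    ref_start: int
    ref_end: int
    ops: str  # extended CIGAR (=/X/I/D), query sense = read
    score: int
    mapq: int
    category: str  # primary | secondary | supplementary
    chain_score: float = 0.0
    n_anchors: int = 0

    @property
    def identity(self) -> float:
        import re

        matches = total = 0
        for n, op in re.findall(r"(\d+)([=XID])", self.ops):
            n = int(n)
            total += n
            if op == "=":
                matches += n
        return matches / total if total else 0.0


def index_reference(ref: str, k: int = 15, w: int = 10) -> MinimizerIndex:
    """Minimizer index of the reference (canonical k-mers, window w)."""
    if not (0 < k <= 28):
        raise ValueError("k must be in (0, 28]")
    if w < 1:
        raise ValueError("w must be >= 1")
    if len(ref) < k:
        raise ValueError(f"reference shorter than k ({len(ref)} < {k})")
    table: dict[int, list[tuple[int, int]]] = {}
    for pos, h, strand in util.minimizers(ref, k, w):
        table.setdefault(h, []).append((pos, strand))
    return MinimizerIndex(k, w, table, len(ref))


def _chain_anchors(anchors: np.ndarray, k: int, max_gap: int = 5000,
                   max_chains: int = 6, min_anchors: int = 3,
                   window: int = 60) -> list[tuple[float, np.ndarray]]:
    """Greedy multi-chain colinear chaining (minimap2-style DP).

    ``anchors``: (n, 2) array of (qpos, rpos), assumed same orientation.
    Returns up to ``max_chains`` (score, anchor_rows) sorted by score.
    """
    if len(anchors) == 0:
        return []
    order = np.lexsort((anchors[:, 0], anchors[:, 1]))
    a = anchors[order]
    n = len(a)
    score = np.full(n, float(k))
    parent = np.full(n, -1)
    q, r = a[:, 0].astype(float), a[:, 1].astype(float)
    for i in range(1, n):
        j0 = max(0, i - window)
        dq = q[i] - q[j0:i]
        dr = r[i] - r[j0:i]
        ok = (dq > 0) & (dr > 0) & (dq <= max_gap) & (dr <= max_gap)
        if not ok.any():
            continue
        gain = np.minimum(np.minimum(dq, dr), k) - 0.05 * np.abs(dr - dq) - 0.01
        cand = np.where(ok, score[j0:i] + gain, -np.inf)
        best = int(np.argmax(cand))
        if cand[best] > score[i]:
            score[i] = cand[best]
            parent[i] = j0 + best
    used = np.zeros(n, dtype=bool)
    chains = []
    attempts = 0
    while len(chains) < max_chains and attempts < 8 * max_chains:
        attempts += 1
        avail = np.where(~used)[0]
        if len(avail) == 0:
            break
        tip = avail[np.argmax(score[avail])]
        rows = []
        node = tip
        while node != -1 and not used[node]:
            rows.append(node)
            node = parent[node]
        rows = rows[::-1]
        used[rows] = True
        if len(rows) < min_anchors:
            continue  # stub hanging off an already-used chain
        # retire every anchor inside the chain's bounding box: parallel
        # leftovers would otherwise surface as spurious duplicate chains
        qlo, qhi = a[rows[0], 0], a[rows[-1], 0]
        rlo, rhi = a[rows[0], 1], a[rows[-1], 1]
        box = ((q >= qlo) & (q <= qhi) & (r >= rlo) & (r <= rhi))
        used |= box
        chains.append((float(score[tip]), a[rows]))
    chains.sort(key=lambda c: -c[0])
    return chains


def _cigar_score(ops: list[tuple[int, str]]) -> int:
    s = 0
    for n, op in ops:
        if op == "=":
            s += MATCH * n
        elif op == "X":
            s += MISMATCH * n
        else:
            s += GAP_OPEN + GAP_EXT * (n - 1)
    return s


def _parse_cigar(cig: str) -> list[tuple[int, str]]:
    import re

    return [(int(n), op) for n, op in re.findall(r"(\d+)([=XIDM])", cig)]


def _trimmed_extension(query: str, target: str) -> tuple[list[tuple[int, str]], int, int]:
    """Align query against a target window, then trim back to the
    maximum-scoring prefix (x-drop-like tail clipping).

    Returns (ops, query_consumed, target_consumed).
    """
    if not query or not target:
        return [], 0, 0
    res = edlib.align(query, target, mode="SHW", task="path")
    ops = _parse_cigar(res["cigar"] or "")
    best_score, best_idx = 0, -1
    run = 0
    flat: list[str] = []
    for n, op in ops:
        flat.extend([op] * n)
    qc = tc = 0
    best_qc = best_tc = 0
    prev = None
    for idx, op in enumerate(flat):
        if op == "=":
            run += MATCH
        elif op == "X":
            run += MISMATCH
        else:
            run += GAP_EXT if op == prev else GAP_OPEN
        prev = op
        if op in "=XI":
            qc += 1
        if op in "=XD":
            tc += 1
        if run > best_score:
            best_score, best_idx, best_qc, best_tc = run, idx, qc, tc
    if best_idx < 0:
        return [], 0, 0
    trimmed = flat[: best_idx + 1]
    out: list[tuple[int, str]] = []
    for op in trimmed:
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + 1, op)
        else:
            out.append((1, op))
    return out, best_qc, best_tc


def map_read(read_id: str, seq: str, index: MinimizerIndex, ref: str,
             ref_id: str = "ref", min_chain_anchors: int = 3,
             max_gap: int = 5000) -> list[ChainAlignment]:
    """Map one read: anchor, chain, extend, categorize.

    Returns [] for unmapped reads.  The best-scoring alignment is primary;
    chains whose read interval overlaps the primary's by >= 50% become
    secondary, others supplementary.
    """
    k = index.k
    read_mins = util.minimizers(seq, k, index.w)
    fwd_anchors, rev_anchors = [], []
    rlen = len(seq)
    for qpos, h, qstrand in read_mins:
        for rpos, rstrand in index.table.get(h, []):
            if qstrand == rstrand:
                fwd_anchors.append((qpos, rpos))
            else:
                rev_anchors.append((rlen - qpos - k, rpos))
    results = []
    for strand, anchors in (("+", fwd_anchors), ("-", rev_anchors)):
        if not anchors:
            continue
        chains = _chain_anchors(np.array(anchors), k, max_gap=max_gap,
                                min_anchors=min_chain_anchors)
        oriented = seq if strand == "+" else util.revcomp(seq)
        for chain_score, rows in chains:
            aln = _chain_to_alignment(read_id, oriented, ref, ref_id, strand,
                                      rows, k, chain_score)
            if aln is not None:
                results.append(aln)
    if not results:
        return []
    results.sort(key=lambda a: (-a.score, a.ref_start))
    primary = results[0]
    primary.category = "primary"
    for aln in results[1:]:
        ov = _interval_overlap((aln.read_start, aln.read_end),
                               (primary.read_start, primary.read_end))
        shorter = min(aln.read_end - aln.read_start,
                      primary.read_end - primary.read_start)
        aln.category = "secondary" if shorter and ov / shorter >= 0.5 else "supplementary"
    # mapq from competing chain scores
    for aln in results:
        competitors = [
            o for o in results
            if o is not aln
            and _interval_overlap((o.read_start, o.read_end),
                                  (aln.read_start, aln.read_end))
            >= 0.5 * max(1, min(o.read_end - o.read_start,
                                aln.read_end - aln.read_start))
        ]
        if not competitors:
            aln.mapq = 60
        else:
            s1 = aln.chain_score
            s2 = max(o.chain_score for o in competitors)
            if s2 > s1:
                aln.mapq = 0
            else:
                aln.mapq = int(np.clip(round(
                    40.0 * (1.0 - s2 / s1) * min(1.0, aln.n_anchors / 10.0)),
                    0, 60))
    return results


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _chain_to_alignment(read_id: str, oriented: str, ref: str, ref_id: str,
                        strand: str, rows: np.ndarray, k: int,
                        chain_score: float) -> ChainAlignment | None:
    qs, qe = int(rows[0, 0]), int(rows[-1, 0]) + k
    rs, re_ = int(rows[0, 1]), int(rows[-1, 1]) + k
    if qe <= qs or re_ <= rs:
        return None
    core = edlib.align(oriented[qs:qe], ref[rs:re_], mode="NW", task="path")
    ops = _parse_cigar(core["cigar"] or "")
    # left extension (reverse both, SHW, trim, reverse back)
    lq = oriented[:qs][::-1]
    lt_len = min(len(lq) + 200, rs)
    lt = ref[rs - lt_len : rs][::-1]
    lops, lqc, ltc = _trimmed_extension(lq, lt)
    lops = lops[::-1]
    # right extension
    rq = oriented[qe:]
    rt = ref[re_ : re_ + len(rq) + 200]
    rops, rqc, rtc = _trimmed_extension(rq, rt)
    all_ops = _merge_ops(lops + ops + rops)
    score = _cigar_score(all_ops)
    if score <= 0:
        return None
    # read interval in oriented coordinates
    oqs, oqe = qs - lqc, qe + rqc
    nrs, nre = rs - ltc, re_ + rtc
    rlen = len(oriented)
    if strand == "+":
        fqs, fqe = oqs, oqe
    else:
        fqs, fqe = rlen - oqe, rlen - oqs
    return ChainAlignment(read_id, ref_id, strand, fqs, fqe, nrs, nre,
                          "".join(f"{n}{op}" for n, op in all_ops),
                          score, 0, "secondary", chain_score, len(rows))


def _merge_ops(ops: list[tuple[int, str]]) -> list[tuple[int, str]]:
    out: list[tuple[int, str]] = []
    for n, op in ops:
        if n <= 0:
            continue
        if out and out[-1][1] == op:
            out[-1] = (out[-1][0] + n, op)
        else:
            out.append((n, op))
    return out


# ---------------------------------------------------------------------------
# Filtering and extraction


def filter_alignments(alns: list[ChainAlignment], min_mapq: int = 30,
                      drop_categories: set[str] = frozenset({"secondary",
                                                             "supplementary"})
                      ) -> list[ChainAlignment]:
    """Keep alignments with mapq >= min_mapq and category not dropped.

    Defaults reproduce the published filter (SAM flag 2304 = secondary +
    supplementary, and the q >= 30 threshold).
    """
    return [a for a in alns
            if a.mapq >= min_mapq and a.category not in drop_categories]


def extract_locus_reads(alns: list[ChainAlignment],
                        locus: tuple[int, int],
                        ref_len: int | None = None) -> set[str]:
    """Ids of reads with >= 1 alignment overlapping the locus by >= 1 base
    that is not fully contained within the locus (flanking/spanning reads)."""
    ls, le = locus
    if ls < 0 or le <= ls or (ref_len is not None and le > ref_len):
        raise ValueError(f"locus {locus} outside reference bounds")
    out = set()
    for a in alns:
        if a.ref_start < le and a.ref_end > ls:  # >= 1 bp overlap
            if not (a.ref_start >= ls and a.ref_end <= le):  # not contained
                out.add(a.read_id)
    return out


# ---------------------------------------------------------------------------
# SAM output


def write_sam(path, alns: list[ChainAlignment], ref_id: str, ref_len: int,
              reads: dict[str, str], include_unmapped: bool = True) -> None:
    mapped = {a.read_id for a in alns}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_id}\tLN:{ref_len}\n")
        fh.write("@PG\tID:tylocus\tPN:tylocus\n")
        for a in alns:
            flag = 0
            if a.strand == "-":
                flag |= 16
            if a.category == "secondary":
                flag |= 256
            elif a.category == "supplementary":
                flag |= 2048
            seq = reads[a.read_id]
            if a.strand == "-":
                seq = util.revcomp(seq)
            rlen = len(seq)
            # clip in oriented coordinates
            if a.strand == "+":
                lc, rc = a.read_start, rlen - a.read_end
            else:
                lc, rc = rlen - a.read_end, a.read_start
            cigar = (f"{lc}S" if lc else "") + a.ops + (f"{rc}S" if rc else "")
            fh.write("\t".join([
                a.read_id, str(flag), ref_id, str(a.ref_start + 1),
                str(a.mapq), cigar, "*", "0", "0", seq, "*"]) + "\n")
        if include_unmapped:
            for rid, seq in reads.items():
                if rid not in mapped:
                    fh.write("\t".join([rid, "4", "*", "0", "0", "*", "*",
                                        "0", "0", seq, "*"]) + "\n")
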