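"""Quality control of local assemblies and strain de-duplication.

Two gates decide whether a strain's assembly advances:

* ``coverage_discrepancy`` — reads are remapped to the contig and two
  depth profiles compared: all alignments vs the primary/mapq>=30
  filtered set.  Windows where the filtered depth collapses, balloons
  relative to its own median (collapsed/expanded duplications), or where
  the all/filtered ratio blows up (mapping discordance) fail the check.
* ``collinearity_check`` — unique exact k-mer anchors between contig and
  reference must chain collinearly across both flanks of the locus.

The numeric thresholds are configuration, not dogma: the published
analysis made these calls by visual inspection of coverage tracks and
dot plots, so the defaults here are chosen to separate clean from
corrupted simulations by a wide margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from . import mapping, util


@dataclass
class QCReport:
    strain: str
    coverage_check: str  # pass | fail
    coverage_windows: list[tuple[int, int, str]] = field(default_factory=list)
    collinearity_check: str = "fail"
    chain_spans: list[tuple[int, int, int, int]] = field(default_factory=list)
    concordance: float | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def overall(self) -> str:
        return ("pass" if self.coverage_check == "pass"
                and self.collinearity_check == "pass" else "fail")

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "coverage_check": self.coverage_check,
            "collinearity_check": self.collinearity_check,
            "concordance": self.concordance,
            "overall": self.overall,
            "notes": self.notes,
        }


def _depth_profiles(reads, contig) -> tuple[np.ndarray, np.ndarray]:
    idx = mapping.index_reference(contig)
    all_depth = np.zeros(len(contig))
    filt_depth = np.zeros(len(contig))
    for rid, seq in reads:
        alns = mapping.map_read(rid, seq, idx, contig)
        for a in alns:
            all_depth[a.ref_start : a.ref_end] += 1
        for a in mapping.filter_alignments(alns):
            filt_depth[a.ref_start : a.ref_end] += 1
    return all_depth, filt_depth


def coverage_discrepancy(reads: list[tuple[str, str]], contig: str,
                         window: int = 200, r_low: float = 0.25,
                         r_high: float = 1.3, r_depth: float = 2.0
                         ) -> tuple[list[tuple[int, int, str]], str]:
    """Windowed comparison of unfiltered vs filtered depth profiles.

    Fails when any ``window``-sized stretch has no filtered coverage, a
    filtered depth below ``r_low`` x the unfiltered depth, an
    all/filtered ratio above ``r_high`` (the discrepancy signal left by
    collapsed or artifactual duplications, whose junction-spanning reads
    survive only as secondary/supplementary alignments), or filtered
    depth above ``r_depth`` x its own median.
    """
    if not contig:
        raise ValueError("empty contig")
    if not reads:
        return [(0, len(contig), "no coverage")], "fail"
    all_depth, filt_depth = _depth_profiles(reads, contig)
    if filt_depth.sum() == 0:
        return [(0, len(contig), "no coverage")], "fail"
    med = np.median(filt_depth[filt_depth > 0])
    bad: list[tuple[int, int, str]] = []
    # the low-support signal is judged against the unfiltered profile so
    # that natural coverage ramps at the contig ends (where both profiles
    # taper together) do not trigger it
    for s in range(window, max(window + 1, len(contig) - 2 * window), window):
        e = min(s + window, len(contig))
        f = filt_depth[s:e].mean()
        a = all_depth[s:e].mean()
        if f == 0:
            bad.append((s, e, "no filtered coverage"))
        elif f < r_low * a or a / f > r_high:
            bad.append((s, e, "all/filtered discrepancy"))
        elif f > r_depth * med:
            bad.append((s, e, "excess filtered depth"))
    return bad, ("fail" if bad else "pass")


def collinearity_check(contig: str, reference: str, flank_len: int = 1000,
                       k: int = 21, min_flank_cov: float = 0.80
                       ) -> tuple[list[tuple[int, int, int, int]], str]:
    """Unique exact k-mer anchor chain between contig and reference.

    The reference must be the locus plus >= ``flank_len`` flank on each
    side; the check passes iff the longest strand-consistent collinear
    chain covers >= ``min_flank_cov`` of each flank region.  The chain
    (ref_start, ref_end, contig_start, contig_end per anchor) doubles as
    dot-plot coordinates.
    """
    if len(contig) < k:
        return [], "fail"
    if len(reference) < 2 * flank_len:
        raise ValueError("reference must include both flanks")
    ref_pos = _unique_kmers(reference, k)
    best_chain: list[tuple[int, int]] = []
    for seq in (contig, util.revcomp(contig)):
        con_pos = _unique_kmers(seq, k)
        pairs = sorted((ref_pos[km], cp) for km, cp in con_pos.items()
                       if km in ref_pos)
        chain = _lis_chain(pairs)
        if len(chain) > len(best_chain):
            best_chain = chain
    if not best_chain:
        return [], "fail"
    spans = [(rp, rp + k, cp, cp + k) for rp, cp in best_chain]
    covered = np.zeros(len(reference), dtype=bool)
    for rp, cp in best_chain:
        covered[rp : rp + k] = True
    left_cov = covered[:flank_len].mean()
    right_cov = covered[-flank_len:].mean()
    ok = left_cov >= min_flank_cov and right_cov >= min_flank_cov
    return spans, ("pass" if ok else "fail")


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in seen:
            del seen[km]
            dup.add(km)
        else:
            seen[km] = i
    return seen


def _lis_chain(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain increasing in both coordinates (pairs sorted by ref).

    O(n log n) patience algorithm on the second coordinate.
    """
    import bisect

    if not pairs:
        return []
    tails: list[int] = []
    tail_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, c) in enumerate(pairs):
        j = bisect.bisect_left(tails, c)
        if j == len(tails):
            tails.append(c)
            tail_idx.append(i)
        else:
            tails[j] = c
            tail_idx[j] = i
        parent[i] = tail_idx[j - 1] if j > 0 else -1
    chain = []
    node = tail_idx[-1]
    while node != -1:
        chain.append(pairs[node])
        node = parent[node]
    return chain[::-1]


def assembler_concordance(contig_olc: str, contig_sdbg: str
                          ) -> tuple[float, bool]:
    """Global alignment identity between the two assemblers' contigs
    after orientation normalization; reported, not gating."""
    if not contig_olc or not contig_sdbg:
        raise ValueError("empty contig")
    best = -1
    for seq in (contig_sdbg, util.revcomp(contig_sdbg)):
        d = edlib.align(contig_olc, seq, mode="NW", task="distance")["editDistance"]
        if best < 0 or d < best:
            best = d
    aln_len = max(len(contig_olc), len(contig_sdbg))
    identity = 1.0 - best / aln_len
    return identity, identity >= 0.95


@dataclass
class StrainRecord:
    strain: str  # canonical strain name
    dataset: str
    qc: QCReport | None = None
    year: int = 0


def dedup_strains(records: list[StrainRecord]) -> list[StrainRecord]:
    """One record per canonical strain name: prefer QC pass, then the
    newer dataset, then lexicographically smaller dataset id (stable)."""
    by_name: dict[str, list[StrainRecord]] = {}
    for r in records:
        by_name.setdefault(r.strain, []).append(r)
    kept = []
    for name in sorted(by_name):
        group = by_name[name]
        group.sort(key=lambda r: (
            0 if r.qc is not None and r.qc.overall == "pass" else 1,
            -r.year, r.dataset))
        kept.append(group[0])
    return kept
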