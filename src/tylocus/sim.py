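"""Synthetic strain panels with known truth.

Everything downstream of raw data ingestion can be exercised without
downloads: this module builds a Ty consensus library, composes a
tRNA-bracketed locus haplotype carrying nested Ty insertions, evolves it
along a strain tree with structural events (deletion, new insertion,
subfamily gene conversion), and simulates noisy long reads.

The default library and blueprint emulate the structure of a relic
locus: a truncated Ty1-subfamily internal fragment whose GAG-homologous
ORF has been disrupted by an engineered 1 bp deletion upstream of an
internal start codon, leaving an intact downstream ORF — plus solo LTRs
of three families and two flanking tRNA genes in opposite orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import util
from .trees import Node, parse_newick

# ---------------------------------------------------------------------------
# Domain types


@dataclass
class TyLibraryEntry:
    name: str
    family: str
    subfamily: str
    ltr_seq: str
    internal_seq: str
    orf_interval: tuple[int, int]  # half-open, within internal_seq
    orf_internal_start: int | None = None  # offset of internal ATG (DRT-like)

    def __post_init__(self):
        if not self.ltr_seq or not self.internal_seq:
            raise ValueError(f"{self.name}: empty LTR or internal sequence")
        if set(self.ltr_seq + self.internal_seq) - set("ACGT"):
            raise ValueError(f"{self.name}: sequences must be over ACGT")
        s, e = self.orf_interval
        if (e - s) % 3:
            raise ValueError(f"{self.name}: ORF interval not divisible by 3")


@dataclass
class BlueprintFeature:
    kind: str  # flank | trna | solo_ltr | truncated_ty | full_ty
    entry: str | None = None  # library entry or tRNA name
    orient: str = "+"
    truncation: tuple[int, int] | None = None  # within internal_seq
    indels: list[tuple[int, int]] = field(default_factory=list)  # (offset, +/-len)
    length: int | None = None  # flank length override


@dataclass
class LocusBlueprint:
    features: list[BlueprintFeature]

    def validate(self, library: dict[str, TyLibraryEntry], trnas: dict[str, str]):
        trna_idx = [i for i, f in enumerate(self.features) if f.kind == "trna"]
        ty_idx = [i for i, f in enumerate(self.features)
                  if f.kind in ("solo_ltr", "truncated_ty", "full_ty")]
        if len(trna_idx) != 2:
            raise ValueError(f"blueprint must have exactly 2 tRNA features, got {len(trna_idx)}")
        for i in ty_idx:
            if not (trna_idx[0] < i < trna_idx[1]):
                raise ValueError(f"feature {i}: Ty features must lie between the tRNAs")
        for i, f in enumerate(self.features):
            if f.kind == "trna" and f.entry not in trnas:
                raise ValueError(f"feature {i}: unknown tRNA {f.entry}")
            if f.kind in ("solo_ltr", "truncated_ty", "full_ty"):
                if f.entry not in library:
                    raise ValueError(f"feature {i}: unknown library entry {f.entry}")
                if f.kind == "truncated_ty":
                    src = library[f.entry].internal_seq
                    t = f.truncation or (0, len(src))
                    if not (0 <= t[0] < t[1] <= len(src)):
                        raise ValueError(f"feature {i}: truncation {t} outside source")


@dataclass
class Feature:
    kind: str  # flank | trna | solo_ltr | truncated_ty | full_ty | orf
    start: int
    end: int
    strand: str
    name: str = ""
    family: str = ""
    subfamily: str = ""
    # provenance for structural events
    entry: str | None = None
    truncation: tuple[int, int] | None = None
    indels: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusTruth:
    features: list[Feature]
    orf: tuple[int, int] | None = None  # intact downstream ORF, half-open
    indels: list[tuple[int, int]] = field(default_factory=list)  # global coords
    seq_len: int = 0

    def feature_of_kind(self, kind: str) -> Feature | None:
        hits = [f for f in self.features if f.kind == kind]
        return hits[0] if hits else None

    def locus_interval(self) -> tuple[int, int]:
        """Outer limits of the two flanking tRNAs."""
        trnas = [f for f in self.features if f.kind == "trna"]
        if len(trnas) != 2:
            raise ValueError("truth does not contain exactly 2 tRNAs")
        return trnas[0].start, trnas[1].end

    def to_gff3(self, seqid: str) -> str:
        lines = ["##gff-version 3"]
        for f in self.features:
            attrs = f"ID={f.name or f.kind};kind={f.kind}"
            if f.family:
                attrs += f";family={f.family};subfamily={f.subfamily}"
            lines.append("\t".join([
                seqid, "tylocus_sim", f.kind, str(f.start + 1), str(f.end),
                ".", f.strand, ".", attrs]))
        if self.orf:
            lines.append("\t".join([
                seqid, "tylocus_sim", "ORF", str(self.orf[0] + 1),
                str(self.orf[1]), ".", "+", "0", "ID=orf"]))
        return "\n".join(lines) + "\n"


@dataclass
class ReadProfile:
    platform: str = "pacbio_clr"
    loglen_mean: float = 9.0  # log-space; exp(9) ~ 8.1 kb median
    loglen_sigma: float = 0.35
    min_len: int = 1000
    mismatch: float = 0.05
    insertion: float = 0.05
    deletion: float = 0.04

    def __post_init__(self):
        for r in (self.mismatch, self.insertion, self.deletion):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must lie in [0, 1)")
        if self.min_len <= 0:
            raise ValueError("min length must be positive")
        if self.platform == "perfect":
            self.mismatch = self.insertion = self.deletion = 0.0


def load_blueprint(path) -> LocusBlueprint:
    """Read a locus blueprint from YAML (a list of feature mappings)."""
    import yaml

    with open(path) as fh:
        items = yaml.safe_load(fh)
    feats = []
    for item in items:
        if "truncation" in item and item["truncation"] is not None:
            item["truncation"] = tuple(item["truncation"])
        if "indels" in item:
            item["indels"] = [tuple(x) for x in item["indels"]]
        feats.append(BlueprintFeature(**item))
    return LocusBlueprint(feats)


def load_profile(path) -> "ReadProfile":
    """Read a read profile from YAML."""
    import yaml

    with open(path) as fh:
        return ReadProfile(**(yaml.safe_load(fh) or {}))


def pacbio_clr_profile(**kw) -> ReadProfile:
    return ReadProfile(platform="pacbio_clr", mismatch=0.05, insertion=0.05,
                       deletion=0.04, **kw)


def ont_profile(**kw) -> ReadProfile:
    return ReadProfile(platform="ont", mismatch=0.04, insertion=0.03,
                       deletion=0.05, **kw)


def perfect_profile(**kw) -> ReadProfile:
    return ReadProfile(platform="perfect", **kw)


@dataclass
class StrainEvolutionModel:
    tree: str | Node  # rooted binary tree, branch lengths in subs/site
    events: dict[str, list[tuple]] = field(default_factory=dict)
    subst_model: str = "JC"  # or K2P
    kappa: float = 2.0
    seed: int = 0


# ---------------------------------------------------------------------------
# Library fixture


_TRNA_LEN = {"tRNA-Gly": 71, "tRNA-Ser": 82}


def default_trnas(seed: int = 101) -> dict[str, str]:
    """Fixed synthetic stand-ins for the two flanking tRNA genes."""
    rng = np.random.default_rng(seed)
    return {name: util.random_dna(rng, n) for name, n in _TRNA_LEN.items()}


def _random_orf(rng: np.random.Generator, ncodons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    from .molevol import SENSE_CODONS

    codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=ncodons - 2)]
    return "ATG" + "".join(codons) + "TAA"


def _mutate_preserving_orf(seq: str, orf: tuple[int, int], rate: float,
                           rng: np.random.Generator) -> str:
    codes = util.encode(seq).copy()
    mask = rng.random(len(codes)) < rate
    shift = rng.integers(1, 4, size=len(codes))
    mutated = (codes + shift) % 4
    new = np.where(mask, mutated, codes)
    out = _revert_orf_stops(new, codes, orf)
    return util.decode(out)


def _revert_orf_stops(new: np.ndarray, old: np.ndarray,
                      orf: tuple[int, int] | None) -> np.ndarray:
    """Revert substitutions that create in-frame stop codons in the ORF."""
    if orf is None:
        return new
    stops = {"TAA", "TAG", "TGA"}
    s, e = orf
    for _ in range(10):
        dirty = False
        for i in range(s, e - 3, 3):  # keep the terminal stop intact too
            codon = util.decode(new[i : i + 3])
            if codon in stops:
                new[i : i + 3] = old[i : i + 3]
                dirty = True
        # never mutate the terminal stop into a sense codon either
        new[e - 3 : e] = old[e - 3 : e]
        if not dirty:
            break
    return new


def default_library(seed: int = 202) -> list[TyLibraryEntry]:
    """Synthetic Ty consensus library: three Ty1 subfamilies ~5% diverged
    from one another, plus unrelated Ty2 and Ty3 entries.

    LTRs are ~300 bp, internals ~5 kb with a GAG-homologous ORF carrying
    an internal start codon (the domesticated-ORF anchor).
    """
    rng = np.random.default_rng(seed)
    gag_start, gag_codons = 501, 600  # ORF interval [501, 2304)
    internal_atg_codon = 428
    orf = _random_orf(rng, gag_codons)
    # plant the internal ATG at a codon boundary
    orf = (orf[: 3 * internal_atg_codon] + "ATG" + orf[3 * internal_atg_codon + 3 :])
    base_internal = (util.random_dna(rng, gag_start) + orf
                     + util.random_dna(rng, 5000 - gag_start - len(orf)))
    gag_iv = (gag_start, gag_start + 3 * gag_codons)
    base_ltr = util.random_dna(rng, 300)
    entries = []
    for sub in ("Ty1canonical", "Ty1prime", "Ty101"):
        if sub == "Ty1canonical":
            internal, ltr = base_internal, base_ltr
        else:
            internal = _mutate_preserving_orf(base_internal, gag_iv, 0.05, rng)
            ltr = _mutate_preserving_orf(base_ltr, None, 0.05, rng)
        entries.append(TyLibraryEntry(sub, "Ty1", sub, ltr, internal, gag_iv,
                                      orf_internal_start=gag_start + 3 * internal_atg_codon))
    for fam in ("Ty2", "Ty3"):
        internal = util.random_dna(rng, 4500)
        ltr = util.random_dna(rng, 330)
        entries.append(TyLibraryEntry(fam, fam, fam, ltr, internal, (0, 0)))
    return entries


def library_index(library: list[TyLibraryEntry]) -> dict[str, TyLibraryEntry]:
    return {e.name: e for e in library}


def relic_blueprint(truncation: tuple[int, int] = (1100, 3900),
                    deletion_offset: int = 300) -> LocusBlueprint:
    """Default relic-like blueprint: tRNA-bracketed nest of Ty fragments
    with a frame-disrupting 1 bp deletion upstream of the internal ORF.

    The truncation cuts into the GAG interior so that only a ~1.2 kb
    GAG-derived segment survives; the 1 bp deletion upstream of the
    internal start codon frameshifts the 5' remnant (creating premature
    stops) while leaving the downstream ORF intact."""
    return LocusBlueprint([
        BlueprintFeature("flank"),
        BlueprintFeature("trna", "tRNA-Gly", "+"),
        BlueprintFeature("solo_ltr", "Ty2", "+"),
        BlueprintFeature("truncated_ty", "Ty1prime", "+", truncation,
                         indels=[(deletion_offset, -1)]),
        BlueprintFeature("solo_ltr", "Ty1canonical", "+"),
        BlueprintFeature("solo_ltr", "Ty3", "-"),
        BlueprintFeature("trna", "tRNA-Ser", "-"),
        BlueprintFeature("flank"),
    ])


# ---------------------------------------------------------------------------
# Haplotype construction


def _apply_indels(seq: str, indels: list[tuple[int, int]],
                  rng: np.random.Generator) -> str:
    out = seq
    # apply right-to-left so offsets stay valid
    for off, ln in sorted(indels, reverse=True):
        if not (0 <= off <= len(out)):
            raise ValueError(f"indel offset {off} outside feature")
        if ln < 0:
            out = out[:off] + out[off - ln :]
        else:
            out = out[:off] + util.random_dna(rng, ln) + out[off:]
    return out


from .annotation import find_longest_orf  # noqa: E402 (truth ORF scanning)


def build_locus_haplotype(blueprint: LocusBlueprint,
                          library: list[TyLibraryEntry],
                          flank_len: int = 5000, seed: int = 0,
                          trnas: dict[str, str] | None = None
                          ) -> tuple[str, LocusTruth]:
    """Concatenate blueprint features into a haplotype with truth.

    Orientation '-' reverse-complements the feature sequence; engineered
    indels are applied to the feature before placement and recorded in
    global coordinates.  Deterministic for a fixed seed.
    """
    trnas = trnas or default_trnas()
    lib = library_index(library)
    blueprint.validate(lib, trnas)
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    feats: list[Feature] = []
    global_indels: list[tuple[int, int]] = []
    pos = 0
    orf_iv = None
    counters: dict[str, int] = {}
    for f in blueprint.features:
        if f.kind == "flank":
            seq = util.random_dna(rng, f.length or flank_len)
            fam = sub = ""
            name = "flank"
        elif f.kind == "trna":
            seq = trnas[f.entry]
            fam = sub = ""
            name = f.entry
        else:
            entry = lib[f.entry]
            fam, sub = entry.family, entry.subfamily
            if f.kind == "solo_ltr":
                seq = entry.ltr_seq
            elif f.kind == "truncated_ty":
                t = f.truncation or (0, len(entry.internal_seq))
                seq = entry.internal_seq[t[0] : t[1]]
            else:  # full_ty
                seq = entry.ltr_seq + entry.internal_seq + entry.ltr_seq
            name = f"{f.entry}_{f.kind}"
        if f.indels:
            seq = _apply_indels(seq, f.indels, rng)
            for off, ln in f.indels:
                global_indels.append((pos + off, ln))
        if f.orient == "-":
            seq = util.revcomp(seq)
        counters[name] = counters.get(name, 0) + 1
        uname = f"{name}.{counters[name]}" if counters[name] > 1 else name
        feat = Feature(f.kind, pos, pos + len(seq), f.orient, uname, fam, sub,
                       entry=f.entry, truncation=f.truncation,
                       indels=list(f.indels))
        feats.append(feat)
        if f.kind == "truncated_ty" and f.orient == "+":
            orf_local = find_longest_orf(seq)
            if orf_local:
                orf_iv = (pos + orf_local[0], pos + orf_local[1])
        parts.append(seq)
        pos += len(seq)
    seq = "".join(parts)
    return seq, LocusTruth(feats, orf_iv, global_indels, len(seq))


# ---------------------------------------------------------------------------
# Strain evolution


def _labelled_tree(tree: str | Node) -> Node:
    root = parse_newick(tree) if isinstance(tree, str) else tree.copy()
    k = 0
    for node in root.preorder():
        if not node.is_leaf and node.label is None:
            node.label = f"node{k}"
            k += 1
    return root


def _substitute(seq: str, t: float, orf: tuple[int, int] | None,
                model: str, kappa: float, rng: np.random.Generator) -> str:
    if t <= 0:
        return seq
    from .phylo import GTRModel

    rates = np.ones(6)
    if model == "K2P":
        rates[[1, 4]] = kappa  # AG, CT transitions
    gtr = GTRModel(rates, np.full(4, 0.25), alpha=None)
    P = gtr.transition_matrices(t)[0]
    codes = util.encode(seq).copy()
    old = codes.copy()
    cum = np.cumsum(P, axis=1)
    u = rng.random(len(codes))
    new = (cum[codes] > u[:, None]).argmax(axis=1).astype(np.uint8)
    new = _revert_orf_stops(new, old, orf)
    return util.decode(new)


def _shift_truth(truth: LocusTruth, at: int, delta: int) -> None:
    for f in truth.features:
        if f.start >= at:
            f.start += delta
        if f.end > at:
            f.end += delta
    if truth.orf and truth.orf[0] >= at:
        truth.orf = (truth.orf[0] + delta, truth.orf[1] + delta)
    truth.indels = [(p + delta if p >= at else p, ln) for p, ln in truth.indels]
    truth.seq_len += delta


def _apply_event(seq: str, truth: LocusTruth, event: tuple,
                 lib: dict[str, TyLibraryEntry],
                 rng: np.random.Generator) -> str:
    kind = event[0]
    if kind == "delete_locus_insertion":
        frag = truth.feature_of_kind("truncated_ty")
        if frag is None:
            raise ValueError("delete_locus_insertion: no truncated Ty present")
        s, e = frag.start, frag.end
        truth.features.remove(frag)
        _shift_truth(truth, e, -(e - s))
        truth.orf = None
        return seq[:s] + seq[e:]
    if kind == "insert_ty":
        _, entry_name, after_kind = event
        entry = lib[entry_name]
        anchor = truth.feature_of_kind(after_kind)
        if anchor is None:
            raise ValueError(f"insert_ty: no {after_kind} feature to anchor on")
        at = anchor.end
        ins = entry.ltr_seq
        _shift_truth(truth, at, len(ins))
        truth.features.append(
            Feature("solo_ltr", at, at + len(ins), "+",
                    f"{entry_name}_inserted", entry.family, entry.subfamily,
                    entry=entry_name))
        truth.features.sort(key=lambda f: f.start)
        return seq[:at] + ins + seq[at:]
    if kind == "gene_convert":
        _, subfamily = event
        frag = truth.feature_of_kind("truncated_ty")
        if frag is None:
            raise ValueError("gene_convert: locus insertion was deleted; "
                             "event inapplicable")
        donors = [e for e in lib.values() if e.subfamily == subfamily]
        if not donors:
            raise ValueError(f"gene_convert: unknown subfamily {subfamily}")
        donor = donors[0]
        t = frag.truncation or (0, len(donor.internal_seq))
        new_frag = donor.internal_seq[t[0] : t[1]]
        new_frag = _apply_indels(new_frag, frag.indels, rng)
        if frag.strand == "-":
            new_frag = util.revcomp(new_frag)
        if len(new_frag) != frag.length:
            raise ValueError("gene conversion donor length mismatch")
        frag.subfamily = donor.subfamily
        frag.entry = donor.name
        out = seq[: frag.start] + new_frag + seq[frag.end :]
        orf_local = find_longest_orf(new_frag)
        truth.orf = ((frag.start + orf_local[0], frag.start + orf_local[1])
                     if orf_local else None)
        return out
    raise ValueError(f"unknown event {kind}")


def _copy_truth(truth: LocusTruth) -> LocusTruth:
    return LocusTruth([replace(f, indels=list(f.indels)) for f in truth.features],
                      truth.orf, list(truth.indels), truth.seq_len)


def evolve_strains(root_seq: str, root_truth: LocusTruth,
                   model: StrainEvolutionModel,
                   library: list[TyLibraryEntry]
                   ) -> dict[str, tuple[str, LocusTruth]]:
    """Evolve the root haplotype along the strain tree.

    Point substitutions are drawn per branch under the configured
    substitution model (stop-creating substitutions inside the tracked
    ORF are rejected so the domesticated ORF stays translatable);
    structural events attached to a branch (keyed by its child node
    label) are applied after the substitutions of that branch and
    inherited by all descendants.
    """
    lib = library_index(library)
    tree = _labelled_tree(model.tree)
    out: dict[str, tuple[str, LocusTruth]] = {}
    bidx = [0]

    def walk(node: Node, seq: str, truth: LocusTruth):
        rng = np.random.default_rng([model.seed % (2**31), bidx[0]])
        bidx[0] += 1
        if node.length:
            seq = _substitute(seq, node.length, truth.orf,
                              model.subst_model, model.kappa, rng)
        for event in model.events.get(node.label or "", []):
            seq = _apply_event(seq, truth, event, lib, rng)
            truth.seq_len = len(seq)
        if node.is_leaf:
            out[node.label] = (seq, truth)
        for child in node.children:
            walk(child, seq, _copy_truth(truth))

    walk(tree, root_seq, _copy_truth(root_truth))
    return out


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(genome: str, profile: ReadProfile, coverage: float,
                   seed: int = 0, prefix: str = "read"
                   ) -> tuple[list[tuple[str, str]], list[tuple[str, int, int, str]]]:
    """Simulate long reads at the requested fold coverage.

    Returns ``(reads, placements)`` where each placement is
    ``(read_id, start, end, strand)`` on the input genome (0-based
    half-open).  Lengths are log-normal (clamped at ``min_len`` and the
    genome length); strands uniform; errors injected per profile.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(genome)
    target = coverage * L
    total = 0
    reads: list[tuple[str, str]] = []
    placements: list[tuple[str, int, int, str]] = []
    i = 0
    while total < target:
        rlen = int(rng.lognormal(profile.loglen_mean, profile.loglen_sigma))
        rlen = max(profile.min_len, min(rlen, L))
        start = int(rng.integers(0, L - rlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        truth = genome[start : start + rlen]
        if strand == "-":
            truth = util.revcomp(truth)
        seq = _corrupt(truth, profile, rng)
        rid = f"{prefix}{i:04d}"
        reads.append((rid, seq))
        placements.append((rid, start, start + rlen, strand))
        total += rlen
        i += 1
    return reads, placements


def _corrupt(seq: str, p: ReadProfile, rng: np.random.Generator) -> str:
    if p.platform == "perfect" or (p.mismatch == p.insertion == p.deletion == 0):
        return seq
    codes = util.encode(seq)
    n = len(codes)
    mism = rng.random(n) < p.mismatch
    shift = rng.integers(1, 4, size=n)
    codes = np.where(mism, (codes + shift) % 4, codes).astype(np.uint8)
    keep = rng.random(n) >= p.deletion
    ins = rng.random(n) < p.insertion
    reps = keep.astype(np.int64) + ins
    out = np.repeat(codes, reps)
    # positions that were duplicated by an insertion get a random base
    # in the second slot
    if ins.any():
        # last output slot of each inserting position holds the new base
        ins_slots = np.cumsum(reps)[np.nonzero(ins)[0]] - 1
        out[ins_slots] = rng.integers(0, 4, size=len(ins_slots)).astype(np.uint8)
    return util.decode(out)


# ---------------------------------------------------------------------------
# Codon alignment simulation (GY94)


def simulate_codon_alignment(tree: str | Node, omega: float, kappa: float,
                             ncodon: int, freqs: np.ndarray | None = None,
                             seed: int = 0):
    """Evolve codon sequences site-independently under GY94 along a tree.

    The root sequence is drawn from ``freqs`` (default: uniform over the
    61 sense codons); no internal stop codons can arise by construction.
    """
    from .molevol import SENSE_CODONS, GY94, CodonAlignment

    if omega <= 0 or kappa <= 0 or ncodon <= 0:
        raise ValueError("omega, kappa and ncodon must be positive")
    root = parse_newick(tree) if isinstance(tree, str) else tree
    for node in root.postorder():
        if node is not root and node.length is None:
            raise ValueError("tree must have branch lengths")
    pi = np.full(61, 1.0 / 61.0) if freqs is None else np.asarray(freqs, float)
    model = GY94(omega, kappa, pi)
    rng = np.random.default_rng(seed)
    root_states = rng.choice(61, size=ncodon, p=pi)
    taxa: list[str] = []
    seqs: list[str] = []

    def walk(node: Node, states: np.ndarray):
        if node is not root and node.length and node.length > 0:
            P = model.transition_matrix(node.length)
            cum = np.cumsum(P, axis=1)
            u = rng.random(len(states))
            states = (cum[states] > u[:, None]).argmax(axis=1)
        if node.is_leaf:
            taxa.append(node.label)
            seqs.append("".join(SENSE_CODONS[s] for s in states))
        for child in node.children:
            walk(child, states)

    walk(root, root_states)
    return CodonAlignment(taxa, seqs)


# ---------------------------------------------------------------------------
# Default 20-strain panel (the desk-scale study conditions)

# events sit on branches whose subtrees are separated by present strains,
# so the engineered event count is also the parsimony minimum
PANEL_NEWICK = (
    "((((s01:{b},s02:{b})og:{b},(s11:{b},s12:{b}):{b}):{b},"
    "(((s03:{b},s04:{b}):{b},s05:{b})cladeA:{b},"
    "(s13:{b},s14:{b}):{b}):{b}):{b},"
    "((((s08:{b},s09:{b})cladeC:{b},s15:{b}):{b},"
    "(s10:{b},(s16:{b},s17:{b}):{b}):{b}):{b},"
    "(((s06:{b},s07:{b})cladeB:{b},(s18:{b},s19:{b}):{b}):{b},"
    "s20:{b}):{b}):{b});"
)

PANEL_EVENTS: dict[str, list[tuple]] = {
    "cladeA": [("delete_locus_insertion",)],
    "cladeB": [("delete_locus_insertion",)],
    "cladeC": [("gene_convert", "Ty101")],
    "s10": [("gene_convert", "Ty101")],
}

PANEL_TRUTH_STATUS = {
    **{s: "present" for s in
       ("s01 s02 s11 s12 s13 s14 s15 s16 s17 s18 s19 s20".split())},
    **{s: "absent" for s in ("s03", "s04", "s05", "s06", "s07")},
    **{s: "converted" for s in ("s08", "s09", "s10")},
}


def panel_tree(branch: float = 0.004) -> str:
    """The default 20-strain tree: 12 present / 5 absent / 3 converted,
    with all structural events on distinct branches."""
    return PANEL_NEWICK.format(b=branch)


def build_panel(seed: int = 0, branch: float = 0.004, flank_len: int = 5000,
                library: list[TyLibraryEntry] | None = None
                ) -> tuple[dict[str, tuple[str, LocusTruth]], list[TyLibraryEntry], str]:
    """Build the default simulated strain panel.

    Returns ``(strains, library, tree_newick)`` where strains maps strain
    name to (genome segment, truth).
    """
    library = library or default_library()
    bp = relic_blueprint()
    root_seq, root_truth = build_locus_haplotype(bp, library, flank_len=flank_len,
                                                 seed=seed)
    nwk = panel_tree(branch)
    model = StrainEvolutionModel(nwk, dict(PANEL_EVENTS), seed=seed)
    strains = evolve_strains(root_seq, root_truth, model, library)
    return strains, library, nwk
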