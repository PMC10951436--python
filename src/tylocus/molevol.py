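"""Codon-level selection analysis: GY94/M0 model, NG86 counting,
protein-guided codon alignment.

The M0 model assigns every site the same nonsynonymous/synonymous rate
ratio omega and transition/transversion ratio kappa, with instantaneous
rates between codons differing at one position:

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]

(zero for multi-position changes), diagonal set so rows sum to zero, and
Q scaled so the expected rate at stationarity is one substitution per
codon per unit branch length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .trees import Node
from .phylo import progressive_msa

# --- genetic code ----------------------------------------------------------

_BASES = "TCAG"
_CODONS_ALL = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [c for c in _CODONS_ALL if c not in _STOPS]
_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}

_CODE = {}
_AA_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
_CODE.update(_AA_TABLE)


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in _STOPS:
            out.append("*")
        else:
            out.append(_CODE.get(codon, "X"))
    return "".join(out)


def _is_transition(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def _neighbour_table():
    """(i, j, is_transition, is_synonymous) for codon pairs 1 nt apart."""
    rows = []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            a, b = diffs[0]
            rows.append((i, j, _is_transition(a, b), _CODE[ci] == _CODE[cj]))
    return rows

_NEIGHBOURS = _neighbour_table()


# --- GY94 rate matrix ------------------------------------------------------


class GY94:
    """GY94 (M0) rate matrix with spectral decomposition for fast P(t)."""

    def __init__(self, omega: float, kappa: float, pi: np.ndarray):
        if omega <= 0 or kappa <= 0:
            raise ValueError("omega and kappa must be positive")
        pi = np.asarray(pi, dtype=float)
        if pi.shape != (61,) or abs(pi.sum() - 1) > 1e-8 or np.any(pi < 0):
            raise ValueError("pi must be a 61-codon distribution")
        self.omega, self.kappa, self.pi = omega, kappa, pi
        Q = np.zeros((61, 61))
        for i, j, ts, syn in _NEIGHBOURS:
            Q[i, j] = pi[j] * (kappa if ts else 1.0) * (1.0 if syn else omega)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        Q /= scale
        self.q = Q
        # fraction of the (unit) total rate that is synonymous
        syn_rate = sum(pi[i] * Q[i, j] for i, j, _, syn in _NEIGHBOURS if syn)
        self.rho_s = float(syn_rate)
        d = np.sqrt(np.clip(pi, 1e-300, None))
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        self._w, U = np.linalg.eigh(B)
        self._left = U / d[None, :].T  # d^-1 U
        self._right = U.T * d[None, :]  # U^T d

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def f3x4_frequencies(codon_rows: list[list[str]]) -> np.ndarray:
    """F3x4 codon frequencies from observed codons (gaps ignored)."""
    counts = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate("TCAG")}
    for row in codon_rows:
        for codon in row:
            if len(codon) == 3 and all(b in base_idx for b in codon):
                for p, b in enumerate(codon):
                    counts[p, base_idx[b]] += 1
    counts = np.clip(counts, 1e-6, None)
    pos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([pos[0, base_idx[c[0]]] * pos[1, base_idx[c[1]]] * pos[2, base_idx[c[2]]]
                   for c in SENSE_CODONS])
    pi = np.clip(pi, 1e-10, None)
    return pi / pi.sum()


# --- codon alignment -------------------------------------------------------


@dataclass
class CodonAlignment:
    taxa: list[str]
    seqs: list[str]  # aligned nucleotide sequences, gaps in codon runs
    trim: dict | None = None

    def __post_init__(self):
        L = {len(s) for s in self.seqs}
        if len(L) > 1 or (L and next(iter(L)) % 3):
            raise ValueError("aligned length must be equal and divisible by 3")

    @property
    def ncodons(self) -> int:
        return len(self.seqs[0]) // 3 if self.seqs else 0

    def codon_rows(self) -> list[list[str]]:
        return [[s[i : i + 3] for i in range(0, len(s), 3)] for s in self.seqs]


def codon_align(cds_seqs: list[tuple[str, str]]) -> CodonAlignment:
    """Codon-aware multiple alignment by protein-guided threading.

    Sequences are translated, the proteins aligned progressively, and the
    codons threaded back under each amino acid so gaps stay codon-sized.
    """
    prots = []
    for name, seq in cds_seqs:
        if len(seq) % 3:
            raise ValueError(f"{name}: length {len(seq)} not divisible by 3")
        p = translate(seq)
        stop = p[:-1].find("*")
        if stop >= 0:
            raise ValueError(f"{name}: internal stop codon at codon {stop}")
        prots.append((name, p.rstrip("*")))
    aligned = progressive_msa(prots, alphabet="protein")
    cds = dict(cds_seqs)
    rows = []
    for name, prow in aligned:
        codons = []
        k = 0
        for aa in prow:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(cds[name][3 * k : 3 * k + 3])
                k += 1
        # carry a trailing stop codon if present and ungapped everywhere later
        rows.append((name, "".join(codons)))
    return CodonAlignment([n for n, _ in rows], [s for _, s in rows])


def trim_at_indel(aln: CodonAlignment, reference_taxon: str,
                  indel_position: int) -> CodonAlignment:
    """Drop codon columns at/after ``indel_position`` (codon index).

    Mirrors trimming an alignment at a reference strain's terminal indel
    so a downstream frame-disrupting event does not enter the codon model.
    """
    if indel_position < 0:
        raise ValueError("indel position out of range")
    if reference_taxon not in aln.taxa:
        raise ValueError(f"unknown reference taxon {reference_taxon}")
    if indel_position >= aln.ncodons:
        return CodonAlignment(list(aln.taxa), list(aln.seqs),
                              {"reference": reference_taxon,
                               "position": indel_position, "noop": True})
    cut = 3 * indel_position
    return CodonAlignment(list(aln.taxa), [s[:cut] for s in aln.seqs],
                          {"reference": reference_taxon,
                           "position": indel_position, "noop": False})


# --- NG86 ------------------------------------------------------------------


def _codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon (NG86)."""
    syn = 0.0
    valid = 0
    for p in range(3):
        for b in "TCAG":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut in _STOPS:
                continue
            valid += 1
            if _CODE[mut] == _CODE[codon]:
                syn += 1.0
    # each position offers 3 changes; scale to 3 sites total
    if valid == 0:
        return 0.0, 3.0
    s = 3.0 * syn / valid
    return s, 3.0 - s


def _pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences over minimal mutation
    pathways between two codons, skipping pathways through stops."""
    from itertools import permutations

    pos = [p for p in range(3) if c1[p] != c2[p]]
    if not pos:
        return 0.0, 0.0
    tot_s = tot_n = 0.0
    npaths = 0
    for order in permutations(pos):
        cur = c1
        s = n = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODE[cur] == _CODE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            tot_s += s
            tot_n += n
            npaths += 1
    if npaths == 0:  # all pathways hit stops; count direct changes as nonsyn
        return 0.0, float(len(pos))
    return tot_s / npaths, tot_n / npaths


@dataclass
class NGResult:
    dn: float
    ds: float
    ratio: float | None
    undefined: bool = False


def nei_gojobori(aln: CodonAlignment) -> NGResult:
    """NG86 dN/dS averaged over all sequence pairs (JC-corrected)."""
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    rows = aln.codon_rows()
    dns, dss = [], []
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            S = N = Sd = Nd = 0.0
            for c1, c2 in zip(rows[i], rows[j]):
                if "-" in c1 or "-" in c2 or c1 in _STOPS or c2 in _STOPS:
                    continue
                s1, n1 = _codon_sites(c1)
                s2, n2 = _codon_sites(c2)
                S += (s1 + s2) / 2
                N += (n1 + n2) / 2
                sd, nd = _pair_diffs(c1, c2)
                Sd += sd
                Nd += nd
            ps = Sd / S if S > 0 else 0.0
            pn = Nd / N if N > 0 else 0.0
            dss.append(_jc_correct(ps))
            dns.append(_jc_correct(pn))
    dn, ds = float(np.mean(dns)), float(np.mean(dss))
    if ds <= 0:
        return NGResult(dn, ds, None, undefined=True)
    return NGResult(dn, ds, dn / ds)


def _jc_correct(p: float) -> float:
    # saturated proportions (p >= 3/4) fall back to the raw proportion:
    # the correction is undefined there and tiny alignments can reach it
    if p >= 0.75:
        return p
    return -0.75 * float(np.log(1.0 - 4.0 * p / 3.0))


# --- M0 likelihood and fitting --------------------------------------------


class _M0Engine:
    """Pattern-compressed pruning engine on a fixed rooted topology."""

    def __init__(self, aln: CodonAlignment, tree: Node):
        rows = {t: r for t, r in zip(aln.taxa, aln.codon_rows())}
        leaves = tree.leaf_labels()
        missing = set(leaves) - set(aln.taxa)
        if missing:
            raise ValueError(f"tree taxa missing from alignment: {sorted(missing)}")
        mat = np.array(
            [[_CODON_IDX.get(c, -1) for c in rows[t]] for t in leaves],
            dtype=np.int16,
        )
        pats, counts = np.unique(mat, axis=1, return_counts=True)
        self.pats, self.counts = pats, counts.astype(float)
        self.leaves = leaves
        # flatten tree: nodes in postorder, parent pointers
        self.nodes = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.parent = np.full(len(self.nodes), -1)
        for n in self.nodes:
            for c in n.children:
                self.parent[self.index[id(c)]] = self.index[id(n)]
        self.children = [[self.index[id(c)] for c in n.children] for n in self.nodes]
        self.leaf_row = {}
        for li, label in enumerate(leaves):
            for i, n in enumerate(self.nodes):
                if n.is_leaf and n.label == label:
                    self.leaf_row[i] = li
        self.blens = np.array(
            [max(n.length if n.length is not None else 0.05, 1e-9)
             for n in self.nodes], dtype=float
        )
        self.root = len(self.nodes) - 1
        self.npat = pats.shape[1]

    def _leaf_partial(self, node_i: int) -> np.ndarray:
        row = self.pats[self.leaf_row[node_i]]
        part = np.zeros((61, self.npat))
        obs = row >= 0
        part[:, ~obs] = 1.0
        part[row[obs], np.where(obs)[0]] = 1.0
        return part

    def down_partials(self, model: GY94) -> list[np.ndarray]:
        down = [None] * len(self.nodes)
        for i, n in enumerate(self.nodes):
            if n.is_leaf:
                down[i] = self._leaf_partial(i)
            else:
                part = np.ones((61, self.npat))
                for ci in self.children[i]:
                    P = model.transition_matrix(self.blens[ci])
                    part = part * (P @ down[ci])
                down[i] = part
        return down

    def loglik(self, model: GY94, down=None) -> float:
        if down is None:
            down = self.down_partials(model)
        site = model.pi @ down[self.root]
        if np.any(site <= 0):
            raise ValueError("non-finite log-likelihood")
        return float(np.dot(self.counts, np.log(site)))

    def contexts(self, model: GY94, down) -> list[np.ndarray]:
        """Outside partial for each non-root node: context C[v] such that
        L = sum_ij C[v][i] P(t_v)_ij down[v][j] summed per site."""
        ctx = [None] * len(self.nodes)
        above = [None] * len(self.nodes)
        above[self.root] = np.tile(model.pi[:, None], (1, self.npat))
        for i in reversed(range(len(self.nodes))):  # preorder (root last in postorder)
            if above[i] is None:
                continue
            msgs = {}
            for ci in self.children[i]:
                P = model.transition_matrix(self.blens[ci])
                msgs[ci] = P @ down[ci]
            for ci in self.children[i]:
                c = above[i].copy()
                for cj in self.children[i]:
                    if cj != ci:
                        c = c * msgs[cj]
                ctx[ci] = c
                P = model.transition_matrix(self.blens[ci])
                above[ci] = P.T @ c
        return ctx

    def optimize_branches(self, model: GY94) -> float:
        best = None
        for i in range(len(self.nodes)):
            if i == self.root:
                continue
            down = self.down_partials(model)
            ctx = self.contexts(model, down)
            C, Dn = ctx[i], down[i]

            def f(t):
                P = model.transition_matrix(t)
                site = np.einsum("ip,ij,jp->p", C, P, Dn)
                if np.any(site <= 0):
                    return 1e30
                return -float(np.dot(self.counts, np.log(site)))

            res = minimize_scalar(f, bounds=(1e-8, 20.0), method="bounded",
                                  options={"xatol": 1e-7})
            if -res.fun > -f(self.blens[i]):
                self.blens[i] = float(res.x)
            best = -f(self.blens[i])
        return best if best is not None else self.loglik(model)

    def write_back(self):
        for i, n in enumerate(self.nodes):
            if i != self.root:
                n.length = float(self.blens[i])


@dataclass
class M0Fit:
    omega: float
    kappa: float
    pi: np.ndarray
    tree: Node
    logl: float
    dn: float
    ds: float
    converged: bool
    iterations: int = 0
    history: list = field(default_factory=list)


def gy94_loglik(aln: CodonAlignment, tree: Node, omega: float, kappa: float,
                pi: np.ndarray) -> float:
    """Pruning log-likelihood of a codon alignment under GY94/M0.

    Gap codons are treated as missing data.  Branch lengths are read from
    the tree (expected substitutions per codon).
    """
    engine = _M0Engine(aln, tree)
    return engine.loglik(GY94(omega, kappa, pi))


def fit_m0(aln: CodonAlignment, tree_topology: Node | None = None,
           freq_model: str = "F3x4", tol: float = 1e-6,
           max_iter: int = 200) -> M0Fit:
    """Fit the M0 model: joint omega, kappa and branch-length estimation
    by coordinate ascent with golden-section/Brent line searches.

    ``dN`` and ``dS`` are derived from the fitted rate matrix: with tree
    length ``T`` (substitutions/codon) and synonymous rate fraction
    ``rho_s``, ``dS = T * rho_s / (3 * f_s)`` where ``f_s`` is the
    synonymous site fraction of the neutral (omega=1) matrix, and
    analogously for ``dN``.
    """
    if len(aln.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    if len({s for s in aln.seqs}) == 1:
        raise ValueError("alignment has no variation; omega unidentifiable")
    if freq_model == "F3x4":
        pi = f3x4_frequencies(aln.codon_rows())
    elif freq_model == "F1x4":
        rows = [[c for c in row] for row in aln.codon_rows()]
        counts = np.zeros(4)
        bidx = {b: i for i, b in enumerate("TCAG")}
        for row in rows:
            for codon in row:
                for b in codon:
                    if b in bidx:
                        counts[bidx[b]] += 1
        f = counts / counts.sum()
        pi = np.array([f[bidx[c[0]]] * f[bidx[c[1]]] * f[bidx[c[2]]]
                       for c in SENSE_CODONS])
        pi /= pi.sum()
    else:
        pi = np.full(61, 1.0 / 61.0)
    if tree_topology is None:
        tree_topology = _nj_start_tree(aln)
    tree = tree_topology.copy()
    engine = _M0Engine(aln, tree)
    omega, kappa = 0.5, 2.0
    cur = engine.loglik(GY94(omega, kappa, pi))
    history = [cur]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cur = engine.optimize_branches(GY94(omega, kappa, pi))

        def f_omega(w):
            try:
                return -engine.loglik(GY94(w, kappa, pi))
            except ValueError:
                return 1e30

        res = minimize_scalar(f_omega, bounds=(1e-4, 50.0), method="bounded",
                              options={"xatol": 1e-6})
        if -res.fun >= cur:
            omega, cur = float(res.x), -res.fun

        def f_kappa(k):
            try:
                return -engine.loglik(GY94(omega, k, pi))
            except ValueError:
                return 1e30

        res = minimize_scalar(f_kappa, bounds=(1e-3, 100.0), method="bounded",
                              options={"xatol": 1e-6})
        if -res.fun >= cur:
            kappa, cur = float(res.x), -res.fun
        history.append(cur)
        if len(history) > 2 and abs(history[-1] - history[-2]) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"M0 optimizer did not converge after {max_iter} iterations; "
            f"logL trace tail: {history[-5:]}")
    engine.write_back()
    model = GY94(omega, kappa, pi)
    neutral = GY94(1.0, kappa, pi)
    T = float(engine.blens[np.arange(len(engine.nodes)) != engine.root].sum())
    f_s = neutral.rho_s
    ds = T * model.rho_s / (3.0 * f_s)
    dn = T * (1.0 - model.rho_s) / (3.0 * (1.0 - f_s))
    return M0Fit(omega, kappa, pi, tree, cur, dn, ds, converged, it, history)


def _nj_start_tree(aln: CodonAlignment) -> Node:
    from .phylo import DistanceMatrix, bionj, distances

    msa = list(zip(aln.taxa, aln.seqs))
    if len(aln.taxa) == 2:
        return Node(children=[Node(aln.taxa[0], 0.05), Node(aln.taxa[1], 0.05)])
    if len(aln.taxa) == 3:
        dm = distances(msa, model="p")
        t = bionj(dm)
        return t
    try:
        return bionj(distances(msa, model="JC"))
    except ValueError:
        return bionj(distances(msa, model="p"))
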