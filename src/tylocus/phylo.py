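"""Distance and likelihood phylogenetics for the locus pipeline.

Provides a progressive multiple aligner, p/JC distances with complete
deletion of gapped columns, BioNJ tree building, nonparametric bootstrap,
and a GTR+Gamma maximum-likelihood tree search (BioNJ start, NNI
hill-climbing).  The ML search deliberately trades the exhaustive
heuristics of dedicated tools for a small, testable implementation:
on well-separated data the topology is identifiable and that is the
contract the pipeline relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import Node, is_monophyletic, root_by_clade  # noqa: F401 (re-export)

MSA = list[tuple[str, str]]

_DNA = "ACGT"
_AA = "ARNDCQEGHILKMFPSTWYV"


# ---------------------------------------------------------------------------
# Progressive multiple alignment


def _score_matrix(alphabet: str) -> tuple[str, np.ndarray, float, float]:
    if alphabet == "dna":
        letters = _DNA
        S = np.full((4, 4), -2.0)
        np.fill_diagonal(S, 2.0)
        return letters, S, 6.0, 1.0
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    letters = _AA
    S = np.zeros((20, 20))
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            S[i, j] = blosum[a][b]
    return letters, S, 11.0, 1.0


def _profile(rows: list[str], letters: str) -> np.ndarray:
    """Column frequency profile over letters + gap (last column)."""
    A = len(letters)
    idx = {c: i for i, c in enumerate(letters)}
    L = len(rows[0])
    prof = np.zeros((L, A + 1))
    for row in rows:
        for j, c in enumerate(row):
            prof[j, idx.get(c, A)] += 1  # unknowns counted as gaps
    return prof / len(rows)


def _align_profiles(pa: np.ndarray, pb: np.ndarray, S: np.ndarray,
                    gap_open: float, gap_ext: float) -> tuple[list[int], list[int]]:
    """Affine-gap global profile-profile alignment.

    Returns two aligned index lists over columns of ``pa``/``pb`` with -1
    marking gap columns.
    """
    A = S.shape[0]
    fa, fb = pa[:, :A], pb[:, :A]
    sub = fa @ S @ fb.T  # (la, lb) expected substitution scores
    la, lb = sub.shape
    NEG = -1e30
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (A column unmatched)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A
    M[0, 0] = 0.0
    X[1:, 0] = -gap_open - gap_ext * np.arange(la)
    Y[0, 1:] = -gap_open - gap_ext * np.arange(lb)
    for i in range(1, la + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        M[i, 1:] = np.maximum(np.maximum(prevM[:-1], prevX[:-1]), prevY[:-1]) + sub[i - 1]
        X[i] = np.maximum(prevM - gap_open, prevX - gap_ext)
        # Y within-row recurrence via running max trick
        base = np.maximum(M[i], X[i]) - gap_open
        j_idx = np.arange(lb + 1)
        run = np.maximum.accumulate(base[:-1] + gap_ext * j_idx[:-1])
        Y[i, 1:] = run - gap_ext * j_idx[1:]
    # traceback
    out_a: list[int] = []
    out_b: list[int] = []
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(i - 1)
            out_b.append(j - 1)
            prev = np.array([M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            out_a.append(i - 1)
            out_b.append(-1)
            # did X come from M (open) or X (extend)?
            state = 0 if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_ext else 1
            i -= 1
        elif state == 2 and j > 0:
            out_a.append(-1)
            out_b.append(j - 1)
            cand = [M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                    Y[i, j - 1] - gap_ext]
            state = int(np.argmax(cand))
            j -= 1
        else:  # boundary
            if i > 0:
                out_a.append(i - 1)
                out_b.append(-1)
                i -= 1
            else:
                out_a.append(-1)
                out_b.append(j - 1)
                j -= 1
    return out_a[::-1], out_b[::-1]


def _kmer_distance(a: str, b: str, k: int) -> float:
    sa = {a[i : i + k] for i in range(max(0, len(a) - k + 1))}
    sb = {b[i : i + k] for i in range(max(0, len(b) - k + 1))}
    if not sa or not sb:
        return 1.0
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def progressive_msa(seqs: MSA, alphabet: str = "dna") -> MSA:
    """Progressive profile-profile alignment with affine gaps.

    Guide order comes from shared-k-mer distances (UPGMA agglomeration).
    All input residues are preserved in the output columns.
    """
    if not seqs:
        raise ValueError("no sequences")
    names = [n for n, _ in seqs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sequence ids")
    if len(seqs) == 1:
        return list(seqs)
    letters, S, go, ge = _score_matrix(alphabet)
    k = 8 if alphabet == "dna" else 3
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = _kmer_distance(seqs[i][1], seqs[j][1], k)
    # UPGMA merge order
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    aligned: dict[int, list[tuple[str, str]]] = {i: [seqs[i]] for i in range(n)}
    nxt = n
    while len(clusters) > 1:
        (i, j) = min(dist, key=lambda p: (dist[p], p))
        rows_a = aligned.pop(i)
        rows_b = aligned.pop(j)
        pa = _profile([r[1] for r in rows_a], letters)
        pb = _profile([r[1] for r in rows_b], letters)
        ia, ib = _align_profiles(pa, pb, S, go, ge)
        merged = []
        for name, row in rows_a:
            merged.append((name, "".join(row[x] if x >= 0 else "-" for x in ia)))
        for name, row in rows_b:
            merged.append((name, "".join(row[x] if x >= 0 else "-" for x in ib)))
        aligned[nxt] = merged
        members = clusters.pop(i) + clusters.pop(j)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        for other, mem in clusters.items():
            d = np.mean([D[a, b] for a in members for b in mem])
            dist[(min(other, nxt), max(other, nxt))] = d
        clusters[nxt] = members
        nxt += 1
    rows = next(iter(aligned.values()))
    order = {name: idx for idx, name in enumerate(names)}
    rows.sort(key=lambda r: order[r[0]])
    return rows


# ---------------------------------------------------------------------------
# Distances


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.matrix = m


def distances(msa: MSA, model: str = "p",
              gap_policy: str = "complete_deletion") -> DistanceMatrix:
    """Pairwise p or Jukes-Cantor distances.

    ``complete_deletion`` removes every column containing a gap (or any
    non-ACGT symbol) in any row before counting, matching the -nogaps
    convention of distance tree programs.
    """
    if len(msa) < 2:
        raise ValueError("need >= 2 sequences")
    labels = [n for n, _ in msa]
    arr = np.array([list(s.upper()) for _, s in msa])
    if gap_policy == "complete_deletion":
        keep = np.all(np.isin(arr, list(_DNA)), axis=0)
        arr = arr[:, keep]
    if arr.shape[1] == 0:
        raise ValueError("no columns left after gap deletion")
    n = len(msa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = float(np.mean(arr[i] != arr[j]))
            if model == "JC":
                if p >= 0.75:
                    raise ValueError(f"saturated JC distance between {labels[i]} and {labels[j]}")
                d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D, model)


# ---------------------------------------------------------------------------
# BioNJ


def bionj(dm: DistanceMatrix) -> Node:
    """BioNJ agglomeration (variance-weighted NJ branch estimates).

    Returns an unrooted tree represented with a trifurcating root.  On an
    exactly additive matrix this reconstructs the generating topology with
    exact branch lengths.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = dm.matrix.copy()
    V = dm.matrix.copy()
    nodes = [Node(label) for label in dm.labels]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        R = sub.sum(axis=1)
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                q = (m - 2) * sub[ai, aj] - R[ai] - R[aj]
                if best is None or q < best[0] - 1e-12:
                    best = (q, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = D[i, j]
        liu = 0.5 * dij + (R[ai] - R[aj]) / (2.0 * (m - 2))
        lju = dij - liu
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length = max(liu, 0.0)
        nodes[j].length = max(lju, 0.0)
        others = [a for a in active if a not in (i, j)]
        vij = V[i, j]
        if vij > 1e-12:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2.0 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        newD = np.zeros(len(others))
        newV = np.zeros(len(others))
        for idx, k in enumerate(others):
            newD[idx] = lam * (D[i, k] - liu) + (1 - lam) * (D[j, k] - lju)
            newV[idx] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
        # reuse slot i for u
        nodes[i] = u
        for idx, k in enumerate(others):
            D[i, k] = D[k, i] = newD[idx]
            V[i, k] = V[k, i] = newV[idx]
        active.remove(j)
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return Node(children=[nodes[a], nodes[b], nodes[c]])


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(msa: MSA, tree_builder, replicates: int = 100,
                      seed: int = 0) -> Node:
    """Annotate the point-estimate tree with bootstrap supports.

    Alignment columns are resampled with replacement; support for each
    internal edge of the point tree is the number of replicates whose tree
    contains the same bipartition.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    from .trees import bipartitions

    point = tree_builder(msa)
    target: dict[frozenset, int] = {bp: 0 for bp in bipartitions(point)}
    rng = np.random.default_rng(seed)
    L = len(msa[0][1])
    names = [n for n, _ in msa]
    rows = [s for _, s in msa]
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        rep = [(names[i], "".join(rows[i][c] for c in cols)) for i in range(len(msa))]
        try:
            rep_tree = tree_builder(rep)
        except ValueError:
            continue  # e.g. saturated distances in a pathological resample
        for bp in bipartitions(rep_tree):
            if bp in target:
                target[bp] += 1
    all_leaves = frozenset(point.leaf_labels())
    for node in point.postorder():
        if node is point or node.is_leaf:
            continue
        side = frozenset(node.leaf_labels())
        key = min(side, all_leaves - side, key=lambda s: (len(s), sorted(s)))
        if key in target:
            node.support = target[key]
    return point


# ---------------------------------------------------------------------------
# GTR + Gamma likelihood


@dataclass
class GTRModel:
    """GTR substitution model with optional discrete-Gamma rate variation.

    ``rates`` are the six symmetric exchangeabilities in the order
    AC, AG, AT, CG, CT, GT (GT conventionally fixed to 1);
    ``freqs`` the stationary base frequencies (A, C, G, T);
    ``alpha`` the Gamma shape (None = rate homogeneity); ``ncat``
    the number of mean-discretized rate categories.
    """

    rates: np.ndarray
    freqs: np.ndarray
    alpha: float | None = 4.0
    ncat: int = 4

    def q_matrix(self) -> np.ndarray:
        r = self.rates
        pi = self.freqs
        S = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), rate in zip(idx, r):
            S[i, j] = S[j, i] = rate
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.dot(pi, np.diag(Q))
        return Q / scale

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        a, K = self.alpha, self.ncat
        bounds = gamma_dist.ppf(np.arange(1, K) / K, a, scale=1.0 / a)
        edges = np.concatenate([[0.0], bounds, [np.inf]])
        upper = gammainc(a + 1, edges[1:] * a)
        lower = gammainc(a + 1, edges[:-1] * a)
        return K * (upper - lower)

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(t * r_c) for each rate category, via spectral decomposition."""
        Q = self.q_matrix()
        pi = self.freqs
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        B = 0.5 * (B + B.T)
        w, U = np.linalg.eigh(B)
        cats = self.category_rates()
        out = np.empty((len(cats), 4, 4))
        for c, r in enumerate(cats):
            expw = np.exp(w * t * r)
            P = (U * expw) @ U.T
            P = P / d[:, None] * d[None, :]
            out[c] = np.clip(P, 0.0, None)
            out[c] /= out[c].sum(axis=1, keepdims=True)
        return out


def default_gtr(msa: MSA, alpha: float | None = 1.0) -> GTRModel:
    arr = np.array([list(s.upper()) for _, s in msa])
    freqs = np.array([(arr == b).sum() for b in _DNA], dtype=float)
    freqs = freqs / freqs.sum() if freqs.sum() else np.full(4, 0.25)
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum()
    return GTRModel(np.ones(6), freqs, alpha)


def _patterns(msa: MSA) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = [n for n, _ in msa]
    code = {c: i for i, c in enumerate(_DNA)}
    arr = np.array([[code.get(c, 4) for c in s.upper()] for _, s in msa], dtype=np.int8)
    pats, counts = np.unique(arr, axis=1, return_counts=True)
    return pats, counts.astype(float), names


def loglik(tree: Node, msa: MSA, model: GTRModel) -> float:
    """Felsenstein pruning log-likelihood under GTR(+Gamma)."""
    pats, counts, names = _patterns(msa)
    name_to_row = {n: i for i, n in enumerate(names)}
    ncat = len(model.category_rates())
    npat = pats.shape[1]
    site_lik = np.zeros((ncat, npat))
    log_scale = np.zeros(npat)

    def prune(node: Node) -> np.ndarray:
        nonlocal log_scale
        if node.is_leaf:
            row = pats[name_to_row[node.label]]
            part = np.zeros((ncat, 4, npat))
            obs = row < 4
            part[:, :, ~obs] = 1.0
            part[:, row[obs], np.where(obs)[0]] = 1.0
            return part
        part = np.ones((ncat, 4, npat))
        for child in node.children:
            cpart = prune(child)
            P = model.transition_matrices(max(child.length or 0.0, 0.0))
            part *= np.einsum("cij,cjp->cip", P, cpart)
        mx = part.max(axis=(0, 1))
        mx = np.where(mx > 0, mx, 1.0)
        part /= mx[None, None, :]
        log_scale += np.log(mx)
        return part

    root_part = prune(tree)
    site = np.einsum("i,cip->cp", model.freqs, root_part).mean(axis=0)
    if np.any(site <= 0):
        raise ValueError("non-finite likelihood")
    return float(np.dot(counts, np.log(site) + log_scale))


def _optimize_branch_lengths(tree: Node, msa: MSA, model: GTRModel,
                             passes: int = 2) -> float:
    best = loglik(tree, msa, model)
    edges = [n for n in tree.postorder() if n is not tree]
    for _ in range(passes):
        for node in edges:
            t0 = node.length or 0.01

            def f(t):
                node.length = t
                return -loglik(tree, msa, model)

            res = minimize_scalar(f, bounds=(1e-9, 10.0), method="bounded",
                                  options={"xatol": 1e-6})
            if -res.fun >= best:
                node.length = float(res.x)
                best = -res.fun
            else:
                node.length = t0
    return best


def _nni_neighbours(tree: Node):
    """Yield (apply, undo) closures for every NNI move on internal edges."""
    for parent in tree.preorder():
        for v in parent.children:
            if v.is_leaf:
                continue
            siblings = [c for c in parent.children if c is not v]
            if not siblings:
                continue
            s = siblings[0]
            for ci in range(len(v.children)):
                c = v.children[ci]

                def apply(parent=parent, v=v, s=s, c=c):
                    parent.children[parent.children.index(s)] = c
                    v.children[v.children.index(c)] = s

                def undo(parent=parent, v=v, s=s, c=c):
                    parent.children[parent.children.index(c)] = s
                    v.children[v.children.index(s)] = c

                yield apply, undo


def ml_tree(msa: MSA, model: GTRModel | None = None,
            max_rounds: int = 10) -> tuple[Node, float]:
    """Maximum-likelihood tree: BioNJ start, NNI hill-climbing.

    Branch lengths are optimized by bounded line search; GTR
    exchangeabilities and the Gamma shape by Nelder-Mead on the log scale.
    The returned likelihood is never below the starting likelihood.
    """
    if len(msa) < 4:
        raise ValueError("need >= 4 taxa")
    if model is None:
        model = default_gtr(msa)
    try:
        tree = bionj(distances(msa, model="JC"))
    except ValueError:
        tree = bionj(distances(msa, model="p"))
    for node in tree.postorder():
        if node is not tree and (node.length is None or node.length <= 0):
            node.length = 1e-6
    best = _optimize_branch_lengths(tree, msa, model)
    best = _optimize_model(tree, msa, model, best)
    for _ in range(max_rounds):
        improved = False
        for apply, undo in list(_nni_neighbours(tree)):
            apply()
            try:
                cand = loglik(tree, msa, model)
            except ValueError:
                cand = -np.inf
            if cand > best + 1e-9:
                cand = _optimize_branch_lengths(tree, msa, model, passes=1)
                best = cand
                improved = True
            else:
                undo()
        if not improved:
            break
        best = _optimize_branch_lengths(tree, msa, model, passes=1)
    return tree, best


def _optimize_model(tree: Node, msa: MSA, model: GTRModel, best: float) -> float:
    x0 = np.concatenate([np.log(model.rates[:5]),
                         [np.log(model.alpha)] if model.alpha else []])

    def f(x):
        model.rates[:5] = np.exp(np.clip(x[:5], -6, 6))
        if model.alpha is not None:
            model.alpha = float(np.exp(np.clip(x[5], np.log(0.05), np.log(10.0))))
        try:
            return -loglik(tree, msa, model)
        except (ValueError, FloatingPointError):
            return 1e30

    res = minimize(f, x0, method="Nelder-Mead",
                   options={"maxiter": 200, "fatol": 1e-6})
    cand = -f(res.x)
    if cand >= best:
        return cand
    f(x0)
    return best


# ---------------------------------------------------------------------------
# Flank extraction


def extract_flank_concat(assembly: str, trna_calls, flank_len: int = 1000) -> str:
    """Concatenate the regions upstream of the 5' tRNA and downstream of
    the 3' tRNA, excluding the tRNAs and everything between them.

    ``trna_calls`` must be oriented (5' tRNA first).  Raises if either
    side has fewer than ``flank_len`` bases available.
    """
    if len(trna_calls) < 2:
        raise ValueError("need both flanking tRNA calls")
    calls = sorted(trna_calls, key=lambda c: c.start)
    five, three = calls[0], calls[-1]
    if five.start < flank_len:
        raise ValueError(f"insufficient 5' flank: {five.start} < {flank_len}")
    if len(assembly) - three.end < flank_len:
        raise ValueError(
            f"insufficient 3' flank: {len(assembly) - three.end} < {flank_len}")
    return (assembly[five.start - flank_len : five.start]
            + assembly[three.end : three.end + flank_len])
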