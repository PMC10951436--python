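"""Shared sequence utilities: encoding, k-mer hashing, minimizers, I/O."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def encode(seq: str) -> np.ndarray:
    """2-bit encode A,C,G,T -> 0..3; anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer: invertible scrambling of k-mer integer values
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def kmer_values(seq: str, k: int) -> np.ndarray:
    """Integer value of every k-mer (4^k base); -1 marks k-mers with N."""
    codes = encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        vals = vals * 4 + np.minimum(c, 3).astype(np.int64)
        bad |= c == 4
    vals[bad] = -1
    return vals


def canonical_kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Hashes of canonical k-mers and the strand achieving them.

    Returns ``(hashes, strands)`` with ``strands[i]`` 0 if the forward
    k-mer hashes lower, 1 if the reverse complement does.  Positions
    containing non-ACGT bases get hash ``2**64 - 1`` (never minimal).
    """
    fwd = kmer_values(seq, k)
    rcv = kmer_values(revcomp(seq), k)[::-1]
    bad = (fwd < 0) | (rcv < 0)
    hf = _mix64(fwd.astype(np.uint64))
    hr = _mix64(rcv.astype(np.uint64))
    strands = (hr < hf).astype(np.int8)
    h = np.minimum(hf, hr)
    h[bad] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return h, strands


def minimizers(seq: str, k: int, w: int) -> list[tuple[int, int, int]]:
    """(w,k)-minimizers: ``(position, hash, strand)`` triples.

    Every window of ``w`` consecutive k-mers contributes the position of
    its minimal canonical k-mer hash (leftmost on ties).
    """
    h, strands = canonical_kmer_hashes(seq, k)
    n = len(h)
    if n == 0:
        return []
    if n <= w:
        p = int(np.argmin(h))
        return [(p, int(h[p]), int(strands[p]))]
    win = np.lib.stride_tricks.sliding_window_view(h, w)
    pos = np.argmin(win, axis=1) + np.arange(n - w + 1)
    pos = np.unique(pos)
    return [(int(p), int(h[p]), int(strands[p])) for p in pos]


# ---------------------------------------------------------------------------
# Light-weight FASTA/FASTQ I/O (sequences are plain strings throughout)

def write_fasta(path, records: dict[str, str] | list[tuple[str, str]]) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_fastq(path, records: list[tuple[str, str]], qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        while True:
            h = fh.readline()
            if not h:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            out.append((h[1:].strip().split()[0], seq))
    return out
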