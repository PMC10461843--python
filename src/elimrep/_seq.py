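"""Low-level DNA string utilities shared across modules.

Everything here is strand-aware: canonical k-mers use the lexicographic
minimum of a k-mer and its reverse complement, and canonical monomers use
the minimal rotation over both strands, so repeat calls are comparable
across runs regardless of read orientation.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")

#: byte -> 2-bit code lookup; 255 marks non-ACGT
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T, case preserved)."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def kmer_to_int(kmer: str) -> int:
    """2-bit encode a k-mer (A=0, C=1, G=2, T=3), big-endian."""
    v = 0
    for c in kmer:
        v = (v << 2) | int(_LUT[ord(c)])
    return v


def int_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(out))


def canonical_code(kmer: str) -> int:
    """Integer code of the canonical form of ``kmer``."""
    return kmer_to_int(canonical(kmer))


def encode_codes(seq: str) -> np.ndarray:
    """Per-base 2-bit codes as uint8; non-ACGT bases map to 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def kmer_codes_canonical(seq: str, k: int) -> np.ndarray:
    """Canonical integer codes of every valid k-mer window of ``seq``.

    Windows containing non-ACGT characters are skipped. Vectorised Horner
    evaluation over 2-bit codes; fits in uint64 for k <= 31.
    """
    a = encode_codes(seq)
    m = len(a) - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64)
    a64 = a.astype(np.uint64)
    fw = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    comp = (np.uint64(3) - np.where(a64 > 3, np.uint64(3), a64)).astype(np.uint64)
    for j in range(k):
        fw = fw * np.uint64(4) + a64[j:j + m] % np.uint64(4)
        jj = k - 1 - j
        rc = rc * np.uint64(4) + comp[jj:jj + m]
    canon = np.minimum(fw, rc)
    bad = (a > 3).astype(np.int64)
    cs = np.concatenate([[0], np.cumsum(bad)])
    ok = (cs[k:] - cs[:-k]) == 0
    return canon[ok]


def smallest_period(s: str) -> int:
    """Smallest p such that s is (s[:p]) repeated; len(s) if aperiodic.

    Border (KMP failure function) analysis; the smallest period of a string
    is unique, so there are no ties to break.
    """
    n = len(s)
    if n == 0:
        return 0
    f = [0] * n
    j = 0
    for i in range(1, n):
        while j and s[i] != s[j]:
            j = f[j - 1]
        if s[i] == s[j]:
            j += 1
        f[i] = j
    p = n - f[-1]
    return p if n % p == 0 else n


def minimal_rotation(s: str) -> str:
    """Lexicographically minimal rotation (Booth's algorithm, O(n))."""
    if not s:
        return s
    n = len(s)
    s2 = s + s
    i, j, k = 0, 1, 0
    while i < n and j < n and k < n:
        a, b = s2[i + k], s2[j + k]
        if a == b:
            k += 1
            continue
        if a > b:
            i = max(i + k + 1, j)
        else:
            j = max(j + k + 1, i)
        if i == j:
            j = i + 1
        k = 0
    start = min(i, j)
    return s2[start:start + n]


def canonical_monomer(s: str) -> str:
    """Strand- and rotation-normalised monomer: min rotation over both strands."""
    return min(minimal_rotation(s), minimal_rotation(revcomp(s)))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
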