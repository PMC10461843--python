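"""Characterisation of repeat families from cloned monomer copies.

Given a set of cloned copies of one tandem-repeat family (germline- or
somatic-derived), this module aligns them, calls a per-column majority
consensus, and computes the statistics used to describe satellite monomers:
mean pairwise intraspecific divergence (gap sites excluded pair-wise), GC
content, direct repeats within the monomer, open reading frames in tandem
context, and the number of nucleotide substitutions between two consensus
sequences of the same family (e.g. germline vs somatic).

Alignment is a star alignment around a centroid clone: practical for sets
of near-identical monomer copies, and every scoring parameter is exposed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import revcomp
from .synthdata import CloneSet

#: star-alignment scoring; GENETYX-style defaults are unpublished, these are
#: conventional DNA scores and can be overridden per call.
DEFAULT_SCORING = dict(match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5)

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class Alignment:
    """Rows of equal length over {A,C,G,T,-}; one label per row."""

    sequences: list[str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("invalid-input: empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("invalid-input: rows of unequal length")
        if not self.labels:
            self.labels = [f"seq{i+1}" for i in range(len(self.sequences))]
        cols = np.array([list(s) for s in self.sequences])
        if cols.size and np.any(np.all(cols == "-", axis=0)):
            raise ValueError("invalid-input: all-gap column")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for lab, s in zip(self.labels, self.sequences):
                fh.write(f">{lab}\n{s}\n")


@dataclass
class ConsensusReport:
    """Summary statistics for one clone set."""

    family: str
    source: str
    consensus: str
    n_clones: int
    divergence_pct: float | None
    gc_pct: float
    direct_repeats: list[tuple[str, int, int, int]]
    orfs: list[tuple[int, int, int]]


def _aligner(scoring: dict | None = None):
    from Bio import Align

    sc = dict(DEFAULT_SCORING, **(scoring or {}))
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = sc["match"]
    al.mismatch_score = sc["mismatch"]
    al.open_gap_score = sc["gap_open"]
    al.extend_gap_score = sc["gap_extend"]
    return al


def _pairwise_rows(aligner, a: str, b: str) -> tuple[str, str]:
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def align_clones(clones: CloneSet | Sequence[str], labels: Sequence[str] | None = None,
                 scoring: dict | None = None) -> Alignment:
    """Star alignment of clone sequences around a centroid.

    The centroid is the clone with minimal summed edit distance to all
    others (edlib); every other clone is globally aligned to it and the
    pairwise alignments are merged column-wise under the usual
    once-a-gap-always-a-gap rule (new centroid gaps are propagated to all
    previously merged rows).
    """
    if isinstance(clones, CloneSet):
        seqs = list(clones.sequences)
        labels = labels or [f"{clones.family}_{clones.source}_{i+1}"
                            for i in range(len(seqs))]
    else:
        seqs = list(clones)
        labels = list(labels) if labels else [f"seq{i+1}" for i in range(len(seqs))]
    if len(seqs) < 2:
        raise ValueError("invalid-input: need at least 2 clones")
    if all(s == seqs[0] for s in seqs):
        return Alignment(seqs, labels)

    import edlib

    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d
    centroid = int(np.argmin(dist.sum(axis=1)))
    center = seqs[centroid]

    aligner = _aligner(scoring)
    # master gap bookkeeping: ins[p] = gap columns inserted before centroid
    # position p (p in 0..len(center)); per-clone rows are re-padded as the
    # master insertion profile grows.
    m = len(center)
    ins = [0] * (m + 1)
    per_clone: list[tuple[int, list[str], list[int]]] = []  # (index, pieces, its ins)
    for idx in range(n):
        if idx == centroid:
            continue
        ca, ra = _pairwise_rows(aligner, center, seqs[idx])
        pieces: list[list[str]] = [[] for _ in range(m + 1)]  # insertions before p
        aligned_char: list[str] = []  # char aligned to centroid position p
        p = 0
        for cc, rc in zip(ca, ra):
            if cc == "-":
                pieces[p].append(rc)
            else:
                aligned_char.append(rc)
                p += 1
        my_ins = [len(x) for x in pieces]
        for p in range(m + 1):
            ins[p] = max(ins[p], my_ins[p])
        per_clone.append((idx, ["".join(x) for x in pieces] + aligned_char, my_ins))

    def build_row(pieces_ins: list[str], aligned: list[str] | None) -> str:
        out: list[str] = []
        for p in range(m + 1):
            piece = pieces_ins[p] if pieces_ins else ""
            out.append(piece + "-" * (ins[p] - len(piece)))
            if p < m:
                out.append(aligned[p] if aligned is not None else center[p])
        return "".join(out)

    rows: list[str | None] = [None] * n
    rows[centroid] = build_row([""] * (m + 1), None)
    for idx, packed, _my in per_clone:
        pieces_ins, aligned = packed[: m + 1], packed[m + 1:]
        rows[idx] = build_row(pieces_ins, aligned)
    return Alignment([r for r in rows if r is not None], list(labels))


def call_consensus(aln: Alignment) -> str:
    """Per-column majority base; strictly-majority-gap columns are dropped.

    Base ties break alphabetically (A < C < G < T); a tie between the top
    base and the gap keeps the base, matching the gapless consensus rows
    satellite reports conventionally show.
    """
    cols = np.array([list(s) for s in aln.sequences])
    out: list[str] = []
    for j in range(cols.shape[1]):
        col = cols[:, j]
        gaps = int(np.sum(col == "-"))
        bases, counts = np.unique(col[col != "-"], return_counts=True)
        if len(bases) == 0:
            continue
        top_count = int(counts.max())
        if gaps > top_count:
            continue
        # alphabetical tie-break among equally counted bases
        tied = sorted(b for b, c in zip(bases, counts) if c == top_count)
        out.append(tied[0])
    return "".join(out)


def pairwise_divergence(aln: Alignment) -> float | None:
    """Mean pairwise mismatch percentage; gap sites excluded per pair.

    For each unordered row pair, columns where either row has a gap are
    excluded; the pair contributes mismatches / comparable columns. Pairs
    with no comparable columns are skipped; if all pairs are skipped the
    result is a no-call (None).
    """
    if aln.n < 2:
        raise ValueError("invalid-input: need >= 2 rows")
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8)
                    for s in aln.sequences])
    gap = ord("-")
    vals: list[float] = []
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            ok = (mat[i] != gap) & (mat[j] != gap)
            ncomp = int(ok.sum())
            if ncomp == 0:
                continue
            mism = int(((mat[i] != mat[j]) & ok).sum())
            vals.append(mism / ncomp)
    if not vals:
        return None
    return 100.0 * float(np.mean(vals))


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def gc_content(seq: str) -> float:
    """GC percentage to one decimal (round half up)."""
    if not seq:
        raise ValueError("invalid-input: empty sequence")
    if set(seq) - set("ACGT"):
        raise ValueError("invalid-input: ambiguous bases in sequence")
    return _round1(100.0 * (seq.count("G") + seq.count("C")) / len(seq))


def _best_rotation(a: str, b: str, scoring: dict | None = None) -> str:
    """Rotation of b (either strand) that best matches a."""
    cands = []
    if len(a) == len(b):
        av = np.frombuffer(a.encode(), dtype=np.uint8)
        for strand in (b, revcomp(b)):
            doubled = strand + strand
            for r in range(len(strand)):
                rot = doubled[r:r + len(strand)]
                score = int((np.frombuffer(rot.encode(), dtype=np.uint8) == av).sum())
                cands.append((score, rot))
    else:
        aligner = _aligner(scoring)
        for strand in (b, revcomp(b)):
            doubled = strand + strand
            for r in range(len(strand)):
                rot = doubled[r:r + len(strand)]
                cands.append((aligner.score(a, rot), rot))
    return max(cands, key=lambda t: (t[0], t[1]))[1]


def count_substitutions(cons_a: str, cons_b: str, scoring: dict | None = None) -> int:
    """Substitution count between two consensus sequences of one family.

    The second sequence is first rotation- and strand-normalised against the
    first (tandem monomers have no natural origin), then globally aligned;
    mismatch columns are counted, indel columns are not.
    """
    if not cons_a or not cons_b:
        raise ValueError("invalid-pair: empty consensus")
    ratio = len(cons_b) / len(cons_a)
    if not 0.5 <= ratio <= 2.0:
        raise ValueError("invalid-pair: length ratio outside [0.5, 2]")
    if cons_a == cons_b:
        return 0
    b = _best_rotation(cons_a, cons_b, scoring)
    if len(b) == len(cons_a):
        return int(sum(x != y for x, y in zip(cons_a, b)))
    ra, rb = _pairwise_rows(_aligner(scoring), cons_a, b)
    return int(sum(x != y and x != "-" and y != "-" for x, y in zip(ra, rb)))


def find_direct_repeats(seq: str, min_len: int = 8,
                        max_pairs: int = 10) -> list[tuple[str, int, int, int]]:
    """Maximal exact same-strand repeats with >= 2 non-overlapping copies.

    A repeated substring is maximal when no one-character extension of it is
    still repeated; nested hits contained within a longer reported pair are
    suppressed. Each hit is reported as (substring, pos1, pos2, length)
    using its first two non-overlapping occurrences, longest first.
    """
    if not seq:
        raise ValueError("invalid-input: empty sequence")
    n = len(seq)
    occ_by_len: dict[int, dict[str, list[int]]] = {}
    for L in range(min_len, n):
        d: dict[str, list[int]] = {}
        for i in range(n - L + 1):
            d.setdefault(seq[i:i + L], []).append(i)
        rep = {s: p for s, p in d.items() if len(p) >= 2}
        if not rep:
            break
        occ_by_len[L] = rep

    results: list[tuple[str, int, int, int]] = []
    for L in sorted(occ_by_len, reverse=True):
        longer = occ_by_len.get(L + 1, {})
        extendable = set()
        for t in longer:
            extendable.add(t[:-1])
            extendable.add(t[1:])
        for s in sorted(occ_by_len[L]):
            if s in extendable:
                continue
            pos = occ_by_len[L][s]
            pair = None
            first = pos[0]
            for j in pos[1:]:
                if j >= first + L:
                    pair = (first, j)
                    break
            if pair is None:
                continue
            i, j = pair
            contained = any(
                i >= i2 and i + L <= i2 + L2 and j >= j2 and j + L <= j2 + L2
                for _s2, i2, j2, L2 in results
            )
            if not contained:
                results.append((s, i, j, L))
    return results[:max_pairs]


def find_orfs(seq: str, min_aa: int = 30) -> list[tuple[int, int, int]]:
    """ORFs (ATG..stop, >= min_aa codons) in tandem context, all six frames.

    The sequence is doubled before scanning so reading frames crossing the
    arbitrary monomer origin are seen; coordinates are reported modulo the
    unit length as (start, end, frame) with frames +1..+3 / -1..-3.
    """
    if not seq:
        raise ValueError("invalid-input: empty sequence")
    n = len(seq)
    found: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()
    for sign, s in ((1, seq + seq), (-1, revcomp(seq + seq))):
        for frame in range(3):
            i = frame
            while i + 3 <= len(s):
                if s[i:i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= len(s) and s[j:j + 3] not in _STOPS:
                        j += 3
                    if j + 3 <= len(s):  # found a stop
                        n_codons = (j - i) // 3
                        if n_codons >= min_aa and i < n:
                            key = (sign * (frame + 1), i % n, n_codons)
                            if key not in seen:
                                seen.add(key)
                                found.append((i % n, j % n, sign * (frame + 1)))
                        i = j + 3
                        continue
                i += 3
    return found


def characterize(clones: CloneSet, scoring: dict | None = None,
                 min_repeat_len: int = 8, min_aa: int = 30) -> ConsensusReport:
    """Full per-clone-set report: consensus, divergence, GC, repeats, ORFs."""
    aln = align_clones(clones, scoring=scoring)
    cons = call_consensus(aln)
    return ConsensusReport(
        family=clones.family,
        source=clones.source,
        consensus=cons,
        n_clones=clones.n,
        divergence_pct=pairwise_divergence(aln),
        gc_pct=gc_content(cons),
        direct_repeats=find_direct_repeats(cons, min_len=min_repeat_len),
        orfs=find_orfs(cons, min_aa=min_aa),
    )


def reports_to_tsv(reports: Sequence[ConsensusReport], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([
        dict(family=r.family, source=r.source, n=r.n_clones,
             divergence_pct=(None if r.divergence_pct is None
                             else round(r.divergence_pct, 2)),
             gc_pct=r.gc_pct, n_direct_repeat_pairs=len(r.direct_repeats),
             n_orfs=len(r.orfs), consensus_length=len(r.consensus))
        for r in reports
    ]).to_csv(path, sep="\t", index=False)
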