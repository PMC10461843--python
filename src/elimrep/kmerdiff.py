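"""Differential k-mer discovery of germline-enriched tandem repeats.

Satellite families restricted to eliminated chromosomes leave a simple
signature in whole-genome reads: their k-mers are present at high frequency
in germline reads and (nearly) absent from somatic reads. The filter keeps
canonical k-mers whose germline frequency exceeds the (depth-normalised)
somatic frequency by a large factor - the discovery criterion is a 100-fold
enrichment - then reassembles the survivors into repeat contigs by greedy
unique-extension unitigging and reads the tandem monomer off each circular
contig as its smallest period.

The assembler is deliberately minimal: tandem satellites circularise into
simple de Bruijn cycles, so no bubble popping or coverage-based tip clipping
is attempted. It is not a general-purpose assembler.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import (
    BASES,
    canonical,
    canonical_monomer,
    int_to_kmer,
    kmer_codes_canonical,
    kmer_to_int,
    smallest_period,
)
from .synthdata import ReadSet

_CHUNK_BASES = 4_000_000


@dataclass
class KmerCountTable:
    """Canonical k-mer counts, stored as parallel sorted arrays.

    ``kmers`` holds 2-bit-encoded canonical k-mers (uint64, sorted) and
    ``counts`` the matching occurrence counts; ``total_kmers`` is the number
    of counted windows (= sum of counts).
    """

    k: int
    kmers: np.ndarray
    counts: np.ndarray
    total_kmers: int

    def get(self, kmer: str | int) -> int:
        code = kmer_to_int(canonical(kmer)) if isinstance(kmer, str) else kmer
        i = int(np.searchsorted(self.kmers, np.uint64(code)))
        if i < len(self.kmers) and self.kmers[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def __len__(self) -> int:
        return len(self.kmers)

    def items_decoded(self):
        for code, c in zip(self.kmers, self.counts):
            yield int_to_kmer(int(code), self.k), int(c)


def _check_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("invalid-parameter: k must be odd "
                         "(avoids self-complementary k-mers)")
    if not 11 <= k <= 31:
        raise ValueError("invalid-parameter: k must be in [11, 31]")


def _count_codes(chunks: Iterable[str], k: int) -> KmerCountTable:
    parts: list[np.ndarray] = []
    total = 0
    for chunk in chunks:
        codes = kmer_codes_canonical(chunk, k)
        total += len(codes)
        parts.append(codes)
    if not parts:
        return KmerCountTable(k, np.empty(0, np.uint64), np.empty(0, np.int64), 0)
    allc = np.concatenate(parts)
    kmers, counts = np.unique(allc, return_counts=True)
    return KmerCountTable(k, kmers, counts.astype(np.int64), total)


def _batched(seqs: Sequence[str]) -> Iterable[str]:
    # join reads with 'N' separators so no window spans two reads
    buf: list[str] = []
    size = 0
    for s in seqs:
        buf.append(s)
        size += len(s) + 1
        if size >= _CHUNK_BASES:
            yield "N".join(buf)
            buf, size = [], 0
    if buf:
        yield "N".join(buf)


def count_kmers(reads: ReadSet | Sequence[str], k: int) -> KmerCountTable:
    """Canonical k-mer counts over a read set (non-ACGT windows skipped)."""
    _check_k(k)
    seqs = reads.sequences if isinstance(reads, ReadSet) else list(reads)
    if not seqs:
        raise ValueError("invalid-input: empty read set")
    return _count_codes(_batched(seqs), k)


def count_genome_kmers(sequences: Sequence[str], k: int) -> KmerCountTable:
    """Direct canonical k-mer counts of chromosome sequences."""
    _check_k(k)
    return _count_codes(_batched(list(sequences)), k)


@dataclass
class EnrichedKmerSet:
    """Canonical k-mers passing the germline-enrichment filter."""

    k: int
    kmers: np.ndarray          # uint64 codes of members
    germ_counts: np.ndarray
    soma_counts: np.ndarray
    ratios: np.ndarray
    ratio_threshold: float
    min_germline_count: int
    pseudocount: float

    def __len__(self) -> int:
        return len(self.kmers)

    @property
    def members(self) -> set[int]:
        return set(int(x) for x in self.kmers)

    def germ_count_of(self) -> dict[int, int]:
        return {int(k): int(c) for k, c in zip(self.kmers, self.germ_counts)}

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({
            "kmer": [int_to_kmer(int(c), self.k) for c in self.kmers],
            "germ_count": self.germ_counts,
            "soma_count": self.soma_counts,
            "ratio": np.round(self.ratios, 3),
        }).to_csv(path, sep="\t", index=False)


def enrichment_filter(germ: KmerCountTable, soma: KmerCountTable,
                      ratio_threshold: float = 100.0,
                      min_germline_count: int = 10,
                      pseudocount: float = 1.0) -> EnrichedKmerSet:
    """Keep k-mers >= ratio_threshold-fold enriched in germline reads.

    Somatic counts are scaled to the germline sequencing depth
    (``germ.total_kmers / soma.total_kmers``) before the ratio
    ``germ / (scaled_soma + pseudocount)`` is taken; the pseudocount keeps
    somatic-absent k-mers finite and demands real germline depth of them.
    """
    if germ.k != soma.k:
        raise ValueError("invalid-input: k-mer sizes differ between tables")
    if soma.total_kmers == 0:
        raise ValueError("invalid-input: empty somatic table")
    scale = germ.total_kmers / soma.total_kmers
    idx = np.searchsorted(soma.kmers, germ.kmers)
    idx_c = np.minimum(idx, max(len(soma.kmers) - 1, 0))
    hit = (len(soma.kmers) > 0) & (soma.kmers[idx_c] == germ.kmers)
    s = np.where(hit, soma.counts[idx_c], 0).astype(float)
    ratios = germ.counts / (s * scale + pseudocount)
    keep = (ratios >= ratio_threshold) & (germ.counts >= min_germline_count)
    return EnrichedKmerSet(
        germ.k, germ.kmers[keep], germ.counts[keep].astype(np.int64),
        s[keep].astype(np.int64), ratios[keep],
        ratio_threshold, min_germline_count, pseudocount,
    )


@dataclass
class RepeatContig:
    """A unitig over enriched k-mers; circular contigs are tandem monomer cycles."""

    sequence: str
    circular: bool
    mean_kmer_count: float
    member_kmers: set[int] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MonomerCall:
    """A tandem monomer: unit length plus strand/rotation-normalised sequence."""

    unit_length: int
    canonical_monomer: str
    estimated_copies: float = 0.0


def _succ(kmer: str, members: set[int]) -> list[str]:
    suf = kmer[1:]
    return [suf + b for b in BASES if kmer_to_int(canonical(suf + b)) in members]


def _pred(kmer: str, members: set[int]) -> list[str]:
    pre = kmer[:-1]
    return [b + pre for b in BASES if kmer_to_int(canonical(b + pre)) in members]


def assemble_enriched(enriched: EnrichedKmerSet) -> list[RepeatContig]:
    """Greedy unique-extension unitigs over (k-1)-overlaps of enriched k-mers.

    Extension from x to y requires x to have exactly one member successor and
    y exactly one member predecessor; it also stops when the next k-mer was
    already consumed. A unitig whose (k-1)-suffix re-enters its own
    (k-1)-prefix is flagged circular. Each member k-mer lands in at most one
    contig; the k-mer order of traversal is seeded by the smallest unused
    code, so output is deterministic.
    """
    members = enriched.members
    if not members:
        return []
    counts = enriched.germ_count_of()
    unused = set(members)
    k = enriched.k
    contigs: list[RepeatContig] = []
    while unused:
        seed_code = min(unused)
        seed = int_to_kmer(seed_code, k)
        unused.discard(seed_code)
        path = [seed]
        # forward
        cur = seed
        while True:
            nxt = _succ(cur, members)
            if len(nxt) != 1:
                break
            nk = nxt[0]
            code = kmer_to_int(canonical(nk))
            if code not in unused or len(_pred(nk, members)) != 1:
                break
            path.append(nk)
            unused.discard(code)
            cur = nk
        # backward
        cur = seed
        while True:
            prv = _pred(cur, members)
            if len(prv) != 1:
                break
            pk = prv[0]
            code = kmer_to_int(canonical(pk))
            if code not in unused or len(_succ(pk, members)) != 1:
                break
            path.insert(0, pk)
            unused.discard(code)
            cur = pk
        seq = path[0] + "".join(p[-1] for p in path[1:])
        codes = {kmer_to_int(canonical(p)) for p in path}
        circular = False
        if len(path) >= 2 and seq[:k - 1] == seq[-(k - 1):]:
            wrap = seq[-(k - 1):] + seq[k - 1]
            if kmer_to_int(canonical(wrap)) in members:
                circular = True
                seq = seq[: len(path)]  # cyclic form: one char per k-mer node
        mean_count = float(np.mean([counts[c] for c in codes]))
        contigs.append(RepeatContig(seq, circular, mean_count, codes))
    contigs.sort(key=lambda c: (-len(c.sequence), c.sequence))
    return contigs


def infer_monomer(contig: RepeatContig, k: int) -> MonomerCall | None:
    """Read the tandem unit off a contig; None when no period is detectable.

    A circular contig is stored in cyclic form (one character per k-mer
    node) and its unit is the smallest period of that cyclic string. A
    linear contig must contain at least two full unit repetitions to make a
    call.
    """
    seq = contig.sequence
    if contig.circular:
        circ = seq
        if not circ:
            return None
        u = smallest_period(circ)
        mono = circ[:u]
        return MonomerCall(u, canonical_monomer(mono), len(circ) / u)
    u = smallest_period(seq)
    if u < len(seq) and len(seq) >= 2 * u:
        return MonomerCall(u, canonical_monomer(seq[:u]), len(seq) / u)
    return None


def estimate_copy_number(call: MonomerCall, enriched: EnrichedKmerSet,
                         per_base_coverage: float) -> float:
    """Median germline depth of the monomer's k-mers over the base depth.

    ``per_base_coverage`` should be the k-mer-adjusted depth,
    ``coverage * (read_length - k + 1) / read_length``.
    """
    if per_base_coverage <= 0:
        raise ValueError("invalid-parameter: per_base_coverage must be positive")
    k = enriched.k
    doubled = call.canonical_monomer + call.canonical_monomer[: k - 1]
    codes = [kmer_to_int(canonical(doubled[i:i + k]))
             for i in range(len(call.canonical_monomer))]
    counts = enriched.germ_count_of()
    depths = [counts.get(c, 0) for c in codes]
    if not depths:
        return 0.0
    return float(np.median(depths)) / per_base_coverage


def discover_monomers(germ_reads: ReadSet | Sequence[str],
                      soma_reads: ReadSet | Sequence[str],
                      k: int = 21, ratio_threshold: float = 100.0,
                      min_germline_count: int = 10,
                      per_base_coverage: float | None = None):
    """End-to-end discovery: count, filter, assemble, call monomers.

    Returns ``(enriched, contigs, calls)`` where ``calls`` is the
    deduplicated list of MonomerCall (unique canonical monomers, longest
    contigs first); junction fragments with no detectable period are
    reported as no-calls and dropped.
    """
    germ = count_kmers(germ_reads, k)
    soma = count_kmers(soma_reads, k)
    enriched = enrichment_filter(germ, soma, ratio_threshold, min_germline_count)
    contigs = assemble_enriched(enriched)
    calls: list[MonomerCall] = []
    seen: set[str] = set()
    for c in contigs:
        call = infer_monomer(c, k)
        if call is None or call.canonical_monomer in seen:
            continue
        seen.add(call.canonical_monomer)
        if per_base_coverage:
            call = MonomerCall(call.unit_length, call.canonical_monomer,
                               estimate_copy_number(call, enriched, per_base_coverage))
        calls.append(call)
    return enriched, contigs, calls


def contigs_to_fasta(contigs: Sequence[RepeatContig], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(contigs, 1):
            fh.write(f">contig{i} circular={int(c.circular)} "
                     f"mean_count={c.mean_kmer_count:.1f}\n{c.sequence}\n")


def calls_to_tsv(calls: Sequence[MonomerCall], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame([
        dict(name=f"monomer{i}", unit_length=c.unit_length,
             est_copies=round(c.estimated_copies, 2), monomer=c.canonical_monomer)
        for i, c in enumerate(calls, 1)
    ]).to_csv(path, sep="\t", index=False)
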