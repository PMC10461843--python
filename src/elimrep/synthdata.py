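"""Synthetic germline/somatic genomes with planted tandem-repeat families.

This module generates every input the analysis pipeline consumes, with known
ground truth: a germline karyotype (2n = 52) in which 16 eliminated
(E-)chromosomes carry tandem arrays of ten repeat families laid out in six
distinct per-pair patterns; a somatic karyotype (2n = 36) identical except
for the removed E-chromosomes; sequencing reads; clone sets of mutated
monomer copies; and per-chromosome per-probe 1-D fluorescence-intensity
profiles.

The model system is programmed DNA elimination in the Japanese hagfish,
where roughly a fifth of the germline genome - sixteen chromosomes built
largely from a handful of satellite families (EEEb1-EEEb10) - is discarded
from presumptive somatic cells. Chromosome lengths here are scaled down to
desk scale (50 kb E-chromosomes, 100 kb retained chromosomes); chromosome
*counts* follow the real karyotype.

Layout model
------------
Each E-chromosome is tiled in 2 kb bins. Terminal "inside" bins interleave
blocks of the reference family (EEEb1) with blocks of the other families;
adjacent "outside" bins carry families without the reference; pattern
variants add interior islands, drop families, or remove one arm. Blocks are
whole monomer copies separated by random background spacers, so at fiber
resolution families are interspersed while at karyogram resolution each
family shows a reproducible overlap fraction with the reference signal.
One family (EEEb10) additionally receives low-density dispersed single
copies on *all* chromosomes, germline and somatic alike.
"""
from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import (
    canonical_monomer,
    gc_fraction,
    revcomp,
    smallest_period,
)

BIN_BP = 2000
E_CHROM_LEN = 50_000
RETAINED_CHROM_LEN = 100_000

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatFamily:
    """A named tandem-repeat family.

    ``monomer`` is the repeating unit (A/C/G/T only); ``unit_length`` equals
    its length; ``target_gc`` is the GC fraction the generator aimed for.
    """

    name: str
    monomer: str
    unit_length: int
    target_gc: float

    def __post_init__(self):
        if self.unit_length != len(self.monomer):
            raise ValueError("unit_length must equal monomer length")
        if set(self.monomer) - set("ACGT"):
            raise ValueError("monomer must contain only A/C/G/T")

    @property
    def gc(self) -> float:
        return gc_fraction(self.monomer)

    @property
    def canonical(self) -> str:
        return canonical_monomer(self.monomer)


@dataclass(frozen=True)
class KaryotypeConfig:
    """Chromosome counts and scaled-down lengths for both karyotypes."""

    germline_2n: int = 52
    somatic_2n: int = 36
    e_chromosome_length: int = E_CHROM_LEN
    retained_chromosome_length: int = RETAINED_CHROM_LEN
    eliminated_fraction_target: float = 0.21

    def __post_init__(self):
        if self.germline_2n % 2 or self.somatic_2n % 2:
            raise ValueError("diploid chromosome counts must be even")
        if self.somatic_2n >= self.germline_2n:
            raise ValueError("germline_2n must exceed somatic_2n")

    @property
    def e_chromosome_count(self) -> int:
        return self.germline_2n - self.somatic_2n

    @property
    def e_pair_count(self) -> int:
        return self.e_chromosome_count // 2

    @property
    def retained_pair_count(self) -> int:
        return self.somatic_2n // 2


@dataclass(frozen=True)
class Placement:
    """One placed tandem block: 0-based half-open interval on a chromosome.

    ``rotation`` is the monomer phase the block starts at; interspersed
    satellite blocks carry no shared phase, so the generator randomises it.
    """

    chromosome_id: str
    pair_id: str
    family: str
    start: int
    end: int
    copies: int
    orientation: str = "+"
    dispersed: bool = False
    rotation: int = 0

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid placement interval")
        if self.orientation not in "+-":
            raise ValueError("orientation must be + or -")


class PlacementMap:
    """Collection of placements with per-chromosome overlap validation."""

    def __init__(self, rows: Iterable[Placement] = ()):
        self.rows: list[Placement] = list(rows)

    def add(self, row: Placement) -> None:
        self.rows.append(row)

    def validate(self, chrom_lengths: Mapping[str, int] | None = None) -> None:
        by_chrom: dict[str, list[Placement]] = {}
        for r in self.rows:
            by_chrom.setdefault(r.chromosome_id, []).append(r)
        for chrom, rows in by_chrom.items():
            rows = sorted(rows, key=lambda r: r.start)
            for a, b in zip(rows, rows[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"invalid-placement: overlapping intervals on {chrom}: "
                        f"{a.family}[{a.start},{a.end}) vs {b.family}[{b.start},{b.end})"
                    )
            if chrom_lengths is not None:
                L = chrom_lengths[chrom]
                if rows and (rows[0].start < 0 or rows[-1].end > L):
                    raise ValueError(f"invalid-placement: interval out of bounds on {chrom}")

    def for_chromosome(self, chrom: str) -> list[Placement]:
        return sorted((r for r in self.rows if r.chromosome_id == chrom),
                      key=lambda r: r.start)

    def families(self) -> set[str]:
        return {r.family for r in self.rows}

    def total_bases(self, family: str, chromosomes: Iterable[str] | None = None,
                    include_dispersed: bool = True) -> int:
        chroms = set(chromosomes) if chromosomes is not None else None
        tot = 0
        for r in self.rows:
            if r.family != family:
                continue
            if not include_dispersed and r.dispersed:
                continue
            if chroms is not None and r.chromosome_id not in chroms:
                continue
            tot += r.end - r.start
        return tot

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                dict(chrom=r.chromosome_id, start=r.start, end=r.end,
                     family=r.family, copies=r.copies, strand=r.orientation,
                     pair=r.pair_id, dispersed=int(r.dispersed),
                     rotation=r.rotation)
                for r in sorted(self.rows, key=lambda r: (r.chromosome_id, r.start))
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PlacementMap":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        rows = [
            Placement(str(r.chrom), str(r.pair), str(r.family), int(r.start),
                      int(r.end), int(r.copies), str(r.strand),
                      bool(getattr(r, "dispersed", 0)),
                      int(getattr(r, "rotation", 0)))
            for r in df.itertuples()
        ]
        return cls(rows)


@dataclass
class Chromosome:
    id: str
    sequence: str
    is_eliminated: bool
    pair_id: str


@dataclass
class Genome:
    chromosomes: list[Chromosome]
    placement: PlacementMap

    def __len__(self) -> int:
        return sum(len(c.sequence) for c in self.chromosomes)

    @property
    def chromosome_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes]

    def chromosome(self, cid: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def eliminated_ids(self) -> list[str]:
        return [c.id for c in self.chromosomes if c.is_eliminated]

    def eliminated_fraction(self) -> float:
        e = sum(len(c.sequence) for c in self.chromosomes if c.is_eliminated)
        return e / len(self) if len(self) else 0.0

    def lengths(self) -> dict[str, int]:
        return {c.id: len(c.sequence) for c in self.chromosomes}

    def to_fasta(self, path: str | Path) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        recs = [
            SeqRecord(Seq(c.sequence), id=c.id,
                      description=f"pair={c.pair_id} eliminated={int(c.is_eliminated)}")
            for c in self.chromosomes
        ]
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class ReadSet:
    """Simulated reads; qualities are constant Sanger Q40."""

    reads: list[tuple[str, str]]
    read_length: int
    coverage: float
    error_rate: float
    seed: int

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.reads]

    def total_bases(self) -> int:
        return sum(len(s) for _, s in self.reads)

    def to_fastq(self, path: str | Path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for name, seq in self.reads:
                fh.write(f"@{name}\n{seq}\n+\n{qual[:len(seq)]}\n")

    @classmethod
    def from_fastq(cls, path: str | Path) -> "ReadSet":
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        reads = []
        rl = 0
        with open(path) as fh:
            for name, seq, _q in FastqGeneralIterator(fh):
                reads.append((name, seq.upper()))
                rl = max(rl, len(seq))
        return cls(reads, rl, coverage=float("nan"), error_rate=float("nan"), seed=-1)


@dataclass
class CloneSet:
    """Sampled monomer copies of one family from one tissue source."""

    family: str
    source: str
    n: int
    mutation_rate: float
    sequences: list[str]
    seed: int

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(self.sequences, 1):
                fh.write(f">{self.family}_{self.source}_clone{i}\n{s}\n")


@dataclass
class ProfileSet:
    """Per-(chromosome, probe) 1-D intensity vectors on a fixed bin grid."""

    intensities: dict[tuple[str, str], np.ndarray]
    bin_bp: int
    chromosome_meta: dict[str, tuple[str, bool]]  # chrom -> (pair_id, is_eliminated)
    background_level: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def probes(self) -> list[str]:
        return sorted({p for _, p in self.intensities})

    @property
    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.intensities})

    def get(self, chrom: str, probe: str) -> np.ndarray:
        return self.intensities[(chrom, probe)]

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = []
        for (chrom, probe), v in sorted(self.intensities.items()):
            pair, elim = self.chromosome_meta[chrom]
            for i, x in enumerate(v):
                rows.append((chrom, pair, int(elim), probe, i, float(x)))
        pd.DataFrame(rows, columns=["chrom", "pair", "eliminated", "probe",
                                    "bin", "intensity"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, bin_bp: int = BIN_BP) -> "ProfileSet":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        intens: dict[tuple[str, str], np.ndarray] = {}
        meta: dict[str, tuple[str, bool]] = {}
        for (chrom, probe), grp in df.groupby(["chrom", "probe"]):
            grp = grp.sort_values("bin")
            intens[(str(chrom), str(probe))] = grp["intensity"].to_numpy(float)
            meta[str(chrom)] = (str(grp["pair"].iloc[0]), bool(grp["eliminated"].iloc[0]))
        return cls(intens, bin_bp, meta)


# ---------------------------------------------------------------------------
# repeat-family construction
# ---------------------------------------------------------------------------


def _random_monomer(length: int, target_gc: float, rng: np.random.Generator) -> str:
    n_gc = int(round(target_gc * length))
    bases = np.array(list("AT"))[rng.integers(0, 2, size=length)]
    pos = rng.permutation(length)[:n_gc]
    gc = np.array(list("GC"))[rng.integers(0, 2, size=n_gc)]
    bases[pos] = gc
    return "".join(bases)


def make_repeat_family(name: str, unit_length: int, target_gc: float,
                       seed: int) -> RepeatFamily:
    """Random primitive monomer of exact length and approximate GC.

    The monomer is guaranteed primitive (not a power of a shorter word), so
    its tandem arrays have a well-defined unit length.
    """
    if unit_length < 10:
        raise ValueError("invalid-parameter: unit_length must be >= 10")
    if not 0.0 <= target_gc <= 1.0:
        raise ValueError("invalid-parameter: target_gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        mono = _random_monomer(unit_length, target_gc, rng)
        if smallest_period(mono) == unit_length:
            return RepeatFamily(name, mono, unit_length, target_gc)
    raise RuntimeError("could not generate a primitive monomer")


def make_primer_anchored_family(name: str, unit_length: int, target_gc: float,
                                forward: str, reverse: str, seed: int) -> RepeatFamily:
    """Synthetic stand-in monomer anchored on a real primer pair.

    The monomer starts with the forward primer and ends with the reverse
    complement of the reverse primer, so an internal-primer PCR on a tandem
    array of it yields the classic monomer/dimer/multimer ladder with rung
    spacing exactly ``unit_length``. This is a synthetic surrogate for a
    cloned consensus sequence, not a real deposit.
    """
    head, tail = forward.upper(), revcomp(reverse.upper())
    mid_len = unit_length - len(head) - len(tail)
    if mid_len < 0:
        raise ValueError("unit_length too short for the primer pair")
    rng = np.random.default_rng(seed)
    want_gc = int(round(target_gc * unit_length))
    have_gc = sum(c in "GC" for c in head + tail)
    mid_gc = min(max(want_gc - have_gc, 0), mid_len) / mid_len if mid_len else 0.0
    for _ in range(100):
        mid = _random_monomer(mid_len, mid_gc, rng) if mid_len else ""
        mono = head + mid + tail
        if smallest_period(mono) == unit_length:
            return RepeatFamily(name, mono, unit_length, target_gc)
    raise RuntimeError("could not generate a primitive anchored monomer")


#: default unit lengths; EEEb7-10 use the published unit lengths of the four
#: novel families (360/47/84/120 bp); EEEb1-6 units are desk-scale choices.
DEFAULT_UNIT_LENGTHS: dict[str, int] = {
    "EEEb1": 171, "EEEb2": 53, "EEEb3": 89, "EEEb4": 64, "EEEb5": 101,
    "EEEb6": 143, "EEEb7": 360, "EEEb8": 47, "EEEb9": 84, "EEEb10": 120,
}

#: GC targets; EEEb7-10 follow the reported consensus GC contents
#: (40.8 / 39.2 / 39.3 / 29.8 %), the rest sit in the same realistic band.
DEFAULT_GC: dict[str, float] = {
    "EEEb1": 0.37, "EEEb2": 0.41, "EEEb3": 0.34, "EEEb4": 0.39, "EEEb5": 0.36,
    "EEEb6": 0.40, "EEEb7": 0.408, "EEEb8": 0.392, "EEEb9": 0.393, "EEEb10": 0.298,
}

DISPERSED_FAMILY = "EEEb10"

#: primer pairs used for the four novel families (packaged fixture mirrors this)
PRIMER_ANCHORS: dict[str, tuple[str, str]] = {
    "EEEb7": ("CCGCCAAATGTGTTAGGAATG", "CCTGTTGAAAGAGGCCAAAAAC"),
    "EEEb8": ("AAAAAAAGGGATTATTGTATATTTTG", "CGGTTCGGAATTTTCCAC"),
    "EEEb9": ("AAACCCTACAATTGTTCTG", "CTCTCCGGTGTGTATTC"),
    "EEEb10": ("GTTCTAAATATGGGGCCTACCTT", "CATCTTGGCAGAACCCTTTTC"),
}


def default_families(seed: int = 0) -> dict[str, RepeatFamily]:
    """The ten study families as synthetic monomers (EEEb7-10 primer-anchored)."""
    ss = np.random.SeedSequence(seed).spawn(len(DEFAULT_UNIT_LENGTHS))
    fams: dict[str, RepeatFamily] = {}
    for child, (name, u) in zip(ss, DEFAULT_UNIT_LENGTHS.items()):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        if name in PRIMER_ANCHORS:
            f, r = PRIMER_ANCHORS[name]
            fams[name] = make_primer_anchored_family(name, u, DEFAULT_GC[name],
                                                     f, r, child_seed)
        else:
            fams[name] = make_repeat_family(name, u, DEFAULT_GC[name], child_seed)
    return fams


# ---------------------------------------------------------------------------
# placement layout (six karyogram patterns over eight E-pairs)
# ---------------------------------------------------------------------------

# per-bin packing tables: list of (family, n_units) blocks per 2 kb bin.
_BIN_X = [("EEEb1", 4), ("EEEb8", 2), ("EEEb2", 2), ("EEEb4", 2), ("EEEb7", 2)]
_BIN_Y = [("EEEb1", 4), ("EEEb8", 2), ("EEEb2", 2), ("EEEb6", 2), ("EEEb9", 2),
          ("EEEb3", 2), ("EEEb10", 1)]
_BIN_O1 = [("EEEb2", 2), ("EEEb4", 2), ("EEEb7", 2), ("EEEb6", 2), ("EEEb3", 2),
           ("EEEb5", 2)]
_BIN_O2 = [("EEEb6", 2), ("EEEb9", 4), ("EEEb3", 4), ("EEEb5", 4), ("EEEb10", 2)]
_BIN_O3 = [("EEEb3", 6), ("EEEb5", 6), ("EEEb10", 4)]
_BIN_ISLAND = [("EEEb3", 4), ("EEEb5", 4), ("EEEb10", 2)]

#: left-arm bin plan: bins 0-4 carry the reference family, bins 5-7 do not.
_ARM_PLAN = {0: _BIN_X, 1: _BIN_Y, 2: _BIN_X, 3: _BIN_Y, 4: _BIN_X,
             5: _BIN_O1, 6: _BIN_O2, 7: _BIN_O3}

#: pattern id per E-pair; patterns 1 and 2 are each used by two pairs.
DEFAULT_PATTERN_OF_PAIR: dict[str, int] = {
    "E1": 1, "E2": 1, "E3": 2, "E4": 2, "E5": 3, "E6": 4, "E7": 5, "E8": 6,
}


def _drop(table: Sequence[tuple[str, int]], family: str) -> list[tuple[str, int]]:
    return [(f, u) for f, u in table if f != family]


def pattern_bin_plan(pattern: int, n_bins: int) -> dict[int, list[tuple[str, int]]]:
    """Bin -> block table for one karyogram pattern on an E-chromosome."""
    plan: dict[int, list[tuple[str, int]]] = {}
    arm = {b: list(t) for b, t in _ARM_PLAN.items()}
    if pattern == 3:
        arm = {b: _drop(t, "EEEb4") for b, t in arm.items()}
    elif pattern == 4:
        arm = {b: _drop(t, "EEEb7") for b, t in arm.items()}
        for b in (5, 6):  # EEEb6 becomes fully coincident with the reference
            arm[b] = _drop(arm[b], "EEEb6")
    elif pattern == 5:
        for b in (0, 1, 2, 3, 4):
            arm[b] = _drop(arm[b], "EEEb2")
        arm[5] = [("EEEb2", 4) if f == "EEEb2" else (f, u) for f, u in arm[5]]
    for b, t in arm.items():
        plan[b] = list(t)
    if pattern != 6:  # mirrored right arm
        for b, t in arm.items():
            plan[n_bins - 1 - b] = list(t)
    if pattern == 2:
        mid = n_bins // 2
        for b in (mid - 1, mid, mid + 1):
            plan[b] = list(_BIN_ISLAND)
    return plan


def default_placement(config: KaryotypeConfig, families: Mapping[str, RepeatFamily],
                      seed: int, dispersed_family: str = DISPERSED_FAMILY,
                      dispersed_per_bp: float = 1e-4) -> PlacementMap:
    """Build the packaged six-pattern placement map plus dispersed copies.

    Block order within each bin is shuffled per bin instance and blocks are
    separated by background spacers, so block junctions are locus-unique.
    Homologs of a pair receive identical placements.
    """
    rng = np.random.default_rng(seed)
    n_bins = config.e_chromosome_length // BIN_BP
    pm = PlacementMap()
    pattern_of_pair = {f"E{i+1}": DEFAULT_PATTERN_OF_PAIR.get(f"E{i+1}", 1)
                       for i in range(config.e_pair_count)}

    for pair, pattern in pattern_of_pair.items():
        plan = pattern_bin_plan(pattern, n_bins)
        rows_a: list[tuple[str, int, int, int, int]] = []  # family, start, end, copies, rot
        for b_idx in sorted(plan):
            blocks = plan[b_idx]
            order = rng.permutation(len(blocks))
            total = sum(u * families[f].unit_length for f, u in blocks)
            slack = BIN_BP - total
            if slack < 0:
                raise ValueError(f"bin overflow in pattern {pattern} bin {b_idx}")
            gap = slack // (len(blocks) + 1)
            pos = b_idx * BIN_BP + gap
            for i in order:
                f, u = blocks[i]
                L = u * families[f].unit_length
                rot = int(rng.integers(0, families[f].unit_length))
                rows_a.append((f, pos, pos + L, u, rot))
                pos += L + gap
        for hom in "ab":
            chrom = f"{pair}{hom}"
            for f, s, e, u, rot in rows_a:
                pm.add(Placement(chrom, pair, f, s, e, u, rotation=rot))

    # dispersed single copies on every chromosome (identical between homologs)
    unit = families[dispersed_family].unit_length
    all_pairs = ([(f"E{i+1}", config.e_chromosome_length)
                  for i in range(config.e_pair_count)]
                 + [(f"R{i+1}", config.retained_chromosome_length)
                    for i in range(config.retained_pair_count)])
    for pair, L in all_pairs:
        n = rng.poisson(L * dispersed_per_bp)
        occupied = [(r.start, r.end) for r in pm.rows
                    if r.chromosome_id == f"{pair}a"]
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < n and tries < 50 * max(n, 1):
            tries += 1
            s = int(rng.integers(0, L - unit))
            iv = (s, s + unit)
            if any(s < e0 and iv[1] > s0 for s0, e0 in occupied + placed):
                continue
            placed.append(iv)
        for s, e in placed:
            rot = int(rng.integers(0, unit))
            for hom in "ab":
                pm.add(Placement(f"{pair}{hom}", pair, dispersed_family,
                                 s, e, 1, "+", dispersed=True, rotation=rot))
    pm.validate()
    return pm


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_background(length: int, rng: np.random.Generator) -> np.ndarray:
    return np.array(list("ACGT"), dtype="U1")[rng.integers(0, 4, size=length)]


def build_germline_genome(config: KaryotypeConfig,
                          families: Mapping[str, RepeatFamily],
                          placement: PlacementMap, seed: int) -> Genome:
    """Materialise the germline genome from a placement map.

    E-chromosomes carry the placed tandem arrays over random background;
    retained chromosomes carry background plus any dispersed placements.
    Homologs within a pair are byte-identical.
    """
    unknown = placement.families() - set(families)
    if unknown:
        raise ValueError(f"placement references undeclared families: {unknown}")
    rng = np.random.default_rng(seed)
    chrom_lengths: dict[str, int] = {}
    pairs = ([(f"E{i+1}", config.e_chromosome_length, True)
              for i in range(config.e_pair_count)]
             + [(f"R{i+1}", config.retained_chromosome_length, False)
                for i in range(config.retained_pair_count)])
    for pair, L, _e in pairs:
        for hom in "ab":
            chrom_lengths[f"{pair}{hom}"] = L
    placement.validate(chrom_lengths)

    chromosomes: list[Chromosome] = []
    for pair, L, elim in pairs:
        bg = _random_background(L, rng)
        for hom in "ab":
            cid = f"{pair}{hom}"
            seq = bg.copy()
            for r in placement.for_chromosome(cid):
                fam = families[r.family]
                mono = fam.monomer[r.rotation:] + fam.monomer[: r.rotation]
                ncopy = (r.end - r.start) // fam.unit_length
                arr = mono * (ncopy + 1)
                arr = arr[: r.end - r.start]
                if r.orientation == "-":
                    arr = revcomp(arr)
                seq[r.start:r.end] = list(arr)
            chromosomes.append(Chromosome(cid, "".join(seq), elim, pair))
    return Genome(chromosomes, placement)


def derive_somatic_genome(germline: Genome) -> Genome:
    """Drop eliminated chromosomes; retained chromosomes are byte-identical.

    Idempotent: applying it to a somatic genome returns an identical copy.
    """
    kept_ids = {c.id for c in germline.chromosomes if not c.is_eliminated}
    chroms = [_copy.deepcopy(c) for c in germline.chromosomes if c.id in kept_ids]
    pm = PlacementMap([r for r in germline.placement.rows
                       if r.chromosome_id in kept_ids])
    return Genome(chroms, pm)


# ---------------------------------------------------------------------------
# reads and clones
# ---------------------------------------------------------------------------


def simulate_reads(genome: Genome, coverage: float, read_length: int = 100,
                   error_rate: float = 0.0, seed: int = 0) -> ReadSet:
    """Uniform single-end reads from both strands, seeded and deterministic."""
    if coverage <= 0:
        raise ValueError("invalid-parameter: coverage must be positive")
    min_len = min(len(c.sequence) for c in genome.chromosomes)
    if read_length > min_len:
        raise ValueError("invalid-parameter: read_length exceeds shortest chromosome")
    rng = np.random.default_rng(seed)
    G = len(genome)
    n_reads = int(round(coverage * G / read_length))
    weights = np.array([len(c.sequence) - read_length + 1
                        for c in genome.chromosomes], dtype=float)
    weights /= weights.sum()
    chrom_idx = rng.choice(len(genome.chromosomes), size=n_reads, p=weights)
    strands = rng.integers(0, 2, size=n_reads)
    fwd = [c.sequence for c in genome.chromosomes]
    rev = [revcomp(s) for s in fwd]
    starts = rng.random(n_reads)
    reads: list[tuple[str, str]] = []
    for i in range(n_reads):
        ci = int(chrom_idx[i])
        L = len(fwd[ci])
        s = int(starts[i] * (L - read_length + 1))
        src = fwd[ci] if strands[i] == 0 else rev[ci]
        reads.append((f"r{i}", src[s:s + read_length]))
    if error_rate > 0:
        nerr = rng.binomial(read_length, error_rate, size=n_reads)
        others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
        for i in np.nonzero(nerr)[0]:
            name, seq = reads[i]
            arr = list(seq)
            for p in rng.choice(read_length, size=nerr[i], replace=False):
                arr[p] = others[arr[p]][rng.integers(0, 3)]
            reads[i] = (name, "".join(arr))
    return ReadSet(reads, read_length, coverage, error_rate, seed)


def sample_clones(family: RepeatFamily, source: str, n: int, mutation_rate: float,
                  seed: int, indel_rate_fraction: float = 0.0) -> CloneSet:
    """Clone copies of the monomer with independent per-site substitutions.

    Each mutated site is replaced by a uniformly random *different* base.
    With ``indel_rate_fraction`` > 0 an indel mode adds insertions/deletions
    at rate ``indel_rate_fraction * mutation_rate`` per site (geometric
    length, mean 2), emulating the gap sites seen in real clone alignments.
    """
    if not 0 <= mutation_rate < 0.25:
        raise ValueError("invalid-parameter: mutation_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    mono = family.monomer
    u = len(mono)
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    seqs: list[str] = []
    indel_rate = indel_rate_fraction * mutation_rate
    for _ in range(n):
        arr = list(mono)
        if mutation_rate > 0:
            hits = np.nonzero(rng.random(u) < mutation_rate)[0]
            for p in hits:
                arr[p] = others[arr[p]][rng.integers(0, 3)]
        if indel_rate > 0:
            out: list[str] = []
            for c in arr:
                r = rng.random()
                if r < indel_rate / 2:
                    continue  # deletion
                out.append(c)
                if r >= indel_rate / 2 and r < indel_rate:
                    ln = rng.geometric(0.5)
                    out.extend("ACGT"[rng.integers(0, 4)] for _ in range(ln))
            arr = out
        seqs.append("".join(arr))
    return CloneSet(family.name, source, n, mutation_rate, seqs, seed)


# ---------------------------------------------------------------------------
# FISH profile rendering
# ---------------------------------------------------------------------------


def render_fish_profiles(genome: Genome, probes: Sequence[str], bin_bp: int = BIN_BP,
                         background_level: float = 0.0, noise_sd: float = 0.0,
                         seed: int = 0, include_dispersed: bool = True) -> ProfileSet:
    """Per-bin intensity = placed probe bases / bin_bp + background + noise.

    Noise is Gaussian truncated at zero. ``include_dispersed=False`` renders
    only the dense arrays, emphasising intense signals the way a karyogram
    does for a family that also shows weak genome-wide background.
    """
    if bin_bp < 1:
        raise ValueError("invalid-parameter: bin_bp must be >= 1")
    known = genome.placement.families()
    for p in probes:
        if p not in known:
            raise ValueError(f"invalid-probe: {p} not in placement map")
    rng = np.random.default_rng(seed)
    intens: dict[tuple[str, str], np.ndarray] = {}
    meta: dict[str, tuple[str, bool]] = {}
    for chrom in genome.chromosomes:
        meta[chrom.id] = (chrom.pair_id, chrom.is_eliminated)
        n_bins = int(np.ceil(len(chrom.sequence) / bin_bp))
        rows = genome.placement.for_chromosome(chrom.id)
        for probe in probes:
            v = np.zeros(n_bins)
            for r in rows:
                if r.family != probe or (r.dispersed and not include_dispersed):
                    continue
                b0, b1 = r.start // bin_bp, (r.end - 1) // bin_bp
                for b in range(b0, b1 + 1):
                    lo, hi = max(r.start, b * bin_bp), min(r.end, (b + 1) * bin_bp)
                    v[b] += (hi - lo) / bin_bp
            v = v + background_level
            if noise_sd > 0:
                v = v + rng.normal(0.0, noise_sd, size=n_bins)
            intens[(chrom.id, probe)] = np.maximum(v, 0.0)
    return ProfileSet(intens, bin_bp, meta, background_level, noise_sd, seed)


def render_fiber_masks(genome: Genome, chromosome_id: str,
                       region: tuple[int, int], probes: Sequence[str],
                       bin_bp: int = 50) -> dict[str, np.ndarray]:
    """Boolean per-probe occupancy masks along one chromatin-fiber region."""
    lo, hi = region
    n_bins = (hi - lo) // bin_bp
    masks: dict[str, np.ndarray] = {p: np.zeros(n_bins, dtype=bool) for p in probes}
    for r in genome.placement.for_chromosome(chromosome_id):
        if r.family not in masks or r.end <= lo or r.start >= hi:
            continue
        b0 = max(r.start - lo, 0) // bin_bp
        b1 = min(r.end - lo, hi - lo - 1) // bin_bp
        masks[r.family][b0:b1 + 1] = True
    return masks


# ---------------------------------------------------------------------------
# ground-truth manifest
# ---------------------------------------------------------------------------


def build_manifest(config: KaryotypeConfig, families: Mapping[str, RepeatFamily],
                   germline: Genome, somatic: Genome,
                   dispersed_family: str = DISPERSED_FAMILY) -> dict:
    """Ground truth for parameter-recovery scoring, JSON-serialisable."""
    e_ids = set(germline.eliminated_ids)
    fam_entries = {}
    for name, fam in sorted(families.items()):
        g_bases = germline.placement.total_bases(name)
        s_bases = somatic.placement.total_bases(name)
        fam_entries[name] = {
            "unit_length": fam.unit_length,
            "monomer": fam.monomer,
            "canonical_monomer": fam.canonical,
            "gc_pct": round(100 * fam.gc, 1),
            "germline_bases": g_bases,
            "somatic_bases": s_bases,
            "germline_copies": g_bases // fam.unit_length,
            "somatic_copies": s_bases // fam.unit_length,
            "germline_restricted": s_bases == 0,
            "expected_discoverable": s_bases == 0 and g_bases // fam.unit_length >= 20,
        }
    return {
        "karyotype": {
            "germline_2n": config.germline_2n,
            "somatic_2n": config.somatic_2n,
            "e_chromosome_count": config.e_chromosome_count,
            "germline_chromosomes": len(germline.chromosomes),
            "somatic_chromosomes": len(somatic.chromosomes),
            "eliminated_fraction": germline.eliminated_fraction(),
            "eliminated_fraction_target": config.eliminated_fraction_target,
        },
        "families": fam_entries,
        "dispersed_family": dispersed_family,
        "pattern_of_pair": {p: DEFAULT_PATTERN_OF_PAIR[p]
                            for p in sorted({c.pair_id for c in germline.chromosomes
                                             if c.is_eliminated})},
    }


def save_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
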