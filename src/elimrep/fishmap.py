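"""Classification of FISH signal distributions on 1-D intensity profiles.

Multi-probe FISH on metaphase chromosomes is summarised here as, per
chromosome and probe, a 1-D intensity vector (the line-scan histogram of a
chromosome image). The module segments signal from background, measures how
much of each probe's intensity falls inside the reference probe's signal
mask, classifies each probe into the co-localization groups used for
eliminated-chromosome karyotyping (coincident / largely overlapping / half
overlapping / peripheral, plus dispersed and absent), scores terminal
cluster symmetry (isochromosome signature), partitions chromosome pairs
into karyogram patterns by signature equality, and quantifies fiber-level
interspersion of probe segments with a permutation test.

The numeric class cut-offs formalise qualitative microscopy categories and
are exposed in :class:`ClassifyConfig`.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .synthdata import ProfileSet

REFERENCE_PROBE = "EEEb1"

CALL_ORDER = ["coincident", "largely_overlapping", "half_overlapping",
              "peripheral", "dispersed", "absent"]


@dataclass(frozen=True)
class ClassifyConfig:
    """Thresholds for localization calls; defaults formalise the four groups."""

    coincident_min: float = 0.90
    largely_min: float = 0.60
    half_min: float = 0.35
    absent_floor_fraction: float = 0.05   # of the reference probe's total
    dispersed_bin_fraction: float = 0.5
    dispersed_max_over_threshold: float = 2.0
    symmetry_min: float = 0.80
    mad_multiplier: float = 3.0
    min_run_bins: int = 2


@dataclass(frozen=True)
class LocalizationCall:
    call: str
    overlap_fraction: float

    def __post_init__(self):
        if self.call not in CALL_ORDER:
            raise ValueError(f"unknown call {self.call}")


@dataclass(frozen=True)
class PatternSignature:
    """Per-probe categorical signature of one chromosome pair."""

    entries: tuple[tuple[str, str, bool, int], ...]  # (probe, call, symmetric, clusters)

    @classmethod
    def build(cls, per_probe: Mapping[str, tuple[str, bool, int]]) -> "PatternSignature":
        return cls(tuple((p, *per_probe[p]) for p in sorted(per_probe)))


@dataclass
class Karyogram:
    pattern_of_pair: dict[str, int]
    signatures: dict[str, PatternSignature]
    n_patterns: int

    def pairs_of_pattern(self, pattern: int) -> list[str]:
        return sorted(p for p, g in self.pattern_of_pair.items() if g == pattern)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_patterns": self.n_patterns,
            "patterns": {str(g): self.pairs_of_pattern(g)
                         for g in sorted(set(self.pattern_of_pair.values()))},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# segmentation and overlap
# ---------------------------------------------------------------------------


def segment_threshold(intensities: np.ndarray,
                      config: ClassifyConfig = ClassifyConfig()) -> float:
    """Background median + 3 x background MAD.

    Background bins are those at or below the profile's 75th percentile
    (the brightest quarter is assumed to be signal).
    """
    v = np.asarray(intensities, dtype=float)
    bg = v[v <= np.percentile(v, 75)]
    med = float(np.median(bg))
    mad = float(np.median(np.abs(bg - med)))
    return med + config.mad_multiplier * mad


def segment_signal(intensities: np.ndarray,
                   config: ClassifyConfig = ClassifyConfig()) -> np.ndarray:
    """Binary signal mask: above-threshold bins, short runs removed.

    A bin is signal-positive when its intensity reaches the threshold *and*
    strictly exceeds the background median (so an exactly-flat profile
    yields an empty mask); isolated positive runs shorter than
    ``min_run_bins`` are dropped.
    """
    v = np.asarray(intensities, dtype=float)
    if len(v) < 10:
        raise ValueError("invalid-input: need >= 10 bins")
    bg = v[v <= np.percentile(v, 75)]
    med = float(np.median(bg))
    thr = segment_threshold(v, config)
    mask = (v >= thr) & (v > med)
    return _drop_short_runs(mask, config.min_run_bins)


def _drop_short_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    out = mask.copy()
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True bins."""
    out: list[tuple[int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def overlap_fraction(target_intensities: np.ndarray,
                     reference_mask: np.ndarray) -> float:
    """Fraction of the target's total intensity inside the reference mask."""
    t = np.asarray(target_intensities, dtype=float)
    m = np.asarray(reference_mask, dtype=bool)
    if len(t) != len(m):
        raise ValueError("invalid-input: bin grids differ")
    total = float(t.sum())
    if total == 0:
        return 0.0
    return float(t[m].sum()) / total


def cluster_count(intensities: np.ndarray,
                  config: ClassifyConfig = ClassifyConfig()) -> int:
    return len(runs(segment_signal(intensities, config)))


def symmetry_score(intensities: np.ndarray) -> float:
    """Pearson correlation of a profile with its own reversal (0 if flat)."""
    v = np.asarray(intensities, dtype=float)
    if np.ptp(v) == 0:
        return 0.0
    return float(np.corrcoef(v, v[::-1])[0, 1])


def classify_localization(target_intensities: np.ndarray,
                          reference_intensities: np.ndarray,
                          config: ClassifyConfig = ClassifyConfig()) -> LocalizationCall:
    """Assign a co-localization class for one probe against the reference.

    Order of precedence: absent (target total below the detection floor,
    a fraction of the reference total) -> dispersed (signal spread over
    most of the chromosome with no bin much above threshold) -> overlap
    classes by fraction of target intensity inside the reference mask,
    boundaries inclusive on the lower edge of each class.
    """
    t = np.asarray(target_intensities, dtype=float)
    r = np.asarray(reference_intensities, dtype=float)
    if len(t) != len(r):
        raise ValueError("invalid-input: bin grids differ")
    ref_mask = segment_signal(r, config)
    total = float(t.sum())
    floor = config.absent_floor_fraction * float(r.sum())
    if total == 0 or total < floor:
        return LocalizationCall("absent", 0.0)
    positive_frac = float((t > 0).mean())
    thr = segment_threshold(t, config)
    if (positive_frac > config.dispersed_bin_fraction and thr > 0
            and float(t.max()) < config.dispersed_max_over_threshold * thr):
        return LocalizationCall("dispersed", overlap_fraction(t, ref_mask))
    frac = overlap_fraction(t, ref_mask)
    if frac >= config.coincident_min:
        return LocalizationCall("coincident", frac)
    if frac >= config.largely_min:
        return LocalizationCall("largely_overlapping", frac)
    if frac >= config.half_min:
        return LocalizationCall("half_overlapping", frac)
    return LocalizationCall("peripheral", frac)


# ---------------------------------------------------------------------------
# karyogram construction
# ---------------------------------------------------------------------------


def _orient_and_average(profiles: Sequence[np.ndarray],
                        reference: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Average homolog profiles after orienting each homolog.

    Each homolog is flipped (all probes together) so the centroid of its
    reference-probe intensity lies in the first half of the chromosome;
    an exactly central centroid leaves the homolog unflipped.
    """
    n_probes = len(profiles) // len(reference)
    oriented: list[list[np.ndarray]] = []
    for h, ref in enumerate(reference):
        v = np.asarray(ref, dtype=float)
        idx = np.arange(len(v))
        centroid = float((idx * v).sum() / v.sum()) if v.sum() > 0 else 0.0
        flip = centroid > (len(v) - 1) / 2
        block = profiles[h * n_probes:(h + 1) * n_probes]
        oriented.append([np.asarray(p, dtype=float)[::-1] if flip
                         else np.asarray(p, dtype=float) for p in block])
    return [np.mean([hom[i] for hom in oriented], axis=0)
            for i in range(len(oriented[0]))]


def build_karyogram(profile_set: ProfileSet,
                    reference_probe: str = REFERENCE_PROBE,
                    config: ClassifyConfig = ClassifyConfig()) -> Karyogram:
    """Partition E-chromosome pairs into patterns by signature equality.

    Homologs of each pair are orientation-normalised and averaged; each
    probe then contributes (localization call, symmetry flag, cluster
    count) to the pair's signature. Pairs with equal signatures share a
    pattern id; ids are assigned in pair order, so the result is invariant
    to input order.
    """
    probes = profile_set.probes
    if reference_probe not in probes:
        raise ValueError(f"invalid-input: missing reference probe {reference_probe}")
    pairs: dict[str, list[str]] = {}
    for chrom, (pair, elim) in profile_set.chromosome_meta.items():
        if elim:
            pairs.setdefault(pair, []).append(chrom)
    signatures: dict[str, PatternSignature] = {}
    for pair in sorted(pairs, key=_natural_key):
        homologs = sorted(pairs[pair])
        for chrom in homologs:
            for p in probes:
                if (chrom, p) not in profile_set.intensities:
                    raise ValueError(f"invalid-input: missing probe {p} on {chrom}")
        flat = [profile_set.get(c, p) for c in homologs for p in probes]
        refs = [profile_set.get(c, reference_probe) for c in homologs]
        avg = _orient_and_average(flat, refs)
        by_probe = dict(zip(probes, avg))
        ref_avg = by_probe[reference_probe]
        per_probe: dict[str, tuple[str, bool, int]] = {}
        for p in probes:
            call = classify_localization(by_probe[p], ref_avg, config)
            sym = symmetry_score(by_probe[p]) >= config.symmetry_min
            per_probe[p] = (call.call, sym, cluster_count(by_probe[p], config))
        signatures[pair] = PatternSignature.build(per_probe)
    pattern_of_pair: dict[str, int] = {}
    seen: dict[PatternSignature, int] = {}
    for pair in sorted(signatures, key=_natural_key):
        sig = signatures[pair]
        if sig not in seen:
            seen[sig] = len(seen) + 1
        pattern_of_pair[pair] = seen[sig]
    return Karyogram(pattern_of_pair, signatures, n_patterns=len(seen))


def _natural_key(s: str):
    head = s.rstrip("0123456789")
    tail = s[len(head):]
    return (head, int(tail) if tail else -1)


def classification_table(profile_set: ProfileSet,
                         reference_probe: str = REFERENCE_PROBE,
                         config: ClassifyConfig = ClassifyConfig()):
    """Per-(chromosome, probe) calls as a DataFrame (calls TSV surface)."""
    import pandas as pd

    rows = []
    for chrom in profile_set.chromosomes:
        ref = profile_set.get(chrom, reference_probe)
        pair, elim = profile_set.chromosome_meta[chrom]
        for p in profile_set.probes:
            t = profile_set.get(chrom, p)
            call = classify_localization(t, ref, config)
            rows.append(dict(chrom=chrom, pair=pair, eliminated=int(elim), probe=p,
                             call=call.call,
                             overlap_fraction=round(call.overlap_fraction, 4),
                             symmetry=round(symmetry_score(t), 4),
                             clusters=cluster_count(t, config)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fiber-level interspersion
# ---------------------------------------------------------------------------


def fiber_interspersion(masks: Mapping[str, np.ndarray], n_permutations: int = 1000,
                        seed: int = 0) -> tuple[float, float] | None:
    """Interspersion of probe segments along one chromatin fiber.

    Segments are contiguous occupancy runs per probe, ordered along the
    fiber; the index is the fraction of adjacent segment pairs carrying
    different probe labels (1 = perfectly alternating). The p-value comes
    from permuting the segment label order. Probes with fewer than two
    segments are excluded; with fewer than two probes left the result is a
    no-call (None). This index is this package's formalisation of the
    qualitative "intermingled signals" observation.
    """
    segs: list[tuple[int, int, str]] = []
    for probe in sorted(masks):
        r = runs(np.asarray(masks[probe], dtype=bool))
        if len(r) < 2:
            continue
        segs.extend((a, b, probe) for a, b in r)
    labels = [p for _, _, p in sorted(segs, key=lambda t: (t[0], t[1], t[2]))]
    if len(set(labels)) < 2:
        return None
    lab = np.array(labels)
    n_adj = len(lab) - 1

    def alternations(x: np.ndarray) -> int:
        return int((x[1:] != x[:-1]).sum())

    obs = alternations(lab)
    index = obs / n_adj
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_permutations):
        if alternations(rng.permutation(lab)) >= obs:
            ge += 1
    p = (1 + ge) / (n_permutations + 1)
    return index, p
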