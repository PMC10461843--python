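"""End-to-end orchestration: simulate -> discover -> characterize -> PCR -> map.

One YAML-serialisable :class:`RunConfig` drives every stage with a single
master seed (per-stage child seeds are derived deterministically), and
:func:`run_all` returns a JSON-serialisable :class:`RunSummary` whose
content is byte-identical across runs with the same config and seed.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from . import fishmap, ispcr, kmerdiff, repchar, synthdata
from ._seq import canonical_monomer

log = logging.getLogger("elimrep")


@dataclass
class RunConfig:
    """All tunables of the pipeline; defaults are the packaged study setup."""

    seed: int = 0
    # karyotype
    germline_2n: int = 52
    somatic_2n: int = 36
    e_chromosome_length: int = synthdata.E_CHROM_LEN
    retained_chromosome_length: int = synthdata.RETAINED_CHROM_LEN
    eliminated_fraction_target: float = 0.21
    # synthesis
    family_seed: int = 0
    dispersed_per_bp: float = 1e-4
    # reads
    coverage: float = 10.0
    read_length: int = 100
    error_rate: float = 0.0
    # discovery
    k: int = 21
    ratio_threshold: float = 100.0
    min_germline_count: int = 10
    # characterization
    clones_per_family: int = 20
    clone_mutation_rate: float = 0.01
    # fishmap
    bin_bp: int = synthdata.BIN_BP
    reference_probe: str = fishmap.REFERENCE_PROBE
    fiber_bin_bp: int = 50
    fiber_region_bp: int = 16000
    n_permutations: int = 1000
    # ispcr
    pcr_template_copies: int = 3
    pcr_max_len: int = 3000

    def validate(self) -> None:
        if self.germline_2n % 2 or self.somatic_2n % 2:
            raise ValueError("diploid counts must be even")
        if self.k % 2 == 0:
            raise ValueError("k must be odd")
        for name in ("eliminated_fraction_target",):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    def karyotype(self) -> synthdata.KaryotypeConfig:
        return synthdata.KaryotypeConfig(
            self.germline_2n, self.somatic_2n,
            self.e_chromosome_length, self.retained_chromosome_length,
            self.eliminated_fraction_target,
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage and return the run summary dictionary.

    Stages: synthesis (genomes + manifest), read simulation, k-mer
    discovery, clone characterization, in-silico PCR ladders, karyogram
    classification, fiber interspersion, and a dispersed-family check on a
    somatically retained chromosome.
    """
    config.validate()
    seeds = _child_seeds(config.seed, 8)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- synthesis -------------------------------------------------------
    log.info("stage=synthdata seed=%d", seeds[0])
    kary = config.karyotype()
    families = synthdata.default_families(config.family_seed)
    placement = synthdata.default_placement(kary, families, seeds[0],
                                            dispersed_per_bp=config.dispersed_per_bp)
    germline = synthdata.build_germline_genome(kary, families, placement, seeds[1])
    somatic = synthdata.derive_somatic_genome(germline)
    manifest = synthdata.build_manifest(kary, families, germline, somatic)

    # --- reads -----------------------------------------------------------
    log.info("stage=reads coverage=%.1f", config.coverage)
    germ_reads = synthdata.simulate_reads(germline, config.coverage,
                                          config.read_length, config.error_rate,
                                          seeds[2])
    soma_reads = synthdata.simulate_reads(somatic, config.coverage,
                                          config.read_length, config.error_rate,
                                          seeds[3])

    # --- discovery -------------------------------------------------------
    log.info("stage=discovery k=%d ratio=%.0f", config.k, config.ratio_threshold)
    per_base_cov = config.coverage * (config.read_length - config.k + 1) / config.read_length
    enriched, contigs, calls = kmerdiff.discover_monomers(
        germ_reads, soma_reads, k=config.k,
        ratio_threshold=config.ratio_threshold,
        min_germline_count=config.min_germline_count,
        per_base_coverage=per_base_cov,
    )
    planted = {name: fam.canonical for name, fam in families.items()
               if manifest["families"][name]["expected_discoverable"]}
    discovered = {c.canonical_monomer: c for c in calls}
    matches = {name: mono for name, mono in planted.items() if mono in discovered}
    recall = len(matches) / len(planted) if planted else 1.0
    precision = (len(matches) / len(discovered)) if discovered else 1.0
    discovery = {
        "n_enriched_kmers": len(enriched),
        "n_contigs": len(contigs),
        "n_monomer_calls": len(calls),
        "recall": recall,
        "precision": precision,
        "families": sorted(
            (dict(matched_family=name, unit_length=discovered[mono].unit_length,
                  planted_unit_length=families[name].unit_length,
                  est_copies=round(discovered[mono].estimated_copies, 1))
             for name, mono in matches.items()),
            key=lambda d: d["matched_family"],
        ),
    }

    # --- characterization ------------------------------------------------
    log.info("stage=characterize n=%d rate=%.3f", config.clones_per_family,
             config.clone_mutation_rate)
    char_seeds = _child_seeds(seeds[4], len(families))
    characterization = {}
    for cseed, (name, fam) in zip(char_seeds, sorted(families.items())):
        clones = synthdata.sample_clones(fam, "germline", config.clones_per_family,
                                         config.clone_mutation_rate, cseed)
        rep = repchar.characterize(clones)
        characterization[name] = dict(
            n_clones=rep.n_clones,
            consensus_matches_monomer=(canonical_monomer(rep.consensus) == fam.canonical),
            divergence_pct=round(rep.divergence_pct, 3),
            gc_pct=rep.gc_pct,
            n_direct_repeat_pairs=len(rep.direct_repeats),
            n_orfs=len(rep.orfs),
        )

    # --- in-silico PCR ---------------------------------------------------
    log.info("stage=ispcr")
    primer_pairs = ispcr.load_primer_pairs()
    ladders = {}
    for name, pair in sorted(primer_pairs.items()):
        fam = families[name]
        template = fam.monomer * config.pcr_template_copies
        ladder = ispcr.predict_amplicons(template, pair, max_len=config.pcr_max_len)
        report = ispcr.ladder_report(ladder, fam.unit_length)
        ladders[name] = dict(unit_length=fam.unit_length,
                             band_sizes=ladder.band_sizes,
                             labels=[r["label"] for r in report])

    # --- karyogram -------------------------------------------------------
    log.info("stage=fishmap")
    probes = sorted(families)
    karyo_profiles = synthdata.render_fish_profiles(
        germline, probes, bin_bp=config.bin_bp, seed=seeds[5],
        include_dispersed=False,  # emphasise intense signals, as a karyogram does
    )
    karyogram = fishmap.build_karyogram(karyo_profiles, config.reference_probe)

    # --- fiber interspersion --------------------------------------------
    fiber_chrom = germline.eliminated_ids[0]
    masks = synthdata.render_fiber_masks(germline, fiber_chrom,
                                         (0, config.fiber_region_bp), probes,
                                         bin_bp=config.fiber_bin_bp)
    fiber = fishmap.fiber_interspersion(masks, config.n_permutations, seeds[6])
    fiber_out = (dict(index=round(fiber[0], 4), p_value=round(fiber[1], 5))
                 if fiber else None)

    # --- dispersed-family demonstration ---------------------------------
    noisy = synthdata.render_fish_profiles(
        germline, [config.reference_probe, synthdata.DISPERSED_FAMILY],
        bin_bp=config.bin_bp, background_level=0.1, noise_sd=0.02, seed=seeds[7],
    )
    retained = next(c.id for c in germline.chromosomes if not c.is_eliminated)
    disp_call = fishmap.classify_localization(
        noisy.get(retained, synthdata.DISPERSED_FAMILY),
        noisy.get(retained, config.reference_probe),
    )

    summary = {
        "config": asdict(config),
        "manifest": manifest,
        "karyotype": manifest["karyotype"],
        "discovery": discovery,
        "characterization": characterization,
        "ispcr": ladders,
        "fishmap": {
            "n_patterns": karyogram.n_patterns,
            "pattern_of_pair": dict(sorted(karyogram.pattern_of_pair.items())),
        },
        "fiber": fiber_out,
        "dispersed_on_retained": disp_call.call,
    }

    if out is not None:
        germline.to_fasta(out / "germline.fa")
        somatic.to_fasta(out / "somatic.fa")
        placement.to_tsv(out / "placement.tsv")
        germ_reads.to_fastq(out / "germline_reads.fastq")
        soma_reads.to_fastq(out / "somatic_reads.fastq")
        synthdata.save_manifest(manifest, out / "manifest.json")
        enriched.to_tsv(out / "enriched_kmers.tsv")
        kmerdiff.contigs_to_fasta(contigs, out / "contigs.fa")
        kmerdiff.calls_to_tsv(calls, out / "monomer_calls.tsv")
        karyo_profiles.to_tsv(out / "profiles.tsv")
        karyogram.to_json(out / "karyogram.json")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def rand_index(labels_a: dict[str, int], labels_b: dict[str, int]) -> float:
    """Pair-counting Rand index between two partitions of the same items."""
    items = sorted(labels_a)
    if sorted(labels_b) != items:
        raise ValueError("invalid-input: partitions cover different items")
    if len(items) < 2:
        return 1.0
    agree = 0
    total = 0
    for x, y in combinations(items, 2):
        total += 1
        same_a = labels_a[x] == labels_a[y]
        same_b = labels_b[x] == labels_b[y]
        agree += same_a == same_b
    return agree / total


def compare_to_truth(summary: dict, manifest: dict) -> dict:
    """Score a run summary against the generator's ground-truth manifest."""
    if not manifest:
        raise ValueError("invalid-input: missing manifest")
    fams = manifest.get("families", {})
    expected = {n for n, f in fams.items() if f.get("expected_discoverable")}
    if not summary:
        return dict(recall=0.0, precision=0.0, unit_length_exact=0.0, rand_index=0.0)
    disc = summary.get("discovery", {})
    found = {d["matched_family"]: d for d in disc.get("families", [])}
    n_calls = disc.get("n_monomer_calls", 0)
    recall = len(set(found) & expected) / len(expected) if expected else 0.0
    precision = len(set(found) & expected) / n_calls if n_calls else 0.0
    exact = (np.mean([found[n]["unit_length"] == found[n]["planted_unit_length"]
                      for n in found]) if found else 0.0)
    truth_patterns = {p: int(g) for p, g in manifest.get("pattern_of_pair", {}).items()}
    run_patterns = {p: int(g) for p, g in
                    summary.get("fishmap", {}).get("pattern_of_pair", {}).items()}
    ri = (rand_index(truth_patterns, run_patterns)
          if truth_patterns and sorted(truth_patterns) == sorted(run_patterns) else 0.0)
    return dict(recall=recall, precision=precision,
                unit_length_exact=float(exact), rand_index=ri)
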