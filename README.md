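# elimrep

Discovery and chromosomal mapping of germline-restricted tandem-repeat
families, modelled on programmed DNA elimination in the Japanese hagfish.

## The problem

In hagfish, germ cells carry 2n = 52 chromosomes but presumptive somatic
cells retain only 2n = 36: sixteen **eliminated (E-)chromosomes**, built
largely from a small set of satellite DNA families (EEEb1–EEEb10), are
discarded early in development, removing roughly a fifth of the germline
genome. Studying this system computationally requires a chain of standard
but fiddly steps, which this package implements as a tested pipeline:

1. **Differential k-mer discovery** (`elimrep.kmerdiff`): canonical k-mer
   frequencies are compared between germline and somatic read sets. A
   k-mer is germline-enriched when, after depth normalisation,
   `germ / (soma + pseudocount) ≥ 100` — the 100-fold criterion used to
   identify eliminated repeat families. Enriched k-mers are reassembled by
   greedy unique-extension unitigging; a tandem satellite closes into a
   circular contig whose **smallest period** is the monomer unit length,
   and monomers are reported as the lexicographically minimal rotation
   over both strands, so calls are comparable across runs.
2. **Monomer characterisation** (`elimrep.repchar`): star alignment of
   cloned monomer copies, majority consensus, mean pairwise divergence
   with gap sites excluded per pair, GC content, direct repeats, ORF
   scanning in tandem context, and substitution counts between germline
   and somatic consensus sequences after rotation/strand normalisation.
3. **In-silico PCR** (`elimrep.ispcr`): an internal primer pair on a
   tandem array yields the classic monomer/dimer/multimer ladder; band
   sizes step by exactly one unit length and off-ladder bands are flagged
   as variants.
4. **FISH-profile classification** (`elimrep.fishmap`): per-chromosome
   1-D intensity profiles are segmented (median + 3×MAD over background
   bins), each probe is classified against the reference probe's mask into
   *coincident / largely overlapping / half overlapping / peripheral /
   dispersed / absent* (cut-offs 0.90 / 0.60 / 0.35 on the overlap
   fraction), terminal-cluster symmetry is scored as the Pearson
   correlation of a profile with its reversal (isochromosome signature),
   chromosome pairs are partitioned into karyogram patterns by signature
   equality, and fiber-level interspersion is quantified as the fraction
   of adjacent probe segments with different labels, with a permutation
   p-value.
5. **Synthetic study generator** (`elimrep.synthdata`): seeded germline
   (2n = 52) and somatic (2n = 36) genomes at desk scale (50 kb
   E-chromosomes, 100 kb retained chromosomes) with ten repeat families
   placed in six distinct per-pair patterns, interleaved at sub-bin scale
   so fibers are interspersed; reads, clone sets, and intensity profiles
   all come with a ground-truth manifest for parameter-recovery scoring.
6. **Orchestration** (`elimrep.pipeline`, `elimrep` CLI): one YAML config,
   one master seed, byte-identical summaries across reruns.

## Worked example

```python
from elimrep import pipeline
summary = pipeline.run_all(pipeline.RunConfig(seed=0))
d = summary["discovery"]
print(d["recall"], d["precision"], summary["fishmap"]["n_patterns"])
# 1.0 1.0 6
print([(f["matched_family"], f["unit_length"]) for f in d["families"][:3]])
# [('EEEb1', 171), ('EEEb2', 53), ('EEEb3', 89)]
print(summary["ispcr"]["EEEb8"]["band_sizes"], summary["ispcr"]["EEEb8"]["labels"])
# [47, 94, 141] ['monomer', 'dimer', 'trimer']
```

All nine germline-restricted families are rediscovered from reads alone
with exact unit lengths (recall and precision 1.0), the eight E-chromosome
pairs fall into exactly six karyogram patterns (two patterns shared by two
pairs each), and the 47 bp-unit family's PCR ladder reads
monomer/dimer/trimer. The tenth family (EEEb10) is deliberately *not*
germline-restricted — it carries dispersed copies on all chromosomes — and
is correctly rejected by the 100-fold filter while being called
`dispersed` on retained-chromosome profiles.

The same stages are available from a shell:

```bash
elimrep simulate --outdir sim --seed 1
elimrep discover --germ sim/germline_reads.fastq --soma sim/somatic_reads.fastq -o disc
elimrep fishmap --profiles sim/profiles.tsv -o fish
elimrep run --seed 1 --outdir run1
```

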