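# Methods

## Study system and scope

The package models a chromosome-elimination system: a germline karyotype of
2n = 52 in which sixteen chromosomes (eight pairs) are discarded from
somatic lineages, leaving 2n = 36. The eliminated chromosomes are composed
largely of ten tandem-repeat (satellite) families; one of them also leaves
dispersed single copies on the somatically retained chromosomes. The
pipeline covers the sequence-level workflow only — k-mer discovery from
reads, monomer reconstruction and statistics, in-silico PCR, and 1-D
intensity-profile classification. Wet-lab protocol modelling, microscopy
image processing, and homology searches against external databases are out
of scope.

## Synthetic genome generator

**Karyotype and scale.** Chromosome counts follow the real karyotype
(52/36, sixteen E-chromosomes); lengths are scaled to desk size: 50 kb per
E-chromosome and 100 kb per retained chromosome. At these lengths the
eliminated fraction is 18.2% of the germline genome, approximating rather
than enforcing the ~21% of the real system; the realised value is recorded
in the ground-truth manifest. Homologs within a pair are byte-identical
(no heterozygosity is modelled), and the somatic genome is the germline
genome minus the eliminated chromosomes, byte-identical on what remains.

**Repeat families.** Ten families with unit lengths 171/53/89/64/101/143/
360/47/84/120 bp. The last four use the published unit lengths of the four
novel families and are *synthetic primer-anchored stand-ins*: each monomer
begins with the real forward primer and ends with the reverse complement
of the real reverse primer from the published primer table, with a random
interior tuned to the reported GC content. They are surrogates for the
deposited consensus sequences (which require a network fetch this package
does not perform), so deposit-specific statistics (e.g. their exact GC
percentages) are not claimed — only machinery-level recovery of planted
ground truth is tested. All monomers are guaranteed primitive (not a power
of a shorter word), so unit lengths are well defined.

**Placement layout.** Each E-chromosome is tiled in 2 kb bins. Five
terminal bins per arm interleave blocks of the reference family (EEEb1)
with the other families; three adjacent bins carry families without the
reference. Blocks are whole monomer copies (1–6 units) at a **random
rotation phase**, separated by ≥ 20 bp of random background. Three design
constraints drive this layout:

- *Exact overlap fractions*: every terminal "inside" bin contains the
  reference family, so the reference mask is exactly the inside bins and
  each family's overlap fraction is a ratio of placed bases — 1.0 for the
  coincident family, 0.71–0.83 for the largely-overlapping group, 0.50 for
  the half-overlapping group, and 0–0.30 for the peripheral group,
  mirroring the four co-localization groups.
- *Clean discovery*: random rotation phases and background spacers make
  block-junction k-mers locus-specific, so they fall far below the
  100-fold enrichment criterion and each family's de Bruijn cycle
  assembles into a single circular contig. (With a shared phase, the four
  possible one-base-overhang junction k-mers per family end recur hundreds
  of times and pass the filter — a lesson recorded here because it shapes
  the generator's defaults.)
- *Fiber realism*: at 50 bp resolution the blocks of different families
  alternate along the chromatin fiber, giving interspersion indices near 1.

Six patterns are planted across the eight pairs (patterns 1 and 2 used
twice, per the reference karyogram): pattern 2 adds a symmetric interior
island; patterns 3 and 4 each lack one family (and pattern 4 moves one
family fully inside the reference); pattern 5 moves one family fully
outside; pattern 6 has a single terminal cluster (no mirrored arm), the
non-isochromosome case. The paper-level source gives no copy numbers or
densities, so these are generator choices recorded in the manifest.

**Dispersed family.** EEEb10-like copies are placed as Poisson-distributed
single units (default density 1 per 10 kb) on every chromosome. At desk
scale its germline:somatic copy ratio is ~1.5, far below the 100-fold
criterion, so the generator marks it `expected_discoverable = false` and
recall/precision are computed over the nine germline-restricted families.
On real data this family passes the filter because its germline copy
number is orders of magnitude higher — a scale effect of the simulation,
not of the method.

**Reads and clones.** Single-end reads of 100 bp, uniform over both
strands, constant Q40 qualities, optional uniform substitution errors;
total bases equal coverage × genome size by construction. Clone sets apply
independent per-site substitutions to a uniformly random different base
(closed-form expected pairwise divergence `2p(1−p) + (2/3)p²`); an
optional indel mode (rate 10% of the substitution rate, geometric lengths)
exists for exercising gap handling.

## Discovery

Canonical k-mers (k odd, default 21; lexicographic min of k-mer and
reverse complement) are counted with a vectorised 2-bit Horner encoding;
windows containing non-ACGT bases are skipped. The enrichment filter
scales somatic counts to germline depth, adds a pseudocount of 1 on the
somatic side, and keeps k-mers with ratio ≥ 100 and germline count ≥ 10
(the count floor suppresses sequencing-error k-mers; the source criterion
states only the 100-fold ratio). Assembly is greedy unique-extension
unitigging over (k−1)-overlaps within the enriched set — sufficient for
tandem satellites, deliberately not a general assembler (no bubbles, no
coverage-based tip clipping). A unitig whose end re-enters its start is
circular and stored in cyclic form; the monomer is its smallest period
(border-array analysis; the smallest period is unique), normalised to the
minimal rotation over both strands (Booth's algorithm). Copy number is the
median germline count of the monomer's k-mers divided by the k-mer-adjusted
per-base depth `coverage × (L − k + 1)/L`.

## Characterisation

Star alignment: the centroid clone (minimal summed edit distance, edlib)
is globally aligned to every other clone (match +1, mismatch −1, gap open
−2, extension −0.5 — conventional values, since the original alignment
tool's parameters are unpublished; all overridable) and merged column-wise
under once-a-gap-always-a-gap. Consensus is per-column majority over
non-gap symbols; columns with a strict gap majority are dropped, base ties
break alphabetically, and a gap/base tie keeps the base (consensus rows
are conventionally gapless). Divergence excludes, per pair, columns where
either row has a gap. Percentages are reported to one decimal, rounded
half up. Substitution counts first normalise the second consensus by
rotation and strand (tandem monomers have no origin), then count mismatch
columns of a global alignment; indel columns are reported separately.
Direct repeats are maximal exact same-strand substrings (no one-character
extension still repeats) of ≥ 8 bp with two non-overlapping occurrences,
nested hits suppressed — the counts are parameter-dependent, so they are
reported, not asserted against published figures. ORFs are scanned on the
doubled sequence (tandem context) in six frames with a 30-codon floor;
note that random sequence of satellite length frequently contains such
ORFs, so "no ORFs" is a property of real consensus sequences, not of
random stand-ins.

## In-silico PCR

Primer sites allow up to 2 substitution mismatches but require the 5 bases
at the primer's 3' end to match exactly (extension anchor). Products pair
a plus-strand forward site with a minus-strand reverse site downstream,
capped at 3 kb (gel-resolvable range with headroom); sizes within 1 bp
collapse into one band. Bands are labelled monomer/dimer/k-mer within ±10%
of k × unit, otherwise flagged `variant`. Thermodynamics (Tm, cycling
conditions) are not modelled.

## Profile classification

Segmentation: background bins are those at or below the 75th percentile;
threshold = background median + 3 × MAD (unscaled); positive bins must
also strictly exceed the median (so flat profiles segment empty), and runs
shorter than 2 bins are dropped. Classification order: **absent** (target
total below 5% of the reference probe's total on that chromosome, or
zero), **dispersed** (> 50% of bins positive with maximum intensity below
2× the segmentation threshold — the weak genome-wide signal case), then by
overlap fraction: **coincident** ≥ 0.90, **largely overlapping** ≥ 0.60,
**half overlapping** ≥ 0.35, else **peripheral**; boundaries are inclusive
on the lower edge. These cut-offs formalise qualitative microscopy
categories and are exposed in `ClassifyConfig`. Symmetry is the Pearson
correlation of a profile with its reversal (flag at ≥ 0.80; zero-variance
profiles score 0). Homolog profiles are oriented so the reference
centroid falls in the first half, then averaged per pair; pairs with equal
per-probe signatures (call, symmetry flag, cluster count) share a pattern.
Karyogram profiles are rendered **without** the dispersed family's
background copies, matching how a karyogram emphasises intense signals;
the full render (used for conservation checks and the dispersed call)
includes them. The fiber interspersion index — alternating fraction of
adjacent probe segments, permutation null on the label order — is this
package's formalisation of the qualitative "intermingled signals"
observation; note a two-probe fiber needs at least four segments per probe
before perfect alternation can reach p ≤ 0.05.

## Determinism and problem sizes

One master seed feeds every stage through spawned child seeds; two runs
with the same config produce byte-identical summary JSON. Default problem
sizes — 4.4 Mb germline genome, 10× coverage, 200-copy arrays at 50× in
the recovery scenarios, 200 Monte-Carlo replicates for the divergence
check, 1000 label permutations for the fiber test — keep a full pipeline
run around half a minute on one CPU while leaving every k-mer count far
from threshold boundaries.

## Known limitations

- Homologs are identical; no polymorphism between haplotypes.
- The read simulator has substitution errors only (no indels, no quality
  decay), and reads are single-end.
- The assembler targets satellite cycles; interspersed transposable
  elements or low-copy repeats are out of scope.
- Profile classification operates on 1-D line scans; no 2-D image
  segmentation or pixel-level colocalization statistics.
- The dispersed family cannot pass the 100-fold filter at desk scale (see
  above); conclusions about filter behaviour at realistic copy numbers
  rest on the criterion itself, not on this simulation.
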