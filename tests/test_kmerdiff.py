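"""Differential k-mer discovery: counting, filtering, assembly, monomer calls."""
import numpy as np
import pytest

from elimrep import kmerdiff, synthdata
from elimrep._seq import canonical, kmer_to_int, revcomp

from conftest import tandem_scenario


def brute_force_counts(seqs, k):
    """Independent oracle: dict counting with Biopython reverse complements."""
    from Bio.Seq import Seq

    counts = {}
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            if set(km) - set("ACGT"):
                continue
            rc = str(Seq(km).reverse_complement())
            canon = min(km, rc)
            counts[canon] = counts.get(canon, 0) + 1
    return counts


class TestCounting:
    def test_four_base_read_collapses_to_one_canonical_kmer(self):
        t = kmerdiff.count_kmers(["ACGTACGTACGTA"][0:1], k=11)
        # enumerate by hand via the oracle
        assert dict(t.items_decoded()) == brute_force_counts(["ACGTACGTACGTA"], 11)

    def test_read_and_reverse_complement_give_identical_tables(self):
        reads = ["ACGTTGCAACGGTTACGTACG", "TTTTACGTACGGGGCATCATA"]
        a = kmerdiff.count_kmers(reads, 13)
        b = kmerdiff.count_kmers([revcomp(r) for r in reads], 13)
        assert np.array_equal(a.kmers, b.kmers)
        assert np.array_equal(a.counts, b.counts)

    def test_total_kmers_counts_every_window(self):
        reads = ["ACGTACGTACGTACG", "TTGCATGCATGCA"]
        t = kmerdiff.count_kmers(reads, 11)
        assert t.total_kmers == sum(max(0, len(r) - 10) for r in reads)
        assert t.total_kmers == int(t.counts.sum())

    def test_even_k_rejected(self):
        with pytest.raises(ValueError, match="invalid-parameter"):
            kmerdiff.count_kmers(["ACGTACGTACGTACGT"], 12)

    def test_read_counting_matches_brute_force_on_tiling_reads(self, default_genomes):
        # full single-pass coverage: reads tile the chromosome with k-1 bp
        # overlaps, so read k-mer counts equal direct genome counts exactly
        _, germ, _ = default_genomes
        k, rl = 21, 100
        seq = germ.chromosome("E1a").sequence[:20_000 + rl - (rl - k + 1)]
        step = rl - k + 1
        reads = [seq[i:i + rl] for i in range(0, len(seq) - rl + 1, step)]
        table = kmerdiff.count_kmers(reads, k)
        windows = [s for s in reads]
        oracle = brute_force_counts(windows, k)
        assert dict(table.items_decoded()) == oracle


class TestEnrichment:
    @staticmethod
    def _table(k, counts, total=None):
        items = sorted((kmer_to_int(canonical(km)), c) for km, c in counts.items())
        kmers = np.array([i for i, _ in items], dtype=np.uint64)
        cts = np.array([c for _, c in items], dtype=np.int64)
        return kmerdiff.KmerCountTable(k, kmers, cts,
                                       total if total else int(cts.sum()))

    def test_ratio_formula_hand_examples(self):
        km = "ACGTACGTACGTACGTACGTA"
        germ = self._table(21, {km: 500}, total=10_000)
        soma = self._table(21, {km: 2}, total=10_000)
        es = kmerdiff.enrichment_filter(germ, soma, 100.0, min_germline_count=10)
        # 500 / (2 + 1) = 166.7 >= 100 -> retained
        assert len(es) == 1 and es.ratios[0] == pytest.approx(500 / 3)

        soma0 = self._table(21, {"TTTTTTTTTTTTTTTTTTTTG": 4}, total=10_000)
        germ50 = self._table(21, {km: 50}, total=10_000)
        es2 = kmerdiff.enrichment_filter(germ50, soma0, 100.0, 10)
        # 50 / (0 + 1) = 50 < 100 -> excluded
        assert len(es2) == 0

    def test_identical_tables_yield_empty_set(self):
        t = self._table(21, {"ACGTACGTACGTACGTACGTA": 300,
                             "GGGGCCCCAAAATTTTGGGGA": 200})
        assert len(kmerdiff.enrichment_filter(t, t, 100.0, 10)) == 0

    def test_mismatched_k_rejected(self):
        a = self._table(21, {"ACGTACGTACGTACGTACGTA": 10})
        b = self._table(19, {"ACGTACGTACGTACGTACG": 10})
        with pytest.raises(ValueError, match="invalid-input"):
            kmerdiff.enrichment_filter(a, b)

    def test_raising_threshold_never_adds_members(self):
        rng = np.random.default_rng(0)
        kms = {"".join("ACGT"[b] for b in rng.integers(0, 4, 21)): int(c)
               for c in rng.integers(1, 2000, size=200)}
        germ = self._table(21, kms)
        soma = self._table(21, {k: max(1, v // 50) for k, v in list(kms.items())[:100]})
        prev = None
        for thr in (10, 50, 100, 500):
            members = kmerdiff.enrichment_filter(germ, soma, thr, 1).members
            if prev is not None:
                assert members <= prev
            prev = members


class TestAssembly:
    @staticmethod
    def _enriched_from_cycle(monomer, k=5):
        doubled = monomer + monomer[:k - 1]
        codes = sorted({kmer_to_int(canonical(doubled[i:i + k]))
                        for i in range(len(monomer))})
        arr = np.array(codes, dtype=np.uint64)
        n = len(arr)
        return kmerdiff.EnrichedKmerSet(k, arr, np.full(n, 100, np.int64),
                                        np.zeros(n, np.int64), np.full(n, 100.0),
                                        100.0, 10, 1.0)

    def test_primitive_cycle_assembles_to_one_circular_contig(self):
        fam = synthdata.make_repeat_family("f", 47, 0.39, seed=2)
        es = self._enriched_from_cycle(fam.monomer, k=11)
        contigs = kmerdiff.assemble_enriched(es)
        assert len(contigs) == 1
        assert contigs[0].circular
        assert len(contigs[0].sequence) == 47

    def test_two_disjoint_families_give_two_contigs(self):
        a = synthdata.make_repeat_family("a", 40, 0.3, seed=3)
        b = synthdata.make_repeat_family("b", 40, 0.6, seed=4)
        ea = self._enriched_from_cycle(a.monomer, k=11)
        eb = self._enriched_from_cycle(b.monomer, k=11)
        merged_kmers = np.sort(np.concatenate([ea.kmers, eb.kmers]))
        n = len(merged_kmers)
        es = kmerdiff.EnrichedKmerSet(11, merged_kmers, np.full(n, 100, np.int64),
                                      np.zeros(n, np.int64), np.full(n, 100.0),
                                      100.0, 10, 1.0)
        contigs = kmerdiff.assemble_enriched(es)
        assert len(contigs) == 2
        assert all(c.circular for c in contigs)

    def test_empty_input_gives_empty_output(self):
        es = kmerdiff.EnrichedKmerSet(21, np.empty(0, np.uint64),
                                      np.empty(0, np.int64), np.empty(0, np.int64),
                                      np.empty(0), 100.0, 10, 1.0)
        assert kmerdiff.assemble_enriched(es) == []


class TestMonomerCalls:
    def test_smallest_period_of_circular_contig(self):
        contig = kmerdiff.RepeatContig("ACGACGACG", circular=True,
                                       mean_kmer_count=10.0)
        call = kmerdiff.infer_monomer(contig, k=3)
        assert call.unit_length == 3
        assert call.canonical_monomer == "ACG"

    def test_linear_contig_needs_two_full_units(self):
        contig = kmerdiff.RepeatContig("ACGTTGCA", circular=False,
                                       mean_kmer_count=1.0)
        assert kmerdiff.infer_monomer(contig, k=3) is None

    def test_call_is_rotation_invariant(self):
        fam = synthdata.make_repeat_family("f", 60, 0.4, seed=5)
        m = fam.monomer
        calls = set()
        for r in (0, 7, 31):
            rot = m[r:] + m[:r]
            contig = kmerdiff.RepeatContig(rot, circular=True, mean_kmer_count=5.0)
            call = kmerdiff.infer_monomer(contig, k=9)
            calls.add((call.unit_length, call.canonical_monomer))
        assert len(calls) == 1


class TestEndToEnd:
    def test_discovery_recovers_planted_monomer_and_copy_number(self, families):
        fam = families["EEEb8"]  # 47 bp unit
        germ_reads, soma_reads = tandem_scenario(fam.monomer, copies=100,
                                                 coverage=30, seed=21)
        per_base = 30 * (100 - 21 + 1) / 100
        enriched, contigs, calls = kmerdiff.discover_monomers(
            germ_reads, soma_reads, k=21, per_base_coverage=per_base)
        assert len(calls) == 1
        assert calls[0].unit_length == 47
        assert calls[0].canonical_monomer == fam.canonical
        assert calls[0].estimated_copies == pytest.approx(100, rel=0.15)

    def test_reverse_complementing_reads_changes_no_call(self, families):
        fam = families["EEEb9"]
        germ_reads, soma_reads = tandem_scenario(fam.monomer, copies=80,
                                                 coverage=25, seed=33)
        _, _, calls_fwd = kmerdiff.discover_monomers(germ_reads, soma_reads, k=21)
        flipped = synthdata.ReadSet([(n, revcomp(s)) for n, s in germ_reads.reads],
                                    germ_reads.read_length, germ_reads.coverage,
                                    germ_reads.error_rate, germ_reads.seed)
        _, _, calls_rev = kmerdiff.discover_monomers(flipped, soma_reads, k=21)
        assert [(c.unit_length, c.canonical_monomer) for c in calls_fwd] == \
            [(c.unit_length, c.canonical_monomer) for c in calls_rev]

    def test_somatic_kmers_are_subset_of_germline_genome(self, default_genomes):
        _, germ, soma = default_genomes
        k = 21
        gt = kmerdiff.count_genome_kmers([c.sequence for c in germ.chromosomes], k)
        reads = synthdata.simulate_reads(soma, 0.2, 100, 0.0, seed=9)
        st_ = kmerdiff.count_kmers(reads, k)
        idx = np.searchsorted(gt.kmers, st_.kmers)
        idx = np.minimum(idx, len(gt.kmers) - 1)
        assert bool(np.all(gt.kmers[idx] == st_.kmers))

    def test_zero_coverage_copy_estimate_rejected(self):
        call = kmerdiff.MonomerCall(5, "ACGTA")
        es = kmerdiff.EnrichedKmerSet(5, np.empty(0, np.uint64),
                                      np.empty(0, np.int64), np.empty(0, np.int64),
                                      np.empty(0), 100.0, 10, 1.0)
        with pytest.raises(ValueError, match="invalid-parameter"):
            kmerdiff.estimate_copy_number(call, es, 0.0)
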