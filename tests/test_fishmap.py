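"""FISH-profile classification: segmentation, overlap classes, karyogram, fibers."""
import numpy as np
import pytest

from elimrep import fishmap, synthdata


def two_pulse_profile(n=40, pulses=((2, 6), (32, 36)), height=10.0):
    v = np.zeros(n)
    for a, b in pulses:
        v[a:b] = height
    return v


class TestSegmentation:
    def test_all_zero_profile_has_empty_mask(self):
        assert not fishmap.segment_signal(np.zeros(30)).any()

    def test_two_rectangular_pulses_give_two_runs(self):
        mask = fishmap.segment_signal(two_pulse_profile())
        assert fishmap.runs(mask) == [(2, 6), (32, 36)]

    def test_noisy_pulse_recovered_within_one_bin(self):
        rng = np.random.default_rng(3)
        v = np.full(60, 1.0) + rng.normal(0, 0.1, 60)
        v[20:30] += 1.5
        mask = fishmap.segment_signal(np.maximum(v, 0))
        r = fishmap.runs(mask)
        assert len(r) == 1
        a, b = r[0]
        assert abs(a - 20) <= 1 and abs(b - 30) <= 1

    def test_short_runs_removed(self):
        v = np.zeros(30)
        v[5] = 10.0
        v[10:14] = 10.0
        assert fishmap.runs(fishmap.segment_signal(v)) == [(10, 14)]

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="invalid-input"):
            fishmap.segment_signal(np.zeros(5))


class TestOverlap:
    def test_target_inside_reference_is_one(self):
        ref_mask = np.zeros(40, bool)
        ref_mask[2:6] = True
        t = np.zeros(40)
        t[3:5] = 4.0
        assert fishmap.overlap_fraction(t, ref_mask) == 1.0

    def test_disjoint_supports_is_zero(self):
        ref_mask = np.zeros(40, bool)
        ref_mask[2:6] = True
        t = np.zeros(40)
        t[20:24] = 4.0
        assert fishmap.overlap_fraction(t, ref_mask) == 0.0

    def test_half_mass_inside_is_half(self):
        ref_mask = np.zeros(40, bool)
        ref_mask[0:10] = True
        t = np.zeros(40)
        t[5:10] = 2.0   # 10 units inside
        t[20:25] = 2.0  # 10 units outside
        assert fishmap.overlap_fraction(t, ref_mask) == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="invalid-input"):
            fishmap.overlap_fraction(np.zeros(10), np.zeros(12, bool))


class TestClassification:
    @staticmethod
    def _target_with_fraction(frac, ref):
        # reference mask covers bins [2, 6); put frac of the target mass
        # there and the rest far away, in pulses >= 2 bins
        t = np.zeros(len(ref))
        t[2:6] = 100 * frac / 4
        t[30:34] = 100 * (1 - frac) / 4
        return t

    def test_identical_profiles_are_coincident(self):
        ref = two_pulse_profile(40, ((2, 6),), 10.0)
        call = fishmap.classify_localization(ref, ref)
        assert call.call == "coincident"
        assert call.overlap_fraction == 1.0

    @pytest.mark.parametrize("frac,expected", [
        (0.34, "peripheral"),
        (0.35, "half_overlapping"),
        (0.59, "half_overlapping"),
        (0.60, "largely_overlapping"),
        (0.89, "largely_overlapping"),
        (0.90, "coincident"),
    ])
    def test_class_boundaries_inclusive_on_lower_edge(self, frac, expected):
        ref = two_pulse_profile(40, ((2, 6),), 10.0)
        t = self._target_with_fraction(frac, ref)
        call = fishmap.classify_localization(t, ref)
        assert call.call == expected
        assert call.overlap_fraction == pytest.approx(frac)

    def test_weak_genome_wide_signal_is_dispersed(self):
        rng = np.random.default_rng(1)
        ref = np.maximum(rng.normal(0.1, 0.02, 50), 0)  # retained: no reference
        t = np.maximum(rng.normal(0.1, 0.02, 50), 0)
        t[7] += 0.06  # one weak dispersed copy
        call = fishmap.classify_localization(t, ref)
        assert call.call == "dispersed"

    def test_empty_target_is_absent(self):
        ref = two_pulse_profile(40, ((2, 6),), 10.0)
        call = fishmap.classify_localization(np.zeros(40), ref)
        assert call.call == "absent"

    def test_target_below_detection_floor_is_absent(self):
        ref = two_pulse_profile(40, ((2, 6),), 100.0)
        t = np.zeros(40)
        t[2:6] = 1.0  # 4 units << 5% of 400
        assert fishmap.classify_localization(t, ref).call == "absent"


class TestSymmetry:
    def test_palindromic_profile_scores_one(self):
        v = np.array([0, 1, 5, 9, 5, 1, 0], float)
        assert fishmap.symmetry_score(v) == pytest.approx(1.0)

    def test_ramp_scores_minus_one(self):
        assert fishmap.symmetry_score(np.arange(20.0)) == pytest.approx(-1.0)

    def test_flat_profile_scores_zero(self):
        assert fishmap.symmetry_score(np.full(15, 3.0)) == 0.0

    def test_score_invariant_under_reversal(self):
        rng = np.random.default_rng(2)
        v = rng.random(30)
        assert fishmap.symmetry_score(v) == pytest.approx(
            fishmap.symmetry_score(v[::-1]))

    def test_single_terminal_cluster_is_asymmetric_with_one_run(self):
        v = np.zeros(25)
        v[0:5] = 8.0
        assert fishmap.symmetry_score(v) < 0.8
        assert fishmap.cluster_count(v) == 1


def make_profile_set(vectors):
    """vectors: {(chrom, probe): array}; chrom 'Xn[a|b]' -> pair Xn, eliminated."""
    meta = {}
    for chrom, _ in vectors:
        meta[chrom] = (chrom[:-1], True)
    return synthdata.ProfileSet({k: np.asarray(v, float) for k, v in vectors.items()},
                                2000, meta)


class TestKaryogram:
    def test_identical_pairs_share_one_pattern(self):
        ref = two_pulse_profile(25, ((0, 4), (21, 25)), 8.0)
        vectors = {}
        for pair in ("E1", "E2", "E3"):
            for hom in "ab":
                vectors[(f"{pair}{hom}", "EEEb1")] = ref.copy()
                vectors[(f"{pair}{hom}", "EEEb8")] = ref.copy()
        ps = make_profile_set(vectors)
        karyo = fishmap.build_karyogram(ps)
        assert karyo.n_patterns == 1

    def test_all_distinct_pairs_all_distinct_patterns(self):
        ref = two_pulse_profile(25, ((0, 4), (21, 25)), 8.0)
        layouts = {
            "E1": {(0, 4): 8.0},                 # fully inside -> coincident
            "E2": {(6, 10): 8.0},                # fully outside -> peripheral
            "E3": {(0, 4): 8.0, (8, 12): 8.0},   # half in -> half_overlapping
        }
        vectors = {}
        for pair, pulses in layouts.items():
            probe2 = np.zeros(25)
            for (a, b), h in pulses.items():
                probe2[a:b] = h
            for hom in "ab":
                vectors[(f"{pair}{hom}", "EEEb1")] = ref.copy()
                vectors[(f"{pair}{hom}", "EEEb8")] = probe2.copy()
        karyo = fishmap.build_karyogram(make_profile_set(vectors))
        assert karyo.n_patterns == 3

    def test_missing_probe_rejected(self):
        ref = two_pulse_profile(25, ((0, 4), (21, 25)), 8.0)
        vectors = {("E1a", "EEEb1"): ref, ("E1b", "EEEb1"): ref,
                   ("E1a", "EEEb8"): ref}
        with pytest.raises(ValueError, match="invalid-input"):
            fishmap.build_karyogram(make_profile_set(vectors))

    def test_pattern_count_invariant_to_input_order(self, default_genomes, families):
        _, germ, _ = default_genomes
        probes = sorted(families)
        ps = synthdata.render_fish_profiles(germ, probes, include_dispersed=False)
        karyo = fishmap.build_karyogram(ps)
        shuffled = synthdata.ProfileSet(
            dict(reversed(list(ps.intensities.items()))), ps.bin_bp,
            dict(reversed(list(ps.chromosome_meta.items()))))
        karyo2 = fishmap.build_karyogram(shuffled)
        assert karyo.n_patterns == karyo2.n_patterns
        assert karyo.pattern_of_pair == karyo2.pattern_of_pair

    def test_end_to_end_calls_on_synthetic_profiles(self, default_genomes, families):
        # every probe is detected on E-chromosomes; on retained chromosomes
        # everything but the dispersed family is absent
        _, germ, _ = default_genomes
        probes = sorted(families)
        ps = synthdata.render_fish_profiles(germ, probes, include_dispersed=False)
        table = fishmap.classification_table(ps)
        e_rows = table[table.eliminated == 1]
        assert (e_rows[e_rows.probe == "EEEb8"].call == "coincident").all()
        retained = table[(table.eliminated == 0)
                         & (table.probe != synthdata.DISPERSED_FAMILY)]
        assert (retained.call == "absent").all()


class TestFiber:
    def test_perfectly_alternating_segments_score_one(self):
        # ABABABAB: perfect alternation has null probability 2/C(8,4) < 0.05
        a = np.zeros(80, bool)
        b = np.zeros(80, bool)
        for i in range(0, 80, 20):
            a[i:i + 8] = True
            b[i + 10:i + 18] = True
        out = fishmap.fiber_interspersion({"A": a, "B": b}, n_permutations=1000,
                                          seed=5)
        assert out is not None
        index, p = out
        assert index == 1.0
        assert p <= 0.05

    def test_blocked_arrangement_scores_one_fifth(self):
        # AAABBB: five adjacencies, one label change
        a = np.zeros(90, bool)
        b = np.zeros(90, bool)
        for i in range(3):
            a[i * 10:i * 10 + 6] = True
            b[50 + i * 10:50 + i * 10 + 6] = True
        out = fishmap.fiber_interspersion({"A": a, "B": b}, seed=1)
        index, _ = out
        assert index == pytest.approx(0.2)

    def test_single_probe_is_a_no_call(self):
        a = np.zeros(40, bool)
        a[0:5] = True
        a[20:25] = True
        assert fishmap.fiber_interspersion({"A": a}) is None

    def test_probe_with_single_segment_excluded(self):
        a = np.zeros(40, bool)
        a[0:5] = True
        a[20:25] = True
        b = np.zeros(40, bool)
        b[10:15] = True  # only one segment -> excluded
        assert fishmap.fiber_interspersion({"A": a, "B": b}) is None

    def test_synthetic_fiber_is_highly_interspersed(self, default_genomes, families):
        _, germ, _ = default_genomes
        masks = synthdata.render_fiber_masks(germ, germ.eliminated_ids[0],
                                             (0, 16000), sorted(families), bin_bp=50)
        out = fishmap.fiber_interspersion(masks, n_permutations=500, seed=2)
        assert out is not None
        index, p = out
        assert index >= 0.8
        assert p <= 0.1
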