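import numpy as np
import pytest
from scipy.stats import binom

from _util import naive_pileup_counts, other_base, random_seq
from tilling._seq import encode
from tilling.call import (TargetAmplicon, assign_read, assign_reads,
                          build_pileup, call_variants)
from tilling.pele import merge_pairs
from tilling.pool_design import LibraryDesign, expected_carrier_frequency
from tilling.simulate import (PlantedVariant, SimConfig, random_amplicon,
                              simulate_genotypes, simulate_pool_reads)


@pytest.fixture
def amplicon(rng):
    return random_amplicon(rng, "amp1", 240)


class TestAssignRead:
    def test_exact_read_maps_at_origin(self, amplicon):
        a = assign_read(amplicon.sequence, [amplicon])
        assert (a.amplicon_id, a.offset, a.mismatches) == ("amp1", 0, 0)

    def test_single_substitution_still_maps(self, amplicon):
        s = list(amplicon.sequence)
        s[100] = other_base(s[100])
        a = assign_read("".join(s), [amplicon])
        assert (a.amplicon_id, a.offset, a.mismatches) == ("amp1", 0, 1)

    def test_partial_read_with_offset(self, amplicon):
        a = assign_read(amplicon.sequence[50:200], [amplicon])
        assert (a.offset, a.mismatches) == (50, 0)

    def test_equidistant_read_is_ambiguous(self, rng):
        base = random_seq(rng, 200)
        v1, v2 = list(base), list(base)
        v1[50] = other_base(v1[50])
        v2[150] = other_base(v2[150])
        refs = [TargetAmplicon("r1", "".join(v1), (0, 200)),
                TargetAmplicon("r2", "".join(v2), (0, 200))]
        read = list(base)
        read[50], read[150] = v1[50], v2[150]  # one change from each ref
        assert assign_read("".join(read), refs) is None

    def test_high_divergence_unassigned(self, rng, amplicon):
        assert assign_read(random_seq(rng, 240), [amplicon]) is None

    def test_duplicate_reference_ids_rejected(self, amplicon):
        with pytest.raises(ValueError):
            assign_read(amplicon.sequence, [amplicon, amplicon])


class TestBuildPileup:
    def test_uniform_reference_reads(self, amplicon):
        reads = [amplicon.codes for _ in range(10)]
        asg = assign_reads(reads, [amplicon])
        pp = build_pileup(reads, asg, amplicon, "0")
        assert np.all(pp.depth == 10)
        ref = amplicon.codes
        assert np.all(pp.counts[ref, np.arange(240)] == 10)

    def test_single_alt_read(self, amplicon):
        ref = amplicon.codes
        alt = (ref[100] + 1) % 4
        reads = [ref.copy() for _ in range(10)]
        reads[0] = ref.copy()
        reads[0][100] = alt
        asg = assign_reads(reads, [amplicon])
        pp = build_pileup(reads, asg, amplicon, "0")
        assert np.all(pp.depth == 10)
        assert pp.counts[alt, 100] == 1
        assert pp.counts[ref[100], 100] == 9

    def test_n_bases_do_not_count(self, amplicon):
        read = amplicon.codes
        read[5] = 4  # N
        pp = build_pileup([read], assign_reads([read], [amplicon]),
                          amplicon, "0")
        assert pp.depth[5] == 0 and pp.depth[6] == 1

    def test_matches_naive_recount(self, rng, amplicon):
        """Pileup counts equal a brute-force per-read tally, including
        partial reads at non-zero offsets and N bases."""
        ref = amplicon.codes
        reads, offsets = [], []
        for _ in range(500):
            start = int(rng.integers(0, 60))
            length = int(rng.integers(150, 240 - start))
            r = ref[start:start + length].copy()
            mask = rng.random(length) < 0.02
            r[mask] = (r[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
            r[rng.random(length) < 0.01] = 4
            reads.append(r)
            offsets.append(start)
        asg = assign_reads(reads, [amplicon])
        assert all(a is not None and a.offset == o for a, o in zip(asg, offsets))
        pp = build_pileup(reads, asg, amplicon, "0")
        assert np.array_equal(pp.counts, naive_pileup_counts(reads, offsets, 240))


class TestCallVariants:
    def test_singleton_frequency(self, amplicon):
        ref = amplicon.codes
        alt = (ref[100] + 1) % 4
        reads = [ref.copy() for _ in range(2880)]
        for i in range(5):
            reads[i] = ref.copy()
            reads[i][100] = alt
        asg = assign_reads(reads, [amplicon])
        pp = build_pileup(reads, asg, amplicon, "0")
        calls = call_variants(pp, amplicon)
        assert len(calls) == 1
        c = calls[0]
        assert (c.variant_reads, c.total_reads) == (5, 2880)
        assert c.frequency == pytest.approx(
            expected_carrier_frequency(288, 2, 1), rel=1e-9)

    def test_pure_reference_gives_no_calls(self, amplicon):
        reads = [amplicon.codes for _ in range(12)]
        pp = build_pileup(reads, assign_reads(reads, [amplicon]), amplicon, "0")
        assert call_variants(pp, amplicon) == []

    def test_fixed_difference(self, amplicon):
        ref = amplicon.codes
        alt = (ref[7] + 2) % 4
        reads = []
        for _ in range(12):
            r = ref.copy()
            r[7] = alt
            reads.append(r)
        pp = build_pileup(reads, assign_reads(reads, [amplicon]), amplicon, "0")
        calls = call_variants(pp, amplicon)
        by_pos = {c.position: c for c in calls}
        assert by_pos[7].frequency == 1.0

    def test_frequency_conservation(self, rng, amplicon):
        """Variant reads never exceed depth, and base frequencies (ref
        included) sum to 1 wherever there is coverage."""
        ref = amplicon.codes
        reads = []
        for _ in range(300):
            r = ref.copy()
            mask = rng.random(240) < 0.05
            r[mask] = (r[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
            reads.append(r)
        pp = build_pileup(reads, assign_reads(reads, [amplicon]), amplicon, "0")
        calls = call_variants(pp, amplicon)
        depth = pp.depth
        for c in calls:
            assert 0 < c.variant_reads <= depth[c.position]
        covered = depth > 0
        freq_sum = (pp.counts[:, covered] / depth[covered]).sum(axis=0)
        assert np.allclose(freq_sum, 1.0)


class TestPlantedVariantRecovery:
    def test_singleton_frequency_within_binomial_bounds(self):
        """One heterozygous carrier in a 288-fish pool: over seeded
        replicates the called F stays inside the 99% binomial envelope
        around 1/576 (error-free reads isolate the sampling noise)."""
        base = np.random.default_rng(77)
        amp = random_amplicon(base, "amp1", 240)
        alt = other_base(amp.sequence[120])
        ok = 0
        reps = 25
        for i in range(reps):
            cfg = SimConfig(seed=900 + i, design=LibraryDesign(288),
                            amplicons=(amp,),
                            planted_variants=(PlantedVariant("amp1", 120, alt, 3),),
                            seq_error_rate=0.0, pcr_error_rate=0.0,
                            depth_per_pool=2880, dispersion=None)
            rng = np.random.default_rng(cfg.seed)
            geno = simulate_genotypes(cfg, rng)
            pr = simulate_pool_reads(cfg, range(288), amp, rng, genotypes=geno)
            batch = merge_pairs(pr.S1, pr.Q1, pr.S2, pr.Q2)
            reads = [s for s in batch.seqs if s is not None]
            asg = assign_reads(reads, [amp])
            pp = build_pileup(reads, asg, amp, "0")
            calls = {(c.position, c.alt_base): c for c in call_variants(pp, amp)}
            c = calls.get((120, alt))
            if c is None:
                continue
            lo, hi = binom.ppf([0.005, 0.995], c.total_reads, 1 / 576)
            ok += lo <= c.variant_reads <= hi
        assert ok >= reps - 1
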