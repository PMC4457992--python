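import numpy as np
import pytest

from _util import other_base
from tilling._seq import decode
from tilling.call import assign_reads, build_pileup, call_variants
from tilling.pele import merge_pairs
from tilling.pool_design import LibraryDesign
from tilling.simulate import (ADAPTER, PlantedVariant, Polymorphism,
                              PoolReads, SimConfig, random_amplicon,
                              simulate_genotypes, simulate_library,
                              simulate_pool_reads, write_truth)


@pytest.fixture
def amplicon():
    return random_amplicon(np.random.default_rng(42), "amp1", 240)


def small_cfg(amplicon, **kw):
    defaults = dict(seed=101, design=LibraryDesign(288),
                    amplicons=(amplicon,), depth_per_pool=2000,
                    dispersion=None)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGenotypes:
    def test_planted_only(self, amplicon):
        alt = other_base(amplicon.sequence[50])
        cfg = small_cfg(amplicon,
                        planted_variants=(PlantedVariant("amp1", 50, alt, 7),))
        geno = simulate_genotypes(cfg, np.random.default_rng(0))
        assert set(geno) == {7}
        (gv,) = geno[7]
        assert (gv.position, gv.alt, gv.copies, gv.kind) == (50, alt, 1, "planted")

    def test_all_reference_when_nothing_planted(self, amplicon):
        cfg = small_cfg(amplicon)
        assert simulate_genotypes(cfg, np.random.default_rng(0)) == {}

    def test_polymorphism_carrier_count_binomial(self, amplicon):
        """At population frequency 0.5 in 288 diploids the carrier allele
        count stays within 4 sigma of 288."""
        alt = other_base(amplicon.sequence[60])
        cfg = small_cfg(amplicon,
                        polymorphisms=(Polymorphism("amp1", 60, alt, 0.5),))
        geno = simulate_genotypes(cfg, np.random.default_rng(3))
        alleles = sum(gv.copies for fish in geno.values() for gv in fish)
        mean, sd = 576 * 0.5, np.sqrt(576 * 0.25)
        assert abs(alleles - mean) < 4 * sd

    def test_invalid_planted_position_rejected(self, amplicon):
        with pytest.raises(ValueError):
            small_cfg(amplicon,
                      planted_variants=(PlantedVariant("amp1", 900, "A", 0),))


class TestSimulatePoolReads:
    def test_error_free_pool_is_pure_reference(self, amplicon):
        cfg = small_cfg(amplicon, seq_error_rate=0.0, pcr_error_rate=0.0,
                        depth_per_pool=300)
        rng = np.random.default_rng(cfg.seed)
        pr = simulate_pool_reads(cfg, range(288), amplicon, rng, genotypes={})
        batch = merge_pairs(pr.S1, pr.Q1, pr.S2, pr.Q2)
        assert batch.n_merged == pr.n_pairs
        assert np.all(batch.identity == 1.0)
        for s in batch.seqs:
            assert decode(s) == amplicon.sequence

    def test_adapter_padding_when_fragment_shorter_than_read(self, amplicon):
        cfg = small_cfg(amplicon, seq_error_rate=0.0, pcr_error_rate=0.0,
                        depth_per_pool=5, read_len=250)
        rng = np.random.default_rng(cfg.seed)
        pr = simulate_pool_reads(cfg, range(288), amplicon, rng, genotypes={})
        assert pr.S1.shape == (5, 250)
        assert decode(pr.S1[0][240:]) == ADAPTER[:10]

    def test_planted_carrier_frequency(self, amplicon):
        """Error-free reads from a pool with one het carrier put the alt
        count within binomial bounds of depth/576."""
        alt = other_base(amplicon.sequence[100])
        cfg = small_cfg(amplicon, seq_error_rate=0.0, pcr_error_rate=0.0,
                        depth_per_pool=5760,
                        planted_variants=(PlantedVariant("amp1", 100, alt, 0),))
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            geno = simulate_genotypes(cfg, rng)
            pr = simulate_pool_reads(cfg, range(288), amplicon, rng,
                                     genotypes=geno)
            assert pr.template_variants == {(100, alt): pytest.approx(1 / 576)}
            alt_code = "ACGT".index(alt)
            counts.append(int((pr.S1[:, 100] == alt_code).sum()))
        mean = np.mean(counts)
        assert 5760 / 1200 <= mean <= 5760 / 300

    def test_pcr_noise_mass_below_noise_floor(self, amplicon):
        """Realized PCR-layer variant frequencies concentrate below 1/1000
        (the empirical noise floor) at default rates."""
        cfg = small_cfg(amplicon, seq_error_rate=0.0, depth_per_pool=8000)
        below = total = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            pr = simulate_pool_reads(cfg, range(288), amplicon, rng,
                                     genotypes={})
            for pos, alt, _ in pr.pcr_lineages:
                c = int((pr.S1[:, pos] == "ACGT".index(alt)).sum())
                total += 1
                below += (c / pr.n_pairs) < 1e-3
            for pos, alt in pr.pcr_read_errors:
                total += 1
                c = int((pr.S1[:, pos] == "ACGT".index(alt)).sum())
                below += (c / pr.n_pairs) < 1e-3
        assert total > 0
        assert below / total >= 0.9

    def test_byte_identical_determinism(self, amplicon):
        alt = other_base(amplicon.sequence[100])
        cfg = small_cfg(amplicon,
                        planted_variants=(PlantedVariant("amp1", 100, alt, 0),))

        def run():
            rng = np.random.default_rng(cfg.seed)
            geno = simulate_genotypes(cfg, rng)
            return simulate_pool_reads(cfg, range(288), amplicon, rng,
                                       genotypes=geno)

        a, b = run(), run()
        for attr in ("S1", "Q1", "S2", "Q2"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert a.pcr_lineages == b.pcr_lineages
        assert a.pcr_read_errors == b.pcr_read_errors


class TestTruthTables:
    def test_pool_attribution(self, amplicon):
        alt = other_base(amplicon.sequence[100])
        cfg = SimConfig(seed=1, design=LibraryDesign(1152),
                        amplicons=(amplicon,),
                        planted_variants=(PlantedVariant("amp1", 100, alt, 700),),
                        dispersion=None)
        geno = simulate_genotypes(cfg, np.random.default_rng(1))
        truth = write_truth(cfg, geno)
        assert len(truth) == 1
        row = truth.iloc[0]
        assert row["pool_id"] == 700 // 288
        assert row["expected_pool_freq"] == pytest.approx(1 / 576)
        assert row["pos_1based"] == 101

    def test_empty_truth(self, amplicon):
        truth = write_truth(small_cfg(amplicon), {})
        assert len(truth) == 0

    def test_three_variants_three_pools(self, amplicon):
        ref = amplicon.sequence
        cfg = SimConfig(seed=1, design=LibraryDesign(864),
                        amplicons=(amplicon,),
                        planted_variants=tuple(
                            PlantedVariant("amp1", p, other_base(ref[p]), f)
                            for p, f in [(10, 0), (20, 300), (30, 600)]),
                        dispersion=None)
        truth = write_truth(cfg, simulate_genotypes(cfg, np.random.default_rng(1)))
        assert sorted(truth["pool_id"]) == [0, 1, 2]


class TestEndToEnd:
    def test_singleton_recovered_with_polymorphism_and_noise_separated(self):
        """Merged pipeline on a simulated 288-fish pool: the planted
        singleton passes while a 5% founder polymorphism is filtered as
        polymorphism (smoke-scale version of the screen property)."""
        from tilling.screen import ScreenConfig, apply_screen

        base = np.random.default_rng(5150)
        amp = random_amplicon(base, "amp1", 240)
        alt = other_base(amp.sequence[120])
        poly_alt = other_base(amp.sequence[30])
        ok_singleton = ok_poly = 0
        reps = 10
        for i in range(reps):
            cfg = SimConfig(
                seed=3000 + i, design=LibraryDesign(288), amplicons=(amp,),
                planted_variants=(PlantedVariant("amp1", 120, alt, 5),),
                polymorphisms=(Polymorphism("amp1", 30, poly_alt, 0.05),),
                dispersion=None)
            rng = np.random.default_rng(cfg.seed)
            geno = simulate_genotypes(cfg, rng)
            pr = simulate_pool_reads(cfg, range(288), amp, rng, genotypes=geno)
            batch = merge_pairs(pr.S1, pr.Q1, pr.S2, pr.Q2)
            reads = [s for s in batch.seqs if s is not None]
            pp = build_pileup(reads, assign_reads(reads, [amp]), amp, "0")
            calls = call_variants(pp, amp)
            apply_screen(calls, ScreenConfig())
            status = {(c.position, c.alt_base): c.filter_status for c in calls}
            ok_singleton += status.get((120, alt)) == "pass"
            ok_poly += status.get((30, poly_alt)) == "polymorphism"
        assert ok_singleton >= 9
        assert ok_poly == reps


class TestSimulateLibrary:
    def test_two_pool_library_shapes(self, amplicon):
        cfg = SimConfig(seed=8, design=LibraryDesign(576),
                        amplicons=(amplicon,), depth_per_pool=50,
                        dispersion=None)
        plans, geno, pools = simulate_library(cfg)
        assert len(plans) == 2
        assert set(pools) == {(0, "amp1"), (1, "amp1")}
        assert all(pr.n_pairs == 50 for pr in pools.values())

    def test_dispersion_varies_depth_deterministically(self, amplicon):
        from tilling.simulate import AmplificationDispersion

        cfg = SimConfig(seed=8, design=LibraryDesign(576),
                        amplicons=(amplicon,), depth_per_pool=400,
                        dispersion=AmplificationDispersion())
        _, _, pools = simulate_library(cfg)
        depths = sorted(pr.n_pairs for pr in pools.values())
        _, _, pools2 = simulate_library(cfg)
        assert depths == sorted(pr.n_pairs for pr in pools2.values())
        assert depths[0] != depths[1]  # lognormal factors differ by pool
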