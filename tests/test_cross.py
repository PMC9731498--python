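"""Simulator: recombination, Mendelian segregation, expected VAF, read sampling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridscar import (
    GenomeModel,
    InstabilityEvent,
    SimConfig,
    StrainCatalog,
    expected_vaf,
    sample_reads,
    simulate_embryo,
    simulate_f1_gamete,
    simulate_litter,
    substream,
    whole_chromosome_event,
)
from hybridscar.cross import GENOTYPE_PROBS, diplotype_segments


def mean_abs_dev_binomial(d: int) -> float:
    """Exact E|K/d - 1/2| for K ~ Binomial(d, 1/2), by direct summation."""
    return sum(abs(k / d - 0.5) * math.comb(d, k) / 2 ** d for k in range(d + 1))


class TestGametes:
    def test_zero_map_length_gives_single_strain_chromosome(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=0.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            mosaic = simulate_f1_gamete(g, rng)
            assert len(mosaic.segments["chr1"]) == 1

    def test_breakpoint_count_matches_poisson_mean(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=1.0)
        rng = np.random.default_rng(1)
        n = 10_000
        counts = [len(simulate_f1_gamete(g, rng).segments["chr1"]) - 1
                  for _ in range(n)]
        se = math.sqrt(1.0 / n)  # Poisson(1) variance = 1
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_fixed_seed_reproduces_mosaic(self, genome):
        m1 = simulate_f1_gamete(genome, np.random.default_rng(5))
        m2 = simulate_f1_gamete(genome, np.random.default_rng(5))
        assert m1.segments == m2.segments

    def test_segments_tile_chromosome(self, genome):
        mosaic = simulate_f1_gamete(genome, np.random.default_rng(3))
        for c in genome.chromosomes:
            segs = mosaic.segments[c.name]
            assert segs[0][0] == 1 and segs[-1][1] == c.length_bp + 1
            for (_, e1, s1), (s2, _, s2t) in zip(segs[:-1], segs[1:]):
                assert e1 == s2 and s1 != s2t  # contiguous, alternating


class TestLitters:
    def test_dko_fraction_matches_one_sixteenth(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=0.0)
        cfg = SimConfig(lethality={}, seed=3)
        embryos = simulate_litter(g, cfg, 16_000)
        frac = np.mean([e.is_dko for e in embryos])
        p = 1 / 16
        half_width = 2.576 * math.sqrt(p * (1 - p) / 16_000)  # 99% binomial interval
        assert abs(frac - p) < half_width

    def test_two_locus_classes_follow_product_mendelian_law(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=0.0)
        cfg = SimConfig(lethality={}, seed=4)
        embryos = simulate_litter(g, cfg, 20_000)
        for ga, pa in GENOTYPE_PROBS.items():
            for gb, pb in GENOTYPE_PROBS.items():
                obs = np.mean([e.genotype_class() == (ga, gb) for e in embryos])
                se = math.sqrt(pa * pb * (1 - pa * pb) / 20_000)
                assert abs(obs - pa * pb) < 4 * se

    def test_full_lethality_removes_dko_at_later_stage(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=0.0)
        cfg = SimConfig(lethality={("-/-", "-/-"): 1.0}, seed=5)
        embryos = simulate_litter(g, cfg, 4000)
        assert all(e.alive_at["E12.5"] for e in embryos)
        assert not any(e.is_dko and e.alive_at["E14.5"] for e in embryos)

    def test_half_lethality_halves_surviving_dko_fraction(self):
        g = GenomeModel.example(n_chromosomes=1, map_length_morgans=0.0)
        cfg = SimConfig(lethality={("-/-", "-/-"): 0.5}, seed=6)
        embryos = simulate_litter(g, cfg, 10_000)
        frac = np.mean([e.is_dko and e.alive_at["E14.5"] for e in embryos])
        p = 1 / 32
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(frac - p) < 3 * se

    def test_invalid_lethality_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(lethality={("-/-", "-/-"): 1.5})


class TestExpectedVaf:
    @pytest.mark.parametrize("e", [0.0, 0.001, 0.01])
    def test_balanced_het_is_exactly_half(self, e):
        assert expected_vaf("B9", [], e) == pytest.approx(0.5)

    @pytest.mark.parametrize("case, expected", [
        (("CN_LOH", "9", 1.0), 1.0),       # full copy-neutral LOH to alt strain
        (("CN_LOH", "B", 1.0), 0.0),
        (("CHR_GAIN", "9", 1.0), 2 / 3),   # 2 alt of 3 copies
        (("DELETION", "B", 0.5), 1 / 3),   # copy-weighted mixture
        (("DELETION", "9", 1.0), 1.0),     # only the retained alt copy remains
    ])
    def test_het_site_under_event(self, case, expected):
        kind, hap, cf = case
        ev = InstabilityEvent(kind, "chr1", 1, 100, hap, cf)
        assert expected_vaf("B9", [ev]) == pytest.approx(expected)

    def test_cn_loh_is_invisible_at_homozygous_sites(self):
        ev = InstabilityEvent("CN_LOH", "chr1", 1, 100, "9")
        assert expected_vaf("BB", [ev]) == pytest.approx(0.0)
        assert expected_vaf("99", [ev]) == pytest.approx(1.0)

    def test_error_rate_shifts_homozygous_sites(self):
        assert expected_vaf("BB", [], 0.01) == pytest.approx(0.01)
        assert expected_vaf("99", [], 0.01) == pytest.approx(0.99)

    @settings(derandomize=True, max_examples=200)
    @given(
        diplotype=st.sampled_from(["BB", "B9", "99"]),
        kind=st.sampled_from(["CN_LOH", "DELETION", "DUPLICATION"]),
        hap=st.sampled_from(["B", "9"]),
        cf=st.floats(0.01, 1.0),
        e=st.floats(0.0, 0.4),
    )
    def test_expected_vaf_stays_in_unit_interval(self, diplotype, kind, hap, cf, e):
        ev = InstabilityEvent(kind, "chr1", 1, 100, hap, cf)
        v = expected_vaf(diplotype, [ev], e)
        assert 0.0 <= v <= 1.0

    def test_invalid_event_parameters_rejected(self):
        with pytest.raises(ValueError):
            InstabilityEvent("CN_LOH", "chr1", 100, 100, "9")
        with pytest.raises(ValueError):
            InstabilityEvent("CN_LOH", "chr1", 1, 100, "9", cell_fraction=0.0)
        with pytest.raises(ValueError):
            InstabilityEvent("INVERSION", "chr1", 1, 100, "9")


class TestSampleReads:
    def test_mean_depth_and_het_vaf_calibration(self, genome, catalog):
        cfg = SimConfig(mean_depth=80.0, base_error_rate=0.0, seed=9)
        emb = simulate_embryo(genome, substream(9, "emb"))
        ad = sample_reads([emb], catalog, cfg)
        n = ad.n_sites
        assert abs(ad.total_depth.mean() - 80.0) < 3 * math.sqrt(80.0 / n)
        het = np.concatenate([
            emb.alt_copies_at(chrom, grp["pos"].to_numpy()) == 1
            for chrom, grp in ad.sites.groupby("chrom", sort=False)])
        vaf = ad.vaf()[het, 0]
        se = 0.5 / math.sqrt(vaf.size * 80.0)
        assert abs(vaf.mean() - 0.5) < 3 * se

    def test_zero_error_homref_sites_have_no_alt_reads(self, genome, catalog):
        cfg = SimConfig(base_error_rate=0.0, seed=10)
        emb = simulate_embryo(genome, substream(10, "emb"))
        ad = sample_reads([emb], catalog, cfg)
        homref = np.concatenate([
            emb.alt_copies_at(chrom, grp["pos"].to_numpy()) == 0
            for chrom, grp in ad.sites.groupby("chrom", sort=False)])
        assert (ad.alt_count[homref, 0] == 0).all()

    def test_identical_seed_gives_identical_matrix(self, genome, catalog, config):
        embryos = simulate_litter(genome, config, 4)
        ad1 = sample_reads(embryos, catalog, config)
        ad2 = sample_reads(embryos, catalog, config)
        assert ad1.equals(ad2)

    def test_het_mean_absolute_deviation_matches_binomial_expectation(self, genome):
        # fixed depth isolates the closed-form binomial oracle
        d = 40
        catalog = StrainCatalog.random(genome, 5000, substream(12, "cat"))
        cfg = SimConfig(mean_depth=d, base_error_rate=0.0, seed=12,
                        depth_dispersion=0.0)
        emb = simulate_embryo(genome, substream(12, "emb"))
        ad = sample_reads([emb], catalog, cfg)
        het = np.concatenate([
            emb.alt_copies_at(chrom, grp["pos"].to_numpy()) == 1
            for chrom, grp in ad.sites.groupby("chrom", sort=False)])
        at_depth = het & (ad.total_depth[:, 0] == d)
        vaf = ad.vaf()[at_depth, 0]
        expect = mean_abs_dev_binomial(d)
        sd = math.sqrt(sum((abs(k / d - 0.5) - expect) ** 2
                           * math.comb(d, k) / 2 ** d for k in range(d + 1)))
        assert abs(np.abs(vaf - 0.5).mean() - expect) < 3 * sd / math.sqrt(vaf.size)

    def test_dead_embryos_carry_no_reads(self, genome, catalog):
        cfg = SimConfig(lethality={("-/-", "-/-"): 1.0}, seed=13)
        embryos = simulate_litter(genome, cfg, 30)
        ad = sample_reads(embryos, catalog, cfg, stage="E14.5")
        alive = {e.id for e in embryos if e.alive_at["E14.5"]}
        assert set(ad.samples) == alive

    def test_overdispersed_depth_has_inflated_variance(self, genome, catalog):
        cfg = SimConfig(mean_depth=80.0, depth_dispersion=0.2, seed=14)
        emb = simulate_embryo(genome, substream(14, "emb"))
        ad = sample_reads([emb], catalog, cfg)
        # NB variance = m + alpha m^2 = 80 + 1280 >> Poisson's 80
        assert ad.total_depth[:, 0].var() > 3 * 80.0


class TestDiplotypeSegments:
    def test_segments_cover_genome_and_match_point_queries(self, genome, rng):
        emb = simulate_embryo(genome, rng)
        segs = diplotype_segments(genome, emb.hap1, emb.hap2)
        for c in genome.chromosomes:
            sub = segs[segs["chrom"] == c.name]
            assert sub["start"].iloc[0] == 1
            assert sub["end"].iloc[-1] == c.length_bp + 1
            assert (sub["start"].iloc[1:].to_numpy()
                    == sub["end"].iloc[:-1].to_numpy()).all()
        pos = np.array([1, 17, 50_000_000, 99_999_999])
        for c in genome.chromosomes:
            ac = emb.alt_copies_at(c.name, pos)
            sub = segs[segs["chrom"] == c.name]
            for p, a in zip(pos, ac):
                row = sub[(sub["start"] <= p) & (p < sub["end"])].iloc[0]
                assert {"BB": 0, "B9": 1, "99": 2}[row["diplotype"]] == a

    def test_overlapping_events_rejected(self, genome, rng):
        emb = simulate_embryo(genome, rng)
        with pytest.raises(ValueError, match="overlap"):
            emb.with_events([
                InstabilityEvent("CN_LOH", "chr1", 1, 1000, "9"),
                InstabilityEvent("DELETION", "chr1", 500, 2000, "B"),
            ])

    def test_whole_chromosome_event_spans_chromosome(self, genome):
        ev = whole_chromosome_event("CHR_GAIN", genome, "chr2", "9")
        assert (ev.start, ev.end) == (1, genome["chr2"].length_bp + 1)
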