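"""Generator contracts: planted truth, determinism, scale handling."""

import numpy as np
import pytest

from msypipe import synthetic
from msypipe.config import ScenarioConfig
from msypipe.genes import merge_annotation
from msypipe.poolsex import call_sex_specific_snps
from msypipe.repeats import region_repeat_fraction


def _flat_cfg(**kwargs) -> ScenarioConfig:
    """A scenario without region contrast unless overridden."""
    base = dict(
        chrom_length_bp=200_000,
        boundary_bp=150_000,
        telomere_bp=600,
        sub_rate_par=0.0,
        sub_rate_msy=0.0,
        indel_rate_par=0.0,
        indel_rate_msy=0.0,
        seed=11,
    )
    base.update(kwargs)
    return ScenarioConfig(**base)


class TestXYPair:
    def test_zero_rates_give_identical_sequences(self):
        x, y, truth = synthetic.simulate_xy_pair(_flat_cfg())
        assert x == y
        assert len(truth.snp_x) == 0
        assert truth.indels == []
        assert truth.boundary_y == truth.boundary_x

    def test_planted_snp_count_matches_binomial_expectation(self):
        # 1 Mb PAR at substitution rate 0.01, no indels: the planted count
        # must sit within 4 sigma of Binomial(1e6, 0.01)
        cfg = _flat_cfg(
            chrom_length_bp=1_100_000, boundary_bp=1_000_000, sub_rate_par=0.01
        )
        _, _, truth = synthetic.simulate_xy_pair(cfg)
        n_par = int((truth.snp_x < 1_000_000).sum())
        mean = 1_000_000 * 0.01
        sigma = np.sqrt(1_000_000 * 0.01 * 0.99)
        assert abs(n_par - mean) < 4 * sigma

    def test_identical_seed_identical_output(self, small_cfg):
        a = synthetic.simulate_xy_pair(small_cfg)
        b = synthetic.simulate_xy_pair(small_cfg)
        assert a[0] == b[0] and a[1] == b[1]
        assert np.array_equal(a[2].snp_y, b[2].snp_y)
        assert a[2].indels == b[2].indels

    def test_truth_regions_tile_chromosome(self, small_scenario):
        _, _, y, truth = small_scenario
        assert truth.par_interval[0] == 0
        assert truth.par_interval[1] == truth.msy_interval[0]
        assert truth.msy_interval[1] == len(y)

    def test_edits_recorded_exactly_once(self, small_scenario):
        _, x, y, truth = small_scenario
        assert len(np.unique(truth.snp_y)) == len(truth.snp_y)
        # every recorded SNP is a real X/Y base difference
        for px, py in zip(truth.snp_x[:200], truth.snp_y[:200]):
            assert x[px] != y[py]

    def test_telomeres_at_both_termini(self, small_scenario):
        cfg, x, y, truth = small_scenario
        tel = 6 * (cfg.bp(cfg.telomere_bp) // 6)
        assert tel > 0
        assert y[:tel] == "TTAGGG" * (tel // 6)
        assert y[-tel:] == "TTAGGG" * (tel // 6)
        assert truth.telomere_intervals == [(0, tel), (len(y) - tel, len(y))]

    def test_extreme_rates_rejected(self):
        with pytest.raises(ValueError, match="50%"):
            _flat_cfg(sub_rate_msy=0.45, indel_rate_msy=0.04)

    def test_scale_equivariance_of_geometry_and_rates(self):
        # bp geometry scales exactly; rate-type parameters stay untouched,
        # so planted SNP density is scale-free
        dens = {}
        for s in (0.02, 0.04):
            cfg = ScenarioConfig(scale=s, seed=5)
            assert cfg.length == round(cfg.chrom_length_bp * s)
            assert cfg.boundary == round(cfg.boundary_bp * s)
            _, _, truth = synthetic.simulate_xy_pair(cfg)
            assert truth.boundary_x == cfg.boundary
            dens[s] = (truth.snp_x < cfg.boundary).sum() / cfg.boundary
        assert dens[0.02] == pytest.approx(dens[0.04], rel=0.15)


class TestRad:
    def test_male_limited_loci_absent_in_all_females(self, small_scenario):
        cfg, _, y, truth = small_scenario
        rad = synthetic.simulate_rad_individuals(cfg, y, truth)
        females = [i for i in rad.counts.columns if rad.sex[i] == "F"]
        mo = rad.tags.loc[rad.tags.male_limited, "tag_id"]
        assert (rad.counts.loc[mo, females].to_numpy() == 0).all()

    def test_no_dropout_locus_present_in_all_males(self, small_scenario):
        cfg, _, y, truth = small_scenario
        cfg0 = cfg.replace(tag_dropout=0.0, n_tag_loci=10, n_male_only_loci=1)
        rad = synthetic.simulate_rad_individuals(cfg0, y, truth)
        males = [i for i in rad.counts.columns if rad.sex[i] == "M"]
        mo = rad.tags.loc[rad.tags.male_limited, "tag_id"]
        assert (rad.counts.loc[mo, males].to_numpy() > 0).all()

    def test_distal_placement_matches_binomial(self, small_scenario):
        cfg, _, y, truth = small_scenario
        rad = synthetic.simulate_rad_individuals(cfg, y, truth)
        mo = rad.tags[rad.tags.male_limited]
        cutoff = cfg.bp(cfg.distal_cutoff_bp)
        n_distal = int((mo.position >= cutoff).sum())
        n, p = len(mo), cfg.male_only_fraction_distal
        assert abs(n_distal - n * p) < 4 * np.sqrt(n * p * (1 - p))
        # remainder in the proximal band
        prox = mo[mo.position < cutoff]
        assert (prox.position >= cfg.bp(cfg.proximal_band_bp[0])).all()
        assert (prox.position < cfg.bp(cfg.proximal_band_bp[1])).all()

    def test_tag_loci_count_matches_config(self, small_scenario):
        cfg, _, y, truth = small_scenario
        rad = synthetic.simulate_rad_individuals(cfg, y, truth)
        assert len(rad.tags) == cfg.n_tag_loci
        assert rad.tags.male_limited.sum() == cfg.n_male_only_loci
        assert truth.male_only_tag_ids == set(
            rad.tags.loc[rad.tags.male_limited, "tag_id"]
        )


class TestPool:
    def test_planted_site_frequencies_at_high_depth(self):
        cfg = _flat_cfg(sub_rate_msy=0.02, pool_depth=50_000, pool_mask_start_bp=200_000)
        x, y, truth = synthetic.simulate_xy_pair(cfg)
        pool = synthetic.simulate_pool_counts(cfg, x, y, truth)
        snp_rows = pool[pool.pos.isin(truth.snp_x + 1)]
        m = snp_rows[["m_A", "m_C", "m_G", "m_T"]].to_numpy(float)
        f = snp_rows[["f_A", "f_C", "f_G", "f_T"]].to_numpy(float)
        alt_freq_m = 1 - m.max(axis=1) / m.sum(axis=1)
        # ref allele carries the rest; alt allele ~0.5 in males, 0 in females
        assert np.allclose(alt_freq_m, 0.5, atol=0.02)
        ref_freq_f = f.max(axis=1) / f.sum(axis=1)
        assert (ref_freq_f == 1.0).all()

    def test_no_planted_differences_no_sex_snps(self):
        cfg = _flat_cfg(pool_mask_start_bp=200_000)
        x, y, truth = synthetic.simulate_xy_pair(cfg)
        pool = synthetic.simulate_pool_counts(cfg, x, y, truth)
        sites, _ = call_sex_specific_snps(pool)
        assert len(sites) == 0

    def test_terminal_mask_reduces_depth(self, small_scenario):
        cfg, x, y, truth = small_scenario
        pool = synthetic.simulate_pool_counts(cfg, x, y, truth)
        mask_start = cfg.bp(cfg.pool_mask_start_bp)
        depth = pool[["m_A", "m_C", "m_G", "m_T"]].sum(axis=1)
        masked = depth[pool.pos - 1 >= mask_start].mean()
        open_ = depth[pool.pos - 1 < mask_start].mean()
        assert masked < 0.2 * open_


class TestTrio:
    def test_identical_parents_unclassifiable(self):
        from msypipe.trio import bin_readset, build_hapmer_sets, sequence_kmers

        cfg = _flat_cfg(trio_divergence=0.0, trio_hap_len_bp=40_000, n_trio_reads=20)
        trio = synthetic.simulate_trio_reads(cfg)
        assert trio.parentA == trio.parentB
        kms = sequence_kmers(trio.parentA, 21)
        hapA, hapB = build_hapmer_sets(kms, kms, 21)
        assert len(hapA) == len(hapB) == 0
        bins, _ = bin_readset([(r[0], r[1]) for r in trio.reads], hapA, hapB)
        assert len(bins["parentA"]) == len(bins["parentB"]) == 0

    def test_long_reads_carry_parent_unique_kmers(self):
        # error-free reads from 2%-divergent parents: nearly all reads
        # >= 2 kb contain at least one hap-mer (checked against hap-mer
        # sets counted directly on the generated haplotypes)
        from msypipe.trio import classify_read, hapmer_sets_from_sequences

        cfg = _flat_cfg(
            trio_hap_len_bp=100_000, trio_read_error=0.0, n_trio_reads=300
        )
        trio = synthetic.simulate_trio_reads(cfg)
        hapA, hapB = hapmer_sets_from_sequences([trio.parentA], [trio.parentB], k=21)
        long_reads = [r for r in trio.reads if len(r[1]) >= 2_000]
        assert len(long_reads) > 100
        with_hapmer = sum(
            1
            for rid, seq, _ in long_reads
            if (a := classify_read(rid, seq, hapA, hapB)).countA + a.countB > 0
        )
        assert with_hapmer >= 0.99 * len(long_reads)


class TestRepeats:
    def test_measured_density_matches_config(self, small_scenario):
        cfg, _, _, truth = small_scenario
        reps = synthetic.simulate_repeats(cfg, truth)
        par = region_repeat_fraction(reps, truth.par_interval)
        msy = region_repeat_fraction(
            [r for r in reps], truth.msy_interval
        )
        assert par == pytest.approx(cfg.repeat_density_par, abs=0.03)
        assert msy == pytest.approx(cfg.repeat_density_msy, abs=0.03)

    def test_zero_density_empty(self, small_scenario):
        cfg, _, _, truth = small_scenario
        cfg0 = cfg.replace(repeat_density_par=0.0, repeat_density_msy=0.0)
        assert synthetic.simulate_repeats(cfg0, truth) == []


class TestGeneEvidence:
    def test_zero_corruption_merge_equals_truth(self):
        cfg = _flat_cfg(n_genes=30, gene_corrupt_prob=0.0, gene_abinitio_only_prob=0.0)
        ev = synthetic.simulate_gene_evidence(cfg)
        merged = merge_annotation(
            ev.homology, ev.abinitio, ev.transcript_cover, ev.junctions
        )
        got = {(m.chrom, m.strand, m.exons) for m in merged.final_models}
        want = {(m.chrom, m.strand, m.exons) for m in ev.truth_models}
        assert got == want

    def test_abinitio_only_gene_recruited(self):
        cfg = _flat_cfg(n_genes=30, gene_corrupt_prob=0.0, gene_abinitio_only_prob=1.0)
        ev = synthetic.simulate_gene_evidence(cfg)
        assert ev.homology == []
        merged = merge_annotation(
            ev.homology, ev.abinitio, ev.transcript_cover, ev.junctions
        )
        assert len(merged.recruited) == len(ev.truth_models)
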