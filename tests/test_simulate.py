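"""Generator contracts: Mendelian segregation, bulk construction, sequencing noise."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkseg import (
    F2Individual, SimConfig, build_bulks, emit_fastq, read_fastq,
    sequence_bulk, simulate_experiment, simulate_f2_population, simulate_parents,
    trim_read,
)


def _config(**kw) -> SimConfig:
    base = dict(n_chromosomes=1, chrom_length_bp=1_000_000, marker_density=20,
                causal_chrom="chr1", causal_pos=500_000, population_size=50,
                seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestParents:
    def test_marker_count_matches_density(self):
        cfg = _config(chrom_length_bp=10_000_000, marker_density=100)
        parents = simulate_parents(cfg)
        # Poisson(1000): 4 sigma is ~±127
        assert 850 <= parents.n_markers <= 1150

    def test_markers_sorted_divergent_with_causal(self):
        parents = simulate_parents(_config())
        mk = parents.markers
        assert mk["pos"].is_monotonic_increasing
        assert (mk["ref"] != mk["alt"]).all()
        causal = mk[mk["is_causal"]]
        assert len(causal) == 1
        assert causal["pos"].iloc[0] == 500_000
        assert causal["vtype"].iloc[0] == "SNP"

    def test_no_markers_on_causal_chromosome_errors(self):
        with pytest.raises(ValueError, match="0 markers"):
            simulate_parents(_config(marker_density=0))

    def test_seeded_determinism(self):
        cfg = _config()
        a = simulate_parents(cfg).markers
        b = simulate_parents(cfg).markers
        pd.testing.assert_frame_equal(a, b)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            _config(bulk_size=0)
        with pytest.raises(ValueError):
            _config(base_error_rate=0.6)
        with pytest.raises(ValueError):
            _config(causal_pos=2_000_000)


@pytest.fixture(scope="module")
def big_population():
    cfg = _config(chrom_length_bp=1_000_000, marker_density=5, recomb_rate_cM_per_Mb=4)
    parents = simulate_parents(cfg)
    pop = simulate_f2_population(parents, 10_000, cfg,
                                 rng=np.random.default_rng(11))
    return cfg, parents, pop


class TestF2Population:
    def test_single_marker_segregates_1_2_1(self, big_population):
        _, parents, pop = big_population
        ci = parents.causal_index()
        dosage = np.array([ind.dosage[ci] for ind in pop])
        n = len(pop)
        for value, p in ((2, 0.25), (1, 0.5), (0, 0.25)):
            count = int((dosage == value).sum())
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(count - n * p) < 3 * sigma

    def test_recessive_phenotype_fraction_one_quarter(self, big_population):
        _, _, pop = big_population
        n_easy = sum(1 for ind in pop if ind.phenotype == "easy-dehull")
        assert stats.binomtest(n_easy, len(pop), 0.25).pvalue > 1e-3

    def test_phenotype_matches_causal_genotype(self, big_population):
        _, parents, pop = big_population
        ci = parents.causal_index()
        for ind in pop[:500]:
            assert (ind.phenotype == "easy-dehull") == (ind.dosage[ci] == 2)

    def test_zero_recombination_gives_parental_chromosomes(self):
        cfg = _config(recomb_rate_cM_per_Mb=0.0, marker_density=30)
        parents = simulate_parents(cfg)
        pop = simulate_f2_population(parents, 20, cfg)
        for ind in pop:
            # dosage constant along the (single) chromosome
            assert len(np.unique(ind.dosage)) == 1

    def test_empty_population_rejected(self):
        cfg = _config()
        parents = simulate_parents(cfg)
        with pytest.raises(ValueError):
            simulate_f2_population(parents, 0, cfg)


class TestBulks:
    def test_sizes_and_disjoint(self, big_population):
        _, _, pop = big_population
        low, high = build_bulks(pop, 30)
        assert len(low) == len(high) == 30
        assert not {id(i) for i in low} & {id(i) for i in high}

    def test_low_bulk_fixed_at_causal(self, big_population):
        _, parents, pop = big_population
        ci = parents.causal_index()
        low, _ = build_bulks(pop, 30)
        freqs = np.array([ind.dosage[ci] for ind in low]) / 2
        assert freqs.mean() == 1.0

    def test_high_bulk_causal_freq_one_third(self, big_population):
        _, parents, pop = big_population
        ci = parents.causal_index()
        _, high = build_bulks(pop, 500)
        freq = np.mean([ind.dosage[ci] for ind in high]) / 2
        # per-plant freq is 0.5 w.p. 2/3 else 0: sd of the mean ~ 0.0105
        assert abs(freq - 1 / 3) < 3 * 0.0105

    def test_insufficient_phenotype_errors_with_deficit(self):
        pop = [F2Individual(dosage=np.array([0]), phenotype="hard-dehull")] * 40
        with pytest.raises(ValueError, match="easy-dehull.*need 30, have 0"):
            build_bulks(pop, 30)

    def test_background_allele_frequency_near_half(self):
        """Pooled female-allele frequency on an unlinked chromosome ~ 0.5."""
        means = []
        for seed in range(15):
            cfg = SimConfig(n_chromosomes=2, chrom_length_bp=1_000_000,
                            marker_density=20, causal_chrom="chr1",
                            causal_pos=500_000, population_size=200,
                            bulk_size=30, seed=seed)
            rng = np.random.default_rng(seed)
            parents = simulate_parents(cfg, rng)
            pop = simulate_f2_population(parents, cfg.population_size, cfg, rng)
            low, high = build_bulks(pop, cfg.bulk_size)
            chr2 = (parents.markers["chrom"] == "chr2").to_numpy()
            for bulk in (low, high):
                dosage = np.stack([ind.dosage for ind in bulk])
                means.append(dosage[:, chr2].mean() / 2)
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 0.5) < 3 * sem


class TestSequencing:
    def test_mean_depth_tracks_poisson_mean(self):
        cfg = _config(chrom_length_bp=10_000_000, marker_density=1000,
                      mean_depth=30, population_size=20)
        rng = np.random.default_rng(5)
        parents = simulate_parents(cfg, rng)
        pop = simulate_f2_population(parents, 20, cfg, rng)
        ref_d, alt_d = sequence_bulk(pop, parents, cfg, rng)
        depth = ref_d + alt_d
        assert depth.size > 8000
        assert abs(depth.mean() - 30) < 0.01 * 30

    def test_zero_error_all_ref_bulk_has_no_alt_reads(self):
        cfg = _config(base_error_rate=0.0, mean_depth=50)
        parents = simulate_parents(cfg)
        bulk = [F2Individual(dosage=np.zeros(parents.n_markers, dtype=np.int8),
                             phenotype="hard-dehull") for _ in range(10)]
        _, alt_d = sequence_bulk(bulk, parents, cfg, np.random.default_rng(1))
        assert (alt_d == 0).all()

    def test_empty_bulk_rejected(self):
        cfg = _config()
        parents = simulate_parents(cfg)
        with pytest.raises(ValueError):
            sequence_bulk([], parents, cfg, np.random.default_rng(0))

    def test_experiment_table_deterministic(self, small_config):
        a = simulate_experiment(small_config).variants
        b = simulate_experiment(small_config).variants
        pd.testing.assert_frame_equal(a, b)

    def test_variant_table_shape_and_parent_truth(self, small_result):
        df = small_result.variants
        for sample in ("KF", "KM", "K21", "K5"):
            for suffix in ("gt", "gq", "ad_ref", "ad_alt"):
                assert f"{sample}_{suffix}" in df.columns
        assert (df["KF_gt"] == "1/1").all()
        assert (df["KM_gt"] == "0/0").all()
        assert (df["KF_ad_ref"] >= 0).all() and (df["KF_ad_alt"] >= 0).all()


class TestFastqEmission:
    def test_pair_files_have_four_lines_per_read(self, tmp_path):
        cfg = _config(read_length=100)
        emit_fastq(100, cfg, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        for name in ("r1.fastq", "r2.fastq"):
            assert len((tmp_path / name).read_text().splitlines()) == 400

    def test_clean_reads_survive_trimmer_untouched(self, tmp_path):
        cfg = _config(read_length=80)
        emit_fastq(20, cfg, tmp_path / "r1.fastq", tmp_path / "r2.fastq",
                   low_qual_tail_rate=0.0)
        for read in read_fastq(tmp_path / "r1.fastq"):
            assert len(trim_read(read)) == 80

    def test_injected_low_quality_tails_get_trimmed(self, tmp_path):
        cfg = _config(read_length=80, seed=9)
        emit_fastq(50, cfg, tmp_path / "r1.fastq", tmp_path / "r2.fastq",
                   low_qual_tail_rate=1.0, tail_quality=2)
        lengths = [len(trim_read(r)) for r in read_fastq(tmp_path / "r1.fastq")]
        assert all(l < 80 for l in lengths)

    def test_gzip_output(self, tmp_path):
        cfg = _config(read_length=60)
        emit_fastq(5, cfg, tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz")
        assert len(list(read_fastq(tmp_path / "r1.fastq.gz"))) == 5
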