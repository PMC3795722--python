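"""Synthetic fibre generator: determinism, noise calibration, presets."""

import math

import numpy as np
import pytest

from rnu2comb.errors import ConfigError
from rnu2comb.io import write_fibres_tsv
from rnu2comb.locus import build_haplotype
from rnu2comb.simulate import (
    PUBLISHED_CHROMOSOMES,
    PUBLISHED_OCCURRENCES,
    CohortConfig,
    reverse_fibre,
    sample_genotypes,
    simulate_cohort,
    simulate_fibre,
    published_cohort_config,
    published_cohort_pairing,
    zero_noise,
)
from tests.conftest import make_config


class TestSampleGenotypes:
    def test_explicit_passthrough(self):
        cfg = CohortConfig(n_individuals=1, genotypes=[(6, 19)])
        assert sample_genotypes(cfg, np.random.default_rng(0)) == [(6, 19)]

    def test_degenerate_table(self):
        cfg = CohortConfig(n_individuals=5, allele_frequencies={20: 1.0})
        assert sample_genotypes(cfg, np.random.default_rng(0)) == [(20, 20)] * 5

    def test_bad_frequency_sum_rejected(self):
        cfg = CohortConfig(n_individuals=2, allele_frequencies={10: 0.5, 11: 0.3})
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_published_spectrum_sampling_frequency(self):
        # 10,000 chromosomes: empirical frequency of the 19-copy allele
        # within 3 sd of its population value 5/46
        cfg = CohortConfig(n_individuals=5_000)
        genos = sample_genotypes(cfg, np.random.default_rng(42))
        alleles = [a for g in genos for a in g]
        p = 5 / 46
        emp = sum(a == 19 for a in alleles) / len(alleles)
        sd = math.sqrt(p * (1 - p) / len(alleles))
        assert abs(emp - p) <= 3 * sd


class TestSimulateFibre:
    def test_zero_noise_allele_19(self, clean_fibre_factory):
        fibre, hap = clean_fibre_factory(n=19, region="full")
        units = [s for s in fibre.signals
                 if s.truth_source and s.truth_source.startswith("unit[")]
        assert len(units) == 19
        for s in units:
            assert s.end_um - s.start_um == pytest.approx(2.393 / 2.0, abs=1e-9)

    def test_reversal_symmetry(self, clean_fibre_factory):
        fibre, _ = clean_fibre_factory(n=12)
        rev = reverse_fibre(fibre)
        fwd_lengths = [round(s.end_um - s.start_um, 9) for s in fibre.signals]
        rev_lengths = [round(s.end_um - s.start_um, 9) for s in rev.signals]
        assert sorted(fwd_lengths) == sorted(rev_lengths)
        fwd_sources = [s.truth_source for s in fibre.signals]
        assert [s.truth_source for s in rev.signals] == fwd_sources[::-1]

    def test_dropout_expectation(self, lmap):
        # mean surviving array-signal count ~ 19 * (1 - dropout)
        hap = build_haplotype(lmap, 19)
        cfg = make_config()  # default dropout 0.02, jitter, false signals
        counts = []
        for k in range(1_000):
            rng = np.random.default_rng([11, k])
            f = simulate_fibre(hap, cfg, rng, require_region="flanks")
            counts.append(sum(1 for s in f.signals
                              if s.truth_source
                              and s.truth_source.startswith("unit[")))
        assert np.mean(counts) == pytest.approx(19 * 0.98, abs=0.1)

    def test_boundary_jitter_calibrates_signal_length_sd(self, lmap):
        # independent jitter of sd J on both boundaries -> length sd
        # sqrt(2)*J kb = sqrt(2)*J/stretch µm, checked at ~10,000 signals
        hap = build_haplotype(lmap, 30)
        cfg = make_config(dropout_prob=0.0, false_signal_rate=0.0,
                          boundary_jitter_sd_kb=0.3, stretch_sd=0.0)
        lengths = []
        for k in range(350):
            rng = np.random.default_rng([13, k])
            f = simulate_fibre(hap, cfg, rng, require_region="flanks")
            lengths.extend(s.end_um - s.start_um for s in f.signals
                           if s.truth_source
                           and s.truth_source.startswith("unit["))
        assert len(lengths) >= 10_000
        target = math.sqrt(2) * 0.3 / 2.0
        assert np.std(lengths, ddof=1) == pytest.approx(target, rel=0.10)

    def test_signals_stay_inside_window(self, lmap):
        hap = build_haplotype(lmap, 25)
        cfg = CohortConfig()
        for k in range(50):
            rng = np.random.default_rng([17, k])
            f = simulate_fibre(hap, cfg, rng)
            w0, w1 = f.truth.window_bp
            win_um = (w1 - w0) / (1_000.0 * f.truth.stretch_kb_per_um)
            # truth windows are rounded to whole bp -> sub-µm slack
            for s in f.signals:
                assert 0.0 <= s.start_um < s.end_um <= win_um + 1e-3

    def test_required_region_fails_when_unreachable(self, lmap):
        hap = build_haplotype(lmap, 100)
        cfg = zero_noise(make_config(fibre_length_mean_kb=300.0))
        with pytest.raises(ConfigError):
            simulate_fibre(hap, cfg, np.random.default_rng(0),
                           require_region="flanks")


class TestSimulateCohort:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = CohortConfig(n_individuals=4, fibres_per_individual=5, seed=9)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_fibres_tsv(simulate_cohort(cfg).fibres, p1)
        write_fibres_tsv(simulate_cohort(cfg).fibres, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_record_count(self):
        cfg = CohortConfig(n_individuals=41, fibres_per_individual=20, seed=3)
        ds = simulate_cohort(cfg)
        assert len(ds.fibres) == 820

    def test_min_intact_top_up(self, lmap):
        cfg = CohortConfig(n_individuals=2, genotypes=[(6, 19), (22, 35)],
                           fibres_per_individual=4,
                           min_intact_per_haplotype=5, seed=5)
        ds = simulate_cohort(cfg)
        per_hap: dict = {}
        for f in ds.fibres:
            n = f.truth.allele_n
            hap = build_haplotype(lmap, n)
            r0, r1 = hap.regions["flanks"]
            w0, w1 = f.truth.window_bp
            if w0 <= r0 and w1 >= r1:
                per_hap[f.truth.haplotype] = per_hap.get(f.truth.haplotype, 0) + 1
        assert all(v >= 5 for v in per_hap.values())
        assert len(per_hap) == 4

    def test_preset_truth_matches_published_spectrum(self):
        genotypes, unrelated = published_cohort_pairing()
        assert len(genotypes) == 41
        multiset: dict = {}
        for (a, b), (u1, u2) in zip(genotypes, unrelated):
            if u1:
                multiset[a] = multiset.get(a, 0) + 1
            if u2:
                multiset[b] = multiset.get(b, 0) + 1
        assert multiset == PUBLISHED_OCCURRENCES
        assert sum(multiset.values()) == PUBLISHED_CHROMOSOMES == 46
        het = sum(a != b for a, b in genotypes)
        assert het == 40
        # paired alleles are separable by the genotype-calling merge rule
        assert all(a == b or abs(a - b) >= 2 for a, b in genotypes)

    def test_published_cohort_config_validates(self):
        published_cohort_config(seed=1).validate()
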