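"""Statistics layer: tract lengths, tests, normalization, enrichment."""

import itertools
import warnings

import numpy as np
import pytest
from scipy import stats as sps

import uvloh
from uvloh.genome import P1
from uvloh.stats import StatsError


def _event(tract_min, tract_max, kind="NCO_conversion", chrom="chr1"):
    return uvloh.RecombEvent(kind=kind, pattern="3:1", mechanism="SCB",
                             recipient=P1, chromosome=chrom,
                             tract_min=tract_min, tract_max=tract_max)


class TestTractLength:
    def test_estimate_is_mean_of_spans(self):
        rec = uvloh.tract_length(_event((2000, 8000), (1000, 11000)))
        assert rec.min_len == 6000 and rec.max_len == 10000
        assert rec.estimate == 8000

    def test_estimate_within_bounds_property(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = int(rng.integers(1, 10_000))
            b = a + int(rng.integers(1, 50_000))
            rec = uvloh.tract_length(_event((a + 100, b - 100), (a, b)))
            assert rec.min_len <= rec.estimate <= rec.max_len

    def test_no_tract_raises(self):
        ev = uvloh.RecombEvent(kind="CO", pattern="none", mechanism="NA",
                               recipient="ambiguous", chromosome="chr1",
                               tract_min=None, tract_max=None)
        with pytest.raises(StatsError):
            uvloh.tract_length(ev)

    def test_simulated_tract_within_marker_resolution(self, small_genome):
        """A known 5 kb tract at 1 kb SNP spacing is estimated within the
        resolution bound [4, 7] kb."""
        from uvloh.simulate import DiploidChromatids, repair_break, segregate
        import pandas as pd
        snp_map, mk = small_genome
        cfg = uvloh.SimulationConfig(patchy_repair_prob=0, restoration_prob=0,
                                     p_sdsa=1.0, p_dsbr=0.0, p_bir=0.0,
                                     crossover_prob=0.0,
                                     tract_median_bp=5000, tract_shape=2000.0)
        # near-degenerate gamma: tract length ~ 5 kb almost surely
        clf = uvloh.EventClassifier(snp_map, mk)
        estimates = []
        for seed in range(12):
            ch = DiploidChromatids(snp_map, mk)
            rng = np.random.default_rng(seed)
            brk = pd.DataFrame({"chromosome": ["chrT"], "position": [120_000],
                                "homolog": [1], "kind": ["SCB"]}).iloc[0]
            ev = repair_break(brk, cfg, ch, mk, rng)
            colony = segregate(ch, [ev], np.random.default_rng(seed))
            a = uvloh.call_sector(uvloh.sector_ratio_table(colony, 0, 0.0, rng),
                                  sector_id="a")
            b = uvloh.call_sector(uvloh.sector_ratio_table(colony, 1, 0.0, rng),
                                  sector_id="b")
            for e in clf.classify(a, b):
                estimates.append(uvloh.tract_length(e).estimate)
        assert estimates
        assert all(4000 <= x <= 7000 for x in estimates)


class TestMedianCI:
    def test_median_of_one_to_nine(self):
        med, lo, hi = uvloh.median_with_ci(range(1, 10))
        assert med == 5.0
        assert lo <= med <= hi

    def test_small_sample_rejected(self):
        with pytest.raises(StatsError):
            uvloh.median_with_ci([1, 2, 3])

    def test_gamma_median_recovery(self):
        shape = 2.0
        median = 5600.0
        scale = median / sps.gamma.ppf(0.5, shape)
        draws = np.random.default_rng(11).gamma(shape, scale, size=2000)
        med, lo, hi = uvloh.median_with_ci(draws)
        assert abs(med - median) < 300
        assert lo <= med <= hi

    def test_ci_brackets_median_always(self):
        rng = np.random.default_rng(4)
        for n in (8, 15, 100):
            x = rng.exponential(size=n)
            med, lo, hi = uvloh.median_with_ci(x)
            assert lo <= med <= hi


def _exact_mw_p(a, b):
    """Enumeration oracle for the two-sided Mann-Whitney p-value."""
    pooled = list(a) + list(b)
    n1 = len(a)
    def u_stat(ga, gb):
        return sum((x > y) + 0.5 * (x == y) for x in ga for y in gb)
    obs = u_stat(a, b)
    idx = range(len(pooled))
    us = []
    for comb in itertools.combinations(idx, n1):
        ga = [pooled[i] for i in comb]
        gb = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    return min(1.0, 2 * min((us >= obs).mean(), (us <= obs).mean()))


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        assert uvloh.compare_distributions([1, 2, 3, 4], [1, 2, 3, 4]).p_value == 1.0

    def test_fully_separated_small_samples(self):
        res = uvloh.compare_distributions([1, 2, 3], [10, 20, 30])
        assert res.value == 0.0
        assert res.p_value == pytest.approx(_exact_mw_p([1, 2, 3], [10, 20, 30]))

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            vals = rng.choice(1000, size=n1 + n2, replace=False)
            a, b = vals[:n1], vals[n1:]
            res = uvloh.compare_distributions(a, b)
            assert res.p_value == pytest.approx(_exact_mw_p(a, b))

    def test_separated_gammas_highly_significant(self):
        rng = np.random.default_rng(3)
        shape = 2.0
        a = rng.gamma(shape, 4900 / sps.gamma.ppf(0.5, shape), 1000)
        b = rng.gamma(shape, 7600 / sps.gamma.ppf(0.5, shape), 1000)
        assert uvloh.compare_distributions(a, b).p_value < 1e-5

    def test_empty_sample_rejected(self):
        with pytest.raises(StatsError):
            uvloh.compare_distributions([], [1.0])


class TestBinning:
    BOUNDS = [33_000, 63_000, 93_000, 123_000, 153_000]

    def test_uniform_midpoints_type_one_error(self):
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(60):
            mids = rng.uniform(33_000, 153_000, size=40)
            if uvloh.bin_midpoint_distribution(mids, self.BOUNDS).p_value < 0.05:
                rejections += 1
        assert rejections <= 6    # ~5% expected

    def test_all_in_one_bin_significant(self):
        mids = np.full(40, 50_000.0)
        assert uvloh.bin_midpoint_distribution(mids, self.BOUNDS).p_value < 0.001

    def test_empty_reference_falls_back_to_uniform(self):
        mids = np.linspace(34_000, 152_000, 40)
        res = uvloh.bin_midpoint_distribution(mids, self.BOUNDS, reference=[])
        assert res.name == "chi_square_uniform"

    def test_outside_events_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = uvloh.bin_midpoint_distribution([10_000, 50_000, 60_000, 70_000,
                                                   100_000], self.BOUNDS)
        assert sum(res.meta["counts"]) == 4


class TestDetectionCorrection:
    def test_published_counts(self):
        out = uvloh.detection_corrected_counts(60, 21, 300)
        assert out["co_corrected"] == 120
        assert out["conv_unassociated"] == 240
        assert out["association_fraction"] == pytest.approx(1 / 3)
        assert out["co_bir_ratio"] == pytest.approx(120 / 21)

    def test_zero_crossovers_identity(self):
        out = uvloh.detection_corrected_counts(0, 5, 10)
        assert (out["co_corrected"], out["bir"], out["conv_unassociated"]) == (0, 5, 10)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(StatsError):
            uvloh.detection_corrected_counts(10, 0, 5)


class TestNormalization:
    def test_table_worked_example(self):
        ac = uvloh.normalized_induced(49, 1, 3902, 5197)
        assert ac.normalized == pytest.approx(48.249, abs=1e-3)
        assert round(ac.normalized) == 48

    def test_per_kb_frequency(self):
        ac = uvloh.normalized_induced(92, 5, 3902, 5197, length_kb=1170,
                                      detection_factor=2)
        assert ac.per_kb == pytest.approx(3.87e-5, rel=0.01)

    def test_zero_untreated_identity(self):
        ac = uvloh.normalized_induced(10, 0, 1000, 2000)
        assert ac.normalized == 10

    def test_linear_in_treated_count(self):
        f = lambda t: uvloh.normalized_induced(t, 3, 1000, 1000).normalized
        assert f(30) - f(20) == pytest.approx(10)

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            ac = uvloh.normalized_induced(1, 100, 1000, 1000)
        assert ac.normalized == 0.0


class TestRegionExpectation:
    def test_rdna_cold_spot(self):
        res = uvloh.region_expectation_test(0, 60, 0.10)
        assert res.value == 6.0
        assert res.p_value < 0.05 and res.meta["chi2_p"] < 0.05

    def test_bir_telomere_proximity(self):
        res = uvloh.region_expectation_test(8, 21, 32 * 50 / 12_000)
        assert res.value == pytest.approx(2.8, abs=0.01)
        assert res.p_value < 0.01

    def test_zero_events(self):
        res = uvloh.region_expectation_test(0, 0, 0.10)
        assert res.value == 0.0 and res.p_value == 1.0

    def test_expected_counts_sum_over_partition(self):
        fracs = [0.1, 0.2, 0.3, 0.4]
        total = sum(uvloh.region_expectation_test(0, 60, f).value for f in fracs)
        assert total == pytest.approx(60.0)


class TestChromosomeSizeCorrelation:
    def test_proportional_counts_r2_one(self):
        lengths = np.arange(1, 17) * 1e5
        res = uvloh.chromosome_size_correlation(lengths * 3e-5, lengths)
        assert res.value == pytest.approx(1.0)

    def test_uniform_events_strong_correlation(self, snp_map):
        lengths = np.array([l for _, l in snp_map.chromosomes], dtype=float)
        rng = np.random.default_rng(2)
        strong = 0
        for _ in range(20):
            counts = rng.multinomial(381, lengths / lengths.sum())
            if uvloh.chromosome_size_correlation(counts, lengths).value > 0.7:
                strong += 1
        assert strong >= 18

    def test_permuted_counts_weak_on_average(self, snp_map):
        lengths = np.array([l for _, l in snp_map.chromosomes], dtype=float)
        rng = np.random.default_rng(3)
        r2s = []
        for _ in range(30):
            counts = rng.multinomial(381, lengths / lengths.sum())
            rng.shuffle(counts)
            r2s.append(uvloh.chromosome_size_correlation(counts, lengths).value)
        assert np.mean(r2s) < 0.3

    def test_zero_variance_lengths_rejected(self):
        with pytest.raises(StatsError):
            uvloh.chromosome_size_correlation([1, 2, 3], [5, 5, 5])


class TestElementEnrichment:
    def test_everything_overlaps_genomewide_class(self, snp_map):
        ann = uvloh.AnnotationSet(
            classes={"all": [(c, 1, l) for c, l in snp_map.chromosomes]},
            rdna_fraction=0.1)
        tracts = [("chr01", 50_000, 60_000), ("chr02", 100_000, 110_000)]
        (res,) = uvloh.element_enrichment(tracts, ann, snp_map,
                                          n_perm=1000, seed=0)
        assert res.value == len(tracts)
        assert res.p_value == 1.0

    def test_detects_constructed_underrepresentation(self, snp_map):
        # a class covering half the chromosomes end to end; tracts
        # deliberately placed only on the uncovered chromosomes
        covered = [c for i, (c, _l) in enumerate(snp_map.chromosomes) if i % 2 == 0]
        ann = uvloh.AnnotationSet(
            classes={"dense": [(c, 1, dict(snp_map.chromosomes)[c])
                               for c in covered]},
            rdna_fraction=0.1)
        tracts = [("chr04", 100_000 + i * 20_000, 105_000 + i * 20_000)
                  for i in range(30)]
        (res,) = uvloh.element_enrichment(tracts, ann, snp_map,
                                          n_perm=2000, seed=1)
        assert res.value == 0
        assert res.meta["p_under"] < 0.01 and res.p_value < 0.02

    def test_bh_adjustment_monotone_and_geq_raw(self, snp_map, annotations):
        tracts = [("chr02", 100_000 + i * 30_000, 108_000 + i * 30_000)
                  for i in range(20)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = uvloh.element_enrichment(tracts, annotations, snp_map,
                                               n_perm=1000, seed=2)
        assert len(results) >= 3
        by_p = sorted(results, key=lambda r: r.p_value)
        for r in results:
            assert r.adjusted_p >= r.p_value - 1e-12
        adj = [r.adjusted_p for r in by_p]
        assert adj == sorted(adj)

    def test_small_n_perm_rejected(self, snp_map, annotations):
        with pytest.raises(StatsError):
            uvloh.element_enrichment([], annotations, snp_map, n_perm=10)


class TestDinucleotides:
    def test_homopolymer(self):
        assert uvloh.dinucleotide_freq("AAAA") == 1.0

    def test_no_aa_tt(self):
        assert uvloh.dinucleotide_freq("ACGT") == 0.0

    def test_tt_counts_with_aa(self):
        assert uvloh.dinucleotide_freq("TTT") == 1.0

    def test_iid_closed_form(self):
        rng = np.random.default_rng(1)
        p = 0.31
        seq = "".join(rng.choice(list("ATGC"), p=[p, p, 0.19, 0.19],
                                 size=100_000))
        # under independence: f(AA) + f(TT) = 2 p^2
        assert uvloh.dinucleotide_freq(seq) == pytest.approx(2 * p * p, abs=0.01)

    def test_non_acgt_rejected(self):
        with pytest.raises(StatsError):
            uvloh.dinucleotide_freq("ANNNNNNA")

    def test_region_comparison_detects_depletion(self):
        rng = np.random.default_rng(2)
        rich = "".join(rng.choice(list("ATGC"), p=[0.31, 0.31, 0.19, 0.19],
                                  size=30_000))
        poor = "".join(rng.choice(list("ATGC"), p=[0.22, 0.22, 0.28, 0.28],
                                  size=30_000))
        res = uvloh.stats.compare_dinucleotide_regions(rich, poor)
        assert res.p_value < 1e-6
        assert res.meta["freq_a"] > res.meta["freq_b"]


class TestReportingHelpers:
    def test_fold_stimulation_two_sig_figs(self):
        fold = uvloh.fold_stimulation(9.4e-3, 1.1e-6)
        assert fold == pytest.approx(8545.45, abs=0.01)
        assert uvloh.round_sig(fold, 2) == 8500

    def test_round_sig_handles_zero_and_small(self):
        assert uvloh.round_sig(0.0) == 0.0
        assert uvloh.round_sig(3.87e-5, 2) == pytest.approx(3.9e-5)
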