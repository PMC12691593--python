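import numpy as np
import pytest

from conftest import make_callset
from mutkit.design import ExperimentDesign
from mutkit.genome import bin_genome, profile_genome
from mutkit.neutrality import (
    binned_rates,
    coding_enrichment_test,
    dispersion_test,
    origin_distance_correlation,
)
from mutkit.variants import MutationRecord


class TestDispersionTest:
    def test_degenerate_counts_poisson_fallback(self):
        with pytest.warns(UserWarning, match="identical"):
            res = dispersion_test([5] * 20)
        assert res.distribution == "poisson"

    def test_poisson_null_mostly_accepted(self, rng):
        accepted = 0
        for _ in range(50):
            counts = rng.poisson(5, size=66)
            res = dispersion_test(counts)
            accepted += (not np.isfinite(res.p)) or res.p > 0.05
        assert accepted >= 44

    def test_strong_overdispersion_detected(self, rng):
        """A bimodal mixture is rejected: even the fitted NB cannot fit two modes."""
        rejections = 0
        for _ in range(40):
            counts = np.concatenate([rng.poisson(1, 33), rng.poisson(30, 33)])
            res = dispersion_test(counts)
            rejections += np.isfinite(res.p) and res.p < 0.05
        assert rejections >= 36

    def test_overdispersed_counts_use_nb(self, rng):
        counts = rng.negative_binomial(2, 2 / (2 + 8), size=200)
        res = dispersion_test(counts)
        assert res.distribution == "negative_binomial"
        assert res.dispersion == pytest.approx(2.0, rel=0.6)

    def test_expected_counts_pooled_to_five(self, rng):
        res = dispersion_test(rng.poisson(4, size=60))
        assert (res.table["expected"] >= 5).all()
        assert res.df >= 1

    def test_too_few_lines(self):
        with pytest.raises(ValueError):
            dispersion_test([3])


class TestCodingEnrichment:
    def _profile(self, coding_frac=0.5, length=1000):
        seq = "ATGC" * (length // 4)
        return profile_genome(seq, coding_intervals=[(1, int(coding_frac * length))])

    def test_all_coding_closed_form(self):
        profile = self._profile(0.5)
        recs = [MutationRecord("L0", p, "G", "A", "SNM", "GC>AT") for p in range(1, 101)]
        chi2, p = coding_enrichment_test(recs, profile)
        # (100-50)^2/50 * 2 = 100
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-3

    def test_proportional_placement_large_p(self):
        profile = self._profile(0.8)
        positions = list(range(1, 81)) + list(range(801, 821))
        recs = [MutationRecord("L0", p, "G", "A", "SNM", "GC>AT") for p in positions]
        chi2, p = coding_enrichment_test(recs, profile)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_no_snms_rejected(self):
        with pytest.raises(ValueError):
            coding_enrichment_test([], self._profile())

    def test_degenerate_coding_fraction(self):
        profile = profile_genome("ATGC" * 10, coding_intervals=[(1, 40)])
        recs = [MutationRecord("L0", 3, "G", "A", "SNM", "GC>AT")]
        with pytest.raises(ValueError):
            coding_enrichment_test(recs, profile)


class TestBinnedRates:
    def _setup(self):
        profile = profile_genome("ATGC" * 25, origin=1)  # 100 bp
        design = ExperimentDesign("t", n_lines=2, n_transfers=1, generations_total=10,
                                  genome=profile)
        bins = bin_genome(profile, fixed_width=10)
        return profile, design, bins

    def test_hand_toy(self):
        profile, design, bins = self._setup()
        # 3 mutations: two in bin 0, one in bin 1; T=10, l=2
        recs = [MutationRecord("L0", 3, "G", "A", "SNM", "GC>AT"),
                MutationRecord("L1", 7, "C", "T", "SNM", "GC>AT"),
                MutationRecord("L0", 15, "G", "A", "SNM", "GC>AT")]
        series = binned_rates(recs, bins, design, snm_types=("GC>AT",))
        rates = series.for_type("GC>AT")["rate"].tolist()
        assert rates[0] == pytest.approx(2 / (bins[0].gc_sites * 10 * 2))
        assert rates[1] == pytest.approx(1 / (bins[1].gc_sites * 10 * 2))
        assert all(r == 0 for r in rates[2:])

    def test_conservation(self):
        profile, design, bins = self._setup()
        recs = [MutationRecord("L0", p, "G", "A", "SNM", "GC>AT") for p in (3, 4, 43, 99)]
        series = binned_rates(recs, bins, design)
        assert series.table.groupby("type")["m"].sum()["GC>AT"] == 4

    def test_out_of_range_record(self):
        profile, design, bins = self._setup()
        recs = [MutationRecord("L0", 101, "G", "A", "SNM", "GC>AT")]
        with pytest.raises(ValueError, match="outside"):
            binned_rates(recs, bins, design)


class TestOriginDistanceCorrelation:
    def _series(self, rates_by_bin, origin=1, length=100, width=10):
        profile = profile_genome("ATGC" * (length // 4), origin=origin)
        design = ExperimentDesign("t", n_lines=1, n_transfers=1, generations_total=1,
                                  genome=profile)
        bins = bin_genome(profile, fixed_width=width)
        recs = []
        for b, m in zip(bins, rates_by_bin):
            for i in range(m):
                pos = b.start + 2 + 4 * (i % 2)  # lands on G or G
                recs.append(MutationRecord("L0", pos, "G", "A", "SNM", "GC>AT"))
        return binned_rates(recs, bins, design, snm_types=("GC>AT",))

    def test_monotone_decline_gives_rho_minus_one(self):
        # counts fall with circular distance symmetrically on both replichores
        series = self._series([10, 8, 6, 4, 2, 0, 2, 4, 6, 8], length=200, width=20)
        res = origin_distance_correlation(series, n_tests=1, snm_types=("GC>AT",))["GC>AT"]
        assert res.rho == pytest.approx(-1.0)
        assert res.p_raw < 0.05

    def test_bonferroni_multiplication(self):
        series = self._series([10, 8, 6, 4, 2, 0, 2, 4, 6, 8], length=200, width=20)
        res = origin_distance_correlation(series, n_tests=6, snm_types=("GC>AT",))["GC>AT"]
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 6))

    def test_constant_rates_reported_undefined(self):
        series = self._series([2, 2, 2, 2, 2], length=100, width=20)
        res = origin_distance_correlation(series, snm_types=("GC>AT",))["GC>AT"]
        assert np.isnan(res.rho)

    def test_null_p_values_roughly_uniform(self, rng):
        """Permuted (signal-free) rates give a calibrated test."""
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            counts = rng.poisson(3, size=12)
            profile = profile_genome("ATGC" * 30, origin=1)
            design = ExperimentDesign("t", 1, 1, 1, genome=profile)
            bins = bin_genome(profile, fixed_width=10)
            recs = []
            for b, m in zip(bins, counts):
                recs += [MutationRecord("L0", b.start + 2, "G", "A", "SNM", "GC>AT")] * m
            series = binned_rates(recs, bins, design, snm_types=("GC>AT",))
            res = origin_distance_correlation(series, n_tests=1, snm_types=("GC>AT",))["GC>AT"]
            rejections += np.isfinite(res.p_raw) and res.p_raw < 0.05
        assert rejections <= 12  # ~5% nominal
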