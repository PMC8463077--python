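"""Summit distances, differential binding, KO confirmation, crosslink ratios."""

import numpy as np
import pytest

from cobind.cooccupancy import (
    DifferentialBindingResult,
    FactorPeakSet,
    confirm_specific_sites,
    crosslink_ratio_correlation,
    differential_binding,
    median_of_ratios_size_factors,
    overlap_fraction,
    summit_distance_summary,
)
from cobind.genomics import GenomicInterval, Peak


def _peaks(summits, chrom="chr1", half=200, name_prefix="p"):
    out = []
    for i, s in enumerate(summits):
        s = int(s)
        out.append(
            Peak(GenomicInterval(chrom, max(0, s - half), s + half + 1,
                                 name=f"{name_prefix}{i}"), s)
        )
    return out


class TestSummitDistances:
    def test_identical_sets_have_median_zero(self):
        a = FactorPeakSet("A", _peaks([1000, 5000, 9000]))
        assert summit_distance_summary(a, a).median == 0.0

    def test_constant_shift_recovered(self):
        summits = np.arange(1, 50) * 1000
        a = FactorPeakSet("A", _peaks(summits))
        b = FactorPeakSet("B", _peaks(summits + 40))
        assert summit_distance_summary(a, b).median == 40.0

    def test_half_normal_median_for_jittered_summits(self, rng):
        # each factor jitters the shared summit by N(0, 15); the distance is
        # |N(0, 15*sqrt(2))| whose median is 0.674 * 15 * sqrt(2) ~ 14.3 bp
        n = 5000
        base = np.arange(1, n + 1) * 1000
        a = FactorPeakSet("A", _peaks(np.round(base + rng.normal(0, 15, n))))
        b = FactorPeakSet("B", _peaks(np.round(base + rng.normal(0, 15, n))))
        sd = summit_distance_summary(a, b)
        expected = np.sqrt(2) * 15 * 0.6744897501960817
        assert sd.median == pytest.approx(expected, abs=1.5)

    def test_disjoint_sets_warn_and_return_empty(self, caplog):
        a = FactorPeakSet("A", _peaks([1000]))
        b = FactorPeakSet("B", _peaks([1000], chrom="chr2"))
        with caplog.at_level("WARNING", logger="cobind"):
            sd = summit_distance_summary(a, b)
        assert len(sd.distances) == 0 and np.isnan(sd.median)


class TestOverlapFraction:
    def test_subset_gives_one(self):
        a = FactorPeakSet("A", _peaks([1000, 2000]))
        b = FactorPeakSet("B", _peaks([1000, 2000, 3000]))
        assert overlap_fraction(a, b) == 1.0

    def test_disjoint_chromosomes_give_zero(self):
        a = FactorPeakSet("A", _peaks([1000]))
        b = FactorPeakSet("B", _peaks([1000], chrom="chr2"))
        assert overlap_fraction(a, b) == 0.0

    def test_counting(self):
        a = FactorPeakSet("A", _peaks(np.arange(1, 11) * 10_000))
        b = FactorPeakSet("B", _peaks([10_000, 20_000, 30_000]))
        assert overlap_fraction(a, b) == pytest.approx(0.3)

    def test_monotone_in_b(self, rng):
        a = FactorPeakSet("A", _peaks(rng.integers(1000, 100_000, 20)))
        summits = list(rng.integers(1000, 100_000, 10))
        prev = 0.0
        for k in range(1, 11):
            b = FactorPeakSet("B", _peaks(summits[:k]))
            frac = overlap_fraction(a, b)
            assert frac >= prev - 1e-12
            prev = frac

    def test_empty_a_errors(self):
        with pytest.raises(ValueError):
            overlap_fraction(FactorPeakSet("A", []), FactorPeakSet("B", _peaks([1])))


def _nb(rng, mu, disp, shape):
    r = 1.0 / disp
    return rng.negative_binomial(r, r / (r + mu), size=shape)


class TestDifferentialBinding:
    def test_identical_matrices_all_shared(self, rng):
        counts = _nb(rng, 200, 0.05, (50, 3))
        res = differential_binding(counts, counts)
        assert all(r.call == "shared" for r in res)
        assert all(r.log2_fold_change == 0 for r in res)

    def test_library_size_removed_by_normalization(self):
        a = np.full((40, 3), 100)
        b = a * 2
        res = differential_binding(a, b)
        assert all(abs(r.log2_fold_change) < 1e-9 for r in res)

    def test_size_factors_median_of_ratios(self):
        counts = np.array([[100, 200], [10, 20], [50, 100]])
        sf = median_of_ratios_size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_null_calibration_and_planted_sensitivity(self, rng):
        n_null, n_alt = 4000, 100
        mu = 200.0
        a = _nb(rng, mu, 0.05, (n_null + n_alt, 3)).astype(float)
        b = _nb(rng, mu, 0.05, (n_null + n_alt, 3)).astype(float)
        a[:n_alt] = _nb(rng, mu * 2 ** 1.5, 0.05, (n_alt, 3))
        b[:n_alt] = _nb(rng, mu * 2 ** -1.5, 0.05, (n_alt, 3))
        res = differential_binding(a, b)
        null_hits = sum(r.padj < 0.05 for r in res[n_alt:])
        assert null_hits / n_null <= 0.05
        sens = sum(r.call == "YAP_specific" for r in res[:n_alt]) / n_alt
        assert sens >= 0.9

    def test_all_zero_peak_is_shared_with_p_one(self, rng):
        a = _nb(rng, 200, 0.05, (10, 3)).astype(float)
        b = _nb(rng, 200, 0.05, (10, 3)).astype(float)
        a[0] = b[0] = 0
        res = differential_binding(a, b)
        assert res[0].pvalue == 1.0 and res[0].call == "shared"

    def test_padj_at_least_pvalue(self, rng):
        a = _nb(rng, 100, 0.1, (200, 3))
        b = _nb(rng, 100, 0.1, (200, 3))
        assert all(r.padj >= r.pvalue for r in differential_binding(a, b))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            differential_binding(np.ones((5, 1)), np.ones((5, 2)))


def _candidate(pid, call):
    return DifferentialBindingResult(pid, 1.0 if call == "YAP_specific" else -1.0,
                                     0.001, 0.01, call)


class TestKnockoutConfirmation:
    def test_yap_specific_confirmed(self):
        out = confirm_specific_sites(
            [_candidate("p1", "YAP_specific")], {"p1": 100}, {"p1": 10}, {"p1": 95}
        )
        assert out[0].confirmed == "YAP_specific"

    def test_both_dropping_is_unconfirmed(self):
        out = confirm_specific_sites(
            [_candidate("p1", "YAP_specific")], {"p1": 100}, {"p1": 10}, {"p1": 10}
        )
        assert out[0].confirmed == "unconfirmed"

    def test_zero_parent_unconfirmed(self):
        out = confirm_specific_sites(
            [_candidate("p1", "YAP_specific")], {"p1": 0.0}, {"p1": 0}, {"p1": 0}
        )
        assert out[0].confirmed == "unconfirmed"

    def test_swapping_ko_columns_swaps_confirmations(self, rng):
        n = 200
        calls = ["YAP_specific" if i % 2 else "TAZ_specific" for i in range(n)]
        cands = [_candidate(f"p{i}", c) for i, c in enumerate(calls)]
        mirror = [
            _candidate(f"p{i}", "TAZ_specific" if c == "YAP_specific" else "YAP_specific")
            for i, c in enumerate(calls)
        ]
        parent = {f"p{i}": 100.0 for i in range(n)}
        yap_ko = {f"p{i}": float(rng.uniform(0, 120)) for i in range(n)}
        taz_ko = {f"p{i}": float(rng.uniform(0, 120)) for i in range(n)}
        fwd = confirm_specific_sites(cands, parent, yap_ko, taz_ko)
        swp = confirm_specific_sites(mirror, parent, taz_ko, yap_ko)
        swap_map = {"YAP_specific": "TAZ_specific", "TAZ_specific": "YAP_specific",
                    "unconfirmed": "unconfirmed"}
        assert [swap_map[c.confirmed] for c in fwd] == [c.confirmed for c in swp]

    def test_bad_drop_fraction_rejected(self):
        with pytest.raises(ValueError):
            confirm_specific_sites([], {}, {}, {}, drop_fraction=1.5)


class TestCrosslinkRatio:
    def test_equal_signals_degenerate_flag(self):
        s = np.full(10, 5.0)
        scores = np.linspace(0, 9, 10)
        ratios, r, degenerate = crosslink_ratio_correlation(s, s, scores)
        assert degenerate and r == 0.0 and np.allclose(ratios, 0.0)

    def test_perfect_linearity(self):
        scores = np.linspace(1, 20, 50)
        ratios = 0.1 * scores
        s2 = np.full(50, 100.0)
        s1 = (s2 + 0) * 2.0**ratios  # epsilon = 0 keeps the relation exact
        _, r, _ = crosslink_ratio_correlation(s1, s2, scores, epsilon=0.0)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_attenuates_small_signals(self):
        scores = np.linspace(1, 20, 200)
        s2 = np.full(200, 2.0)  # signals comparable to epsilon
        s1 = s2 * 2.0 ** (0.3 * scores)
        _, r0, _ = crosslink_ratio_correlation(s1, s2, scores, epsilon=0.0)
        _, r1, _ = crosslink_ratio_correlation(s1, s2, scores, epsilon=1.0)
        assert r0 == pytest.approx(1.0, abs=1e-9)
        assert r1 < r0  # pseudo-signal compresses the log-ratio

    def test_affine_invariance_only_at_zero_epsilon(self, rng):
        scores = rng.normal(20, 4, 300)
        s2 = rng.uniform(50, 150, 300)
        s1 = s2 * 2.0 ** (0.1 * scores + rng.normal(0, 0.3, 300))
        _, r_a, _ = crosslink_ratio_correlation(s1, s2, scores, epsilon=0.0)
        _, r_b, _ = crosslink_ratio_correlation(3 * s1, 3 * s2, scores, epsilon=0.0)
        assert r_a == pytest.approx(r_b, abs=1e-12)
        _, r_c, _ = crosslink_ratio_correlation(3 * s1, 3 * s2, scores, epsilon=1.0)
        assert r_c != pytest.approx(r_a, abs=1e-9)

    def test_planted_correlation_recovered(self, rng):
        n = 5000
        scores = rng.normal(20, 4, n)
        rho = 0.5
        slope = 0.1
        noise_sd = slope * 4 * np.sqrt(1 / rho**2 - 1)
        ratio = slope * (scores - 20) + rng.normal(0, noise_sd, n)
        s2 = np.full(n, 500.0)
        s1 = s2 * 2.0**ratio
        _, r, _ = crosslink_ratio_correlation(s1, s2, scores, epsilon=1.0)
        assert r == pytest.approx(rho, abs=0.04)

    def test_too_few_peaks_errors(self):
        with pytest.raises(ValueError):
            crosslink_ratio_correlation(np.ones(2), np.ones(2), np.ones(2))
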