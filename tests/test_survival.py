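"""Gene signatures, GSS, Kaplan-Meier, and log-rank tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cobind.motifs import MotifClass, MotifHit, PeakMotifProfile
from cobind.survival import (
    ExpressionMatrix,
    GeneSignature,
    SurvivalRecord,
    cv_filter,
    define_motif_signature,
    gss,
    km_estimate,
    logrank_test,
    split_by_motif_count,
)


def _records(times, events, prefix="p"):
    return [
        SurvivalRecord(f"{prefix}{i}", float(t), int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


class TestSignatureDefinition:
    def test_gene_with_matching_peak_included(self):
        sig = define_motif_signature(
            {"pk1": MotifClass.AP1_ONLY}, {"pk1": {"geneA"}}, "AP1_only"
        )
        assert sig.genes == {"geneA"}

    def test_composite_peak_excluded_from_exclusive_mode(self):
        with pytest.raises(ValueError):
            define_motif_signature(
                {"pk1": MotifClass.AP1_TEAD}, {"pk1": {"geneA"}}, "AP1_only"
            )

    def test_stat3_content_does_not_break_exclusivity(self):
        sig = define_motif_signature(
            {"pk1": MotifClass.AP1_STAT3}, {"pk1": {"geneA"}}, "AP1_only"
        )
        assert sig.genes == {"geneA"}

    def test_multi_peak_gene_joins_both_single_motif_signatures(self):
        classes = {"pk1": MotifClass.AP1_ONLY, "pk2": MotifClass.TEAD_ONLY}
        target_map = {"pk1": {"geneA"}, "pk2": {"geneA"}}
        ap1 = define_motif_signature(classes, target_map, "AP1_only")
        tead = define_motif_signature(classes, target_map, "TEAD_only")
        assert "geneA" in ap1.genes and "geneA" in tead.genes

    def test_both_mode_requires_both_motifs(self):
        classes = {"pk1": MotifClass.AP1_TEAD, "pk2": MotifClass.AP1_ONLY}
        target_map = {"pk1": {"gA"}, "pk2": {"gB"}}
        sig = define_motif_signature(classes, target_map, "AP1_and_TEAD")
        assert sig.genes == {"gA"}


class TestSplitByMotifCount:
    def _profiles(self, hits_per_peak):
        return {
            pid: PeakMotifProfile(
                pid, {"AP1": [MotifHit(i, "+", 5.0, 1e-5) for i in range(n)]}
            )
            for pid, n in hits_per_peak.items()
        }

    def test_single_and_multi_hit_split(self):
        sig = GeneSignature("s", {"gA", "gB"})
        profiles = self._profiles({"pk1": 1, "pk2": 3})
        one, multi = split_by_motif_count(
            sig, profiles, "AP1", {"pk1": {"gA"}, "pk2": {"gB"}}
        )
        assert one == {"gA"} and multi == {"gB"}

    def test_gene_with_two_peaks_lands_in_both_sets(self):
        sig = GeneSignature("s", {"gA"})
        profiles = self._profiles({"pk1": 1, "pk2": 2})
        one, multi = split_by_motif_count(
            sig, profiles, "AP1", {"pk1": {"gA"}, "pk2": {"gA"}}
        )
        assert one == {"gA"} and multi == {"gA"}


class TestCVFilter:
    def _expr(self, rows):
        return ExpressionMatrix(pd.DataFrame(rows).T)

    def test_constant_gene_removed(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"p1": [5.0, 10.0], "p2": [5.0, 20.0]}, index=["gc", "gv"])
        )
        kept = cv_filter(expr)
        assert "gc" not in kept and "gv" in kept

    def test_low_cv_boundary(self):
        # CV = 0.04 < 5% -> removed
        vals = 100 + 3 * np.array([-1.0, 1.0])
        expr = ExpressionMatrix(pd.DataFrame([vals], index=["g"], columns=["p1", "p2"]))
        cv = vals.std(ddof=1) / vals.mean()
        assert cv < 0.05
        assert "g" not in cv_filter(expr)

    def test_hand_computed_cv_retained(self):
        expr = ExpressionMatrix(pd.DataFrame([[10.0, 20.0]], index=["g"], columns=["p1", "p2"]))
        # mean 15, sd 7.071 -> CV 0.471 in [0.05, 0.85]
        assert "g" in cv_filter(expr)

    def test_single_patient_errors(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0]], index=["g"], columns=["p1"]))
        with pytest.raises(ValueError):
            cv_filter(expr)


class TestGSS:
    def test_hand_computed_example(self):
        expr = ExpressionMatrix(
            pd.DataFrame(
                {"p1": [1.0, 2.0], "p2": [3.0, 6.0]}, index=["g1", "g2"]
            )
        )
        table = gss(expr, GeneSignature("s", {"g1", "g2"})).table
        assert table.loc["p1", "gss"] == pytest.approx(-np.sqrt(2), abs=1e-6)
        assert table.loc["p1", "group"] == "low"
        assert table.loc["p2", "group"] == "high"

    def test_cohort_zscore_sum_is_zero(self, rng):
        vals = rng.gamma(2.0, 50.0, size=(30, 40))
        expr = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"g{i}" for i in range(30)],
                         columns=[f"p{j}" for j in range(40)])
        )
        table = gss(expr, GeneSignature("s", {f"g{i}" for i in range(0, 30, 2)})).table
        assert abs(table["gss"].sum()) < 1e-9

    def test_boundary_zero_goes_to_high_group(self):
        # patient p3 sits exactly at the cohort mean of both genes
        expr = ExpressionMatrix(
            pd.DataFrame(
                {"p1": [1.0, 4.0], "p2": [3.0, 6.0], "p3": [2.0, 5.0]},
                index=["g1", "g2"],
            )
        )
        table = gss(expr, GeneSignature("s", {"g1", "g2"})).table
        assert table.loc["p3", "gss"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["p3", "group"] == "high"

    def test_zero_variance_gene_errors(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"p1": [5.0], "p2": [5.0]}, index=["g1"])
        )
        with pytest.raises(ValueError, match="cv_filter"):
            gss(expr, GeneSignature("s", {"g1"}))


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        km = km_estimate(_records([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_flat_at_one(self):
        km = km_estimate(_records([1, 2, 3], [0, 0, 0]))
        assert len(km.event_times) == 0
        assert km.survival_at(10.0) == 1.0

    def test_censoring_hand_example(self):
        km = km_estimate(_records([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])

    def test_matches_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, 60)
        km = km_estimate(_records(times, np.ones(60)))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert km.survival_at(t) == pytest.approx((times > t).mean(), abs=1e-12)

    def test_curve_non_increasing(self, rng):
        times = rng.exponential(10, 100)
        events = rng.random(100) < 0.7
        km = km_estimate(_records(times, events.astype(int)))
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([SurvivalRecord("p", -1.0, 1)])

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        times = rng.exponential(12, 80)
        events = (rng.random(80) < 0.75).astype(int)
        km = km_estimate(_records(times, events))
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-9
            )


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        g = _records([1, 2, 3, 5], [1, 1, 0, 1])
        stat, p = logrank_test(g, list(g))
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_group_relabeling_invariance(self, rng):
        a = _records(rng.exponential(10, 40), rng.random(40) < 0.8)
        b = _records(rng.exponential(15, 35), rng.random(35) < 0.8, prefix="q")
        assert logrank_test(a, b)[0] == pytest.approx(logrank_test(b, a)[0])

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test as ll_logrank

        ta, tb = rng.exponential(10, 50), rng.exponential(18, 45)
        ea = (rng.random(50) < 0.8).astype(int)
        eb = (rng.random(45) < 0.8).astype(int)
        stat, p = logrank_test(_records(ta, ea), _records(tb, eb, prefix="q"))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_asymptotic_p_matches_permutation(self, rng):
        # moderately sized groups with many events: the chi-square p should
        # agree with the label-permutation reference distribution
        n = 40
        ta = rng.exponential(10, n)
        tb = rng.exponential(13, n)
        times = np.concatenate([ta, tb])
        events = np.ones(2 * n, dtype=int)
        stat, p_chi2 = logrank_test(
            _records(ta, np.ones(n)), _records(tb, np.ones(n), prefix="q")
        )
        event_times = np.unique(times)
        at_risk = times[None, :] >= event_times[:, None]  # K x 2n
        death_at = (times[None, :] == event_times[:, None]) & (events[None, :] == 1)
        n_perm = 10_000
        prng = np.random.default_rng(123)
        stats_perm = np.empty(n_perm)
        d_tot = death_at.sum(axis=1)
        n_tot = at_risk.sum(axis=1)
        for i in range(n_perm):
            lab = np.zeros(2 * n)
            lab[prng.choice(2 * n, n, replace=False)] = 1.0
            n1 = at_risk @ lab
            d1 = death_at @ lab
            with np.errstate(invalid="ignore", divide="ignore"):
                e1 = d_tot * n1 / n_tot
                v = d_tot * (n1 / n_tot) * (1 - n1 / n_tot) * (n_tot - d_tot) / np.maximum(n_tot - 1, 1)
            ok = (n_tot >= 2) & (n1 > 0) & (n1 < n_tot)
            num = (d1[ok] - e1[ok]).sum()
            den = v[ok].sum()
            stats_perm[i] = num**2 / den if den > 0 else 0.0
        p_perm = float((stats_perm >= stat - 1e-12).mean())
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert p_chi2 == pytest.approx(p_perm, abs=3 * se + 0.015)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_records([1], [0]), _records([2], [0], prefix="q"))


class TestStratificationRecovery:
    def test_planted_hazard_separates_groups(self, rng):
        # high-GSS patients get hazard ratio 3; the high group must show
        # worse survival in nearly all replicates
        worse = 0
        n_rep = 40
        for rep in range(n_rep):
            prng = np.random.default_rng(500 + rep)
            n = 300
            gss_vals = prng.standard_normal(n)
            high = gss_vals >= 0
            lam = 0.02 * np.where(high, 3.0, 1.0)
            t = prng.exponential(1 / lam)
            cens = prng.exponential(1 / 0.01, n)
            time = np.minimum(t, cens)
            event = (t <= cens).astype(int)
            hi = _records(time[high], event[high])
            lo = _records(time[~high], event[~high], prefix="q")
            km_hi, km_lo = km_estimate(hi), km_estimate(lo)
            horizon = float(np.median(time))
            worse += km_hi.survival_at(horizon) < km_lo.survival_at(horizon)
        assert worse >= 0.95 * n_rep
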