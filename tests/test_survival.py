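"""Survival screen machinery: KM, logrank, Cox, BH, grid, CV, scan, validation."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as ll_logrank

from ectoscreen import (SimulationConfig, bh_adjust, cox_fit, cv_partitions,
                        generate_cohort, km_estimator, logrank_test,
                        propagate_threshold, scan_cohort, select_candidates,
                        select_reference_threshold, survival_from_clinical,
                        threshold_grid, validation_decision)
from ectoscreen.survival import _SortedSurv, _cox_binary_counts


class TestKaplanMeier:
    def test_two_events_product_limit(self):
        kmf = km_estimator([1.0, 2.0], [1, 1])
        assert float(kmf.predict(1.0)) == pytest.approx(0.5)
        assert float(kmf.predict(2.0)) == pytest.approx(0.0)

    def test_all_censored_curve_stays_at_one(self):
        kmf = km_estimator([1.0, 2.0, 3.0], [0, 0, 0])
        assert float(kmf.predict(3.0)) == pytest.approx(1.0)

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2 and 4:
        # S(1) = 3/4; at t=3 two at risk -> S(3) = 3/4 * 1/2 = 0.375
        kmf = km_estimator([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
        assert float(kmf.predict(1.0)) == pytest.approx(0.75)
        assert float(kmf.predict(3.0)) == pytest.approx(0.375)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimator([], [])


def textbook_logrank(times_a, events_a, times_b, events_b):
    """Independent O-E / V computation, written plainly over event times."""
    times = np.concatenate([times_a, times_b])
    events = np.concatenate([events_a, events_b])
    group = np.concatenate([np.ones(len(times_a)), np.zeros(len(times_b))])
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_symmetry_under_label_swap(self):
        rng = np.random.default_rng(3)
        ta, tb = rng.exponential(1, 20), rng.exponential(2, 25)
        ea, eb = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        if ea.sum() + eb.sum() == 0:
            ea[0] = 1
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_matches_textbook_o_minus_e(self):
        ta, ea = np.array([1.0, 4.0, 6.0]), np.array([1, 1, 0])
        tb, eb = np.array([2.0, 3.0, 5.0]), np.array([1, 1, 1])
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(textbook_logrank(ta, ea, tb, eb))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_lifelines_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        ta = rng.integers(1, 8, 30).astype(float)  # heavy ties
        tb = rng.integers(1, 8, 35).astype(float)
        ea = rng.integers(0, 2, 30)
        eb = rng.integers(0, 2, 35)
        ours = logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([], [], [1.0], [1])


class TestFastCoxBinary:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_lifelines_univariate(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        on = rng.random(n) < 0.4
        times = rng.exponential(np.where(on, 0.6, 1.0))
        times = np.round(times, 1) + 0.1   # induce ties
        events = (rng.random(n) < 0.7).astype(int)
        ss = _SortedSurv(times, events)
        r1, d1 = ss.group_counts(on[None, :])
        hr = _cox_binary_counts(ss.N, ss.d, r1, d1)[0]
        df = pd.DataFrame({"t": times, "e": events, "x": on.astype(float)})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert np.log(hr) == pytest.approx(cph.params_["x"], abs=1e-4)

    def test_no_information_split_gives_nan(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 1])
        ss = _SortedSurv(times, events)
        on = np.zeros((1, 4), dtype=bool)   # empty ON arm
        r1, d1 = ss.group_counts(on)
        assert np.isnan(_cox_binary_counts(ss.N, ss.d, r1, d1)[0])


class TestCoxFit:
    def test_planted_log_hazard_recovered(self):
        rng = np.random.default_rng(10)
        n = 1000
        x = rng.normal(size=n)
        times = rng.exponential(1.0 / (0.3 * np.exp(0.7 * x)))
        events = np.ones(n, dtype=int)
        df = pd.DataFrame({"dfs_time": times, "dfs_event": events, "x": x})
        fit = cox_fit(df, ["x"])
        assert fit.loc["x", "coef"] == pytest.approx(0.7, abs=0.15)

    def test_null_covariate_p_calibrated(self):
        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            n = 60
            df = pd.DataFrame({
                "dfs_time": rng.exponential(1, n),
                "dfs_event": np.ones(n, dtype=int),
                "x": rng.normal(size=n)})
            hits += cox_fit(df, ["x"]).loc["x", "p"] < 0.05
        assert 0.0 <= hits / n_sim <= 0.12

    def test_binary_covariate_matches_event_rate_ratio(self):
        # exponential data: the Cox HR of a binary group indicator agrees
        # with the ratio of empirical event rates (events / person-time)
        rng = np.random.default_rng(12)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(1.0 / (0.2 * np.exp(0.8 * x)))
        df = pd.DataFrame({"dfs_time": times, "dfs_event": 1, "x": x})
        fit = cox_fit(df, ["x"])
        rate1 = n / 2 / times[x == 1].sum()
        rate0 = n / 2 / times[x == 0].sum()
        assert fit.loc["x", "hazard_ratio"] == pytest.approx(rate1 / rate0, rel=0.05)

    def test_constant_covariate_dropped(self):
        df = pd.DataFrame({"dfs_time": [1.0, 2, 3, 4], "dfs_event": [1, 1, 0, 1],
                           "x": [1.0, 1, 1, 1], "y": [0.0, 1, 0, 1]})
        fit = cox_fit(df, ["x", "y"])
        assert list(fit.index) == ["y"]


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self):
        p = np.array([0.5, 0.001, 0.04, 0.2, 0.01])
        a = np.sort(bh_adjust(p))
        b = np.sort(bh_adjust(p[::-1]))
        np.testing.assert_allclose(a, b)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj >= p - 1e-12) and np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestThresholdGrid:
    def test_grid_has_141_points_before_collapsing(self):
        rng = np.random.default_rng(0)
        grid = threshold_grid(rng.normal(size=500))
        assert len(grid) == 141
        assert grid["percentile"].iloc[0] == 15.0
        assert grid["percentile"].iloc[-1] == 85.0

    def test_constant_gene_empty_grid(self):
        assert threshold_grid(np.full(50, 3.0)).empty

    def test_quantile_convention(self):
        grid = threshold_grid(np.arange(1.0, 101.0))
        at50 = grid.loc[grid["percentile"] == 50.0, "value"].iloc[0]
        assert at50 == pytest.approx(50.5)

    def test_duplicates_collapse_to_lowest_percentile(self):
        vals = np.concatenate([np.zeros(60), np.ones(40)])
        grid = threshold_grid(vals)
        assert grid["value"].is_unique
        # the run of identical zero-quantiles keeps percentile 15
        assert grid["percentile"].iloc[0] == 15.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            threshold_grid(np.arange(5.0))


class TestCVPartitions:
    def test_folds_partition_each_repeat(self):
        subs = cv_partitions(30, k=3, repeats=5, seed=1, mode="held_out")
        assert len(subs) == 15
        for r in range(5):
            folds = subs[3 * r: 3 * r + 3]
            union = np.sort(np.concatenate(folds))
            np.testing.assert_array_equal(union, np.arange(30))

    def test_held_in_subsets_are_complements(self):
        held_in = cv_partitions(30, seed=2, mode="held_in")
        held_out = cv_partitions(30, seed=2, mode="held_out")
        for hi, ho in zip(held_in, held_out):
            assert set(hi) | set(ho) == set(range(30))
            assert not set(hi) & set(ho)

    def test_seed_determinism(self):
        a = cv_partitions(40, seed=7)
        b = cv_partitions(40, seed=7)
        c = cv_partitions(40, seed=8)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            cv_partitions(8, k=3)


@pytest.fixture(scope="module")
def scanned():
    cfg = SimulationConfig(seed=42)
    cohort = generate_cohort(cfg, 0)
    surv = survival_from_clinical(cohort.clinical)
    genes = cfg.activatable_genes[:8] + ["G0100", "G0101"]
    records = scan_cohort(cohort.expression, surv, genes, seed=42,
                          grid_step=2.0)
    return cfg, records


class TestScan:
    def test_records_well_formed(self, scanned):
        _, records = scanned
        assert records["logrank_p"].between(0, 1).all()
        assert records["stability"].between(0, 1).all()
        assert (records[["n_on", "n_off"]].min(axis=1) >= 90).all()  # 15% of 600
        assert records.groupby("gene")["threshold"].apply(
            lambda s: s.is_unique).all()

    def test_planted_gene_hits_significance(self, scanned):
        cfg, records = scanned
        best = records[records["gene"] == cfg.prognostic_genes[0]]
        top = best.loc[best["logrank_p"].idxmin()]
        assert top["logrank_p"] < 0.05
        assert top["hazard_ratio"] > 1.0

    def test_selected_candidates_respect_gates(self, scanned):
        _, records = scanned
        cands = select_candidates(records)
        assert (cands["hazard_ratio"] > 1.0).all()
        assert (cands["fdr"] < 0.2).all()
        assert (cands["logrank_p"] < 0.05).all()


class TestReferenceSelection:
    def make_records(self, rows):
        return pd.DataFrame(rows, columns=["gene", "percentile", "threshold",
                                           "logrank_p", "hazard_ratio",
                                           "stability", "fdr"])

    def test_no_significant_threshold_returns_none(self):
        rec = self.make_records([("g", 20.0, 1.0, 0.2, 1.5, 0.9, 0.5)])
        assert select_reference_threshold(rec) is None

    def test_max_stability_wins(self):
        rec = self.make_records([
            ("g", 20.0, 1.0, 0.01, 2.0, 0.4, 0.05),
            ("g", 30.0, 1.5, 0.02, 2.0, 0.8, 0.05)])
        assert select_reference_threshold(rec).percentile == 30.0

    def test_stability_tie_breaks_by_p_then_percentile(self):
        rec = self.make_records([
            ("g", 30.0, 1.5, 0.010, 2.0, 0.8, 0.05),
            ("g", 20.0, 1.0, 0.001, 2.0, 0.8, 0.05)])
        assert select_reference_threshold(rec).percentile == 20.0
        rec2 = self.make_records([
            ("g", 30.0, 1.5, 0.01, 2.0, 0.8, 0.05),
            ("g", 20.0, 1.0, 0.01, 2.0, 0.8, 0.05)])
        assert select_reference_threshold(rec2).percentile == 20.0

    def test_hr_below_one_never_selected(self):
        rec = self.make_records([("g", 20.0, 1.0, 0.001, 0.5, 1.0, 0.01)])
        assert select_reference_threshold(rec) is None


class TestPropagation:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=200)
        grid = threshold_grid(vals)
        row = grid.iloc[40]
        assert propagate_threshold(row["percentile"], vals) == \
            pytest.approx(row["value"])

    def test_shift_equivariance(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=150)
        thr = propagate_threshold(40.0, vals)
        assert propagate_threshold(40.0, vals + 1.5) == pytest.approx(thr + 1.5)

    def test_on_frequency_preserved_across_cohort_shift(self):
        # a shifted validation cohort keeps the source ON fraction after
        # percentile propagation (the point of rank-based transfer)
        cfg = SimulationConfig(seed=9, cohort_shift_sd=1.5, n_tumour=500)
        a = generate_cohort(cfg, 0)
        b = generate_cohort(cfg, 1)
        gene = cfg.activatable_genes[0]
        sa = survival_from_clinical(a.clinical)
        sb = survival_from_clinical(b.clinical)
        va = a.expression.loc[gene, sa.index].to_numpy()
        vb = b.expression.loc[gene, sb.index].to_numpy()
        pct = 70.0
        fa = np.mean(va > propagate_threshold(pct, va))
        fb = np.mean(vb > propagate_threshold(pct, vb))
        assert abs(fa - fb) < 0.05


class TestValidationRule:
    def test_all_three_significant(self):
        assert validation_decision([0.01, 0.02, 0.03], [2.0, 1.8, 1.5])

    def test_two_of_three_with_weak_third(self):
        assert validation_decision([0.01, 0.04, 0.09], [2.0, 1.8, 1.5])

    def test_high_third_p_rejected(self):
        assert not validation_decision([0.01, 0.02, 0.5], [2.0, 1.8, 1.5])

    def test_hr_below_one_not_significant(self):
        assert not validation_decision([0.01, 0.02, 0.09], [2.0, 0.5, 1.5])

    def test_nan_always_fails(self):
        assert not validation_decision([0.01, 0.02, np.nan], [2.0, 1.8, 1.5])

    def test_generalized_m_cohorts(self):
        # m=6 needs ceil(12/6/... ) = 4 significant, others < 0.1
        p = [0.01, 0.01, 0.01, 0.04, 0.08, 0.09]
        hr = [2.0] * 6
        assert validation_decision(p, hr)
        assert not validation_decision([0.01, 0.01, 0.01, 0.04, 0.08, 0.2], hr)
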