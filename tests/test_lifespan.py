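"""Spline fits, AIC selection, kneedle inflections, period OLS, BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from hippofactory import lifespan as ls
from hippofactory import phantom as ph
from hippofactory.io_prep import LabelMap


def cohort(n=400, noise=30.0, seed=0, **kw):
    return ph.make_lifespan_cohort(ph.LifespanSpec(n_subjects=n,
                                                   noise_sd=noise, seed=seed,
                                                   **kw))


def single_region_table(ages, volumes, sex="F", region="DG"):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(len(ages))],
        "age": ages, "sex": sex, "region": region, "volume_mm3": volumes})


class TestFitNcs:
    def test_recovers_noiseless_spline_data(self, rng):
        ages = rng.uniform(5, 100, 300)
        from patsy import dmatrix
        basis = np.asarray(dmatrix("cr(age, df=4) - 1", {"age": ages}))
        coef = np.array([800.0, 950.0, 1020.0, 890.0])
        volumes = basis @ coef
        fit = ls.fit_ncs(single_region_table(ages, volumes), "DG", "F", 4)
        assert fit.r_squared >= 0.999
        np.testing.assert_allclose(fit.predict(ages), volumes, rtol=1e-8)

    def test_linear_data_collapses_to_line(self, rng):
        ages = rng.uniform(5, 100, 200)
        volumes = 1000.0 + 3.0 * ages
        fit = ls.fit_ncs(single_region_table(ages, volumes), "DG", "F", 5)
        grid = np.linspace(5, 100, 50)
        np.testing.assert_allclose(fit.predict(grid), 1000.0 + 3.0 * grid,
                                   atol=1e-6 * 3.0 * 100)

    def test_boundary_linearity_of_ncs(self, rng):
        # second derivative ~ 0 beyond the boundary knots
        ages = rng.uniform(20, 80, 300)
        volumes = 1000 + 5 * ages - 0.06 * ages ** 2 + rng.normal(0, 5, 300)
        fit = ls.fit_ncs(single_region_table(ages, volumes), "DG", "F", 5)
        for grid in (np.linspace(0, 15, 10), np.linspace(85, 110, 10)):
            y = fit.predict(grid)
            second = np.diff(y, 2)
            assert np.abs(second).max() < 1e-6 * max(1.0, np.abs(y).max())

    def test_too_few_points_rejected(self, rng):
        ages = rng.uniform(5, 100, 5)
        with pytest.raises(ValueError, match="at least"):
            ls.fit_ncs(single_region_table(ages, ages), "DG", "F", 4)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="lacks columns"):
            ls.fit_ncs(pd.DataFrame({"age": [1, 2, 3]}), "DG", "F", 3)


class TestSelectDfAic:
    def test_singleton_range(self):
        table = cohort(n=100, seed=1)
        assert ls.select_df_aic(table, "DG", "F", [4]) == 4

    def test_scale_equivariance(self):
        table = cohort(n=200, seed=2)
        a = ls.select_df_aic(table, "DG", "F", range(3, 8))
        scaled = table.copy()
        scaled.volume_mm3 *= 1000.0
        b = ls.select_df_aic(scaled, "DG", "F", range(3, 8))
        assert a == b

    def test_pure_noise_selects_parsimonious_df(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            ages = r.uniform(5, 100, 300)
            vols = r.normal(1000, 50, 300)
            table = single_region_table(ages, vols)
            if ls.select_df_aic(table, "DG", "F", range(3, 8)) == 3:
                hits += 1
        assert hits >= 11   # majority of seeds pick the bottom of the range

    def test_recovers_generating_df_majority(self, rng):
        # df=5 structure, low noise: selection should find df=5 mostly
        ages = np.random.default_rng(0).uniform(5, 100, 1000)
        from patsy import dmatrix
        basis = np.asarray(dmatrix("cr(age, df=5) - 1", {"age": ages}))
        coef = np.array([900.0, 1100.0, 980.0, 1250.0, 800.0])
        signal = basis @ coef
        hits = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).normal(0, 8.0, len(ages))
            table = single_region_table(ages, signal + noise)
            if ls.select_df_aic(table, "DG", "F", range(3, 8)) == 5:
                hits += 1
        assert hits >= 18


class TestInflections:
    def test_corner_curve_knee_at_one(self):
        fit = ls.TrajectoryFit(region="x", sex="F", df=3,
                               knots=np.array([0.0]), coefficients=np.array([]),
                               aic=0, r_squared=1, p_value=0,
                               age_range=(0.0, 4.0))
        fit.predict = lambda g: np.minimum(np.asarray(g), 1.0)
        knees = ls.detect_inflections(fit, step=0.5)
        assert len(knees) == 1
        assert abs(knees[0] - 1.0) <= 0.5

    def test_straight_line_has_no_inflection(self):
        fit = ls.TrajectoryFit(region="x", sex="F", df=3,
                               knots=np.array([0.0]), coefficients=np.array([]),
                               aic=0, r_squared=1, p_value=0,
                               age_range=(0.0, 10.0))
        fit.predict = lambda g: 2.0 * np.asarray(g) + 1.0
        assert ls.detect_inflections(fit) == []

    def test_decay_onset_recovered_from_cohort(self):
        # growth-stability-decay cohort, decay knot at 70: detection in 70 +- 3
        table = cohort(n=2000, noise=45.0, seed=11)
        df = ls.select_df_aic(table, "DG", "F", range(3, 8))
        fit = ls.fit_ncs(table, "DG", "F", df)
        knees = ls.detect_inflections(fit)
        assert any(abs(k - 70) <= 3 for k in knees)


class TestPeriodRegressions:
    def test_interaction_detected_when_slopes_differ(self):
        r = np.random.default_rng(3)
        n = 500
        ages = r.uniform(5, 20, 2 * n)
        sexes = np.array(["F"] * n + ["M"] * n)
        slopes = np.where(sexes == "M", 20.0, 10.0)
        vols = 500 + slopes * ages + r.normal(0, 30, 2 * n)
        table = pd.DataFrame({"subject_id": [f"s{i}" for i in range(2 * n)],
                              "age": ages, "sex": sexes, "region": "DG",
                              "volume_mm3": vols})
        res, = ls.period_regressions(table, "DG", [(5, 21)])
        assert res.p_values["age_x_sex"] < 0.05
        assert res.interaction_age_sex == pytest.approx(10.0, abs=2.0)

    def test_no_sex_effect_interaction_near_zero(self):
        r = np.random.default_rng(4)
        n = 400
        ages = r.uniform(25, 60, 2 * n)
        sexes = np.array(["F", "M"] * n)
        vols = 900 + 1.5 * ages + r.normal(0, 25, 2 * n)
        table = pd.DataFrame({"subject_id": [f"s{i}" for i in range(2 * n)],
                              "age": ages, "sex": sexes, "region": "DG",
                              "volume_mm3": vols})
        res, = ls.period_regressions(table, "DG", [(25, 61)])
        assert res.p_values["age_x_sex"] > 0.001   # no spurious certainty

    def test_single_sex_drops_sex_terms(self):
        r = np.random.default_rng(5)
        ages = r.uniform(5, 50, 100)
        table = single_region_table(ages, 400 + 2 * ages + r.normal(0, 5, 100))
        res, = ls.period_regressions(table, "DG", [(5, 51)])
        assert res.effect_sex is None and res.interaction_age_sex is None
        assert res.slope_age == pytest.approx(2.0, abs=0.3)

    def test_empty_period_skipped_with_warning(self):
        table = cohort(n=50, seed=6)
        with pytest.warns(UserWarning, match="empty period"):
            out = ls.period_regressions(table, "DG", [(200.0, 300.0)])
        assert out == []


class TestBhFdr:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(ls.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ls.bh_fdr([0.37]), [0.37])

    def test_all_ones(self):
        np.testing.assert_allclose(ls.bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_hand_step_up_oracle(self, rng):
        def oracle(p):
            p = np.asarray(p, float)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                adj[i] = prev
            return adj

        for _ in range(20):
            p = rng.random(rng.integers(1, 12))
            np.testing.assert_allclose(ls.bh_fdr(p), oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_order_invariant(self, rng):
        p = rng.random(9)
        adj = ls.bh_fdr(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()
        perm = rng.permutation(9)
        np.testing.assert_allclose(ls.bh_fdr(p[perm]), adj[perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ls.bh_fdr([0.5, 1.5])


class TestAnteroposteriorProfile:
    def test_fractions_sum_to_one(self, default_phantom):
        _, lab = default_phantom
        prof = ls.anteroposterior_profile([lab], axis=1)
        sums = prof.drop(columns="position_pct").sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_head_tail_caps_dominate_profile_ends(self, default_phantom):
        _, lab = default_phantom
        prof = ls.anteroposterior_profile([lab], axis=1)
        assert prof.HEAD.iloc[0] > 0.99      # 0% position: pure head cap
        assert prof.TAIL.iloc[-1] > 0.99     # 100% position: pure tail cap
        mid = prof.iloc[len(prof) // 2]
        assert mid[["DG", "CA1", "CA2", "CA3", "SUB"]].sum() > 0.99

    def test_single_subject_average_is_identity(self, default_phantom):
        _, lab = default_phantom
        single = ls.anteroposterior_profile([lab], axis=1)
        double = ls.anteroposterior_profile([lab, lab], axis=1)
        pd.testing.assert_frame_equal(single, double)

    def test_empty_labelmap_rejected(self):
        empty = LabelMap(data=np.zeros((8, 8, 8), dtype=np.int16))
        with pytest.raises(ValueError, match="empty"):
            ls.anteroposterior_profile([empty])

    def test_generator_partition_recovered(self):
        # fractions of the longitudinal partition match the carved geometry
        spec = ph.PhantomSpec(head_fraction=0.2, tail_fraction=0.2)
        _, lab = ph.make_hippocampus_phantom(spec)
        prof = ls.anteroposterior_profile([lab], axis=1)
        head_region = prof[prof.position_pct < 15]
        assert (head_region.HEAD > 0.99).all()
        body = prof[(prof.position_pct > 30) & (prof.position_pct < 70)]
        assert (body.HEAD < 1e-9).all() and (body.TAIL < 1e-9).all()


class TestAnalyzeCohort:
    def test_full_recovery_pipeline(self):
        table = cohort(n=800, noise=35.0, seed=9)
        table = table[table.region.isin(["DG", "SUB"])]
        result = ls.analyze_cohort(table, df_range=range(3, 8))
        for region in ("DG", "SUB"):
            inflections = result["regions"][region]["inflections"]
            assert any(abs(k - 70) <= 5 for k in inflections)
            periods = result["regions"][region]["periods"]
            # periods partition the age range
            for (a, b), (c, d) in zip(periods, periods[1:]):
                assert b == c
        for pr in result["period_results"]:
            for term, adj in pr.p_adjusted.items():
                assert adj >= pr.p_values[term] - 1e-12
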