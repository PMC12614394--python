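"""Group tests, RM-ANOVA, mixed models and severity regression."""

import numpy as np
import pandas as pd
import pytest

from tapvoice.stats import (
    InsufficientDataError,
    build_report,
    fit_lmm_time_group,
    fit_lmm_time_severity,
    group_compare,
    severity_regression,
    tf_anova,
)


def _records(values_by_subject, group_by_subject, task="x", feature="f",
             tf=0, updrs=None):
    rows = []
    for sid, vals in values_by_subject.items():
        for i, v in enumerate(np.atleast_1d(vals)):
            rows.append(dict(subject_id=sid, group=group_by_subject[sid],
                             updrs3=(updrs or {}).get(sid, np.nan),
                             task=task, trial=f"r{i + 1}", tf=tf,
                             feature=feature, value=float(v)))
    return pd.DataFrame(rows)


def _tf_records(subjects, group, values_fn, task="x", feature="f", updrs=None,
                n_trials=2):
    rows = []
    for sid in subjects:
        for r in range(1, n_trials + 1):
            for k in range(1, 6):
                rows.append(dict(subject_id=sid, group=group[sid],
                                 updrs3=(updrs or {}).get(sid, np.nan),
                                 task=task, trial=f"r{r}", tf=k,
                                 feature=feature, value=values_fn(sid, r, k)))
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_hand_computed_pooled_t(self):
        df = _records({"a1": 1, "a2": 2, "a3": 3, "b1": 4, "b2": 5, "b3": 6},
                      {"a1": "control", "a2": "control", "a3": "control",
                       "b1": "PD", "b2": "PD", "b3": "PD"})
        r = group_compare(df, "x", "f")
        assert r.t == pytest.approx(-3.674, abs=1e-3)
        assert r.df == 4
        assert r.mean_a == 2 and r.mean_b == 5

    def test_identical_groups(self):
        vals = {f"a{i}": float(i) for i in range(4)}
        vals.update({f"b{i}": float(i) for i in range(4)})
        grp = {k: ("control" if k.startswith("a") else "PD") for k in vals}
        r = group_compare(_records(vals, grp), "x", "f")
        assert r.t == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_sign_flips_with_labels(self, rng):
        vals = {f"s{i}": rng.normal(i % 2, 1) for i in range(12)}
        grp = {k: ("control" if int(k[1:]) % 2 else "PD") for k in vals}
        r1 = group_compare(_records(vals, grp), "x", "f")
        flipped = {k: ("PD" if v == "control" else "control")
                   for k, v in grp.items()}
        r2 = group_compare(_records(vals, flipped), "x", "f")
        assert r2.t == pytest.approx(-r1.t, rel=1e-9)
        assert r2.p == pytest.approx(r1.p, rel=1e-9)

    def test_df_38_at_20_per_group(self, feature_table):
        df, _ = feature_table
        r = group_compare(df, "tapping", "total_taps")
        assert r.df == 38

    def test_small_group_raises(self):
        df = _records({"a1": 1.0, "b1": 2.0, "b2": 3.0},
                      {"a1": "control", "b1": "PD", "b2": "PD"})
        with pytest.raises(InsufficientDataError):
            group_compare(df, "x", "f")


class TestTfAnova:
    def test_flat_time_course(self, rng):
        subjects = [f"s{i}" for i in range(8)]
        grp = {s: "PD" for s in subjects}
        base = {s: rng.normal(1.0, 0.2) for s in subjects}
        df = _tf_records(subjects, grp, lambda s, r, k: base[s], n_trials=1)
        an, post = tf_anova(df, "PD", "x", "f")
        assert an.F == pytest.approx(0.0, abs=1e-10)
        assert an.p == pytest.approx(1.0)
        assert not any(p.significant for p in post)

    def test_strong_frame_effect_detected(self, rng):
        subjects = [f"s{i}" for i in range(15)]
        grp = {s: "PD" for s in subjects}
        df = _tf_records(subjects, grp,
                         lambda s, r, k: 0.1 * k + rng.normal(0, 0.05))
        an, post = tf_anova(df, "PD", "x", "f")
        assert an.p < 0.01
        assert post[-1].significant  # TF5 vs TF1

    def test_holm_adjusted_monotone_in_raw_rank(self, rng):
        subjects = [f"s{i}" for i in range(12)]
        grp = {s: "PD" for s in subjects}
        df = _tf_records(subjects, grp,
                         lambda s, r, k: 0.05 * k + rng.normal(0, 0.15))
        _, post = tf_anova(df, "PD", "x", "f")
        order = np.argsort([p.p_raw for p in post])
        adj_sorted = np.array([post[i].p_adj for i in order])
        assert np.all(np.diff(adj_sorted) >= -1e-12)
        assert all(p.p_adj >= p.p_raw - 1e-12 for p in post)

    def test_first_significant_posthoc_frame_is_tf2(self, rng):
        # variability rising from TF2 onward: the earliest Holm-significant
        # post hoc frame should be TF2 in the large majority of replicates
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            rows = []
            for i in range(20):
                b = rng.normal(0.10, 0.04)
                for k in range(1, 6):
                    rows.append(dict(subject_id=f"s{i}", group="PD",
                                     updrs3=np.nan, task="x", trial="r1",
                                     tf=k, feature="f",
                                     value=b + 0.012 * (k - 1)
                                     + rng.normal(0, 0.0085)))
            _, post = tf_anova(pd.DataFrame(rows), "PD", "x", "f")
            sig = [p.frame for p in post if p.significant]
            hits += bool(sig) and min(sig) == 2
        assert hits / n_reps >= 0.80

    def test_type1_error_calibrated(self, rng):
        # homogeneous generator: rejections near the nominal 5% level
        rejections = 0
        n_cohorts = 400
        for _ in range(n_cohorts):
            vals = rng.normal(0, 1, (10, 5))
            rows = [dict(subject_id=f"s{i}", group="PD", updrs3=np.nan,
                         task="x", trial="r1", tf=k + 1, feature="f",
                         value=vals[i, k])
                    for i in range(10) for k in range(5)]
            an, _ = tf_anova(pd.DataFrame(rows), "PD", "x", "f")
            rejections += an.p < 0.05
        assert 0.03 <= rejections / n_cohorts <= 0.08


class TestLMM:
    def test_duplicated_trials_leave_fixed_effects_unchanged(self, feature_table):
        df, _ = feature_table
        one = df[(df.task == "a") & (df.feature == "loudness") & (df.tf >= 1)
                 & (df.trial == "r1")]
        fit1 = fit_lmm_time_group(one, "a", "loudness")
        two = pd.concat([one, one.assign(trial="r2")], ignore_index=True)
        fit2 = fit_lmm_time_group(two, "a", "loudness")
        for name in fit1.terms:
            assert fit2[name].coef == pytest.approx(fit1[name].coef, abs=1e-6)

    def test_zero_variance_ratio_matches_ols(self, rng):
        import statsmodels.api as sm
        sid = np.repeat([f"s{i}" for i in range(8)], 10)
        tf = np.tile(np.arange(1, 6), 16).astype(float)
        u = np.repeat(rng.integers(5, 60, 8), 10).astype(float)
        y = 1 + 0.2 * tf + 0.01 * u + 0.005 * tf * u + rng.normal(0, 0.5, 80)
        df = pd.DataFrame(dict(subject_id=sid, group="PD", updrs3=u, task="x",
                               trial="r1", tf=tf, feature="f", value=y))
        fit = fit_lmm_time_severity(df, "x", "f", re_variance_ratio=1e-12)
        X = np.column_stack([np.ones(80), tf, u, tf * u])
        ols = sm.OLS(y, X).fit()
        est = [fit[n].coef for n in ("intercept", "tf", "updrs3", "tf:updrs3")]
        assert np.max(np.abs(np.array(est) - ols.params)) < 1e-6

    def test_constant_updrs_raises(self):
        df = _tf_records([f"s{i}" for i in range(6)],
                         {f"s{i}": "PD" for i in range(6)},
                         lambda s, r, k: float(k),
                         updrs={f"s{i}": 20 for i in range(6)})
        with pytest.raises(InsufficientDataError):
            fit_lmm_time_severity(df, "x", "f")

    def test_severity_interaction_recovered(self, rng):
        subjects = [f"s{i}" for i in range(20)]
        updrs = {s: float(rng.integers(5, 60)) for s in subjects}
        grp = {s: "PD" for s in subjects}
        beta_int = 0.02
        df = _tf_records(
            subjects, grp,
            lambda s, r, k: 1.0 + 0.1 * k + beta_int * updrs[s] * k
            + rng.normal(0, 0.5),
            updrs=updrs, n_trials=4)
        fit = fit_lmm_time_severity(df, "x", "f")
        assert fit["tf:updrs3"].coef == pytest.approx(beta_int, rel=0.25)
        assert fit["tf:updrs3"].p < 0.01

    def test_reported_terms(self, feature_table):
        df, _ = feature_table
        fit = fit_lmm_time_group(df, "i", "shimmer")
        assert set(fit.terms) == {"intercept", "tf", "group", "tf:group"}
        fit = fit_lmm_time_severity(df, "i", "shimmer")
        assert set(fit.terms) == {"intercept", "tf", "updrs3", "tf:updrs3"}
        for t in fit.terms.values():
            assert t.ci_low <= t.coef <= t.ci_high


class TestSeverityRegression:
    def test_exact_linear_feature(self):
        subjects = {f"s{i}": 2.0 * (10 + i) for i in range(8)}
        updrs = {f"s{i}": float(10 + i) for i in range(8)}
        df = _records(subjects, {s: "PD" for s in subjects}, updrs=updrs)
        r = severity_regression(df, "x", "f", tf=0)
        assert r.r == pytest.approx(1.0)
        assert r.r2 == pytest.approx(1.0)
        assert r.slope == pytest.approx(2.0)

    def test_r2_is_r_squared(self, feature_table):
        df, _ = feature_table
        r = severity_regression(df, "a", "loudness")
        assert r.r2 == pytest.approx(r.r**2, abs=1e-12)

    def test_null_feature_near_zero(self, rng):
        subjects = {f"s{i}": rng.normal(0, 1, 10) for i in range(30)}
        updrs = {f"s{i}": float(rng.integers(5, 60)) for i in range(30)}
        df = _records(subjects, {s: "PD" for s in subjects}, updrs=updrs)
        r = severity_regression(df, "x", "f", tf=0)
        assert abs(r.r) < 0.15

    def test_zero_variance_raises(self):
        df = _records({f"s{i}": 1.0 for i in range(5)},
                      {f"s{i}": "PD" for i in range(5)},
                      updrs={f"s{i}": 20.0 + i for i in range(5)})
        with pytest.raises(ZeroDivisionError):
            severity_regression(df, "x", "f", tf=0)


class TestReport:
    def test_empty_table_marked(self, tmp_path):
        rep = build_report(pd.DataFrame(), out_dir=tmp_path)
        assert rep["no_data"] is True
        assert (tmp_path / "report.json").exists()

    def test_one_interaction_row_per_model(self, feature_table, tmp_path):
        df, truth = feature_table
        rep = build_report(df, truth={"models": truth.models}, out_dir=tmp_path)
        rows = [r for r in rep["time_severity_lmm"] if r["term"] == "tf:updrs3"]
        keys = {(r["task"], r["feature"]) for r in rows}
        assert len(rows) == len(keys) == 9
        assert (tmp_path / "tables" / "time_severity_lmm.csv").exists()

    def test_recovery_section_flags_null_truth(self):
        from tapvoice.cohort import sample_cohort, simulate_feature_table
        profiles, truth = sample_cohort(6, 6, "null_interaction", seed=31)
        df = simulate_feature_table(profiles, truth, n_sessions=1, n_trials=1)
        rep = build_report(df, truth={"models": truth.models})
        rec = rep["recovery"]
        assert rec and all(r["true_interaction_is_zero"] for r in rec)
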