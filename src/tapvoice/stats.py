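"""Statistical battery on the long feature table.

Covers the analysis chain for per-time-frame digital biomarkers:

* pooled-variance two-sample t tests on per-subject means (group contrast,
  df = n_a + n_b − 2);
* one-way repeated-measures ANOVA across the five time frames within a
  group, with Holm-adjusted paired post hoc tests of each frame against TF1;
* random-intercept linear mixed models for the time x group and
  time x severity (UPDRS part III) interactions, time frame coded 1..5 as
  numeric, group coded control = 0 / PD = 1, UPDRS uncentered;
* Pearson correlation / simple regression of feature values on severity.

All operations consume the long format produced by the extraction modules:
one row per subject x task x trial x time frame x feature.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, fit_lmm

FEATURE_COLUMNS = ["subject_id", "group", "updrs3", "task", "trial", "tf",
                   "feature", "value"]


@dataclass
class TTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    n_a: int
    n_b: int


@dataclass
class AnovaResult:
    F: float
    df_between: float
    df_within: float
    p: float
    n_subjects: int


@dataclass
class PostHocResult:
    frame: int
    t: float
    p_raw: float
    p_adj: float
    significant: bool


@dataclass
class RegressionResult:
    r: float
    r2: float
    p: float
    slope: float
    intercept: float
    n: int


class InsufficientDataError(ValueError):
    pass


def _select(records: pd.DataFrame, task: str, feature: str,
            tf: int | None = None) -> pd.DataFrame:
    df = records[(records["task"] == task) & (records["feature"] == feature)]
    if tf is not None:
        df = df[df["tf"] == tf]
    return df.dropna(subset=["value"])


def aggregate_per_subject(records: pd.DataFrame, task: str, feature: str,
                          tf: int | None = 0) -> pd.DataFrame:
    """Per-subject mean over trials/hands/sessions (and frames if tf=None)."""
    df = _select(records, task, feature, tf)
    out = (df.groupby(["subject_id", "group"], as_index=False)
             .agg(value=("value", "mean"), updrs3=("updrs3", "first")))
    return out


def group_compare(records: pd.DataFrame, task: str, feature: str,
                  tf: int = 0) -> TTestResult:
    """Pooled-variance t test, healthy controls vs PD, on subject means."""
    agg = aggregate_per_subject(records, task, feature, tf)
    a = agg.loc[agg["group"] == "control", "value"].to_numpy()
    b = agg.loc[agg["group"] == "PD", "value"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 subjects per group for {task}/{feature} (got {len(a)}, {len(b)})"
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        t=float(t), df=len(a) + len(b) - 2, p=float(p),
        n_a=len(a), n_b=len(b),
    )


def tf_anova(records: pd.DataFrame, group: str, task: str, feature: str,
             alpha: float = 0.05) -> tuple[AnovaResult, list[PostHocResult]]:
    """Repeated-measures ANOVA across TF1..TF5 within one group.

    Post hoc: paired t of each later frame against TF1, Holm-adjusted.
    Subjects lacking any frame are dropped listwise with a warning.
    """
    df = _select(records, task, feature)
    df = df[(df["tf"] >= 1) & (df["group"] == group)]
    cell = (df.groupby(["subject_id", "tf"], as_index=False)["value"].mean())
    wide = cell.pivot(index="subject_id", columns="tf", values="value")
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"{len(wide) - len(complete)} subjects dropped listwise "
            f"(incomplete time frames) for {task}/{feature}"
        )
    if len(complete) < 3:
        raise InsufficientDataError("need >= 3 complete subjects for RM-ANOVA")
    centred = complete.to_numpy() - complete.to_numpy().mean(axis=1, keepdims=True)
    if np.allclose(centred, 0.0, atol=1e-12):
        # no within-subject variation across frames: flat time course
        anova = AnovaResult(F=0.0, df_between=4.0,
                            df_within=float(4 * (len(complete) - 1)), p=1.0,
                            n_subjects=len(complete))
        post = [PostHocResult(frame=k, t=0.0, p_raw=1.0, p_adj=1.0,
                              significant=False) for k in range(2, 6)]
        return anova, post
    long = complete.reset_index().melt(id_vars="subject_id", var_name="tf",
                                       value_name="value")
    res = AnovaRM(long, depvar="value", subject="subject_id",
                  within=["tf"]).fit()
    row = res.anova_table.iloc[0]
    anova = AnovaResult(F=float(row["F Value"]), df_between=float(row["Num DF"]),
                        df_within=float(row["Den DF"]), p=float(row["Pr > F"]),
                        n_subjects=len(complete))
    raw = []
    for k in range(2, 6):
        t, p = sps.ttest_rel(complete[k], complete[1])
        raw.append((k, float(t), float(p)))
    rej, p_adj, _, _ = multipletests([p for _, _, p in raw], alpha=alpha,
                                     method="holm")
    post = [PostHocResult(frame=k, t=t, p_raw=p, p_adj=float(pa),
                          significant=bool(r))
            for (k, t, p), pa, r in zip(raw, p_adj, rej)]
    return anova, post


def _lmm_frame(records: pd.DataFrame, task: str, feature: str,
               pd_only: bool) -> pd.DataFrame:
    df = _select(records, task, feature)
    df = df[df["tf"] >= 1]
    if pd_only:
        df = df[df["group"] == "PD"].dropna(subset=["updrs3"])
    if df.empty:
        raise InsufficientDataError(f"no frame-level records for {task}/{feature}")
    return df


def fit_lmm_time_group(records: pd.DataFrame, task: str, feature: str,
                       reml: bool = True,
                       re_variance_ratio: float | None = None) -> LMMFit:
    """value ~ 1 + tf + group + tf:group, random intercept per subject."""
    df = _lmm_frame(records, task, feature, pd_only=False)
    tf = df["tf"].to_numpy(dtype=float)
    grp = (df["group"] == "PD").to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), tf, grp, tf * grp])
    n_subj = df["subject_id"].nunique()
    return fit_lmm(df["value"].to_numpy(), X, df["subject_id"].to_numpy(),
                   ["intercept", "tf", "group", "tf:group"], reml=reml,
                   re_variance_ratio=re_variance_ratio,
                   df_subject=max(n_subj - 2, 1))


def fit_lmm_time_severity(records: pd.DataFrame, task: str, feature: str,
                          reml: bool = True,
                          re_variance_ratio: float | None = None) -> LMMFit:
    """value ~ 1 + tf + updrs3 + tf:updrs3 within the PD group."""
    df = _lmm_frame(records, task, feature, pd_only=True)
    u = df["updrs3"].to_numpy(dtype=float)
    if np.ptp(u) == 0:
        raise InsufficientDataError("updrs3 constant: severity terms inestimable")
    tf = df["tf"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), tf, u, tf * u])
    n_subj = df["subject_id"].nunique()
    return fit_lmm(df["value"].to_numpy(), X, df["subject_id"].to_numpy(),
                   ["intercept", "tf", "updrs3", "tf:updrs3"], reml=reml,
                   re_variance_ratio=re_variance_ratio,
                   df_subject=max(n_subj - 1, 1))


def severity_regression(records: pd.DataFrame, task: str, feature: str,
                        tf: int | None = None) -> RegressionResult:
    """Pearson r / least squares of feature value on UPDRS III (PD pooled).

    Observation units are pooled trial (and frame, for frame-resolved
    features) records, mirroring a pooled correlation analysis.
    """
    df = _select(records, task, feature, tf)
    df = df[df["group"] == "PD"].dropna(subset=["updrs3"])
    if tf is None:
        df = df[df["tf"] >= 1] if (df["tf"] >= 1).any() else df
    x = df["updrs3"].to_numpy(dtype=float)
    y = df["value"].to_numpy(dtype=float)
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 PD observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroDivisionError("zero variance: correlation undefined")
    lr = sps.linregress(x, y)
    return RegressionResult(r=float(lr.rvalue), r2=float(lr.rvalue**2),
                            p=float(lr.pvalue), slope=float(lr.slope),
                            intercept=float(lr.intercept), n=len(x))


# ---------------------------------------------------------------------------
# report assembly

GROUP_TABLE_FEATURES = [
    ("tapping", "total_taps"), ("tapping", "mean_variability"),
    ("a", "loudness"), ("a", "jitter"), ("a", "jitter_cv"),
    ("a", "shimmer"), ("a", "shimmer_cv"),
    ("i", "loudness"), ("i", "jitter"), ("i", "jitter_cv"),
    ("i", "shimmer"), ("i", "shimmer_cv"),
    ("dadada", "repeat_count"), ("dadada", "interval_sd"),
    ("pataka", "repeat_count"), ("pataka", "interval_sd"),
]

LMM_FEATURES = [
    ("tapping", "interval_sd"), ("a", "loudness"), ("a", "jitter"),
    ("a", "shimmer"), ("i", "loudness"), ("i", "jitter"), ("i", "shimmer"),
    ("dadada", "interval_sd"), ("pataka", "interval_sd"),
]


def _lmm_rows(fit: LMMFit, task: str, feature: str) -> list[dict]:
    rows = []
    for name, term in fit.terms.items():
        rows.append(dict(task=task, feature=feature, term=name,
                         coef=term.coef, se=term.se, t=term.t, p=term.p,
                         ci_low=term.ci_low, ci_high=term.ci_high,
                         df_resid=fit.df_resid, df_subject=fit.df_subject,
                         singular=fit.singular))
    return rows


def build_report(
    features: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
    truth: Mapping | None = None,
    out_dir: str | Path | None = None,
    alpha: float = 0.05,
) -> dict:
    """Assemble the full results document from a long feature table.

    Sections mirror the analysis battery: group comparison, TF-wise group
    contrasts of tapping variability, RM-ANOVA with post hoc per group,
    time x group and time x severity mixed models, severity regression, and
    (when generator truth is supplied) truth-vs-estimate recovery
    diagnostics for the interaction slopes. Degenerate inputs produce
    explicit "no data" markers rather than failures.
    """
    report: dict = {"alpha": alpha, "warnings": []}
    if features is None or features.empty:
        report["no_data"] = True
        if out_dir is not None:
            _write_report(report, {}, out_dir)
        return report
    report["no_data"] = False

    def _guard(section: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # degenerate cells are reported, not fatal
            report["warnings"].append(f"{section}: {exc}")
            return None

    group_rows = []
    for task, feature in GROUP_TABLE_FEATURES:
        r = _guard(f"group_compare {task}/{feature}", group_compare,
                   features, task, feature)
        if r is not None:
            group_rows.append(dict(task=task, feature=feature, **asdict(r)))
    report["group_comparison"] = group_rows

    tf_rows = []
    for k in range(1, 6):
        r = _guard(f"tf_compare tapping tf{k}", group_compare,
                   features, "tapping", "interval_sd", tf=k)
        if r is not None:
            tf_rows.append(dict(task="tapping", feature="interval_sd", tf=k,
                                **asdict(r)))
    report["tf_wise_tapping"] = tf_rows

    anova_rows, post_rows = [], []
    for grp in ("control", "PD"):
        res = _guard(f"tf_anova {grp}", tf_anova, features, grp, "tapping",
                     "interval_sd", alpha=alpha)
        if res is not None:
            an, post = res
            anova_rows.append(dict(group=grp, **asdict(an)))
            for ph in post:
                post_rows.append(dict(group=grp, **asdict(ph)))
    report["anova_tapping"] = anova_rows
    report["posthoc_tapping"] = post_rows

    tg_rows, ts_rows, reg_rows = [], [], []
    for task, feature in LMM_FEATURES:
        fit = _guard(f"time_group {task}/{feature}", fit_lmm_time_group,
                     features, task, feature)
        if fit is not None:
            tg_rows.extend(_lmm_rows(fit, task, feature))
        fit = _guard(f"time_severity {task}/{feature}", fit_lmm_time_severity,
                     features, task, feature)
        if fit is not None:
            ts_rows.extend(_lmm_rows(fit, task, feature))
        reg = _guard(f"severity_regression {task}/{feature}",
                     severity_regression, features, task, feature)
        if reg is not None:
            reg_rows.append(dict(task=task, feature=feature, **asdict(reg)))
    report["time_group_lmm"] = tg_rows
    report["time_severity_lmm"] = ts_rows
    report["severity_regression"] = reg_rows

    if truth is not None:
        models = truth.get("models", truth) if isinstance(truth, Mapping) else {}
        est = {(r["task"], r["feature"]): r for r in ts_rows
               if r["term"] == "tf:updrs3"}
        rec = []
        for key, m in models.items():
            if not isinstance(m, Mapping) or "b_int" not in m:
                continue
            e = est.get((m.get("task"), m.get("feature")))
            rec.append(dict(
                task=m.get("task"), feature=m.get("feature"),
                true_interaction=m["b_int"],
                true_interaction_is_zero=m["b_int"] == 0.0,
                estimated_interaction=None if e is None else e["coef"],
                estimate_minus_truth=None if e is None else e["coef"] - m["b_int"],
            ))
        report["recovery"] = rec

    tables = {
        "group_comparison": pd.DataFrame(group_rows),
        "tf_wise_tapping": pd.DataFrame(tf_rows),
        "anova_posthoc_tapping": pd.DataFrame(post_rows),
        "time_group_lmm": pd.DataFrame(tg_rows),
        "time_severity_lmm": pd.DataFrame(ts_rows),
    }
    if out_dir is not None:
        _write_report(report, tables, out_dir)
    return report


def _write_report(report: dict, tables: Mapping[str, pd.DataFrame],
                  out_dir: str | Path) -> None:
    out = Path(out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    for name, df in tables.items():
        df.to_csv(out / "tables" / f"{name}.csv", index=False)
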