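"""Random-intercept linear mixed models for repeated time-frame data.

Two fitting paths share one result type:

* free variance components — statsmodels ``MixedLM`` (REML by default),
  Wald inference on the fixed effects;
* fixed variance ratio — profiled GLS at a user-supplied ratio
  ``lambda = tau^2 / sigma^2`` of random-intercept to residual variance,
  closed form via Sherman–Morrison. At ``lambda -> 0`` this reproduces
  ordinary least squares exactly, which pins down the model's OLS limit.

Degrees of freedom for t tests are the residual approximation
``n_obs - n_fixed``; a subject-level convention (n_subjects minus the
number of subject-constant fixed effects) is reported alongside for
comparability with clinical-style outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.regression.mixed_linear_model import MixedLM


@dataclass
class TermFit:
    coef: float
    se: float
    t: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class LMMFit:
    terms: dict[str, TermFit]
    re_var: float
    resid_var: float
    loglike: float
    n_obs: int
    n_subjects: int
    df_resid: int
    df_subject: int
    singular: bool = False
    converged: bool = True
    method: str = "reml"

    def __getitem__(self, name: str) -> TermFit:
        return self.terms[name]


_VARIANCE_FLOOR = 1e-8


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    term_names: list[str],
    reml: bool = True,
    re_variance_ratio: float | None = None,
    df_subject: int | None = None,
) -> LMMFit:
    """Fit ``y = X beta + b_subject + eps`` with a random intercept per group.

    With ``re_variance_ratio`` set, the random-intercept variance is held
    fixed at that multiple of the residual variance and the fixed effects
    are the closed-form GLS solution; otherwise the variance is estimated
    by (RE)ML.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    if len(term_names) != X.shape[1]:
        raise ValueError("term_names must match design columns")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (inestimable terms)")
    n, p = X.shape
    ids = np.unique(groups)
    n_subj = len(ids)
    if df_subject is None:
        df_subject = max(n_subj - 1, 1)
    df_resid = max(n - p, 1)

    if re_variance_ratio is not None:
        return _fit_gls_fixed_ratio(y, X, groups, term_names, re_variance_ratio,
                                    df_resid, df_subject, n_subj)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(y, X, groups=groups)
        res = None
        converged = True
        for method in (None, "cg", "powell"):
            try:
                res = (model.fit(reml=reml) if method is None
                       else model.fit(reml=reml, method=method))
            except Exception:
                converged = False
                continue
            if np.all(np.isfinite(np.asarray(res.bse_fe, dtype=float))):
                converged = bool(getattr(res, "converged", True))
                break
        if res is None:
            raise RuntimeError("mixed model failed to fit")
        re_var = float(np.asarray(res.cov_re).ravel()[0]) * float(res.scale)
        singular = re_var < _VARIANCE_FLOOR
        if singular:
            re_var = _VARIANCE_FLOOR
        coefs = np.asarray(res.fe_params, dtype=float)
        ses = np.asarray(res.bse_fe, dtype=float)
    terms = _build_terms(term_names, coefs, ses, df_resid)
    return LMMFit(
        terms=terms,
        re_var=re_var,
        resid_var=float(res.scale),
        loglike=float(res.llf),
        n_obs=n,
        n_subjects=n_subj,
        df_resid=df_resid,
        df_subject=df_subject,
        singular=singular,
        converged=converged,
        method="reml" if reml else "ml",
    )


def _fit_gls_fixed_ratio(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    term_names: list[str],
    lam: float,
    df_resid: int,
    df_subject: int,
    n_subj: int,
) -> LMMFit:
    """Profiled GLS with V_g = I + lam * 11' per group (Sherman–Morrison)."""
    n, p = X.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    parts = []
    for g in np.unique(groups):
        m = groups == g
        Xg, yg = X[m], y[m]
        ng = Xg.shape[0]
        w = lam / (1.0 + lam * ng)
        xs, ys = Xg.sum(axis=0), yg.sum()
        xtvx += Xg.T @ Xg - w * np.outer(xs, xs)
        xtvy += Xg.T @ yg - w * xs * ys
        parts.append((Xg, yg, ng, w))
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ xtvy
    # GLS residual quadratic form for sigma^2 (REML-style denominator)
    q = 0.0
    for Xg, yg, ng, w in parts:
        r = yg - Xg @ beta
        q += r @ r - w * r.sum() ** 2
    sigma2 = q / max(n - p, 1)
    ses = np.sqrt(np.diag(xtvx_inv) * sigma2)
    terms = _build_terms(term_names, beta, ses, df_resid)
    return LMMFit(
        terms=terms,
        re_var=float(lam * sigma2),
        resid_var=float(sigma2),
        loglike=float("nan"),
        n_obs=n,
        n_subjects=n_subj,
        df_resid=df_resid,
        df_subject=df_subject,
        singular=lam < _VARIANCE_FLOOR,
        method="gls_fixed_ratio",
    )


def _build_terms(names: list[str], coefs: np.ndarray, ses: np.ndarray,
                 df: int) -> dict[str, TermFit]:
    crit = sps.t.ppf(0.975, df)
    out = {}
    for name, c, s in zip(names, coefs, ses):
        tval = c / s if s > 0 else np.inf * np.sign(c)
        pval = 2 * sps.t.sf(abs(tval), df)
        out[name] = TermFit(
            coef=float(c), se=float(s), t=float(tval), p=float(pval),
            ci_low=float(c - crit * s), ci_high=float(c + crit * s),
        )
    return out
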