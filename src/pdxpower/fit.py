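"""Fitting the growth model and testing the treatment effect.

Two regimes:

* **Replicated designs** (n >= 2 mice per arm): the log-linear mixed
  model with correlated random intercept and slope per mouse, fitted by
  maximum likelihood via :class:`statsmodels` ``MixedLM`` (REML optional).
  For balanced complete data — every mouse measured on the same days —
  the fixed-effect slope contrast equals the difference of group means of
  per-mouse OLS slopes, and the exact test of the treatment effect is the
  two-sample t on those per-mouse slopes with 2(n-1) degrees of freedom.
  That exact test is the default inference here: the Hessian-based Wald
  SE from a numerically fitted LMM is unstable when the slope-variance
  estimate sits on the zero boundary, which is routine at PDX scales
  (tau1 ~ 0.01), whereas the slope-summary t keeps its nominal level.
  ``test="wald-z"`` restores plain Wald inference (also used, with a
  warning in the result, for unbalanced data where no exact test exists).

* **1x1x1 designs** (one mouse per arm): the mixed model is not
  identifiable and reduces to ordinary least squares on
  intercept + day + treated (+ day x treated); the treatment-effect test
  is a t-test with df = N_obs - N_fixed. Note this test's standard error
  cannot include inter-mouse slope variation (tau1) — with one mouse per
  arm it is statistically invisible — so it is calibrated only against
  the narrower null that the two specific animals share a growth rate.
  Power analysis for 1x1x1 designs therefore supplies tau1 externally
  (see :mod:`pdxpower.power`).

A closed-form moment estimator (``engine="closed-form"``) provides the
same output for balanced complete data without iterative optimisation:
fixed effects from per-mouse OLS summaries (exact, since GLS weights
cancel under balance) and Swamy-type variance components.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TrajectorySet

__all__ = ["FitResult", "fit_growth_model", "test_effect", "per_mouse_ols"]

FIXED_EFFECTS = ("beta_int", "beta_day", "gamma", "beta_effect")


@dataclass
class FitResult:
    """Estimates and the treatment-effect test for one fitted experiment."""

    model_kind: str  # "mixed" | "linear"
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    statistic: float
    p_value: float
    test: str  # "slope-t" | "wald-z" | "ols-t"
    df: float | None = None
    sigma: float | None = None
    tau0: float | None = None
    tau1: float | None = None
    tau01: float | None = None
    engine: str = "closed-form"
    converged: bool = True
    fallback: str | None = None
    n_obs: int = 0
    n_per_group: tuple[int, int] = (0, 0)
    notes: list[str] = field(default_factory=list)

    @property
    def beta_effect(self) -> float:
        return self.estimates["beta_effect"]

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "variance_components": {
                "sigma": self.sigma,
                "tau0": self.tau0,
                "tau1": self.tau1,
                "tau01": self.tau01,
            },
            "test": self.test,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "engine": self.engine,
            "converged": self.converged,
            "fallback": self.fallback,
            "n_obs": self.n_obs,
            "n_per_group": list(self.n_per_group),
            "notes": self.notes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def per_mouse_ols(t: TrajectorySet) -> pd.DataFrame:
    """Per-mouse OLS intercept and slope of log-volume on day.

    Returns one row per mouse with columns ``mouse_id``, ``treated``,
    ``intercept``, ``slope``, ``rss``, ``n_days``.
    """
    rows = []
    for mid in pd.unique(t.mouse_id):
        mask = t.mouse_id == mid
        d = t.day[mask].astype(float)
        y = t.log_volume[mask]
        if len(np.unique(d)) < 2:
            raise ValueError(f"mouse {mid} has fewer than 2 distinct days; slope not identifiable")
        dbar = d.mean()
        sxx = ((d - dbar) ** 2).sum()
        slope = ((d - dbar) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * dbar
        resid = y - intercept - slope * d
        rows.append(
            {
                "mouse_id": mid,
                "treated": int(t.treated[mask][0]),
                "intercept": intercept,
                "slope": slope,
                "rss": float(resid @ resid),
                "n_days": len(d),
            }
        )
    return pd.DataFrame(rows)


def _is_balanced(t: TrajectorySet) -> bool:
    days_by_mouse = {}
    for mid in pd.unique(t.mouse_id):
        days_by_mouse[mid] = tuple(sorted(t.day[t.mouse_id == mid]))
    patterns = set(days_by_mouse.values())
    return len(patterns) == 1


def _slope_contrast_test(ols: pd.DataFrame) -> tuple[float, float, float, float, float]:
    """Two-sample t on per-mouse slopes: (diff, se, t, df, p)."""
    sc = ols.loc[ols.treated == 0, "slope"].to_numpy()
    st = ols.loc[ols.treated == 1, "slope"].to_numpy()
    n0, n1 = len(sc), len(st)
    diff = st.mean() - sc.mean()
    df = n0 + n1 - 2
    pooled = ((n0 - 1) * sc.var(ddof=1) + (n1 - 1) * st.var(ddof=1)) / df
    se = float(np.sqrt(pooled * (1.0 / n0 + 1.0 / n1)))
    with np.errstate(divide="ignore"):  # se = 0 in noise-free data
        tstat = diff / se if se > 0 else (np.inf if diff != 0 else 0.0)
    p = 2.0 * stats.t.sf(abs(tstat), df)
    return diff, se, tstat, float(df), p


def _fit_linear(t: TrajectorySet, include_gamma: bool) -> FitResult:
    d = t.day.astype(float)
    trt = t.treated.astype(float)
    cols = [np.ones_like(d), d]
    names = ["beta_int", "beta_day"]
    if include_gamma:
        cols.append(trt)
        names.append("gamma")
    cols.append(d * trt)
    names.append("beta_effect")
    X = np.column_stack(cols)
    y = t.log_volume
    n_obs, k = X.shape
    if n_obs <= k:
        raise ValueError(f"only {n_obs} observations for {k} fixed effects")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < k:
        raise ValueError("singular design: need at least 2 distinct days per arm")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n_obs - k
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 * np.diag(XtX_inv))
    j = names.index("beta_effect")
    tstat = beta[j] / se[j]
    p = 2.0 * stats.t.sf(abs(tstat), df)
    counts = _group_counts(t)
    return FitResult(
        model_kind="linear",
        estimates=dict(zip(names, beta.tolist())),
        standard_errors=dict(zip(names, se.tolist())),
        statistic=float(tstat),
        p_value=float(p),
        test="ols-t",
        df=float(df),
        sigma=float(np.sqrt(s2)),
        engine="ols",
        n_obs=n_obs,
        n_per_group=counts,
    )


def _group_counts(t: TrajectorySet) -> tuple[int, int]:
    return (
        len(np.unique(t.mouse_id[t.treated == 0])),
        len(np.unique(t.mouse_id[t.treated == 1])),
    )


def _closed_form_mixed(t: TrajectorySet, ols: pd.DataFrame) -> dict:
    """Swamy-type moment estimates of the variance components (balanced)."""
    days = np.sort(np.unique(t.day)).astype(float)
    m = len(days)
    Xm = np.column_stack([np.ones(m), days])
    XtX_inv = np.linalg.inv(Xm.T @ Xm)
    M = len(ols)
    # residual variance pooled over mice, df = m - 2 each
    sigma2 = float(ols["rss"].sum()) / (M * (m - 2)) if m > 2 else 0.0
    # between-mouse covariance of (intercept, slope), pooled within arms
    parts = []
    dof = 0
    for g in (0, 1):
        sub = ols.loc[ols.treated == g, ["intercept", "slope"]].to_numpy()
        if len(sub) >= 2:
            dev = sub - sub.mean(axis=0)
            parts.append(dev.T @ dev)
            dof += len(sub) - 1
    S_b = sum(parts) / dof
    psi = S_b - sigma2 * XtX_inv
    # project to PSD
    w, V = np.linalg.eigh(psi)
    psi = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
    tau0 = float(np.sqrt(max(psi[0, 0], 0.0)))
    tau1 = float(np.sqrt(max(psi[1, 1], 0.0)))
    tau01 = float(psi[0, 1] / (tau0 * tau1)) if tau0 > 0 and tau1 > 0 else 0.0
    return {"sigma": float(np.sqrt(sigma2)), "tau0": tau0, "tau1": tau1, "tau01": tau01}


def _fit_mixedlm(t: TrajectorySet, include_gamma: bool, reml: bool):
    """MixedLM with a non-convergence fallback ladder.

    Returns (result, names, fallback_label).
    """
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    d = t.day.astype(float)
    trt = t.treated.astype(float)
    cols = [np.ones_like(d), d]
    names = ["beta_int", "beta_day"]
    if include_gamma:
        cols.append(trt)
        names.append("gamma")
    cols.append(d * trt)
    names.append("beta_effect")
    X = np.column_stack(cols)
    y = t.log_volume
    groups = pd.factorize(t.mouse_id)[0]
    exog_re_full = np.column_stack([np.ones_like(d), d])

    ladder = [
        ("full", exog_re_full, None),
        ("independent-re", exog_re_full, "diag"),
        ("slope-only", d[:, None], None),
    ]
    last_exc = None
    for label, exog_re, constraint in ladder:
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        kwargs = {"reml": reml}
        if constraint == "diag":
            k_fe = X.shape[1]
            free = MixedLMParams.from_components(
                fe_params=np.ones(k_fe), cov_re=np.eye(exog_re.shape[1])
            )
            kwargs["free"] = free
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = model.fit(method=method, **kwargs)
            except Exception as exc:  # noqa: BLE001 - optimiser failures vary
                last_exc = exc
                continue
            if res.converged and np.all(np.isfinite(res.params)):
                return res, names, (None if label == "full" else label)
    raise RuntimeError(f"mixed-model fit failed at every covariance structure: {last_exc}")


def fit_growth_model(
    t: TrajectorySet,
    include_gamma: bool = True,
    reml: bool = False,
    engine: str = "auto",
    test: str = "auto",
) -> FitResult:
    """Fit the growth model to a trajectory set and test ``beta_effect``.

    Parameters
    ----------
    t
        Trajectories (simulated or read from CSV).
    include_gamma
        Include the treatment main effect on baseline (default, standard
        interaction-model practice).
    reml
        Restricted ML for the mixed model; plain ML by default so
        likelihoods are comparable across fixed-effect structures.
    engine
        ``"auto"`` (MixedLM for replicated designs), ``"mixedlm"``, or
        ``"closed-form"`` (balanced complete data only; no optimiser).
    test
        ``"auto"`` — exact slope-contrast t for balanced replicated
        designs, Wald z otherwise; or force ``"slope-t"`` / ``"wald-z"``.
    """
    n0, n1 = _group_counts(t)
    if min(n0, n1) < 1:
        raise ValueError("need at least 1 mouse in each arm")
    if len(np.unique(t.day)) < 2:
        raise ValueError("singular design: need at least 2 distinct days")

    if n0 == 1 and n1 == 1:
        return _fit_linear(t, include_gamma)

    balanced = _is_balanced(t)
    if test == "auto":
        test = "slope-t" if balanced else "wald-z"
    if test == "slope-t" and not balanced:
        raise ValueError("slope-contrast t-test requires balanced data; use test='wald-z'")
    if engine == "auto":
        engine = "mixedlm"

    ols = per_mouse_ols(t)
    notes: list[str] = []

    if engine == "closed-form":
        if not balanced:
            raise ValueError("closed-form engine requires balanced complete data")
        if not include_gamma:
            notes.append("closed-form engine always includes gamma")
        means = ols.groupby("treated")[["intercept", "slope"]].mean()
        estimates = {
            "beta_int": float(means.loc[0, "intercept"]),
            "beta_day": float(means.loc[0, "slope"]),
            "gamma": float(means.loc[1, "intercept"] - means.loc[0, "intercept"]),
            "beta_effect": float(means.loc[1, "slope"] - means.loc[0, "slope"]),
        }
        vc = _closed_form_mixed(t, ols)
        diff, se_diff, tstat, df, p = _slope_contrast_test(ols)
        int_c = ols.loc[ols.treated == 0, "intercept"].to_numpy()
        int_t = ols.loc[ols.treated == 1, "intercept"].to_numpy()
        se = {
            "beta_int": float(int_c.std(ddof=1) / np.sqrt(n0)),
            "beta_day": float(ols.loc[ols.treated == 0, "slope"].std(ddof=1) / np.sqrt(n0)),
            "gamma": float(
                np.sqrt(int_c.var(ddof=1) / n0 + int_t.var(ddof=1) / n1)
            ),
            "beta_effect": se_diff,
        }
        statistic, p_value, dof, test_used = tstat, p, df, "slope-t"
        converged, fallback = True, None
    elif engine == "mixedlm":
        res, names, fallback = _fit_mixedlm(t, include_gamma, reml)
        k = len(names)
        estimates = dict(zip(names, np.asarray(res.params)[:k].tolist()))
        se = dict(zip(names, np.asarray(res.bse)[:k].tolist()))
        vc_cov = np.atleast_2d(np.asarray(res.cov_re))
        sigma_hat = float(np.sqrt(res.scale))
        if fallback == "slope-only":
            tau0_hat, tau1_hat, tau01_hat = 0.0, float(np.sqrt(vc_cov[0, 0])), 0.0
        else:
            tau0_hat = float(np.sqrt(max(vc_cov[0, 0], 0.0)))
            tau1_hat = float(np.sqrt(max(vc_cov[1, 1], 0.0)))
            tau01_hat = (
                float(vc_cov[0, 1] / (tau0_hat * tau1_hat))
                if tau0_hat > 0 and tau1_hat > 0
                else 0.0
            )
        vc = {"sigma": sigma_hat, "tau0": tau0_hat, "tau1": tau1_hat, "tau01": tau01_hat}
        if test == "slope-t":
            _, se_diff, statistic, dof, p_value = _slope_contrast_test(ols)
            se["beta_effect"] = se_diff
            test_used = "slope-t"
        else:
            j = names.index("beta_effect")
            z = float(np.asarray(res.params)[j] / np.asarray(res.bse)[j])
            statistic, dof, test_used = z, None, "wald-z"
            p_value = float(2.0 * stats.norm.sf(abs(z)))
            if not balanced:
                notes.append("unbalanced data: Wald z inference, no exact test available")
        converged = bool(res.converged)
        if fallback is not None:
            notes.append(f"covariance-structure fallback: {fallback}")
    else:
        raise ValueError(f"unknown engine {engine!r}")

    return FitResult(
        model_kind="mixed",
        estimates=estimates,
        standard_errors=se,
        statistic=float(statistic),
        p_value=float(p_value),
        test=test_used,
        df=dof,
        sigma=vc["sigma"],
        tau0=vc["tau0"],
        tau1=vc["tau1"],
        tau01=vc["tau01"],
        engine=engine,
        converged=converged,
        fallback=fallback,
        n_obs=t.n_records,
        n_per_group=(n0, n1),
        notes=notes,
    )


def test_effect(f: FitResult, alpha: float) -> bool:
    """Two-sided decision: reject the no-treatment-effect null iff p < alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return bool(f.p_value < alpha)
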