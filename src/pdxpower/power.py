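"""Power and sample size for the two-arm slope-difference test.

Analytic engine
---------------
For a balanced design in which every mouse is measured on the same days,
the OLS slope of one mouse has variance ``v = tau1^2 + sigma^2/Sxx``
around its arm's mean growth rate, where ``Sxx`` is the sum of squared
day deviations. The treated-minus-control difference of group mean
slopes then has standard error ``SE = sqrt(2 v / n)`` for ``n`` mice per
arm, and the two-sided normal-theory power at level ``alpha`` is

    power = Phi(|beta_effect|/SE - z_{1-alpha/2}) + Phi(-|beta_effect|/SE - z_{1-alpha/2})

The second (far-tail) term matters only near the null, where it makes
``power(beta_effect = 0) = alpha`` exact. Intercept variance ``tau0`` and
the intercept-slope association cancel for this balanced slope contrast
and do not enter the formula (the simulation engine provides the check).

Monte-Carlo engine
------------------
``simulate_power`` repeats simulate -> fit -> test. For replicated
designs (n >= 2) the fit is the mixed model and the test the exact
slope-contrast t. For the 1x1x1 design the inter-mouse slope variance is
invisible to a within-experiment fit, so the default test compares the
estimated slope difference against the *known* variance
``2(tau1^2 + sigma^2/Sxx)`` supplied by the generating parameters — the
premise of 1x1x1 screening being precisely that variation is known from
historical replicated experiments. This choice makes simulation and
formula two routes to the same quantity; the naive OLS t-test
(``test="ols-t"``), which omits tau1 from its standard error, is kept
for reference and is anticonservative whenever tau1 > 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignSpec, ModelParams
from .fit import fit_growth_model
from .simulate import simulate_experiment

__all__ = [
    "PowerResult",
    "SampleSizeResult",
    "slope_variance",
    "analytic_power",
    "simulate_power",
    "simulate_pvalues",
    "required_sample_size",
    "retrospective_power",
    "retrospective_summary",
]


@dataclass
class PowerResult:
    """A power estimate with its provenance."""

    power: float
    method: str  # "analytic" | "simulation"
    params: ModelParams
    design: DesignSpec
    n_sims: int | None = None
    seed: int | None = None
    mc_stderr: float | None = None
    n_nonconverged: int | None = None
    test: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError(f"power {self.power} outside [0, 1]")
        if self.method == "analytic" and (self.n_sims or self.mc_stderr):
            raise ValueError("analytic results carry no Monte-Carlo fields")


@dataclass
class SampleSizeResult:
    """Smallest mice-per-group achieving a target analytic power."""

    n_per_group: int
    target_power: float
    achieved_power: float
    params: ModelParams
    design: DesignSpec


def slope_variance(params: ModelParams, design: DesignSpec) -> float:
    """Per-mouse slope variance v = tau1^2 + sigma^2 / Sxx."""
    sxx = design.sxx()
    if sxx <= 0:
        raise ValueError("degenerate schedule: Sxx = 0")
    return params.tau1**2 + params.sigma**2 / sxx


def _power_from_se(beta_effect: float, se: float, alpha: float) -> float:
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = abs(beta_effect) / se
    return float(stats.norm.cdf(shift - za) + stats.norm.cdf(-shift - za))


def analytic_power(params: ModelParams, design: DesignSpec) -> PowerResult:
    """Closed-form two-sided power of the slope-difference test."""
    v = slope_variance(params, design)
    se = np.sqrt(2.0 * v / design.n_per_group)
    return PowerResult(
        power=_power_from_se(params.beta_effect, se, design.alpha),
        method="analytic",
        params=params,
        design=design,
    )


def _mean_slope_diff(t) -> float:
    """Treated-minus-control mean per-mouse OLS slope (balanced simulated data)."""
    d = np.asarray(t.design.days, dtype=float)
    dc = d - d.mean()
    slopes = t.log_volume.reshape(-1, len(d)) @ dc / (dc @ dc)
    treated = t.treated.reshape(-1, len(d))[:, 0]
    return float(slopes[treated == 1].mean() - slopes[treated == 0].mean())


def _pvalue_one_replicate(
    params: ModelParams, design: DesignSpec, child_seed, test: str, engine: str
) -> tuple[float, bool]:
    """(p-value, converged) for one simulated experiment."""
    t = simulate_experiment(params, design, child_seed)
    if test == "z-known":
        diff = _mean_slope_diff(t)
        se = np.sqrt(2.0 * slope_variance(params, design) / design.n_per_group)
        z = diff / se
        return float(2.0 * stats.norm.sf(abs(z))), True
    try:
        f = fit_growth_model(t, engine=engine, test="auto" if test == "fit" else test)
    except RuntimeError:
        return np.nan, False
    return f.p_value, f.converged


def simulate_pvalues(
    params: ModelParams,
    design: DesignSpec,
    n_sims: int,
    seed: int,
    test: str = "auto",
    engine: str = "closed-form",
) -> np.ndarray:
    """p-values from ``n_sims`` simulated experiments (NaN = failed fit).

    ``test="auto"`` resolves to the known-variance z for 1x1x1 designs
    and to the model fit's own test (exact slope-contrast t) otherwise.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if test == "auto":
        test = "z-known" if design.n_per_group == 1 else "fit"
    children = np.random.SeedSequence(seed).spawn(n_sims)
    out = np.empty(n_sims)
    for i, child in enumerate(children):
        out[i], _ = _pvalue_one_replicate(params, design, child, test, engine)
    return out


def simulate_power(
    params: ModelParams,
    design: DesignSpec,
    n_sims: int = 10_000,
    seed: int = 0,
    test: str = "auto",
    engine: str = "closed-form",
) -> PowerResult:
    """Monte-Carlo power: fraction of simulated experiments rejecting.

    Replicates whose fit fails outright are counted in
    ``n_nonconverged`` and excluded from the rejection fraction (they are
    reported, never silently dropped).
    """
    if test == "auto":
        test = "z-known" if design.n_per_group == 1 else "fit"
    pvals = simulate_pvalues(params, design, n_sims, seed, test=test, engine=engine)
    ok = np.isfinite(pvals)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise RuntimeError("every simulated replicate failed to fit")
    p_hat = float(np.mean(pvals[ok] < design.alpha))
    return PowerResult(
        power=p_hat,
        method="simulation",
        params=params,
        design=design,
        n_sims=n_sims,
        seed=seed,
        mc_stderr=float(np.sqrt(p_hat * (1.0 - p_hat) / n_ok)),
        n_nonconverged=n_sims - n_ok,
        test=test,
    )


def required_sample_size(
    params: ModelParams,
    design: DesignSpec,
    target_power: float = 0.80,
) -> SampleSizeResult:
    """Smallest integer n per group with analytic power >= target.

    Starts from the closed-form inversion
    ``n0 = 2 (z_{1-alpha/2} + z_{target})^2 v / beta_effect^2`` and
    refines by integer search against :func:`analytic_power` (the
    far-tail term can shift the boundary by one).
    """
    if params.beta_effect == 0:
        raise ValueError("beta_effect = 0: no finite sample size achieves the target power")
    if not 0 < target_power < 1:
        raise ValueError("target_power must lie in (0, 1)")
    v = slope_variance(params, design)
    za = stats.norm.ppf(1.0 - design.alpha / 2.0)
    zb = stats.norm.ppf(target_power)
    n = max(1, int(np.ceil(2.0 * (za + zb) ** 2 * v / params.beta_effect**2)))

    def pow_at(k: int) -> float:
        return analytic_power(params, DesignSpec(design.days, k, design.alpha)).power

    while pow_at(n) < target_power:
        n += 1
    while n > 1 and pow_at(n - 1) >= target_power:
        n -= 1
    return SampleSizeResult(
        n_per_group=n,
        target_power=target_power,
        achieved_power=pow_at(n),
        params=params,
        design=design,
    )


REQUIRED_COEF_COLUMNS = ("beta_effect", "tau1", "sigma")


def retrospective_power(
    coeffs: pd.DataFrame | str | Path,
    days: Sequence[int],
    alphas: Sequence[float] = (0.05, 0.2),
) -> pd.DataFrame:
    """Per-experiment 1x1x1 power from a table of fitted coefficients.

    ``coeffs`` is a DataFrame (or CSV/XLSX path) with one row per
    experiment and at least the columns ``beta_effect``, ``tau1``,
    ``sigma``. Returns the input plus one ``power_alpha_<level>`` column
    per alpha and a ``no_effect`` flag for rows with beta_effect = 0
    (whose power equals alpha by construction).
    """
    if not isinstance(coeffs, pd.DataFrame):
        path = Path(coeffs)
        coeffs = (
            pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
        )
    missing = set(REQUIRED_COEF_COLUMNS) - set(coeffs.columns)
    if missing:
        raise ValueError(f"coefficient table missing columns: {sorted(missing)}")
    out = coeffs.copy()
    out["no_effect"] = out["beta_effect"] == 0
    for alpha in alphas:
        powers = []
        for _, row in out.iterrows():
            p = ModelParams(
                beta_effect=float(row["beta_effect"]),
                tau1=float(row["tau1"]),
                sigma=float(row["sigma"]),
            )
            d = DesignSpec(days=tuple(days), n_per_group=1, alpha=alpha)
            powers.append(analytic_power(p, d).power)
        out[f"power_alpha_{alpha}"] = powers
    return out


def retrospective_summary(
    table: pd.DataFrame, threshold: float = 0.80, exclude_no_effect: bool = True
) -> dict[str, dict[str, float]]:
    """Median power and fraction of adequately powered experiments per alpha."""
    if exclude_no_effect and "no_effect" in table.columns:
        table = table.loc[~table["no_effect"]]
    out = {}
    for col in table.columns:
        if col.startswith("power_alpha_"):
            vals = table[col].to_numpy()
            out[col.removeprefix("power_alpha_")] = {
                "median_power": float(np.median(vals)),
                "fraction_powered": float(np.mean(vals >= threshold)),
                "n_experiments": int(len(vals)),
            }
    return out
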