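"""Model parameters, measurement schedules and condition grids.

The growth model is a log-linear mixed-effects model for longitudinal
tumor volume: for mouse *i* measured on day *d*,

    log V_id = (beta_int + gamma*T_i + b0_i) + (beta_day + beta_effect*T_i + b1_i)*d + eps_id

with treatment indicator ``T_i`` (0 control, 1 treated), mouse-level
random intercept/slope ``(b0_i, b1_i)`` with SDs ``(tau0, tau1)``, and
i.i.d. Gaussian residuals ``eps ~ N(0, sigma^2)``. ``beta_effect`` is the
treatment-by-day interaction — the difference in daily log-growth between
arms — and is the quantity every power calculation in this package targets.

Default parameter values are the aggregate medians estimated from a cohort
of NSCLC patient-derived xenograft (PDX) drug-efficacy experiments; the
small/large effect and variation categories are the cohort quartiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ModelParams",
    "DesignSpec",
    "Condition",
    "ConditionGrid",
    "COHORT_MEDIANS",
    "EFFECT_SIZES",
    "TAU1_LEVELS",
    "make_schedule",
    "effect_to_weekly_ratio",
    "make_condition_grid",
    "schedule_sxx",
    "load_config",
]

#: Within-week measurement-day offsets by measurements per week.
#: Twice weekly follows the published day pattern {0, 4}; three times
#: weekly uses the Mon/Wed/Fri analogue {0, 2, 4} (configurable).
WEEKLY_OFFSETS: dict[int, tuple[int, ...]] = {2: (0, 4), 3: (0, 2, 4)}

#: Cohort quartiles of the treatment effect (1/day). "small" is the top
#: quartile (closest to zero), "large" the bottom quartile.
EFFECT_SIZES: dict[str, float] = {"small": -0.010, "medium": -0.02, "large": -0.044}

#: Cohort quartiles of the inter-mouse slope SD tau1 (1/day).
TAU1_LEVELS: dict[str, float] = {"small": 0.005, "average": 0.009, "large": 0.013}


class UnsupportedFrequencyError(ValueError):
    """Raised for a measurements-per-week value with no day pattern."""


@dataclass(frozen=True)
class ModelParams:
    """Coefficients and variance components of the log-linear growth model.

    Parameters
    ----------
    beta_int
        Log baseline tumor volume (log mm^3).
    beta_day
        Control-arm log-growth rate per day (1/day).
    beta_effect
        Treatment-by-day interaction: treated minus control log-growth
        per day (1/day). Negative values denote growth inhibition.
    gamma
        Treatment main effect on log baseline volume. Zero under
        randomization at baseline.
    sigma
        Residual SD of log-volume.
    tau0, tau1
        SDs of the mouse-level random intercept and slope.
    tau01
        Intercept-slope association. Interpreted as a correlation when
        ``tau01_is_correlation`` (default); a covariance otherwise.
    """

    beta_int: float = 5.135
    beta_day: float = 0.076
    beta_effect: float = -0.02
    gamma: float = 0.0
    sigma: float = 0.155
    tau0: float = 0.28
    tau1: float = 0.009
    tau01: float = 0.034
    tau01_is_correlation: bool = True

    def __post_init__(self) -> None:
        for name in ("sigma", "tau0", "tau1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        # validate the implied 2x2 random-effects covariance
        self.random_effects_cov()

    def random_effects_cov(self) -> np.ndarray:
        """The 2x2 covariance matrix of (random intercept, random slope)."""
        if self.tau01_is_correlation:
            if abs(self.tau01) > 1:
                raise ValueError(
                    f"intercept-slope correlation must lie in [-1, 1], got {self.tau01}"
                )
            cov01 = self.tau01 * self.tau0 * self.tau1
        else:
            cov01 = self.tau01
            bound = self.tau0 * self.tau1
            if abs(cov01) > bound + 1e-12:
                raise ValueError(
                    f"intercept-slope covariance {cov01} exceeds tau0*tau1 = {bound}; "
                    "the random-effects covariance would not be positive semidefinite "
                    "(pass tau01_is_correlation=True if the value is a correlation)"
                )
        return np.array(
            [[self.tau0**2, cov01], [cov01, self.tau1**2]], dtype=float
        )

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "beta_int": self.beta_int,
            "beta_day": self.beta_day,
            "beta_effect": self.beta_effect,
            "gamma": self.gamma,
            "sigma": self.sigma,
            "tau0": self.tau0,
            "tau1": self.tau1,
            "tau01": self.tau01,
            "tau01_is_correlation": self.tau01_is_correlation,
        }


#: Aggregate medians of the PDX cohort (the package-wide defaults).
COHORT_MEDIANS = ModelParams()


@dataclass(frozen=True)
class DesignSpec:
    """A two-arm longitudinal design: schedule, group size, alpha level."""

    days: tuple[int, ...] = (0, 4, 7, 11, 14, 18, 21, 25)
    n_per_group: int = 1
    alpha: float = 0.05

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        object.__setattr__(self, "days", days)
        if len(days) < 2 or len(set(days)) != len(days):
            raise ValueError("need at least 2 distinct measurement days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")
        if days[0] < 0:
            raise ValueError("measurement days must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def n_days(self) -> int:
        return len(self.days)

    def sxx(self) -> float:
        """Sum of squared day deviations; precision of a per-mouse slope."""
        return schedule_sxx(self.days)

    def to_dict(self) -> dict:
        return {"days": list(self.days), "n_per_group": self.n_per_group, "alpha": self.alpha}


def schedule_sxx(days: Sequence[float]) -> float:
    d = np.asarray(days, dtype=float)
    return float(((d - d.mean()) ** 2).sum())


def make_schedule(
    weeks: int, per_week: int, offsets: dict[int, Sequence[int]] | None = None
) -> list[int]:
    """Measurement days for ``weeks`` weeks at ``per_week`` visits per week.

    The within-week offset pattern (default {0, 4} for twice weekly,
    {0, 2, 4} for three times weekly) is tiled at 7-day intervals, so
    ``make_schedule(4, 2)`` gives the canonical [0, 4, 7, 11, 14, 18, 21, 25].
    """
    if weeks < 1:
        raise ValueError("weeks must be >= 1")
    table = dict(WEEKLY_OFFSETS)
    if offsets:
        table.update({k: tuple(v) for k, v in offsets.items()})
    if per_week not in table:
        raise UnsupportedFrequencyError(
            f"no day pattern for {per_week} measurements/week (supported: {sorted(table)})"
        )
    pattern = table[per_week]
    if len(pattern) != per_week:
        raise ValueError(f"offset pattern {pattern} does not have {per_week} entries")
    return [7 * w + o for w in range(weeks) for o in pattern]


def effect_to_weekly_ratio(beta_effect: float) -> float:
    """exp(7 * beta_effect): treated/control ratio of weekly growth factors.

    A value of 0.73 means the treated tumor grows each week by 0.73 times
    the factor by which the control grows.
    """
    return float(np.exp(7.0 * beta_effect))


@dataclass(frozen=True)
class Condition:
    """One labelled (parameters, design) cell of a condition grid."""

    label: str
    params: ModelParams
    design: DesignSpec
    weeks: int | None = None
    per_week: int | None = None
    effect_category: str | None = None
    variation_category: str | None = None


@dataclass
class ConditionGrid:
    """An ordered collection of labelled power-analysis conditions."""

    name: str
    conditions: list[Condition] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            rows.append(
                {
                    "label": c.label,
                    "beta_effect": c.params.beta_effect,
                    "tau1": c.params.tau1,
                    "weeks": c.weeks,
                    "per_week": c.per_week,
                    "alpha": c.design.alpha,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _combination_conditions(
    base: ModelParams,
    alphas: Iterable[float],
    weeks_options: Iterable[int] = (4, 8),
    per_week_options: Iterable[int] = (2, 3),
) -> list[Condition]:
    conds = []
    for weeks in weeks_options:
        for per_week in per_week_options:
            days = make_schedule(weeks, per_week)
            for var_cat in ("average", "small"):
                for eff_cat in ("small", "medium", "large"):
                    for alpha in alphas:
                        p = base.with_(
                            beta_effect=EFFECT_SIZES[eff_cat], tau1=TAU1_LEVELS[var_cat]
                        )
                        conds.append(
                            Condition(
                                label=(
                                    f"{eff_cat}-effect/{var_cat}-tau1/"
                                    f"{weeks}wk/{per_week}x/alpha={alpha}"
                                ),
                                params=p,
                                design=DesignSpec(days=tuple(days), n_per_group=1, alpha=alpha),
                                weeks=weeks,
                                per_week=per_week,
                                effect_category=eff_cat,
                                variation_category=var_cat,
                            )
                        )
    return conds


def make_condition_grid(
    which: str,
    base: ModelParams = COHORT_MEDIANS,
    alphas: Sequence[float] = (0.05,),
) -> ConditionGrid:
    """Build one of the canonical condition grids.

    ``which`` selects the family:

    - ``"effect_sweep"``: 20 evenly spaced beta_effect
      values on [-0.08, 0.019], tau1 = 0.005, 4 weeks twice weekly.
    - ``"variation_sweep"``: 20 evenly spaced tau1 values on
      [0.0001, 0.02], beta_effect = -0.02, 4 weeks twice weekly.
    - ``"schedule_sweep"``: weeks 1-8 at 2 and 3
      measurements/week, medians otherwise.
    - ``"combinations"``: {small, medium, large effect} x
      {small, average tau1} x {4, 8 weeks} x {2, 3 per week} per alpha.
    """
    key = which.lower()
    grid = ConditionGrid(name=key)
    days4x2 = tuple(make_schedule(4, 2))
    if key == "effect_sweep":
        for alpha in alphas:
            for b in np.linspace(-0.08, 0.019, 20):
                p = base.with_(beta_effect=float(b), tau1=0.005)
                grid.conditions.append(
                    Condition(
                        label=f"beta_effect={b:+.5f}/alpha={alpha}",
                        params=p,
                        design=DesignSpec(days=days4x2, n_per_group=1, alpha=alpha),
                        weeks=4,
                        per_week=2,
                    )
                )
    elif key == "variation_sweep":
        for alpha in alphas:
            for t in np.linspace(0.0001, 0.02, 20):
                p = base.with_(tau1=float(t))
                grid.conditions.append(
                    Condition(
                        label=f"tau1={t:.5f}/alpha={alpha}",
                        params=p,
                        design=DesignSpec(days=days4x2, n_per_group=1, alpha=alpha),
                        weeks=4,
                        per_week=2,
                    )
                )
    elif key == "schedule_sweep":
        for alpha in alphas:
            for per_week in (2, 3):
                for weeks in range(1, 9):
                    days = tuple(make_schedule(weeks, per_week))
                    p = base.with_(tau1=0.005)
                    grid.conditions.append(
                        Condition(
                            label=f"{weeks}wk/{per_week}x/alpha={alpha}",
                            params=p,
                            design=DesignSpec(days=days, n_per_group=1, alpha=alpha),
                            weeks=weeks,
                            per_week=per_week,
                        )
                    )
    elif key == "combinations":
        use_alphas = alphas if alphas != (0.05,) else (0.05, 0.2)
        grid.conditions = _combination_conditions(base, use_alphas)
    else:
        raise ValueError(f"unknown condition-grid name: {which!r}")
    return grid


def load_config(path) -> tuple[ModelParams, DesignSpec]:
    """Read a YAML or JSON config with ``params`` and ``design`` sections.

    Field names match :class:`ModelParams` and :class:`DesignSpec` exactly.
    Flat files (all fields at top level) are also accepted.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    pfields = set(ModelParams.__dataclass_fields__)
    dfields = set(DesignSpec.__dataclass_fields__)
    psrc = data.get("params", {k: v for k, v in data.items() if k in pfields})
    dsrc = data.get("design", {k: v for k, v in data.items() if k in dfields})
    unknown = set(psrc) - pfields | set(dsrc) - dfields
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    params = COHORT_MEDIANS.with_(**psrc)
    design = DesignSpec(**{**DesignSpec().to_dict(), **dsrc})
    return params, design
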