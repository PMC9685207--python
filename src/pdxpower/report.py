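"""Reproduction of the canonical power tables and curves as DataFrames.

Each function evaluates a condition grid with the analytic engine (and
optionally the Monte-Carlo engine) and returns a tidy, schema-stable
DataFrame; the CLI writes these to CSV. Cells reaching 80% power carry a
``powered`` flag, mirroring the bolding convention of the published
tables.
"""

from __future__ import annotations

import logging

import pandas as pd

from .design import (
    COHORT_MEDIANS,
    ConditionGrid,
    DesignSpec,
    ModelParams,
    make_condition_grid,
)
from .power import analytic_power, required_sample_size, simulate_power

__all__ = ["evaluate_grid", "run_power_grid", "run_samplesize_grid", "run_power_curves"]

log = logging.getLogger("pdxpower")

POWER_THRESHOLD = 0.80

GRID_COLUMNS = [
    "label",
    "beta_effect",
    "tau1",
    "weeks",
    "per_week",
    "alpha",
    "n_per_group",
    "power_analytic",
    "power_sim",
    "mc_stderr",
]


def evaluate_grid(
    grid: ConditionGrid, n_sims: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Analytic (and, if ``n_sims > 0``, Monte-Carlo) power per condition."""
    rows = []
    for i, c in enumerate(grid):
        rec = {
            "label": c.label,
            "beta_effect": c.params.beta_effect,
            "tau1": c.params.tau1,
            "weeks": c.weeks,
            "per_week": c.per_week,
            "alpha": c.design.alpha,
            "n_per_group": c.design.n_per_group,
            "power_analytic": analytic_power(c.params, c.design).power,
            "power_sim": None,
            "mc_stderr": None,
        }
        if n_sims > 0:
            sim = simulate_power(c.params, c.design, n_sims=n_sims, seed=seed + i)
            rec["power_sim"] = sim.power
            rec["mc_stderr"] = sim.mc_stderr
        if c.effect_category:
            rec["effect_category"] = c.effect_category
        if c.variation_category:
            rec["variation_category"] = c.variation_category
        rows.append(rec)
    return pd.DataFrame(rows)


def run_power_grid(
    base: ModelParams = COHORT_MEDIANS, n_sims: int = 0, seed: int = 0
) -> pd.DataFrame:
    """The 48-cell combination power grid (effect x variation x schedule x alpha)."""
    log.info(
        "combination power grid: base=%s, n_sims=%d, seed=%d",
        "paper medians" if base == COHORT_MEDIANS else "user override",
        n_sims,
        seed,
    )
    df = evaluate_grid(make_condition_grid("combinations", base=base), n_sims=n_sims, seed=seed)
    df["powered"] = df["power_analytic"] >= POWER_THRESHOLD
    return df


def run_samplesize_grid(
    base: ModelParams = COHORT_MEDIANS, target_power: float = POWER_THRESHOLD
) -> pd.DataFrame:
    """Required mice per group for the combination grid at the target power."""
    log.info(
        "sample-size grid: base=%s, target=%.2f",
        "paper medians" if base == COHORT_MEDIANS else "user override",
        target_power,
    )
    grid = make_condition_grid("combinations", base=base)
    rows = []
    for c in grid:
        res = required_sample_size(c.params, c.design, target_power=target_power)
        rows.append(
            {
                "label": c.label,
                "effect_category": c.effect_category,
                "variation_category": c.variation_category,
                "beta_effect": c.params.beta_effect,
                "tau1": c.params.tau1,
                "weeks": c.weeks,
                "per_week": c.per_week,
                "alpha": c.design.alpha,
                "n_required": res.n_per_group,
                "achieved_power": res.achieved_power,
            }
        )
    return pd.DataFrame(rows)


def run_power_curves(
    base: ModelParams = COHORT_MEDIANS,
    n_sims: int = 0,
    seed: int = 0,
    alphas: tuple[float, ...] = (0.05, 0.2),
) -> dict[str, pd.DataFrame]:
    """The three power-curve families: effect sweep, tau1 sweep, schedule sweep."""
    out = {}
    for which in ("effect_sweep", "variation_sweep", "schedule_sweep"):
        grid = make_condition_grid(which, base=base, alphas=alphas)
        out[which.removesuffix("_sweep")] = evaluate_grid(grid, n_sims=n_sims, seed=seed)
    return out
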