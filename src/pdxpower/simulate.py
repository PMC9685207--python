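"""Synthetic longitudinal tumor-volume trajectories.

Simulation is on the log scale, where the growth model is linear: each
mouse draws a random intercept/slope pair from the bivariate normal with
SDs (tau0, tau1) and the configured association, then every scheduled day
receives an independent Gaussian residual. Raw-volume export simply
exponentiates, which avoids lognormal-mean bias in round trips.

Reproducibility: one seed per experiment; per-mouse generators are spawned
deterministically from it with :class:`numpy.random.SeedSequence`, so the
trajectory of mouse *k* does not depend on how many mice come before it
being vectorized or looped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignSpec, ModelParams

__all__ = ["TrajectorySet", "simulate_experiment", "write_trajectories", "read_trajectories"]

GROUP_LABELS = ("control", "treated")


@dataclass
class TrajectorySet:
    """Tidy longitudinal records of log tumor volume.

    Arrays are aligned, one entry per (mouse, day) record:
    ``mouse_id`` (str), ``treated`` (0/1), ``day`` (int), ``log_volume``.
    ``params``/``design``/``seed`` record provenance when simulated
    (``None`` when read from a file).
    """

    mouse_id: np.ndarray
    treated: np.ndarray
    day: np.ndarray
    log_volume: np.ndarray
    params: ModelParams | None = None
    design: DesignSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n = len(self.log_volume)
        if not (len(self.mouse_id) == len(self.treated) == len(self.day) == n):
            raise ValueError("record arrays must have equal length")
        if not np.all(np.isfinite(self.log_volume)):
            raise ValueError("log volumes must be finite")

    @property
    def n_records(self) -> int:
        return len(self.log_volume)

    def n_mice(self) -> int:
        return len(np.unique(self.mouse_id))

    def n_per_group(self) -> dict[str, int]:
        out = {}
        for g, lab in enumerate(GROUP_LABELS):
            out[lab] = len(np.unique(self.mouse_id[self.treated == g]))
        return out

    def to_frame(self, raw_volume: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mouse_id": self.mouse_id,
                "group": np.where(self.treated == 1, "treated", "control"),
                "day": self.day,
            }
        )
        if raw_volume:
            df["volume_mm3"] = np.exp(self.log_volume)
        else:
            df["log_volume"] = self.log_volume
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, raw_volume: bool = False) -> "TrajectorySet":
        required = {"mouse_id", "group", "day"}
        value_col = "volume_mm3" if raw_volume else "log_volume"
        missing = (required | {value_col}) - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        dup = df.duplicated(subset=["mouse_id", "day"])
        if dup.any():
            raise ValueError(f"duplicate (mouse_id, day) rows: {int(dup.sum())}")
        groups = df["group"].astype(str).str.lower()
        bad = set(groups.unique()) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}")
        values = df[value_col].to_numpy(dtype=float)
        if raw_volume:
            if np.any(values <= 0):
                raise ValueError("volumes must be positive to take logs")
            values = np.log(values)
        return cls(
            mouse_id=df["mouse_id"].astype(str).to_numpy(),
            treated=(groups == "treated").to_numpy().astype(np.int64),
            day=df["day"].to_numpy(dtype=np.int64),
            log_volume=values,
        )


def simulate_experiment(
    params: ModelParams, design: DesignSpec, seed: int | np.random.SeedSequence
) -> TrajectorySet:
    """Simulate one two-arm experiment under the log-linear growth model.

    For mouse *i* in arm ``T_i``, with random effects ``(b0, b1)``:

        log V = beta_int + gamma*T_i + b0 + (beta_day + beta_effect*T_i + b1)*d + eps

    Bit-reproducible for a given ``seed``.
    """
    cov = params.random_effects_cov()
    days = np.asarray(design.days, dtype=float)
    n = design.n_per_group
    n_mice = 2 * n
    m = len(days)

    # mouse k in 0..n-1 is control, n..2n-1 treated; each mouse gets its
    # own spawned substream so trajectories are stable under resizing
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n_mice)
    treated_flag = np.repeat(np.array([0, 1]), n)

    # sample random effects via Cholesky with a PSD-safe fallback
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))

    log_vol = np.empty((n_mice, m))
    for k in range(n_mice):
        rng = np.random.default_rng(streams[k])
        b0, b1 = L @ rng.standard_normal(2)
        t = treated_flag[k]
        mean = (params.beta_int + params.gamma * t + b0) + (
            params.beta_day + params.beta_effect * t + b1
        ) * days
        log_vol[k] = mean + params.sigma * rng.standard_normal(m)

    ids = np.array(
        [f"{'T' if treated_flag[k] else 'C'}{k % n + 1:03d}" for k in range(n_mice)]
    )
    return TrajectorySet(
        mouse_id=np.repeat(ids, m),
        treated=np.repeat(treated_flag, m),
        day=np.tile(design.days, n_mice).astype(np.int64),
        log_volume=log_vol.ravel(),
        params=params,
        design=design,
        seed=seed,
    )


def write_trajectories(t: TrajectorySet, path, raw_volume: bool = False) -> None:
    """Write tidy CSV (columns mouse_id, group, day, log_volume|volume_mm3)."""
    t.to_frame(raw_volume=raw_volume).to_csv(Path(path), index=False)


def read_trajectories(path, raw_volume: bool | None = None) -> TrajectorySet:
    """Read a tidy trajectory CSV.

    ``raw_volume=None`` auto-detects: a ``volume_mm3`` column is
    log-transformed (rejecting non-positive volumes), a ``log_volume``
    column is used as-is.
    """
    df = pd.read_csv(Path(path))
    if raw_volume is None:
        raw_volume = "volume_mm3" in df.columns and "log_volume" not in df.columns
    return TrajectorySet.from_frame(df, raw_volume=raw_volume)
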