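"""Seeded generator of monthly outpatient-visit-like count series.

Emulates the salient structure of hospital outpatient demand: a high
winter season peaking in January-February, a sharp mid-summer dip in July,
a slow upward trend in the underlying level, and month-to-month noise.
The seasonal pattern is multiplicative on an additive trend,

    value(t) = (baseline + trend_per_month * t) * profile[month] + eps_t,

with eps_t ~ N(0, noise_sd^2), so the seasonal swing grows mildly with the
level while the ground-truth additive split (seasonal + trend + noise)
remains exact and checkable.  The default monthly profile averages to
exactly 1, so the trend component *is* the series' deseasonalized level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError
from .series import TimeSeries

__all__ = ["SimConfig", "default_monthly_profile", "generate", "ground_truth_components"]


def default_monthly_profile() -> np.ndarray:
    """Multiplicative seasonal factors, January first.

    Jan 1.25 and Feb 1.20 (winter peak), Jul 0.80 (summer dip); the nine
    remaining months follow a gentle linear ramp chosen so the twelve
    factors average to exactly 1.
    """
    profile = np.empty(12)
    profile[0] = 1.25  # Jan
    profile[1] = 1.20  # Feb
    profile[6] = 0.80  # Jul
    others = [2, 3, 4, 5, 7, 8, 9, 10, 11]  # Mar-Jun, Aug-Dec
    base = (12.0 - 1.25 - 1.20 - 0.80) / 9.0
    profile[others] = base + np.linspace(-0.03, 0.03, 9)
    return profile


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated series: nine years of monthly
    counts at a ~30000 visits/month level, +50 visits/month linear growth,
    and 1000-visit Gaussian noise."""

    n_years: int = 9
    baseline: float = 30000.0
    monthly_profile: np.ndarray = field(default_factory=default_monthly_profile)
    trend_per_month: float = 50.0
    noise_sd: float = 1000.0
    start_year: int = 2005
    seed: int = 0

    def __post_init__(self) -> None:
        profile = np.asarray(self.monthly_profile, dtype=float)
        if profile.shape != (12,):
            raise InvalidInputError("monthly_profile must have 12 factors")
        if np.any(profile <= 0):
            raise InvalidInputError("monthly_profile factors must be positive")
        if self.baseline <= 0:
            raise InvalidInputError("baseline must be positive")
        if self.n_years < 2:
            raise InvalidInputError("need >= 2 years for a seasonal series")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        object.__setattr__(self, "monthly_profile", profile)


def _level(cfg: SimConfig, t: np.ndarray) -> np.ndarray:
    return cfg.baseline + cfg.trend_per_month * t


def ground_truth_components(
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive (seasonal, trend, noise) split summing exactly to
    ``generate(cfg).values`` for the same seed."""
    n = 12 * cfg.n_years
    t = np.arange(n, dtype=float)
    level = _level(cfg, t)
    factors = cfg.monthly_profile[np.arange(n) % 12]
    seasonal = level * (factors - 1.0)
    rng = np.random.default_rng(cfg.seed)
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    )
    return seasonal, level, noise


def generate(cfg: SimConfig | None = None) -> TimeSeries:
    """Simulate a monthly series of 12 * n_years observations starting in
    January of ``start_year``; deterministic per seed."""
    cfg = cfg or SimConfig()
    seasonal, trend, noise = ground_truth_components(cfg)
    return TimeSeries(seasonal + trend + noise, (cfg.start_year, 1))
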