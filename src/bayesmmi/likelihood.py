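"""Composite Beta / exponential likelihood for steady-state proportions.

Each cohort is summarized by the mean and standard deviation of every
subtype's proportion across replicate samples.  A simulated steady state is
scored subtype by subtype:

* subtypes present in the model's topology contribute the log density of a
  Beta distribution, moment-matched so its mean is the *simulated*
  proportion and its variance is the *data* variance, evaluated at the data
  mean;
* subtypes absent from the topology contribute an exponential log density
  ``ln(lambda) - lambda * x_data`` with ``lambda = 1 / sigma_data`` —
  cheap to omit a rare subtype, costly to omit an abundant one.

Simulations that fail to reach steady state (or trip the overflow guard)
are not scored: the invalid sentinel (NaN) is returned and the sampler
discards the parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .popdyn import SimulationResult

__all__ = [
    "INVALID",
    "DatasetSummary",
    "BetaParams",
    "beta_from_moments",
    "composite_loglik",
]

#: sentinel for "this parameter set cannot be scored"
INVALID: float = float("nan")

_MEAN_CLIP = 1e-6  # degenerate simulated proportions are clipped to (0, 1)


@dataclass(frozen=True)
class DatasetSummary:
    """Per-subtype proportion mean and standard deviation for one cohort."""

    cohort: str
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.means) != set(self.sds):
            raise ValueError("means and sds must cover the same subtypes")
        total = sum(self.means.values())
        if abs(total - 1.0) > 0.02:
            raise ValueError(f"subtype means sum to {total:.3f}, expected ~1")
        for s, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"standard deviation for {s} must be positive")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": self.cohort,
                "subtype": list(self.means),
                "mean": [self.means[s] for s in self.means],
                "sd": [self.sds[s] for s in self.means],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort: str | None = None) -> "DatasetSummary":
        if cohort is not None:
            df = df[df["cohort"] == cohort]
        if df.empty:
            raise ValueError("no rows for the requested cohort")
        name = str(df["cohort"].iloc[0])
        return cls(
            cohort=name,
            means=dict(zip(df["subtype"], df["mean"].astype(float))),
            sds=dict(zip(df["subtype"], df["sd"].astype(float))),
        )


@dataclass(frozen=True)
class BetaParams:
    alpha: float
    beta: float

    @property
    def nu(self) -> float:
        return self.alpha + self.beta

    @property
    def mean(self) -> float:
        return self.alpha / self.nu

    @property
    def variance(self) -> float:
        nu = self.nu
        return self.alpha * self.beta / (nu * nu * (nu + 1.0))


def beta_from_moments(mu: float, sigma2: float) -> BetaParams:
    """Moment-match a Beta distribution: nu = mu(1-mu)/sigma^2 - 1.

    Requires 0 < mu < 1 and 0 < sigma^2 < mu(1-mu); outside that region the
    matched concentration nu would be non-positive.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mu}")
    if not 0.0 < sigma2 < mu * (1.0 - mu):
        raise ValueError(
            f"variance must lie in (0, mu(1-mu)) = (0, {mu * (1 - mu):.6g}), got {sigma2}"
        )
    nu = mu * (1.0 - mu) / sigma2 - 1.0
    return BetaParams(alpha=mu * nu, beta=(1.0 - mu) * nu)


def composite_loglik(sim: SimulationResult, data: DatasetSummary) -> float:
    """Score a simulation against a cohort summary; NaN when unscorable.

    Subtype order is immaterial.  A moment-matching validity failure for any
    modeled subtype (data variance too large for the simulated mean) also
    yields the invalid sentinel.
    """
    if sim.failed or not sim.valid:
        return INVALID
    sim_props = sim.final_proportions
    total = 0.0
    for s in data.subtypes:
        x = data.means[s]
        sd = data.sds[s]
        if s in sim_props:
            mu = float(np.clip(sim_props[s], _MEAN_CLIP, 1.0 - _MEAN_CLIP))
            try:
                bp = beta_from_moments(mu, sd * sd)
            except ValueError:
                return INVALID
            term = stats.beta.logpdf(x, bp.alpha, bp.beta)
        else:
            # ln(lambda) - lambda * x with lambda = 1/sd
            term = stats.expon.logpdf(x, scale=sd)
        if not np.isfinite(term):
            return INVALID if np.isnan(term) else float(term)
        total += float(term)
    return total
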