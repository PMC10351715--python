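"""Priors and marginal-likelihood estimation by nested sampling.

The marginal likelihood (evidence) of a model is the likelihood integrated
over its parameter prior, ``Z = \\int L(theta) p(theta) d(theta)``.  Nested
sampling estimates ``ln Z`` by maintaining a population of "live" points
drawn from the prior and repeatedly replacing the worst one with a new
point of higher likelihood, shrinking the enclosed prior volume
geometrically.  The bundled sampler works in the unit hypercube: a
``PriorSpec`` maps uniform draws to parameter space through the inverse-CDF
transform, and constrained replacement uses a seeded random walk started
from a surviving live point.  Identical seeds give identical results.

Parameter sets whose log-likelihood comes back as the invalid sentinel
(NaN) carry zero likelihood but real prior volume: the live set is filled
by rejection and the run starts from the estimated scorable fraction of
the prior, so unscorable regions (e.g. simulations that never reach
steady state) neither inflate nor deflate the evidence.

``brute_force_evidence`` provides an independent deterministic check for
problems of dimension <= 3 (trapezoid integration on the unit cube).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp, ndtr, ndtri

from .model_space import CandidateModel

__all__ = [
    "PriorSpec",
    "SamplerConfig",
    "EvidenceResult",
    "default_priors",
    "default_rate_table",
    "run_nested_sampling",
    "brute_force_evidence",
]


@lru_cache(maxsize=512)
def _frozen_dist(family: str, center: float, spread: float, low: float, high: float):
    if family == "truncnorm":
        a = (low - center) / spread
        b = (high - center) / spread
        return stats.truncnorm(a, b, loc=center, scale=spread)
    if family == "uniform":
        return stats.uniform(loc=low, scale=high - low)
    if family == "loguniform":
        return stats.loguniform(low, high)
    raise ValueError(f"unknown prior family {family!r}")


@dataclass(frozen=True)
class _Prior1D:
    family: str  # "truncnorm" | "uniform" | "loguniform"
    center: float = 0.0
    spread: float = 1.0
    low: float = 0.0
    high: float = np.inf

    def _dist(self):
        return _frozen_dist(self.family, self.center, self.spread, self.low, self.high)

    def ppf(self, u):
        # fast analytic paths; the sampler calls this in its inner loop
        if self.family == "uniform":
            return self.low + u * (self.high - self.low)
        if self.family == "loguniform":
            llo, lhi = math.log(self.low), math.log(self.high)
            return np.exp(llo + u * (lhi - llo))
        if self.family == "truncnorm":
            a = ndtr((self.low - self.center) / self.spread)
            b = ndtr((self.high - self.center) / self.spread)
            return self.center + self.spread * ndtri(a + u * (b - a))
        return self._dist().ppf(u)

    def logpdf(self, x):
        return self._dist().logpdf(x)

    def mean(self) -> float:
        return float(self._dist().mean())

    def std(self) -> float:
        return float(self._dist().std())


@dataclass(frozen=True)
class PriorSpec:
    """Independent 1-D priors per parameter with a unit-cube transform."""

    params: tuple[str, ...]
    priors: Mapping[str, _Prior1D]

    def __post_init__(self) -> None:
        missing = set(self.params) - set(self.priors)
        if missing:
            raise ValueError(f"no prior for parameters {sorted(missing)}")

    @property
    def ndim(self) -> int:
        return len(self.params)

    def transform(self, u: np.ndarray) -> np.ndarray:
        """Map a point of the unit hypercube onto parameter space."""
        u = np.asarray(u, dtype=float)
        return np.array(
            [self.priors[p].ppf(ui) for p, ui in zip(self.params, u)]
        )

    def transform_dict(self, u: np.ndarray) -> dict[str, float]:
        return dict(zip(self.params, self.transform(u)))

    def logpdf(self, theta: np.ndarray) -> float:
        return float(
            sum(self.priors[p].logpdf(t) for p, t in zip(self.params, theta))
        )

    @classmethod
    def from_families(cls, spec: Mapping[str, _Prior1D]) -> "PriorSpec":
        return cls(params=tuple(spec), priors=dict(spec))

    @classmethod
    def uniform(cls, bounds: Mapping[str, tuple[float, float]]) -> "PriorSpec":
        priors = {
            name: _Prior1D(family="uniform", low=lo, high=hi)
            for name, (lo, hi) in bounds.items()
        }
        return cls(params=tuple(bounds), priors=priors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.params:
            pr = self.priors[p]
            rows.append(
                {
                    "parameter": p,
                    "family": pr.family,
                    "center": pr.center,
                    "spread": pr.spread,
                    "low": pr.low,
                    "high": pr.high,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriorSpec":
        """Read a prior configuration table (parameter, family, center,
        spread, low, high), the inverse of :meth:`to_frame`."""
        priors = {}
        for _, row in df.iterrows():
            priors[str(row["parameter"])] = _Prior1D(
                family=str(row["family"]),
                center=float(row["center"]),
                spread=float(row["spread"]),
                low=float(row["low"]),
                high=float(row["high"]),
            )
        return cls(params=tuple(priors), priors=priors)


# Literature-derived per-day baseline rate centers.  Only the division rate
# of a Y-supported population (0.469 doublings/day) is anchored directly to
# a published conversion; the remaining entries are package defaults chosen
# in the same order of magnitude and are meant to be edited per application.
_DEFAULT_RATE_TABLE: dict[str, float] = {
    "div_A": 0.469,
    "div_N": 0.469,
    "div_A2": 0.469,
    "div_Y": 0.469,
    "die_A": 0.1,
    "die_N": 0.1,
    "die_A2": 0.1,
    "die_Y": 0.1,
}

_BASELINE_REL_SPREAD = 0.25  # relative sd of division/death rate priors
_EFFECT_SHIFT = 0.05  # effect multipliers centered 5% away from neutral
_TRANSITION_SUPPORT = (0.0, 1.0)  # per-day uniform support for transitions
_SATURATION_SUPPORT = (10.0, 1e5)  # cells; log-uniform, median 1000


def default_rate_table() -> dict[str, float]:
    return dict(_DEFAULT_RATE_TABLE)


def default_priors(
    candidate: CandidateModel,
    rate_table: Mapping[str, float] | None = None,
) -> PriorSpec:
    """Prior distributions for every parameter a candidate's rules reference.

    Division/death rates: truncated normals (support > 0) centered at the
    rate table values.  Effect multipliers: truncated normals centered 5%
    below neutral for division (a supportive effector slows nothing down;
    the default models growth damping) and 5% above neutral for death and
    transitions, with twice the baseline relative spread to reflect the
    extra uncertainty of inter-subtype effects.  Transition rates: uniform.
    Saturation constants: log-uniform on [10, 1e5] cells (median 1000).
    """
    table = dict(_DEFAULT_RATE_TABLE)
    if rate_table:
        table.update(rate_table)
    priors: dict[str, _Prior1D] = {}
    for rule in candidate.rules:
        key = rule.rate_param[2:]  # strip "k_"
        if rule.kind in ("division", "death"):
            center = table[key]
            priors.setdefault(
                rule.rate_param,
                _Prior1D(
                    family="truncnorm",
                    center=center,
                    spread=_BASELINE_REL_SPREAD * center,
                    low=0.0,
                ),
            )
        else:
            lo, hi = _TRANSITION_SUPPORT
            priors.setdefault(rule.rate_param, _Prior1D(family="uniform", low=lo, high=hi))
        if rule.effect_param is not None:
            if rule.kind == "division":
                center = 1.0 - _EFFECT_SHIFT
            else:  # death or transition: effector promotes the process
                center = 1.0 + _EFFECT_SHIFT
            priors.setdefault(
                rule.effect_param,
                _Prior1D(
                    family="truncnorm",
                    center=center,
                    spread=2.0 * _BASELINE_REL_SPREAD * center,
                    low=0.0,
                ),
            )
            lo, hi = _SATURATION_SUPPORT
            priors.setdefault(
                rule.saturation_param, _Prior1D(family="loguniform", low=lo, high=hi)
            )
    ordered = tuple(p for p in candidate.parameter_names)
    return PriorSpec(params=ordered, priors=priors)


@dataclass(frozen=True)
class SamplerConfig:
    n_live: int = 200
    dlogz: float = 0.01
    seed: int = 0
    walk_steps: int = 25
    max_iterations: int = 200_000
    max_invalid_draws: int = 10_000

    def validated(self, ndim: int) -> "SamplerConfig":
        if self.n_live < 2 * ndim:
            raise ValueError(
                f"need at least {2 * ndim} live points for a {ndim}-D problem"
            )
        return self


@dataclass
class EvidenceResult:
    logz: float
    logz_err: float
    samples: pd.DataFrame  # equally weighted posterior samples
    best_params: dict[str, float]
    best_loglik: float
    n_iterations: int
    n_calls: int
    information: float  # KL divergence prior -> posterior (nats)

    def posterior_samples(self, n: int | None = None) -> pd.DataFrame:
        if n is None or n >= len(self.samples):
            return self.samples
        return self.samples.iloc[:n]


def _finite_loglik(value: float) -> float:
    """Map the invalid sentinel (NaN) to -inf so it is never accepted."""
    if value is None or math.isnan(value):
        return -math.inf
    return float(value)


def run_nested_sampling(
    loglik: Callable[[Mapping[str, float]], float],
    prior: PriorSpec,
    config: SamplerConfig | None = None,
) -> EvidenceResult:
    """Estimate ln Z and draw posterior samples for one model.

    ``loglik`` receives a parameter dict and returns a float or the invalid
    sentinel.  The run is fully determined by ``config.seed``.
    """
    if config is None:
        config = SamplerConfig()
    ndim = prior.ndim
    config = config.validated(ndim)
    rng = np.random.default_rng(config.seed)

    def call(u: np.ndarray) -> float:
        return _finite_loglik(loglik(prior.transform_dict(u)))

    # Invalid (NaN) likelihoods form an atom at -inf: zero likelihood over
    # real prior volume.  The live set is first filled with valid points by
    # plain rejection, and the run's starting volume is the estimated valid
    # fraction, so the unscorable region neither inflates nor deflates Z.
    n_live = config.n_live
    live_u = np.empty((n_live, ndim))
    live_logl = np.empty(n_live)
    n_calls = 0
    filled = 0
    total_draws = 0
    while filled < n_live:
        u = rng.random(ndim)
        ll = call(u)
        n_calls += 1
        total_draws += 1
        if ll > -math.inf:
            live_u[filled] = u
            live_logl[filled] = ll
            filled += 1
        elif filled == 0 and total_draws > config.max_invalid_draws:
            raise RuntimeError(
                "all initial prior draws were invalid; the model cannot be scored"
            )
        elif total_draws > 100 * config.max_invalid_draws:
            raise RuntimeError("could not populate the live set with valid draws")
    log_valid_fraction = math.log(n_live / total_draws)

    dead_logl: list[float] = []
    dead_u: list[np.ndarray] = []
    shrink = -1.0 / n_live
    it = 0
    scale = 0.25  # walk step size, adapted across the whole run

    while it < config.max_iterations:
        worst = int(np.argmin(live_logl))
        logl_star = float(live_logl[worst])
        dead_logl.append(logl_star)
        dead_u.append(live_u[worst].copy())
        it += 1

        # termination: the whole remaining live volume at the current best
        # likelihood could no longer move ln Z by more than dlogz
        partial_logz = log_valid_fraction + logsumexp(
            _shell_log_widths(len(dead_logl), shrink) + np.array(dead_logl)
        )
        logl_max = float(np.max(live_logl))
        log_x = it * shrink + log_valid_fraction
        if np.isfinite(partial_logz):
            gain = np.logaddexp(partial_logz, logl_max + log_x) - partial_logz
            if gain < config.dlogz:
                break

        # likelihood-constrained random walk from a random survivor
        start = worst
        while start == worst and n_live > 1:
            start = int(rng.integers(n_live))
        u = live_u[start].copy()
        ll = float(live_logl[start])
        for _ in range(config.walk_steps):
            prop = u + scale * rng.standard_normal(ndim)
            prop -= np.floor(prop)  # periodic wrap keeps the walk in the cube
            pll = call(prop)
            n_calls += 1
            if pll > logl_star:
                u, ll = prop, pll
                scale *= 1.06
            else:
                scale *= 0.97
            scale = min(max(scale, 1e-6), 1.0)
        live_u[worst] = u
        live_logl[worst] = ll

    # fold the remaining live points into the run, each carrying an equal
    # share of the final enclosed volume
    n_dead = len(dead_logl)
    order = np.argsort(live_logl)
    for idx in order:
        dead_logl.append(float(live_logl[idx]))
        dead_u.append(live_u[idx].copy())

    log_widths = np.empty(len(dead_logl))
    log_widths[:n_dead] = _shell_log_widths(n_dead, shrink)
    log_widths[n_dead:] = n_dead * shrink - math.log(n_live)
    log_widths += log_valid_fraction
    logl_arr = np.array(dead_logl)
    logz = float(logsumexp(log_widths + logl_arr))
    log_wt = log_widths + logl_arr - logz
    wt = np.exp(log_wt - logsumexp(log_wt))
    pos = wt > 0
    h = float(np.sum(wt[pos] * logl_arr[pos]) - logz)  # KL(posterior || prior)
    h = max(h, 0.0)
    logz_err = math.sqrt(h / n_live)

    # equally weighted posterior samples by importance resampling
    n_samp = min(max(10 * n_live, 1000), 10 * len(wt))
    idx = rng.choice(len(wt), size=n_samp, p=wt)
    theta = np.array([prior.transform(dead_u[i]) for i in idx])
    samples = pd.DataFrame(theta, columns=list(prior.params))

    best_i = int(np.argmax(logl_arr))
    best_params = prior.transform_dict(dead_u[best_i])
    return EvidenceResult(
        logz=logz,
        logz_err=float(logz_err),
        samples=samples,
        best_params=best_params,
        best_loglik=float(logl_arr[best_i]),
        n_iterations=it,
        n_calls=n_calls,
        information=h,
    )


def _shell_log_widths(n: int, shrink: float) -> np.ndarray:
    """log of X_{i-1} - X_i for dead points i = 1..n, with X_i = e^{i*shrink}.

    The widths telescope: together with the live points' equal shares of the
    final volume they sum to exactly 1, so a flat likelihood integrates to
    its constant exactly.
    """
    i = np.arange(1, n + 1, dtype=float)
    return (i - 1.0) * shrink + math.log1p(-math.exp(shrink))


def brute_force_evidence(
    loglik: Callable[[Mapping[str, float]], float],
    prior: PriorSpec,
    resolution: int = 201,
) -> float:
    """ln Z by trapezoid integration on the unit cube (dimension <= 3).

    Because the unit-cube transform carries the prior measure, the evidence
    is the plain integral of the likelihood over the cube.
    """
    ndim = prior.ndim
    if ndim > 3:
        raise ValueError("brute-force integration supports at most 3 dimensions")
    grid = np.linspace(0.0, 1.0, resolution)
    # trapezoid weights per axis
    w = np.full(resolution, 1.0)
    w[0] = w[-1] = 0.5
    w /= resolution - 1
    log_w = np.log(w)

    axes = [grid] * ndim
    logs = np.empty([resolution] * ndim)
    for idx in np.ndindex(*logs.shape):
        u = np.array([axes[d][idx[d]] for d in range(ndim)])
        logs[idx] = _finite_loglik(loglik(prior.transform_dict(u)))
        for d in range(ndim):
            logs[idx] += log_w[idx[d]]
    return float(logsumexp(logs))


def candidate_loglik(
    candidate: CandidateModel,
    data,
    criteria=None,
):
    """Build the composite log-likelihood function for one candidate.

    Returns a callable mapping a parameter dict to the Beta/exponential
    composite log-likelihood of the candidate's simulated steady state
    against the cohort summary (NaN when the simulation is unscorable).
    """
    from .likelihood import composite_loglik
    from .popdyn import SteadyStateCriteria, build_odes, simulate

    if criteria is None:
        criteria = SteadyStateCriteria()
    probe = {p: 0.1 for p in candidate.parameter_names}
    system = build_odes(candidate, probe)

    def loglik(params):
        sim = simulate(system, candidate.initiation, criteria, params)
        return composite_loglik(sim, data)

    return loglik


def fit_candidate(
    candidate: CandidateModel,
    data,
    config: SamplerConfig | None = None,
    rate_table: Mapping[str, float] | None = None,
    criteria=None,
) -> EvidenceResult:
    """Nested-sampling evidence for one candidate against one cohort."""
    prior = default_priors(candidate, rate_table=rate_table)
    return run_nested_sampling(candidate_loglik(candidate, data, criteria), prior, config)
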