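"""Deterministic population dynamics for candidate models.

A candidate's rules translate to a system of ODEs over subtype cell counts:
division contributes ``+k X``, death ``-k X`` and a transition X -> Z moves
mass ``k X`` from X to Z.  When a rule carries an inter-subtype effect, its
rate is modulated by the effector population w through a saturating
multiplier::

    k_eff = k * (1 + (m - 1) * w / (K + w))

which equals the baseline ``k`` when no effector cells are present and
approaches ``k * m`` when the effector population is far above the
saturation constant ``K``.  With all multipliers equal to 1 (or no effect
rules at all) the system is linear in the state and admits a closed-form
matrix-exponential solution, which ``simulate`` exploits.

Tumors are simulated over a 60-day horizon; a simulation counts as having
reached steady state when every subtype's *proportion* trajectory has a
least-squares slope within +/-1e-4 per day over the final 7.5% of the
horizon, and as valid when the final total population lies between 100
cells and an overflow guard of 1e12 cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .model_space import CandidateModel, InitiationScheme

__all__ = [
    "ParameterVector",
    "ODESystem",
    "SteadyStateCriteria",
    "SimulationResult",
    "effective_rate",
    "build_odes",
    "simulate",
    "check_steady_state",
    "trajectory_frame",
]

ParameterVector = Mapping[str, float]


def effective_rate(base: float, multiplier: float, effector_count: float, K: float) -> float:
    """Effect-modulated per-capita rate.

    Monotone in the effector count ``w``: equals ``base`` at w = 0, the
    mid-point ``base * (1 + m) / 2``-style value at w = K, and approaches
    ``base * multiplier`` as w -> infinity.
    """
    if K <= 0:
        raise ValueError("saturation constant must be positive")
    w = effector_count
    return base * (1.0 + (multiplier - 1.0) * w / (K + w))


@dataclass(frozen=True)
class SteadyStateCriteria:
    horizon_days: float = 60.0
    n_points: int = 601
    window_fraction: float = 0.075
    slope_bound: float = 1e-4  # proportion units / day
    min_total_cells: float = 100.0
    max_total_cells: float = 1e12

    def time_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon_days, self.n_points)


@dataclass
class ODESystem:
    """State labels plus a derivative function of (state, params)."""

    labels: tuple[str, ...]
    derivative: Callable[[np.ndarray, ParameterVector], np.ndarray]
    #: rate-matrix builder, present only when the system is linear
    rate_matrix: Callable[[ParameterVector], np.ndarray] | None = None


def _check_params(candidate: CandidateModel, params: ParameterVector) -> None:
    missing = [p for p in candidate.parameter_names if p not in params]
    if missing:
        raise KeyError(f"missing parameters: {missing}")


def build_odes(candidate: CandidateModel, params: ParameterVector) -> ODESystem:
    """Compile a candidate's rules into an ODE derivative function.

    The parameter vector is validated here but passed at call time, so one
    compiled system serves every likelihood evaluation for the candidate.
    """
    _check_params(candidate, params)
    labels = candidate.topology.subtypes
    index = {s: i for i, s in enumerate(labels)}
    n = len(labels)

    # (kind, subject_idx, target_idx|-1, rate_name, effect_name, sat_name,
    #  effector indices)
    compiled = []
    has_effects = False
    for r in candidate.rules:
        eff_idx = tuple(index[e] for e in r.effectors if e in index)
        if r.effect_param is not None:
            has_effects = True
        compiled.append(
            (
                r.kind,
                index[r.subject],
                index[r.target] if r.target else -1,
                r.rate_param,
                r.effect_param,
                r.saturation_param,
                eff_idx,
            )
        )

    def derivative(x: np.ndarray, p: ParameterVector) -> np.ndarray:
        dx = np.zeros(n)
        for kind, i, j, kname, mname, Kname, eff in compiled:
            k = p[kname]
            if mname is not None and eff:
                w = sum(x[e] for e in eff)
                k = effective_rate(k, p[mname], w, p[Kname])
            flux = k * x[i]
            if kind == "division":
                dx[i] += flux
            elif kind == "death":
                dx[i] -= flux
            else:
                dx[i] -= flux
                dx[j] += flux
        return dx

    rate_matrix = None
    if not has_effects:

        def rate_matrix(p: ParameterVector) -> np.ndarray:
            R = np.zeros((n, n))
            for kind, i, j, kname, _, _, _ in compiled:
                k = p[kname]
                if kind == "division":
                    R[i, i] += k
                elif kind == "death":
                    R[i, i] -= k
                else:
                    R[i, i] -= k
                    R[j, i] += k
            return R

    return ODESystem(labels=labels, derivative=derivative, rate_matrix=rate_matrix)


def check_steady_state(
    times: np.ndarray,
    proportions: np.ndarray,
    criteria: SteadyStateCriteria,
) -> bool:
    """True iff every subtype's proportion slope over the final window is flat.

    The slope is the least-squares fit over the last ``window_fraction`` of
    the time grid and must lie strictly within ``(-slope_bound, +slope_bound)``.
    """
    if proportions.ndim == 1:
        proportions = proportions[None, :]
    n_t = times.size
    if proportions.shape[1] != n_t:
        raise ValueError("trajectory does not cover the time grid")
    n_win = max(int(np.ceil(criteria.window_fraction * n_t)), 2)
    t = times[-n_win:]
    y = proportions[:, -n_win:]
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    slopes = (y @ tc) / denom
    return bool(np.all(np.abs(slopes) < criteria.slope_bound))


@dataclass
class SimulationResult:
    times: np.ndarray
    counts: np.ndarray  # shape (n_subtypes, n_times)
    labels: tuple[str, ...]
    steady_state_reached: bool
    valid: bool
    failed: bool = False  # solver failure / overflow guard tripped
    proportions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.proportions = np.where(totals > 0, self.counts / totals, np.nan)

    @property
    def final_proportions(self) -> dict[str, float]:
        return dict(zip(self.labels, self.proportions[:, -1]))


def _failed_result(times: np.ndarray, labels: tuple[str, ...]) -> SimulationResult:
    counts = np.full((len(labels), times.size), np.nan)
    return SimulationResult(
        times=times, counts=counts, labels=labels,
        steady_state_reached=False, valid=False, failed=True,
    )


def simulate(
    system: ODESystem,
    initiation: InitiationScheme,
    criteria: SteadyStateCriteria,
    params: ParameterVector,
) -> SimulationResult:
    """Integrate the system over the horizon and score steady-state status.

    Linear systems (no inter-subtype effects) are solved exactly through the
    eigendecomposition of the rate matrix; systems with effects fall back to
    a stiff-capable adaptive integrator (LSODA, rtol = atol = 1e-6).
    Non-finite states or totals above the overflow guard mark the result as
    failed; the caller scores such samples as invalid.
    """
    labels = system.labels
    times = criteria.time_grid()
    bad = set(initiation.initiators) - set(labels)
    if bad:
        raise ValueError(f"initiators {sorted(bad)} not in system state labels")
    per = initiation.total_initial_cells / len(initiation.initiators)
    x0 = np.array([per if s in initiation.initiators else 0.0 for s in labels])

    if system.rate_matrix is not None:
        R = system.rate_matrix(params)
        counts = _linear_solution(R, x0, times)
        if counts is None:
            return _failed_result(times, labels)
    else:
        try:
            sol = solve_ivp(
                lambda t, x: system.derivative(x, params),
                (times[0], times[-1]),
                x0,
                method="LSODA",
                t_eval=times,
                rtol=1e-6,
                atol=1e-6,
            )
        except (ValueError, FloatingPointError):
            return _failed_result(times, labels)
        if not sol.success or sol.y.shape[1] != times.size:
            return _failed_result(times, labels)
        counts = sol.y

    if not np.all(np.isfinite(counts)):
        return _failed_result(times, labels)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0) or totals[-1] > criteria.max_total_cells:
        return _failed_result(times, labels)

    proportions = counts / totals
    steady = check_steady_state(times, proportions, criteria)
    valid = steady and totals[-1] > criteria.min_total_cells
    return SimulationResult(
        times=times, counts=counts, labels=labels,
        steady_state_reached=steady, valid=valid,
    )


def _linear_solution(R: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray | None:
    """x(t) = expm(R t) x0 on the whole grid via eigendecomposition.

    Falls back to scipy's expm on the grid step when R is defective.
    Returns None if the solution overflows double precision.
    """
    try:
        lam, V = np.linalg.eig(R)
        c = np.linalg.solve(V, x0)
        with np.errstate(over="ignore", invalid="ignore"):
            ex = np.exp(np.outer(times, lam))  # (n_t, n)
            out = np.real(ex * c) @ V.T  # (n_t, n)
        if not np.all(np.isfinite(out)):
            return None
        return np.ascontiguousarray(out.T)
    except np.linalg.LinAlgError:
        pass
    from scipy.linalg import expm

    dt = times[1] - times[0]
    step = expm(R * dt)
    out = np.empty((x0.size, times.size))
    x = x0.astype(float)
    for i in range(times.size):
        out[:, i] = x
        x = step @ x
        if not np.all(np.isfinite(x)):
            return None
    return out


def trajectory_frame(result: SimulationResult):
    """Tidy (time, subtype, count, proportion) table for export."""
    import pandas as pd

    rows = []
    for i, s in enumerate(result.labels):
        rows.append(
            pd.DataFrame(
                {
                    "time": result.times,
                    "subtype": s,
                    "count": result.counts[i],
                    "proportion": result.proportions[i],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
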