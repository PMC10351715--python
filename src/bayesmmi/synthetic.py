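"""Synthetic cohort generators with the structure of the study datasets.

Real inputs are per-sample subtype-proportion tables (one row per tumor
sample, one column per subtype, rows summing to 1) from bulk-RNA-seq
deconvolution of three cohorts: a TKO-like cohort with mass spread over
A/A2/Y, an RPM-like cohort with mass over A/N/Y, and a cell-line cohort
dominated by subtype A.  The generators emulate that shape with Dirichlet
sampling: a preset fixes the mean composition and a concentration
(between-sample dispersion), and replicate proportion vectors are drawn
with ``alpha = concentration * means`` over the subtypes with nonzero
mean.  The preset means are synthetic stand-ins, not published values.

``ground_truth_recovery_fixture`` turns a known candidate model plus known
parameters into a cohort summary whose means are the model's simulated
steady-state proportions, for parameter/topology recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .likelihood import DatasetSummary
from .model_space import CandidateModel
from .popdyn import SteadyStateCriteria, build_odes, simulate

__all__ = [
    "CohortPreset",
    "TKO_LIKE",
    "RPM_LIKE",
    "A_CELL_LINE_LIKE",
    "sample_cohort",
    "summarize_cohort",
    "ground_truth_recovery_fixture",
]


@dataclass(frozen=True)
class CohortPreset:
    """Mean composition and dispersion of one synthetic cohort."""

    name: str
    means: Mapping[str, float]
    concentration: float = 30.0
    replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.means.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"preset means sum to {total}, expected 1")
        if any(v < 0 for v in self.means.values()):
            raise ValueError("preset means must be nonnegative")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


#: synthetic stand-ins for the three study cohorts (not published values)
TKO_LIKE = CohortPreset(
    name="TKO-like", means={"A": 0.25, "N": 0.0, "A2": 0.35, "Y": 0.40}
)
RPM_LIKE = CohortPreset(
    name="RPM-like", means={"A": 0.40, "N": 0.35, "A2": 0.0, "Y": 0.25}
)
A_CELL_LINE_LIKE = CohortPreset(
    name="ACellLine-like", means={"A": 0.70, "N": 0.10, "A2": 0.12, "Y": 0.08}
)


def sample_cohort(preset: CohortPreset) -> pd.DataFrame:
    """Replicate proportion vectors from a Dirichlet around the preset means.

    Subtypes with zero preset mean stay exactly zero (the Dirichlet is
    taken over the positive-mean support only).  Returns one row per
    sample with columns (sample_id, cohort, one column per subtype).
    """
    rng = np.random.default_rng(preset.seed)
    subtypes = list(preset.means)
    support = [s for s in subtypes if preset.means[s] > 0]
    alpha = np.array([preset.means[s] * preset.concentration for s in support])
    draws = rng.dirichlet(alpha, size=preset.replicates)
    df = pd.DataFrame(0.0, index=range(preset.replicates), columns=subtypes)
    df.loc[:, support] = draws
    df.insert(0, "cohort", preset.name)
    df.insert(0, "sample_id", [f"{preset.name}_{i:03d}" for i in range(preset.replicates)])
    return df


def summarize_cohort(samples: pd.DataFrame) -> DatasetSummary:
    """Per-subtype mean and standard deviation across replicate samples.

    Subtypes never observed in the cohort (identically zero columns) are
    dropped from the summary; a subtype that varies but has zero sample
    variance is rejected as degenerate.
    """
    value_cols = [c for c in samples.columns if c not in ("sample_id", "cohort")]
    if len(samples) < 2:
        raise ValueError("need at least two replicates to estimate a variance")
    cohort = str(samples["cohort"].iloc[0]) if "cohort" in samples else "cohort"
    observed = [c for c in value_cols if not (samples[c] == 0).all()]
    means = samples[observed].mean()
    sds = samples[observed].std(ddof=1)
    if (sds <= 0).any():
        bad = list(sds.index[sds <= 0])
        raise ValueError(f"zero between-sample variance for subtypes {bad}")
    return DatasetSummary(cohort=cohort, means=means.to_dict(), sds=sds.to_dict())


def ground_truth_recovery_fixture(
    candidate: CandidateModel,
    params: Mapping[str, float],
    noise_preset: CohortPreset | None = None,
    concentration: float = 200.0,
    replicates: int = 20,
    seed: int = 0,
    criteria: SteadyStateCriteria | None = None,
) -> tuple[DatasetSummary, dict]:
    """Cohort summary generated from a known model's steady state.

    Simulates the candidate under the given parameters, requires steady
    state, then draws Dirichlet replicates centered on the simulated
    steady-state proportions (``alpha = concentration * proportions``).
    Returns the summary plus a truth record (candidate, params, exact
    steady-state proportions) for recovery scoring.  With
    ``concentration = inf`` the summary means equal the simulated
    proportions exactly and a nominal 1% sd is attached.
    """
    if criteria is None:
        criteria = SteadyStateCriteria()
    system = build_odes(candidate, params)
    sim = simulate(system, candidate.initiation, criteria, params)
    if sim.failed or not sim.valid:
        raise ValueError("candidate does not reach a valid steady state")
    props = sim.final_proportions
    truth = {
        "candidate": candidate,
        "params": dict(params),
        "steady_state": dict(props),
    }
    subtypes = list(props)
    if np.isinf(concentration):
        means = {s: float(props[s]) for s in subtypes}
        sds = {s: 0.01 for s in subtypes}
        return DatasetSummary(cohort="recovery", means=means, sds=sds), truth
    rng = np.random.default_rng(seed)
    support = [s for s in subtypes if props[s] > 1e-12]
    alpha = np.array([props[s] * concentration for s in support])
    draws = rng.dirichlet(alpha, size=replicates)
    df = pd.DataFrame(0.0, index=range(replicates), columns=subtypes)
    df.loc[:, support] = draws
    df.insert(0, "cohort", "recovery")
    df.insert(0, "sample_id", [f"recovery_{i:03d}" for i in range(replicates)])
    return summarize_cohort(df), truth
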