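"""Multimodel inference over a candidate set.

Given one marginal likelihood (evidence) per candidate model, this module
computes model posterior probabilities, confidence sets of models,
posterior probabilities of scientific hypotheses (predicates over
candidates, each hypothesis averaging the evidences of its member models),
posterior odds with qualitative evidence bands, Bayesian model averaging of
posterior parameter samples, ANOVA/Tukey comparison of averaged parameter
distributions between groups, and the conservative consolidation rule that
keeps, for a model feature shared between analyses, the posterior closest
to the 0.5 prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ModelPosterior",
    "HypothesisQuery",
    "BMADistribution",
    "model_posteriors",
    "confidence_set",
    "hypothesis_posterior",
    "posterior_odds",
    "odds_band",
    "bma_distribution",
    "compare_groups",
    "consolidate",
    "consolidated_edge_list",
    "RELATIVE_LIKELIHOOD_CUTOFF",
]

#: smallest Bayes factor conventionally taken as a meaningful difference
RELATIVE_LIKELIHOOD_CUTOFF: float = 10.0 ** 0.5


@dataclass
class ModelPosterior:
    """Aligned per-model priors, log evidences and posterior probabilities."""

    model_ids: tuple[str, ...]
    priors: np.ndarray
    log_evidence: np.ndarray
    posteriors: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model_id": self.model_ids,
                "prior": self.priors,
                "log_evidence": self.log_evidence,
                "posterior": self.posteriors,
            }
        )

    def __getitem__(self, model_id: str) -> float:
        return float(self.posteriors[self.model_ids.index(model_id)])


def model_posteriors(
    evidences: Mapping[str, float],
    priors: Mapping[str, float] | None = None,
) -> ModelPosterior:
    """P(M_k | D) = Z_k P(M_k) / sum_j Z_j P(M_j), computed in log space.

    With no explicit priors every candidate is equally likely a priori.
    """
    ids = tuple(evidences)
    if not ids:
        raise ValueError("no models")
    logz = np.array([float(evidences[m]) for m in ids])
    if not np.all(np.isfinite(logz)):
        raise ValueError("non-finite log evidence encountered")
    if priors is None:
        pri = np.full(len(ids), 1.0 / len(ids))
    else:
        pri = np.array([float(priors[m]) for m in ids])
        if abs(pri.sum() - 1.0) > 1e-8:
            raise ValueError("model priors must sum to 1")
    log_post = logz + np.log(pri)
    log_post -= logsumexp(log_post)
    return ModelPosterior(
        model_ids=ids, priors=pri, log_evidence=logz, posteriors=np.exp(log_post)
    )


def confidence_set(
    posterior: ModelPosterior,
    method: str = "percent95",
    cutoff: float = RELATIVE_LIKELIHOOD_CUTOFF,
    level: float = 0.95,
) -> list[str]:
    """Best-model confidence set, ordered by decreasing posterior.

    ``percent95``: the smallest prefix of the descending posteriors whose
    cumulative mass reaches the level.  ``relative_likelihood``: every model
    whose posterior is within the Bayes-factor ``cutoff`` of the best one.
    """
    if len(posterior.model_ids) == 0:
        raise ValueError("empty posterior")
    order = np.argsort(-posterior.posteriors, kind="stable")
    ids = [posterior.model_ids[i] for i in order]
    p = posterior.posteriors[order]
    if method == "percent95":
        csum = np.cumsum(p)
        k = int(np.searchsorted(csum, level)) + 1
        return ids[: min(k, len(ids))]
    if method == "relative_likelihood":
        best = p[0]
        return [m for m, pi in zip(ids, p) if pi > 0 and best / pi <= cutoff]
    raise ValueError(f"unknown confidence-set method {method!r}")


@dataclass(frozen=True)
class HypothesisQuery:
    """A hypothesis = a predicate over candidate models with a prior."""

    name: str
    predicate: Callable[[object], bool]
    prior: float

    def members(self, models: Sequence) -> list:
        return [m for m in models if self.predicate(m)]


def hypothesis_posterior(
    models: Sequence,
    evidences: Mapping[str, float],
    hypotheses: Sequence[HypothesisQuery],
    model_id: Callable[[object], str] | None = None,
    normalized_conditional_prior: bool = False,
) -> pd.DataFrame:
    """Posterior probability of each hypothesis in a competing set.

    Per-model conditional priors follow P(M_k|H_i) = P(H_i)/|{M in H_i}|,
    the hypothesis evidence is the prior-weighted sum of member-model
    evidences, and hypothesis posteriors renormalize over the competing
    set.  Because each hypothesis averages over its members, a hypothesis
    backed by many mediocre models is not favored over one backed by a few
    good ones (bias avoidance): with equal evidences everywhere the
    posterior equals the prior regardless of member counts.

    ``normalized_conditional_prior`` drops the P(H_i) factor from the
    conditional prior (using 1/|members|); the hypothesis prior then enters
    only once, in the final Bayes update.  The default keeps the factor
    exactly as in the reference formulation; the two agree whenever the
    competing hypotheses share a common prior.
    """
    if model_id is None:
        model_id = lambda m: m.identity_key  # noqa: E731
    total_prior = sum(h.prior for h in hypotheses)
    if abs(total_prior - 1.0) > 1e-8:
        raise ValueError("competing hypothesis priors must sum to 1")
    rows = []
    log_numerators = []
    for h in hypotheses:
        members = h.members(models)
        if not members:
            raise ValueError(f"hypothesis {h.name!r} has no member models")
        logz = np.array([float(evidences[model_id(m)]) for m in members])
        cond_prior = (1.0 if normalized_conditional_prior else h.prior) / len(members)
        # P(D|H) = sum_k Z_k * P(M_k|H)
        log_pdh = logsumexp(logz) + np.log(cond_prior)
        log_numerators.append(log_pdh + np.log(h.prior))
        rows.append(
            {
                "hypothesis": h.name,
                "prior": h.prior,
                "n_models": len(members),
                "log_evidence": log_pdh,
            }
        )
    log_num = np.array(log_numerators)
    post = np.exp(log_num - logsumexp(log_num))
    df = pd.DataFrame(rows)
    df["posterior"] = post
    df["odds"] = [posterior_odds(p) if p < 1 else np.inf for p in post]
    df["band"] = [odds_band(p) for p in post]
    return df


def posterior_odds(p: float) -> float:
    """p / (1 - p); infinite for p = 1."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    if p == 1.0:
        return float("inf")
    return p / (1.0 - p)


def odds_band(p: float) -> str:
    """Qualitative evidence label for a hypothesis posterior probability."""
    if p >= 0.75 or p <= 0.25:
        return "substantial"
    if p >= 0.667 or p <= 0.333:
        return "notable"
    return "uninformed"


@dataclass
class BMADistribution:
    """Pooled posterior samples of one parameter, weighted by model posterior."""

    parameter: str
    values: np.ndarray
    weights: np.ndarray  # each sample carries its model's posterior probability
    total_mass: float = field(init=False)

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must align")
        # per-sample weights are model_posterior / n_samples_in_model, so the
        # total equals the posterior mass of the models carrying the parameter
        self.total_mass = float(self.weights.sum())

    def mean(self) -> float:
        w = self.weights
        if w.sum() == 0:
            return float("nan")
        return float(np.average(self.values, weights=w))

    def quantile(self, q) -> np.ndarray:
        """Weighted quantile (inverted CDF; no interpolation across atoms)."""
        order = np.argsort(self.values)
        v = self.values[order]
        w = self.weights[order]
        if w.sum() == 0:
            return np.full(np.shape(q), np.nan)
        cw = np.cumsum(w) / w.sum()
        idx = np.searchsorted(cw, np.asarray(q), side="left")
        return v[np.clip(idx, 0, v.size - 1)]

    def resample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.weights / self.weights.sum()
        return rng.choice(self.values, size=n, p=p)


def bma_distribution(
    posterior: ModelPosterior,
    samples_per_model: Mapping[str, pd.DataFrame],
    parameter: str,
    max_samples_per_model: int = 1000,
) -> BMADistribution:
    """Pool a parameter's posterior samples across models by BMA weighting.

    Takes at most the first ``max_samples_per_model`` equally weighted
    samples from each model containing the parameter; each sample carries
    its model's posterior probability (divided by the model's sample count,
    so a model's total contribution equals its posterior mass).
    """
    values: list[np.ndarray] = []
    weights: list[np.ndarray] = []
    for m, post in zip(posterior.model_ids, posterior.posteriors):
        df = samples_per_model.get(m)
        if df is None or parameter not in df.columns:
            continue
        v = df[parameter].to_numpy()[:max_samples_per_model]
        if v.size == 0:
            continue
        values.append(v)
        weights.append(np.full(v.size, post / v.size))
    if not values:
        raise ValueError(f"parameter {parameter!r} appears in no model")
    return BMADistribution(
        parameter=parameter,
        values=np.concatenate(values),
        weights=np.concatenate(weights),
    )


def compare_groups(
    groups: Mapping[str, BMADistribution],
    fwer: float = 0.01,
    draws: int = 1000,
    iterations: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Are parameter distributions different between groups?

    Per iteration: draw ``draws`` values per group from its BMA-weighted
    distribution (with replacement, probability proportional to weight),
    run one-way ANOVA and all-pairs Tukey HSD at the family-wise error
    rate, and record per-pair significance.  The final verdict per pair is
    the strict majority over iterations; an exact tie counts as
    not-different.  Zero-variance degenerate draws short-circuit to
    not-different.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    pair_hits: dict[tuple[str, str], int] = {}
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            pair_hits[(names[a_i], names[b_i])] = 0
    for it in range(iterations):
        rng = np.random.default_rng((seed, it))
        data = {g: groups[g].resample(draws, rng) for g in names}
        pooled = np.concatenate(list(data.values()))
        if np.allclose(pooled, pooled[0]):
            continue  # degenerate: nothing can differ
        _, p_anova = f_oneway(*data.values())
        if not np.isfinite(p_anova) or p_anova >= fwer:
            continue
        labels = np.repeat(names, draws)
        tk = pairwise_tukeyhsd(pooled, labels, alpha=fwer)
        header = tk.summary().data[0]
        body = tk.summary().data[1:]
        res = pd.DataFrame(body, columns=header)
        for _, row in res.iterrows():
            key = tuple(sorted((str(row["group1"]), str(row["group2"]))))
            key = (key[0], key[1])
            if key not in pair_hits:  # order may differ from ours
                key = (key[1], key[0])
            if bool(row["reject"]):
                pair_hits[key] += 1
    out_rows = []
    for (a, b), hits in pair_hits.items():
        out_rows.append(
            {
                "group1": a,
                "group2": b,
                "significant_iterations": hits,
                "iterations": iterations,
                "different": hits > iterations - hits,  # strict majority
            }
        )
    return pd.DataFrame(out_rows)


def consolidate(posteriors: Sequence[float]) -> tuple[float, int]:
    """Conservative consolidation of a model feature's posteriors.

    When a feature (e.g. a specific transition) was scored in several
    analyses, keep the posterior closest to the uninformed prior of 0.5 —
    the value claiming the least knowledge.  Ties break toward the smaller
    posterior.  Returns (selected value, index in the input).
    """
    vals = list(posteriors)
    if not vals:
        raise ValueError("no posteriors to consolidate")
    best = min(range(len(vals)), key=lambda i: (abs(vals[i] - 0.5), vals[i]))
    return float(vals[best]), best


def consolidated_edge_list(
    feature_posteriors: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """Consolidate per-feature posteriors into an exportable edge list.

    Keys are rule identifiers like ``tr_A_N`` (transition), ``div_A`` or
    ``die_Y`` (behaviors); each maps to the posteriors the feature
    received across analyses.  One row per feature with the consolidated
    (closest-to-0.5) posterior, its source index, odds and band.
    """
    rows = []
    for feature, values in feature_posteriors.items():
        selected, idx = consolidate(values)
        parts = feature.split("_")
        if parts[0] == "tr" and len(parts) == 3:
            src, dst = parts[1], parts[2]
        else:
            src, dst = parts[-1], feature.split("_")[0]
        rows.append(
            {
                "from_subtype": src,
                "to_subtype_or_behavior": dst,
                "feature": feature,
                "posterior": selected,
                "source_analysis": idx,
                "odds": posterior_odds(selected) if selected < 1 else np.inf,
                "band": odds_band(selected),
            }
        )
    return pd.DataFrame(rows)
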