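"""Information-criterion scoring: AIC, AICc, Akaike weights, SW, BIC.

These are the frequentist-flavored counterparts against which the Bayesian
pathway is compared.  The maximum log-likelihood fed in is, by convention
in this package, the best-fit sample from the same nested-sampling run
that produced the model's evidence, so both pathways score identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ICRecord",
    "aic",
    "aicc",
    "akaike_weights",
    "sum_weights",
    "bic",
    "bic_probability",
    "ic_table",
]


def aic(maxloglik: float, k: int) -> float:
    """-2 ln L(theta_best | D) + 2K."""
    if k < 0:
        raise ValueError("parameter count must be nonnegative")
    return -2.0 * maxloglik + 2.0 * k


def aicc(aic_value: float, k: int, n: int) -> float:
    """Small-sample correction: AIC + (2K^2 + 2K) / (n - K - 1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= K+1={k + 1}")
    return aic_value + (2.0 * k * k + 2.0 * k) / (n - k - 1.0)


def akaike_weights(scores: Sequence[float]) -> np.ndarray:
    """w_k = exp(-Delta_k/2) / sum_r exp(-Delta_r/2), Delta_k = score_k - min."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0 or not np.any(np.isfinite(s)):
        raise ValueError("need at least one finite score")
    delta = s - np.nanmin(s[np.isfinite(s)])
    logw = -0.5 * delta
    return np.exp(logw - logsumexp(logw[np.isfinite(logw)]))


def sum_weights(weights: Sequence[float], membership: Sequence[bool]) -> float:
    """SW of a hypothesis: total Akaike weight of its member models."""
    w = np.asarray(weights, dtype=float)
    m = np.asarray(membership, dtype=bool)
    if w.shape != m.shape:
        raise ValueError("weights and membership must align")
    return float(w[m].sum())


def bic(maxloglik: float, k: int, n: int) -> float:
    """-2 ln L + K ln n."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    return -2.0 * maxloglik + k * np.log(n)


def bic_probability(
    maxlogliks: Sequence[float], ks: Sequence[int], n: int
) -> np.ndarray:
    """Approximate model posteriors proportional to exp(-BIC/2)."""
    scores = np.array([bic(ll, k, n) for ll, k in zip(maxlogliks, ks)])
    logp = -0.5 * (scores - scores.min())
    return np.exp(logp - logsumexp(logp))


@dataclass(frozen=True)
class ICRecord:
    model_id: str
    maxloglik: float
    k: int
    n: int

    @property
    def aic(self) -> float:
        return aic(self.maxloglik, self.k)

    @property
    def aicc(self) -> float:
        return aicc(self.aic, self.k, self.n)


def ic_table(records: Sequence[ICRecord], use_aicc: bool = True) -> pd.DataFrame:
    """Per-model IC summary: score, Delta, Akaike weight, BIC probability."""
    if not records:
        raise ValueError("no records")
    scores = [r.aicc if use_aicc else r.aic for r in records]
    w = akaike_weights(scores)
    bic_p = bic_probability([r.maxloglik for r in records], [r.k for r in records],
                            records[0].n)
    df = pd.DataFrame(
        {
            "model_id": [r.model_id for r in records],
            "maxloglik": [r.maxloglik for r in records],
            "K": [r.k for r in records],
            "n": [r.n for r in records],
            "score": scores,
            "delta": np.asarray(scores) - min(scores),
            "weight": w,
            "bic_probability": bic_p,
        }
    )
    return df.sort_values("delta", kind="stable").reset_index(drop=True)
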