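"""Partial-synthesis combining rules for the m augmented-replicate analyses.

An augmented dataset mixes real records with synthesized ones, so the m
replicate analyses are pooled with the partial-synthesis variant of the
multiple-imputation combining rules: with per-replicate estimates q_i and
variances v_i = se_i^2,

    q_bar = mean(q_i)
    v_bar = mean(v_i)
    b     = sum((q_i - q_bar)^2) / (m - 1)      (between-replicate variance)
    T     = v_bar + b / m                        (adjusted total variance)

and the large-sample 95% CI is q_bar +/- 1.96 * sqrt(T). The normal
quantile (not a t quantile) is deliberate: these are large-sample
intervals, and no small-m degrees-of-freedom correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .estimation import EffectEstimate


@dataclass(frozen=True)
class CombinedEstimate:
    """Pooled parameter over m augmented replicates."""

    q_bar: float
    v_bar: float
    b: float
    T: float
    ci_low: float
    ci_high: float
    m: int
    alpha: float
    significant: bool | None
    direction: int
    family: str


def combine(replicates: Sequence[EffectEstimate], alpha: float = 0.05) -> CombinedEstimate:
    """Pool replicate analyses with the partial-synthesis rules.

    Requires m >= 2 replicates of the same analysis family. Permutation
    invariant; when all q_i coincide, b = 0 and the interval collapses to
    the ordinary Wald interval with variance v_bar.
    """
    m = len(replicates)
    if m < 2:
        raise ValueError("combining rules require m >= 2 replicates")
    families = {r.family for r in replicates}
    if len(families) != 1:
        raise ValueError(f"mixed analysis families: {sorted(families)}")
    family = families.pop()

    q = np.array([r.estimate for r in replicates], dtype=float)
    v = np.array([r.se**2 for r in replicates], dtype=float)
    q_bar = float(q.mean())
    v_bar = float(v.mean())
    b = float(np.sum((q - q_bar) ** 2) / (m - 1))
    T = v_bar + b / m
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = q_bar - z * np.sqrt(T), q_bar + z * np.sqrt(T)
    sig = None if family == "descriptive-mean" else bool(lo > 0 or hi < 0)
    return CombinedEstimate(
        q_bar=q_bar,
        v_bar=v_bar,
        b=b,
        T=float(T),
        ci_low=float(lo),
        ci_high=float(hi),
        m=m,
        alpha=alpha,
        significant=sig,
        direction=int(np.sign(q_bar)),
        family=family,
    )


def combined_from_wald(
    estimate: float, se: float, family: str = "mean-difference", alpha: float = 0.05, m: int = 1
) -> CombinedEstimate:
    """Wrap a single (estimate, SE) summary — e.g. a reduced-data baseline or
    a published table cell — in the combined-estimate interface with
    T = se^2 and b = 0, so the replicability metrics apply uniformly."""
    if se <= 0:
        raise ValueError("se must be > 0")
    z = stats.norm.ppf(1 - alpha / 2)
    lo, hi = estimate - z * se, estimate + z * se
    sig = None if family == "descriptive-mean" else bool(lo > 0 or hi < 0)
    return CombinedEstimate(
        q_bar=float(estimate),
        v_bar=float(se**2),
        b=0.0,
        T=float(se**2),
        ci_low=float(lo),
        ci_high=float(hi),
        m=m,
        alpha=alpha,
        significant=sig,
        direction=int(np.sign(estimate)),
        family=family,
    )


__all__ = ["CombinedEstimate", "combine", "combined_from_wald"]
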