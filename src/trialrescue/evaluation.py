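"""Replicability metrics and Hellinger-distance fidelity.

Replicability compares the *real* (full-accrual) analysis with the pooled
*augmented* analysis on four criteria:

estimate agreement
    1 iff the augmented point estimate lies inside the real 95% CI (closed
    at the endpoints). Under no bias and equal variances this happens with
    probability 2*Phi(1.96/sqrt(2)) - 1 ~= 0.834.
decision agreement
    1 iff the two analyses share both statistical significance and sign;
    not applicable (None) for descriptive analyses.
standardized difference
    Z = (q_aug - q_real) / sqrt(se_real^2 + T_aug), flagged consistent with
    no difference iff |Z| <= 1.96.
CI overlap
    The symmetric two-way average overlap proportion
    0.5 * (L / len_real + L / len_aug), L the intersection length.

Fidelity is the per-variable Hellinger distance between training and
generated columns — H = sqrt(1 - sum_k sqrt(p_k q_k)) over shared levels
(continuous columns first binned into equal-width bins over the pooled
range) — averaged over variables and over the m generated replicates.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .combining import CombinedEstimate
from .estimation import EffectEstimate
from .schema import TrialDataset

Z_CRIT = 1.96


@dataclass(frozen=True)
class ReplicabilityResult:
    """The four replicability criteria for one (generator, r) comparison."""

    estimate_agreement: int
    decision_agreement: int | None
    std_diff_z: float
    std_diff_ok: int
    ci_overlap: float


@dataclass(frozen=True)
class FidelityResult:
    """Hellinger fidelity of generated data to its training data."""

    per_variable: dict[str, float]
    dataset_mean: float
    per_replicate: tuple[float, ...]
    replicate_mean: float


def _aug_point(aug) -> float:
    return aug.q_bar if isinstance(aug, CombinedEstimate) else aug.estimate


def _aug_var(aug) -> float:
    return aug.T if isinstance(aug, CombinedEstimate) else aug.se**2


def estimate_agreement(real: EffectEstimate, aug) -> int:
    """1 iff the augmented estimate falls inside the real 95% CI.

    Asymmetric by construction: the real CI is the yardstick.
    """
    q = _aug_point(aug)
    return int(real.ci_low <= q <= real.ci_high)


def decision_agreement(real: EffectEstimate, aug) -> int | None:
    """1 iff significance status and sign both match; None if descriptive."""
    if real.family == "descriptive-mean" or real.significant is None or aug.significant is None:
        return None
    same_sig = bool(real.significant) == bool(aug.significant)
    same_dir = real.direction == (
        aug.direction if hasattr(aug, "direction") else int(np.sign(_aug_point(aug)))
    )
    return int(same_sig and same_dir)


def standardized_difference(real: EffectEstimate, aug) -> tuple[float, int]:
    """Z statistic for the real-vs-augmented estimate difference.

    Z = (q_aug - q_real) / sqrt(v_real + v_aug); the indicator is 1 iff
    |Z| <= 1.96 (consistent with no difference).
    """
    denom = real.se**2 + _aug_var(aug)
    if denom <= 0:
        raise ValueError("zero combined variance")
    z = (_aug_point(aug) - real.estimate) / np.sqrt(denom)
    return float(z), int(abs(z) <= Z_CRIT)


def ci_overlap(real, aug) -> float:
    """Symmetric two-way average CI overlap proportion in [0, 1]."""
    lo1, hi1 = real.ci_low, real.ci_high
    lo2, hi2 = aug.ci_low, aug.ci_high
    len1, len2 = hi1 - lo1, hi2 - lo2
    if len1 <= 0 or len2 <= 0:
        raise ValueError("degenerate zero-length confidence interval")
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    return 0.5 * (inter / len1 + inter / len2)


def replicability(real: EffectEstimate, aug) -> ReplicabilityResult:
    """All four criteria for one comparison."""
    z, ok = standardized_difference(real, aug)
    return ReplicabilityResult(
        estimate_agreement=estimate_agreement(real, aug),
        decision_agreement=decision_agreement(real, aug),
        std_diff_z=z,
        std_diff_ok=ok,
        ci_overlap=ci_overlap(real, aug),
    )


# ---------------------------------------------------------------------------
# Hellinger fidelity
# ---------------------------------------------------------------------------


def _hellinger_from_probs(p: np.ndarray, q: np.ndarray) -> float:
    # (1/sqrt(2)) * ||sqrt(p) - sqrt(q)||_2; algebraically sqrt(1 - BC) with
    # BC the Bhattacharyya coefficient, but exactly 0 for identical inputs
    d = float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))
    return float(min(1.0, np.sqrt(0.5 * d)))


def hellinger_variable(train_col, gen_col, kind: str, n_bins: int = 10) -> float:
    """Hellinger distance between empirical distributions of one variable.

    Categorical/binary: relative frequencies over the union of observed
    levels. Continuous/event-time: both samples binned into ``n_bins``
    equal-width bins spanning the pooled range. Always in [0, 1]; 0 iff the
    empirical distributions coincide, 1 for disjoint supports.
    """
    a = pd.Series(train_col)
    b = pd.Series(gen_col)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty column")
    if kind in ("binary", "categorical"):
        levels = sorted(set(a.astype(str)) | set(b.astype(str)))
        p = a.astype(str).value_counts(normalize=True).reindex(levels, fill_value=0.0)
        q = b.astype(str).value_counts(normalize=True).reindex(levels, fill_value=0.0)
        return _hellinger_from_probs(p.to_numpy(), q.to_numpy())
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:  # all values identical across both samples
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(x, bins=edges)
    q, _ = np.histogram(y, bins=edges)
    return _hellinger_from_probs(p / p.sum(), q / q.sum())


def fidelity_report(
    train: TrialDataset, replicate_generated: list[pd.DataFrame], n_bins: int = 10
) -> FidelityResult:
    """Average per-variable Hellinger distances over generated replicates.

    ``replicate_generated`` holds one generated record table per replicate
    — either just the generated chunk, or a full same-size generated
    dataset, depending on which fidelity view is wanted. The recruitment
    index is excluded.
    """
    if not replicate_generated:
        raise ValueError("at least one generated replicate is required")
    names = train.schema.synth_names
    per_var_acc = {name: [] for name in names}
    per_rep = []
    for gen in replicate_generated:
        missing = [n for n in names if n not in gen.columns]
        if missing:
            raise ValueError(f"generated replicate missing columns {missing}")
        ds = []
        for name in names:
            spec = train.schema.get(name)
            h = hellinger_variable(train.data[name], gen[name], spec.kind, n_bins)
            per_var_acc[name].append(h)
            ds.append(h)
        per_rep.append(float(np.mean(ds)))
    per_variable = {name: float(np.mean(v)) for name, v in per_var_acc.items()}
    dataset_mean = float(np.mean(list(per_variable.values())))
    return FidelityResult(
        per_variable=per_variable,
        dataset_mean=dataset_mean,
        per_replicate=tuple(per_rep),
        replicate_mean=float(np.mean(per_rep)),
    )


__all__ = [
    "ReplicabilityResult",
    "FidelityResult",
    "estimate_agreement",
    "decision_agreement",
    "standardized_difference",
    "ci_overlap",
    "replicability",
    "hellinger_variable",
    "fidelity_report",
]
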