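"""Endpoint-analysis adapters: one treatment-effect estimate per family.

Each adapter returns an :class:`EffectEstimate` on the family's natural
scale (mean difference, log-odds, log-hazard, survival-probability
difference, or a descriptive mean) with a standard error and symmetric Wald
confidence bounds. ``significant`` is derived from the Wald CI excluding
zero (not a separate test statistic) because all downstream replicability
metrics are CI-based.

Families
--------
mean-difference
    Difference in arm means (treated - control) with pooled-variance SE.
adjusted-linear
    Treatment coefficient of an OLS fit with covariates.
logistic
    Treatment log-odds coefficient from maximum-likelihood logistic
    regression; separation/non-convergence raises :class:`FitFailure`.
binary-robust
    Treatment coefficient of a binomial GLM with HC0 sandwich SEs — an
    independence-working-model stand-in for GEE analyses (identical point
    estimates; cluster structure is outside the data model).
cox
    Treatment log-hazard from the Cox partial likelihood (Breslow ties,
    via lifelines).
survival-prob-difference
    Difference of product-limit survival estimates at a horizon, Greenwood
    SEs combined in quadrature.
descriptive-mean
    Single-sample mean and SE of the outcome; significance not applicable.

The module also provides the recruitment-order interaction test used to
probe for a monotone drift of the treatment effect over accrual.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .schema import AnalysisSpec, TrialDataset


class FitFailure(RuntimeError):
    """A model fit failed for statistical reasons (separation, zero events,
    non-convergence) — distinct from a programming error."""


@dataclass(frozen=True)
class EffectEstimate:
    """A treatment-effect (or descriptive) estimate with Wald 95% bounds.

    ``significant`` is True/False for comparative families (CI excludes 0)
    and None for descriptive analyses. ``direction`` is the sign of the
    estimate.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    alpha: float
    significant: bool | None
    direction: int
    family: str
    n_used: int

    @classmethod
    def from_wald(
        cls,
        estimate: float,
        se: float,
        family: str = "mean-difference",
        alpha: float = 0.05,
        n_used: int = 0,
    ) -> "EffectEstimate":
        if se <= 0:
            raise ValueError("se must be > 0")
        z = stats.norm.ppf(1 - alpha / 2)
        lo, hi = estimate - z * se, estimate + z * se
        sig = None if family == "descriptive-mean" else bool(lo > 0 or hi < 0)
        return cls(
            estimate=float(estimate),
            se=float(se),
            ci_low=float(lo),
            ci_high=float(hi),
            alpha=alpha,
            significant=sig,
            direction=int(np.sign(estimate)),
            family=family,
            n_used=n_used,
        )


def _outcome01(ds: TrialDataset, name: str) -> np.ndarray:
    spec = ds.schema.get(name)
    if spec.is_discrete:
        return (ds.data[name].to_numpy() == spec.levels[1]).astype(float)
    return ds.data[name].to_numpy(dtype=float)


def _design(ds: TrialDataset, covariates) -> np.ndarray:
    """Covariate block: continuous as-is, discrete dummy-coded dropping the
    first level."""
    blocks = []
    for name in covariates:
        spec = ds.schema.get(name)
        if spec is None:
            raise ValueError(f"covariate {name!r} not in schema")
        if spec.is_discrete:
            col = ds.data[name].astype(str)
            for lev in spec.levels[1:]:
                blocks.append((col == lev).to_numpy(dtype=float))
        else:
            blocks.append(ds.data[name].to_numpy(dtype=float))
    if not blocks:
        return np.empty((ds.n, 0))
    return np.column_stack(blocks)


def _ols(y, X) -> tuple[float, float]:
    """Treatment coefficient (column 1 of X) and its classical SE."""
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    return float(res.params[1]), float(res.bse[1])


def analyze(ds: TrialDataset, spec: AnalysisSpec) -> EffectEstimate:
    """Run the family-appropriate endpoint analysis on a dataset."""
    import statsmodels.api as sm

    spec.check_compatible(ds.schema)
    fam = spec.family
    y = _outcome01(ds, spec.outcome)
    n = ds.n

    if fam == "descriptive-mean":
        mean = float(np.mean(y))
        se = float(np.std(y, ddof=1) / np.sqrt(n))
        return EffectEstimate.from_wald(mean, se, fam, spec.alpha, n)

    t = ds.arm01()
    if t.min() == t.max():
        raise ValueError("treatment has no contrast in this dataset")

    if fam == "mean-difference":
        y1, y0 = y[t == 1], y[t == 0]
        est = float(y1.mean() - y0.mean())
        sp2 = ((y1.size - 1) * y1.var(ddof=1) + (y0.size - 1) * y0.var(ddof=1)) / (
            y1.size + y0.size - 2
        )
        se = float(np.sqrt(sp2 * (1 / y1.size + 1 / y0.size)))
        return EffectEstimate.from_wald(est, se, fam, spec.alpha, n)

    if fam in ("adjusted-linear", "logistic", "binary-robust"):
        X = np.column_stack([np.ones(n), t, _design(ds, spec.covariates)])
        if fam == "adjusted-linear":
            est, se = _ols(y, X)
        else:
            try:
                if fam == "logistic":
                    res = sm.Logit(y, X).fit(disp=False, maxiter=200)
                    if not res.mle_retvals.get("converged", True):
                        raise FitFailure("logistic fit did not converge")
                else:
                    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
                est, se = float(res.params[1]), float(res.bse[1])
            except FitFailure:
                raise
            except Exception as e:  # perfect separation, singular design, ...
                raise FitFailure(f"{fam} fit failed: {e}") from e
            if not np.isfinite(est) or not np.isfinite(se) or se > 1e3:
                raise FitFailure(f"{fam} fit unstable (estimate {est}, se {se})")
        return EffectEstimate.from_wald(est, se, fam, spec.alpha, n)

    # survival families
    out_spec = ds.schema.get(spec.outcome)
    times = ds.data[spec.outcome].to_numpy(dtype=float)
    ind_spec = ds.schema.get(out_spec.event_indicator)
    events = (ds.data[ind_spec.name].to_numpy() == ind_spec.levels[1]).astype(int)
    if events.sum() == 0:
        raise FitFailure("no events observed")

    if fam == "cox":
        from lifelines import CoxPHFitter

        df = pd.DataFrame({"time": times, "event": events, "treat": t})
        for j, name in enumerate(spec.covariates):
            df[f"x{j}"] = _design(ds, (name,))
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as e:
            raise FitFailure(f"cox fit failed: {e}") from e
        est = float(cph.params_["treat"])
        se = float(cph.standard_errors_["treat"])
        if not np.isfinite(est) or not np.isfinite(se):
            raise FitFailure("cox fit unstable")
        return EffectEstimate.from_wald(est, se, fam, spec.alpha, n)

    # survival-prob-difference
    s1, v1 = km_survival_at(times[t == 1], events[t == 1], spec.horizon)
    s0, v0 = km_survival_at(times[t == 0], events[t == 0], spec.horizon)
    est = float(s1 - s0)
    se = float(np.sqrt(v1 + v0))
    if se == 0:
        raise FitFailure("degenerate survival estimate (zero variance)")
    return EffectEstimate.from_wald(est, se, fam, spec.alpha, n)


def km_survival_at(times, events, horizon: float) -> tuple[float, float]:
    """Product-limit survival estimate and Greenwood variance at ``horizon``.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i);
    Var(S) = S(t)^2 * sum_{t_i <= t} d_i / (n_i * (n_i - d_i)).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    n_at_risk = times.size
    s, gw = 1.0, 0.0
    i = 0
    while i < times.size and times[i] <= horizon:
        ti = times[i]
        d = 0
        c = 0
        while i < times.size and times[i] == ti:
            d += events[i]
            c += 1 - events[i]
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                gw += d / (n_at_risk * (n_at_risk - d))
        n_at_risk -= d + c
    return s, s * s * gw


def interaction_test(ds: TrialDataset, spec: AnalysisSpec) -> EffectEstimate:
    """Treatment-by-recruitment-order interaction coefficient with 95% CI.

    Fits the family-appropriate regression with main effects for treatment
    and normalized recruitment order (rank / n, in (0, 1]) plus their
    interaction, and returns the interaction coefficient. A CI excluding 0
    flags a monotone drift of the treatment effect over accrual.
    """
    import statsmodels.api as sm

    spec.check_compatible(ds.schema)
    if ds.schema.arm_name is None:
        raise ValueError("interaction test requires a treatment variable")
    t = ds.arm01()
    if t.min() == t.max():
        raise ValueError("treatment has no contrast in this dataset")
    idx = ds.data[ds.schema.index_name].to_numpy(dtype=float)
    order = stats.rankdata(idx, method="ordinal") / ds.n
    inter = t * order
    fam = spec.family

    if fam in ("cox", "survival-prob-difference"):
        from lifelines import CoxPHFitter

        out_spec = ds.schema.get(spec.outcome)
        ind_spec = ds.schema.get(out_spec.event_indicator)
        events = (ds.data[ind_spec.name].to_numpy() == ind_spec.levels[1]).astype(int)
        if events.sum() == 0:
            raise FitFailure("no events observed")
        df = pd.DataFrame(
            {
                "time": ds.data[spec.outcome].to_numpy(dtype=float),
                "event": events,
                "treat": t,
                "order": order,
                "treat_order": inter,
            }
        )
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
        except Exception as e:
            raise FitFailure(f"cox interaction fit failed: {e}") from e
        est = float(cph.params_["treat_order"])
        se = float(cph.standard_errors_["treat_order"])
        return EffectEstimate.from_wald(est, se, fam, spec.alpha, ds.n)

    y = _outcome01(ds, spec.outcome)
    X = np.column_stack([np.ones(ds.n), t, order, inter])
    if fam in ("logistic", "binary-robust"):
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception as e:
            raise FitFailure(f"logistic interaction fit failed: {e}") from e
        est, se = float(res.params[3]), float(res.bse[3])
    else:
        res = sm.OLS(y, X).fit()
        est, se = float(res.params[3]), float(res.bse[3])
    if not np.isfinite(est) or not np.isfinite(se):
        raise FitFailure("interaction fit unstable")
    return EffectEstimate.from_wald(est, se, fam, spec.alpha, ds.n)


__all__ = ["EffectEstimate", "FitFailure", "analyze", "interaction_test", "km_survival_at"]
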