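"""Endpoint-analysis adapters checked against hand arithmetic and oracles."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trialrescue import (
    AnalysisSpec,
    SimulationConfig,
    TrialDataset,
    TrialSchema,
    VariableSpec,
    analyze,
    interaction_test,
    simulate_trial,
)
from trialrescue.estimation import EffectEstimate, FitFailure, km_survival_at
from tests.conftest import two_arm_dataset


def _survival_dataset(times, events, arms) -> TrialDataset:
    schema = TrialSchema(
        (
            VariableSpec("order", "continuous", "recruitment-index"),
            VariableSpec("arm", "binary", "treatment", levels=("0", "1")),
            VariableSpec("event", "binary", "event-indicator", levels=("0", "1")),
            VariableSpec("time", "event-time", "outcome", event_indicator="event"),
        )
    )
    df = pd.DataFrame(
        {
            "order": range(1, len(times) + 1),
            "arm": [str(a) for a in arms],
            "event": [str(e) for e in events],
            "time": [float(t) for t in times],
        }
    )
    return TrialDataset(schema, df)


def test_mean_difference_hand_arithmetic():
    # treated {1,2,3} vs control {2,3,4}: pooled variance 1, SE = sqrt(2/3)
    ds = two_arm_dataset(control_y=[2, 3, 4], treated_y=[1, 2, 3])
    est = analyze(ds, AnalysisSpec("mean-difference", "y"))
    assert est.estimate == pytest.approx(-1.0)
    assert est.se == pytest.approx(np.sqrt(2 / 3), abs=1e-4)


def test_identical_arms_give_zero_nonsignificant_estimate():
    ds = two_arm_dataset(control_y=[1, 2, 3, 4], treated_y=[1, 2, 3, 4])
    est = analyze(ds, AnalysisSpec("mean-difference", "y"))
    assert est.estimate == 0.0 and est.significant is False and est.direction == 0


def test_cox_matches_brute_force_partial_likelihood():
    """Grid-search oracle for the Breslow partial likelihood on a 4-subject toy."""
    times, events, arms = [1, 2, 3, 4], [1, 1, 1, 1], [0, 1, 0, 1]
    ds = _survival_dataset(times, events, arms)
    est = analyze(ds, AnalysisSpec("cox", "time"))

    x = np.array(arms, dtype=float)  # distinct event times: Breslow = exact
    def neg_pl(beta):
        ll = 0.0
        for i in range(4):  # subjects ordered by event time; risk set = i..3
            ll += beta * x[i] - np.log(np.exp(beta * x[i:]).sum())
        return -ll

    grid = np.arange(-5, 5, 1e-4)
    beta_hat = grid[np.argmin([neg_pl(b) for b in grid])]
    assert est.estimate == pytest.approx(beta_hat, abs=1e-4)


def test_km_survival_matches_lifelines():
    """Greenwood product-limit estimate cross-checked against lifelines."""
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(5)
    times = rng.exponential(5.0, size=80)
    events = (rng.random(80) < 0.7).astype(int)
    s, var = km_survival_at(times, events, horizon=4.0)
    kmf = KaplanMeierFitter().fit(times, events)
    s_ll = float(kmf.survival_function_at_times(4.0).iloc[0])
    assert s == pytest.approx(s_ll, abs=1e-10)
    assert var > 0


def test_survival_probability_difference_sign_convention():
    # 4/5 treated die by t=0.5 (S1=0.2); 1/5 controls die at t=1.5 (S0=0.8)
    ds = _survival_dataset(
        times=[0.5] * 4 + [10.0] + [1.5] + [10.0] * 4,
        events=[1] * 4 + [0] + [1] + [0] * 4,
        arms=[1] * 5 + [0] * 5,
    )
    est = analyze(ds, AnalysisSpec("survival-prob-difference", "time", horizon=2.0))
    assert est.estimate == pytest.approx(-0.6)


def test_logistic_separation_is_fit_failure_not_crash():
    schema = TrialSchema(
        (
            VariableSpec("order", "continuous", "recruitment-index"),
            VariableSpec("arm", "binary", "treatment", levels=("0", "1")),
            VariableSpec("y", "binary", "outcome", levels=("0", "1")),
        )
    )
    df = pd.DataFrame(
        {"order": range(1, 21), "arm": ["0"] * 10 + ["1"] * 10, "y": ["0"] * 10 + ["1"] * 10}
    )
    ds = TrialDataset(schema, df)
    with pytest.raises(FitFailure):
        analyze(ds, AnalysisSpec("logistic", "y"))


def test_descriptive_mean_has_no_significance():
    ds = two_arm_dataset(control_y=[1, 2, 3], treated_y=[4, 5, 6])
    est = analyze(ds, AnalysisSpec("descriptive-mean", "y"))
    assert est.estimate == pytest.approx(3.5)
    assert est.significant is None


@pytest.mark.parametrize("family", ["mean-difference", "adjusted-linear", "logistic", "binary-robust", "cox"])
def test_wald_ci_reconstructs_from_estimate_and_se(family):
    """For every family, CI bounds equal estimate -+ z * se exactly."""
    if family in ("logistic", "binary-robust"):
        cfg = SimulationConfig(n=300, beta=0.6, seed=31, outcome_family="bernoulli-logit")
        spec = AnalysisSpec(family, "y")
    elif family == "cox":
        cfg = SimulationConfig(n=300, beta=0.6, seed=31, outcome_family="exponential-ph")
        spec = AnalysisSpec(family, "time")
    else:
        cfg = SimulationConfig(n=300, beta=0.6, seed=31)
        spec = AnalysisSpec(family, "y")
    est = analyze(simulate_trial(cfg), spec)
    z = stats.norm.ppf(0.975)
    assert est.ci_low == pytest.approx(est.estimate - z * est.se, rel=1e-12)
    assert est.ci_high == pytest.approx(est.estimate + z * est.se, rel=1e-12)


def test_estimator_recovers_true_effect_with_nominal_coverage():
    """Over 500 trials at n=1000: mean estimate near beta, 95% CI coverage in [92, 98]%."""
    beta, reps = 0.4, 500
    ests, covered = [], 0
    spec = AnalysisSpec("mean-difference", "y")
    for i in range(reps):
        ds = simulate_trial(SimulationConfig(n=1000, beta=beta, seed=9000 + i))
        est = analyze(ds, spec)
        ests.append(est.estimate)
        covered += est.ci_low <= beta <= est.ci_high
    mc_se = np.std(ests, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(ests) - beta) < 3 * mc_se
    assert 0.92 <= covered / reps <= 0.98


def test_interaction_requires_treatment_contrast():
    ds = two_arm_dataset(control_y=[1, 2, 3, 4], treated_y=[])
    with pytest.raises(ValueError, match="contrast"):
        interaction_test(ds, AnalysisSpec("mean-difference", "y"))


def test_interaction_estimates_drift_slope():
    """With drift delta, the interaction coefficient recovers delta."""
    cfg = SimulationConfig(n=4000, beta=0.3, delta=0.8, seed=77)
    est = interaction_test(simulate_trial(cfg), AnalysisSpec("mean-difference", "y"))
    assert est.estimate == pytest.approx(0.8, abs=3 * est.se)
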