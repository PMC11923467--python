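"""Replicability metrics and Hellinger fidelity, incl. published worked cells."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialrescue import (
    SimulationConfig,
    TrialDataset,
    ci_overlap,
    combined_from_wald,
    decision_agreement,
    estimate_agreement,
    fidelity_report,
    fit_bootstrap,
    hellinger_variable,
    simulate_trial,
    standardized_difference,
)
from trialrescue.estimation import EffectEstimate


def _pair(real_est, real_se, aug_est, aug_se, family="binary-robust"):
    real = EffectEstimate.from_wald(real_est, real_se, family)
    aug = combined_from_wald(aug_est, aug_se, family)
    return real, aug


def test_estimate_agreement_uses_real_ci_as_yardstick():
    real, aug = _pair(0.52, 0.25, 0.64, 0.28)
    assert real.ci_low == pytest.approx(0.03, abs=1e-3)
    assert real.ci_high == pytest.approx(1.01, abs=1e-3)
    assert estimate_agreement(real, aug) == 1
    # equal estimates always agree
    r2, a2 = _pair(0.52, 0.25, 0.52, 0.30)
    assert estimate_agreement(r2, a2) == 1
    # far-away estimate does not
    r3, a3 = _pair(0.52, 0.25, 1.50, 0.28)
    assert estimate_agreement(r3, a3) == 0


def test_estimate_agreement_is_asymmetric():
    """Swapping the roles can flip the verdict: the real CI is the reference."""
    wide = EffectEstimate.from_wald(0.0, 1.0)
    narrow = EffectEstimate.from_wald(3.0, 0.1)
    assert estimate_agreement(wide, combined_from_wald(3.0, 0.1)) == 0
    assert estimate_agreement(narrow, combined_from_wald(0.0, 1.0)) == 0
    inside = EffectEstimate.from_wald(1.0, 1.0)
    assert estimate_agreement(inside, combined_from_wald(1.5, 0.1)) == 1
    assert estimate_agreement(EffectEstimate.from_wald(1.5, 0.1), combined_from_wald(1.0, 1.0)) == 0


def test_decision_agreement_published_cells_and_descriptive_na():
    # both significant, same direction
    assert decision_agreement(*_pair(0.52, 0.25, 0.64, 0.28)) == 1
    # significant vs non-significant
    assert decision_agreement(*_pair(0.52, 0.25, 0.39, 0.36)) == 0
    # descriptive analyses have no decision
    assert decision_agreement(*_pair(58.98, 0.76, 58.07, 0.89, family="descriptive-mean")) is None


def test_decision_agreement_requires_matching_sign():
    # both non-significant but opposite directions
    assert decision_agreement(*_pair(0.3, 0.5, -0.3, 0.5)) == 0
    assert decision_agreement(*_pair(0.3, 0.5, 0.2, 0.5)) == 1


def test_standardized_difference_hand_arithmetic():
    z, ok = standardized_difference(*_pair(0.52, 0.25, 0.64, 0.28))
    assert z == pytest.approx(0.320, abs=1e-3)
    assert ok == 1
    z0, ok0 = standardized_difference(*_pair(0.5, 0.2, 0.5, 0.3))
    assert (z0, ok0) == (0.0, 1)
    z7, ok7 = standardized_difference(*_pair(0.0, 0.1, 1.0, 0.1))
    assert z7 == pytest.approx(7.07, abs=0.01)
    assert ok7 == 0


@pytest.mark.parametrize(
    "real_est, real_se, aug_est, aug_se, printed",
    [
        (0.52, 0.25, 0.64, 0.28, 0.88),   # smallest-trial binary endpoint, r=0.2
        (0.52, 0.25, 0.39, 0.36, 0.85),   # same trial, r=0.5
        (-0.036, 0.076, -0.034, 0.085, 0.95),  # large Cox trial, r=0.2
        (-1.85, 1.48, -3.46, 2.03, 0.79),  # linear-model trial, r=0.5
    ],
)
def test_ci_overlap_reproduces_published_cells(real_est, real_se, aug_est, aug_se, printed):
    """Two-way average overlap of printed (estimate, SE) pairs matches the
    published 2-dp cells to within one printed ulp (the source rounded from
    unrounded model output)."""
    real, aug = _pair(real_est, real_se, aug_est, aug_se)
    assert abs(round(ci_overlap(real, aug), 2) - printed) <= 0.01 + 1e-9


def test_ci_overlap_identity_and_disjoint():
    real, aug = _pair(0.5, 0.2, 0.5, 0.2)
    assert ci_overlap(real, aug) == pytest.approx(1.0)
    real, aug = _pair(0.0, 0.1, 5.0, 0.1)
    assert ci_overlap(real, aug) == 0.0


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    st.floats(-5, 5), st.floats(0.05, 3), st.floats(-5, 5), st.floats(0.05, 3)
)
def test_ci_overlap_symmetric_and_bounded(e1, s1, e2, s2):
    a = EffectEstimate.from_wald(e1, s1)
    b = EffectEstimate.from_wald(e2, s2)
    o1, o2 = ci_overlap(a, b), ci_overlap(b, a)
    assert o1 == pytest.approx(o2)
    assert 0.0 <= o1 <= 1.0


# -- Hellinger --------------------------------------------------------------


def test_hellinger_identity_disjoint_and_bernoulli():
    x = np.array(["a"] * 50 + ["b"] * 50)
    assert hellinger_variable(x, x.copy(), "categorical") == pytest.approx(0.0)
    assert hellinger_variable(["a"] * 10, ["b"] * 10, "categorical") == pytest.approx(1.0)
    # continuous identity and disjoint support
    z = np.linspace(0, 1, 100)
    assert hellinger_variable(z, z.copy(), "continuous") == pytest.approx(0.0)
    assert hellinger_variable(z, z + 100.0, "continuous") == pytest.approx(1.0)
    # Bernoulli p=0.5 vs q=0.9: H = sqrt(1 - (sqrt(.45) + sqrt(.05)))
    p = ["1"] * 50 + ["0"] * 50
    q = ["1"] * 90 + ["0"] * 10
    want = np.sqrt(1 - (np.sqrt(0.45) + np.sqrt(0.05)))
    assert hellinger_variable(p, q, "binary") == pytest.approx(want, abs=1e-12)


def test_fidelity_report_identity_and_single_replicate(small_trial):
    cols = small_trial.schema.synth_names
    copy = small_trial.data[cols].copy()
    rep = fidelity_report(small_trial, [copy, copy.copy()])
    assert rep.dataset_mean == 0.0
    assert all(v == 0.0 for v in rep.per_variable.values())
    single = fidelity_report(small_trial, [copy])
    assert single.replicate_mean == single.dataset_mean == single.per_replicate[0]


def test_fidelity_of_bootstrap_resamples_is_high(mixed_trial):
    """Same-size bootstrap resamples of n=2000 stay within H < 0.1 on average."""
    train = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:2000])
    model = fit_bootstrap(train)
    gens = [model.sample(2000, seed=i) for i in range(10)]
    rep = fidelity_report(train, gens)
    assert rep.dataset_mean < 0.1
    assert len(rep.per_replicate) == 10
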