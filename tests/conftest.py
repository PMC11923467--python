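"""Shared fixtures: tiny hand-built trials and a mixed-type simulated trial."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialrescue import (
    Covariate,
    SimulationConfig,
    StratumFactor,
    TrialDataset,
    TrialSchema,
    VariableSpec,
    simulate_trial,
)


def two_arm_dataset(control_y, treated_y) -> TrialDataset:
    """A minimal continuous-outcome trial from explicit per-arm outcome lists."""
    schema = TrialSchema(
        (
            VariableSpec("order", "continuous", "recruitment-index"),
            VariableSpec("arm", "binary", "treatment", levels=("control", "treated")),
            VariableSpec("y", "continuous", "outcome"),
        )
    )
    y = list(control_y) + list(treated_y)
    arm = ["control"] * len(control_y) + ["treated"] * len(treated_y)
    df = pd.DataFrame({"order": range(1, len(y) + 1), "arm": arm, "y": [float(v) for v in y]})
    return TrialDataset(schema, df)


@pytest.fixture(scope="session")
def mixed_trial() -> TrialDataset:
    """A 5-variable mixed-type stratified trial (n=5000) for generator tests."""
    cfg = SimulationConfig(
        n=5000,
        beta=0.6,
        seed=42,
        strata=(StratumFactor("site", ("A", "B", "C"), (0.5, 0.3, 0.2)),),
        covariates=(
            Covariate("age", "continuous", (60.0, 8.0), 0.02),
            Covariate("prior", "binary", (0.3,), 0.4),
        ),
    )
    return simulate_trial(cfg)


@pytest.fixture(scope="session")
def small_trial() -> TrialDataset:
    """A small (n=200) version of the same design for pipeline tests."""
    cfg = SimulationConfig(
        n=200,
        beta=0.5,
        seed=7,
        strata=(StratumFactor("site", ("A", "B"), (0.6, 0.4)),),
        covariates=(Covariate("age", "continuous", (60.0, 8.0), 0.01),),
    )
    return simulate_trial(cfg)
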