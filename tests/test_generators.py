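"""Contracts of the three synthesizers: bootstrap, sequential CART, Bayes net."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trialrescue import (
    SynthesisConfig,
    TrainingSizeError,
    TrialDataset,
    TrialSchema,
    VariableSpec,
    fit_bayes_net,
    fit_bootstrap,
    fit_sequential_trees,
    hellinger_variable,
    sample,
)
from trialrescue.bayesnet import arcs


def _binary_pair_dataset(a: np.ndarray, b: np.ndarray) -> TrialDataset:
    schema = TrialSchema(
        (
            VariableSpec("order", "continuous", "recruitment-index"),
            VariableSpec("a", "binary", "covariate", levels=("0", "1")),
            VariableSpec("b", "binary", "outcome", levels=("0", "1")),
        )
    )
    df = pd.DataFrame(
        {
            "order": np.arange(1, a.size + 1),
            "a": a.astype(int).astype(str),
            "b": b.astype(int).astype(str),
        }
    )
    return TrialDataset(schema, df)


# -- bootstrap --------------------------------------------------------------


def test_bootstrap_emits_only_training_rows(mixed_trial):
    model = fit_bootstrap(mixed_trial)
    assert model.training_n == mixed_trial.n
    out = model.sample(200, seed=1)
    train = mixed_trial.data[model.schema.synth_names]
    merged = out.merge(train.drop_duplicates(), how="left", indicator=True)
    assert (merged["_merge"] == "both").all()


def test_bootstrap_distinct_row_fraction_matches_theory(mixed_trial):
    """Resampling n of n rows touches ~1-(1-1/n)^n ~ 0.632 of distinct rows."""
    n = 1000
    train = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:n])
    model = fit_bootstrap(train)
    fracs = []
    for rep in range(50):
        out = model.sample(n, seed=rep)
        fracs.append(out.drop_duplicates().shape[0] / n)
    assert abs(np.mean(fracs) - (1 - (1 - 1 / n) ** n)) < 0.03


def test_bootstrap_requires_nonempty_training(mixed_trial):
    empty = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:0])
    with pytest.raises(TrainingSizeError):
        fit_bootstrap(empty)


# -- sequential trees -------------------------------------------------------


def test_sequential_trees_refuse_small_training(mixed_trial):
    small = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:49])
    with pytest.raises(TrainingSizeError, match="50"):
        fit_sequential_trees(small, SynthesisConfig(min_train=50))
    # one more record is admissible
    ok = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:50])
    fit_sequential_trees(ok, SynthesisConfig(min_train=50))


def test_sequential_trees_constant_column_stays_constant(mixed_trial):
    df = mixed_trial.data.iloc[:300].copy()
    df["prior"] = "1"
    train = TrialDataset(mixed_trial.schema, df)
    model = fit_sequential_trees(train, SynthesisConfig(seed=0))
    out = model.sample(500, seed=3)
    assert (out["prior"] == "1").all()


def test_sequential_trees_learn_perfect_binary_dependence():
    """If two binary columns are identical in training, generated pairs agree."""
    rng = np.random.default_rng(0)
    a = rng.random(500) < 0.5
    ds = _binary_pair_dataset(a, a.copy())
    model = fit_sequential_trees(ds, SynthesisConfig(min_leaf=5, seed=1))
    out = model.sample(10_000, seed=2)
    assert (out["a"] == out["b"]).mean() >= 0.99


def test_sequential_trees_match_marginal_frequencies():
    """Pure-noise binary column: generated frequency within 3 binomial SEs."""
    rng = np.random.default_rng(1)
    a = rng.random(2000) < 0.35
    b = rng.random(2000) < 0.5  # independent of a
    ds = _binary_pair_dataset(a, b)
    model = fit_sequential_trees(ds, SynthesisConfig(seed=0))
    out = model.sample(5000, seed=5)
    p_train = (ds.data["b"] == "1").mean()
    se = np.sqrt(p_train * (1 - p_train) * (1 / 5000 + 1 / 2000))
    assert abs((out["b"] == "1").mean() - p_train) < 3 * se


# -- Bayes net --------------------------------------------------------------


def test_bayes_net_leaves_independent_variables_unconnected():
    rng = np.random.default_rng(2)
    ds = _binary_pair_dataset(rng.random(5000) < 0.5, rng.random(5000) < 0.5)
    model = fit_bayes_net(ds, SynthesisConfig(seed=0))
    assert arcs(model) == set()


def test_bayes_net_connects_deterministic_copy():
    rng = np.random.default_rng(3)
    a = rng.random(5000) < 0.5
    ds = _binary_pair_dataset(a, a.copy())
    model = fit_bayes_net(ds, SynthesisConfig(seed=0))
    assert arcs(model) in ({("a", "b")}, {("b", "a")})


def test_bayes_net_sampling_respects_levels_and_training_range(mixed_trial):
    train = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:2000])
    model = fit_bayes_net(train, SynthesisConfig(seed=0))
    out = model.sample(1000, seed=9)
    for v in train.schema.variables:
        if v.role == "recruitment-index":
            continue
        if v.is_discrete:
            assert out[v.name].isin(v.levels).all()
        else:
            lo, hi = train.data[v.name].min(), train.data[v.name].max()
            assert out[v.name].between(lo, hi).all()


# -- shared contracts -------------------------------------------------------


@pytest.mark.parametrize("fit", [fit_bootstrap, fit_sequential_trees, fit_bayes_net])
def test_sampling_is_deterministic_given_seed(mixed_trial, fit):
    train = TrialDataset(mixed_trial.schema, mixed_trial.data.iloc[:1000])
    cfg = SynthesisConfig(seed=4)
    model = fit(train) if fit is fit_bootstrap else fit(train, cfg)
    a = sample(model, 300, seed=11)
    b = sample(model, 300, seed=11)
    pd.testing.assert_frame_equal(a, b)
    assert len(sample(model, 0, seed=1)) == 0
    with pytest.raises(ValueError):
        sample(model, -1, seed=1)


@pytest.mark.parametrize("fit", [fit_bootstrap, fit_sequential_trees, fit_bayes_net])
def test_generated_marginals_converge_to_training(mixed_trial, fit):
    """Per-variable Hellinger distance < 0.1 at k = n = 5000."""
    cfg = SynthesisConfig(seed=4)
    model = fit(mixed_trial) if fit is fit_bootstrap else fit(mixed_trial, cfg)
    out = model.sample(mixed_trial.n, seed=21)
    for v in mixed_trial.schema.variables:
        if v.role == "recruitment-index":
            continue
        h = hellinger_variable(mixed_trial.data[v.name], out[v.name], v.kind)
        assert h < 0.1, f"{v.name}: H={h:.3f}"
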