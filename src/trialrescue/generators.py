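"""Tabular synthesizers behind a single fit/sample contract.

Three generators are provided for rescuing an under-accrued trial:

``bootstrap``
    Sampling with replacement from the training records — the baseline.
``sequential-trees``
    Sequential CART synthesis: the first variable in the visit order is
    resampled from its empirical marginal; each later variable gets a
    classification/regression tree fitted on all preceding variables, and at
    sampling time a generated record is routed to a leaf and a value drawn
    uniformly from that leaf's pool of training values (no kernel
    smoothing).
``bayes-net``
    Discrete Bayesian network: continuous variables are quantile-binned,
    structure is found by hill climbing on a BIC score, conditional tables
    are Dirichlet-smoothed, and sampling is ancestral with continuous values
    back-transformed by a uniform draw from the sampled bin's training
    values. See :mod:`trialrescue.bayesnet`.

All three are deterministic given (training data, config, seed), never emit
a categorical level absent from training levels, and refuse to fit (where a
model is actually estimated) below ``min_train`` records — small-sample
synthesis is exactly where generative rescue is known to fail, so the
refusal is an explicit, catchable signal rather than a silent bad model.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from ._util import spawn_rng
from .schema import TrialDataset, TrialSchema

METHODS = ("bootstrap", "sequential-trees", "bayes-net")


class TrainingSizeError(ValueError):
    """Raised when a model-based synthesizer is asked to fit on too few records."""


@dataclass(frozen=True)
class SynthesisConfig:
    """Hyperparameters shared by the model-based synthesizers.

    min_leaf / max_depth control the CART chains; n_bins and dirichlet_alpha
    the Bayesian network; min_train (default 50) is the smallest admissible
    training set for any model-based method.
    """

    visit_order: tuple[str, ...] | None = None
    min_leaf: int = 5
    max_depth: int | None = None
    n_bins: int = 10
    dirichlet_alpha: float = 1.0
    seed: int = 0
    min_train: int = 50

    def __post_init__(self):
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.min_train < 2:
            raise ValueError("min_train must be >= 2")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be > 0")


@dataclass
class SynthesizerModel:
    """A fitted generative model with a uniform sample contract."""

    method: str
    schema: TrialSchema
    training_n: int
    state: Any

    def sample(self, k: int, seed: int = 0) -> pd.DataFrame:
        """Draw ``k`` complete synthetic records (schema columns minus the
        recruitment index). Deterministic given (model, k, seed)."""
        if k < 0:
            raise ValueError("k must be >= 0")
        cols = self.schema.synth_names
        if k == 0:
            return pd.DataFrame({c: [] for c in cols})
        if self.method == "bootstrap":
            out = _sample_bootstrap(self, k, seed)
        elif self.method == "sequential-trees":
            out = _sample_sequential(self, k, seed)
        elif self.method == "bayes-net":
            from .bayesnet import sample_bayes_net

            out = sample_bayes_net(self, k, seed)
        else:  # pragma: no cover
            raise ValueError(f"unknown method {self.method!r}")
        return out.loc[:, cols].reset_index(drop=True)


def sample(model: SynthesizerModel, k: int, seed: int = 0) -> pd.DataFrame:
    """Functional alias for :meth:`SynthesizerModel.sample`."""
    return model.sample(k, seed)


def default_visit_order(schema: TrialSchema) -> tuple[str, ...]:
    """Strata and treatment first, covariates next, outcomes last.

    Conditioning outcomes on design variables follows the causal direction
    of a randomized trial; the recruitment index is never synthesized.
    """
    by_role = {"stratum": [], "treatment": [], "covariate": [], "event-indicator": [], "outcome": []}
    for v in schema.variables:
        if v.role in by_role:
            by_role[v.role].append(v.name)
    return tuple(
        by_role["stratum"]
        + by_role["treatment"]
        + by_role["covariate"]
        + by_role["event-indicator"]
        + by_role["outcome"]
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def fit_bootstrap(train: TrialDataset) -> SynthesizerModel:
    """Store the training records verbatim; sampling resamples rows whole."""
    if train.n < 1:
        raise TrainingSizeError("bootstrap requires at least one training record")
    store = train.data.loc[:, train.schema.synth_names].reset_index(drop=True)
    return SynthesizerModel("bootstrap", train.schema, train.n, store)


def _sample_bootstrap(model: SynthesizerModel, k: int, seed: int) -> pd.DataFrame:
    rng = spawn_rng(seed, "bootstrap-sample")
    idx = rng.integers(0, model.training_n, size=k)
    return model.state.iloc[idx].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sequential CART synthesis
# ---------------------------------------------------------------------------


def _encode_column(values: pd.Series, spec) -> np.ndarray:
    if spec.is_discrete:
        lut = {lev: i for i, lev in enumerate(spec.levels)}
        return values.map(lut).to_numpy(dtype=float)
    return values.to_numpy(dtype=float)


@dataclass
class _TreeStage:
    var: str
    tree: object  # fitted sklearn tree
    pools: dict[int, np.ndarray]  # leaf id -> training target values


@dataclass
class _SequentialState:
    order: tuple[str, ...]
    first_pool: np.ndarray
    stages: list[_TreeStage]


def fit_sequential_trees(train: TrialDataset, cfg: SynthesisConfig) -> SynthesizerModel:
    """Fit the sequential decision-tree synthesizer.

    The first visit-order variable keeps its empirical marginal. Each later
    variable ``v`` gets a CART fitted on all variables before it; per leaf,
    the training values of ``v`` falling in that leaf form the donor pool
    sampled from at generation time.
    """
    if train.n < cfg.min_train:
        raise TrainingSizeError(
            f"sequential-trees refuses to train on {train.n} records: "
            f"minimum admissible training size is {cfg.min_train}"
        )
    schema = train.schema
    order = cfg.visit_order or default_visit_order(schema)
    df = train.data
    enc = {name: _encode_column(df[name], schema.get(name)) for name in order}

    stages: list[_TreeStage] = []
    for j, var in enumerate(order[1:], start=1):
        X = np.column_stack([enc[p] for p in order[:j]])
        spec = schema.get(var)
        y_raw = df[var].to_numpy()
        if spec.is_discrete:
            tree = DecisionTreeClassifier(
                min_samples_leaf=cfg.min_leaf,
                max_depth=cfg.max_depth,
                random_state=cfg.seed,
            )
        else:
            tree = DecisionTreeRegressor(
                min_samples_leaf=cfg.min_leaf,
                max_depth=cfg.max_depth,
                random_state=cfg.seed,
            )
        tree.fit(X, enc[var] if spec.is_discrete else y_raw.astype(float))
        leaves = tree.apply(X)
        pools = {int(l): y_raw[leaves == l] for l in np.unique(leaves)}
        stages.append(_TreeStage(var, tree, pools))

    state = _SequentialState(tuple(order), df[order[0]].to_numpy(), stages)
    return SynthesizerModel("sequential-trees", schema, train.n, state)


def _sample_sequential(model: SynthesizerModel, k: int, seed: int) -> pd.DataFrame:
    st: _SequentialState = model.state
    schema = model.schema
    rng = spawn_rng(seed, "seq-sample")
    out: dict[str, np.ndarray] = {}
    out[st.order[0]] = rng.choice(st.first_pool, size=k, replace=True)
    enc_cols = [_encode_column(pd.Series(out[st.order[0]]), schema.get(st.order[0]))]
    for stage in st.stages:
        X = np.column_stack(enc_cols)
        leaves = stage.tree.apply(X)
        vals = np.empty(k, dtype=object)
        for leaf in np.unique(leaves):
            rows = np.flatnonzero(leaves == leaf)
            pool = stage.pools[int(leaf)]
            vals[rows] = rng.choice(pool, size=rows.size, replace=True)
        spec = schema.get(stage.var)
        col = vals if spec.is_discrete else vals.astype(float)
        out[stage.var] = col
        enc_cols.append(_encode_column(pd.Series(col), spec))
    df = pd.DataFrame(out)
    for v in schema.variables:
        if v.name in df.columns and v.is_discrete:
            df[v.name] = df[v.name].astype(str)
    return df


__all__ = [
    "SynthesisConfig",
    "SynthesizerModel",
    "TrainingSizeError",
    "fit_bootstrap",
    "fit_sequential_trees",
    "sample",
    "default_visit_order",
    "METHODS",
]
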