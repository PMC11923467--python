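"""Synthetic two-arm trial generator with known ground-truth effects.

The real oncology trial datasets this pipeline was designed around are
access-restricted, so every downstream stage is exercised against simulated
trials whose structure mirrors theirs: two arms with a stated allocation
ratio, optional stratification factors, mixed-type covariates, and a
continuous, binary, or time-to-event endpoint with a known treatment effect
``beta``. An optional ``delta`` adds a linear drift of the effect over
normalized recruitment order, the monotone-effect alternative against which
the recruitment-order interaction test is calibrated.

Design choices
--------------
* Arms are assigned by *stratified randomization with exact quotas*: within
  each realized stratum combination the treated count is the
  largest-remainder integerization of ``p_treat``, and treated positions are
  a random permutation. This mirrors stratified block randomization and
  makes quota checks deterministic.
* Patient ``i`` (recruitment order 1..n) has linear predictor
  ``intercept + sum(coef_j * x_ij) + (beta + delta * i/n) * treat_i``.
* Time-to-event outcomes are exponential proportional-hazards with
  independent exponential censoring.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

from ._util import largest_remainder
from .schema import TrialDataset, TrialSchema, VariableSpec

OUTCOME_FAMILIES = ("gaussian", "bernoulli-logit", "exponential-ph")


@dataclass(frozen=True)
class StratumFactor:
    """A stratification factor: levels drawn iid with the given probabilities."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]

    def __post_init__(self):
        if len(self.levels) != len(self.probs) or len(self.levels) < 2:
            raise ValueError(f"stratum {self.name!r}: levels/probs mismatch")
        if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
            raise ValueError(f"stratum {self.name!r}: probabilities must sum to 1")


@dataclass(frozen=True)
class Covariate:
    """A baseline covariate.

    kind ``continuous`` draws Normal(params[0], params[1]); kind ``binary``
    draws Bernoulli(params[0]) with levels ("0", "1"). ``coefficient`` enters
    the outcome linear predictor (binary covariates contribute
    coefficient * 1{level == "1"}).
    """

    name: str
    kind: str
    params: tuple[float, ...]
    coefficient: float = 0.0

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"covariate {self.name!r}: unsupported kind {self.kind!r}")
        if self.kind == "continuous" and (len(self.params) != 2 or self.params[1] <= 0):
            raise ValueError(f"covariate {self.name!r}: needs (mean, sd > 0)")
        if self.kind == "binary" and not (len(self.params) == 1 and 0 < self.params[0] < 1):
            raise ValueError(f"covariate {self.name!r}: needs (p,) with 0 < p < 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated trial design."""

    n: int
    beta: float = 0.0
    p_treat: float = 0.5
    strata: tuple[StratumFactor, ...] = ()
    covariates: tuple[Covariate, ...] = ()
    outcome_family: str = "gaussian"
    sd: float = 1.0
    baseline_rate: float = 0.1
    censoring_rate: float = 0.02
    intercept: float = 0.0
    delta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0 < self.p_treat < 1:
            raise ValueError("p_treat must be in (0, 1)")
        if self.outcome_family not in OUTCOME_FAMILIES:
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")
        if self.sd <= 0 or self.baseline_rate <= 0 or self.censoring_rate <= 0:
            raise ValueError("sd and rates must be > 0")

    # -- serialization (structured-text config dialect) ---------------------

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "beta": self.beta,
            "p_treat": self.p_treat,
            "outcome_family": self.outcome_family,
            "sd": self.sd,
            "baseline_rate": self.baseline_rate,
            "censoring_rate": self.censoring_rate,
            "intercept": self.intercept,
            "delta": self.delta,
            "seed": self.seed,
            "strata": [
                {"name": s.name, "levels": list(s.levels), "probs": list(s.probs)}
                for s in self.strata
            ],
            "covariates": [
                {
                    "name": c.name,
                    "kind": c.kind,
                    "params": list(c.params),
                    "coefficient": c.coefficient,
                }
                for c in self.covariates
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            n=int(d["n"]),
            beta=float(d.get("beta", 0.0)),
            p_treat=float(d.get("p_treat", 0.5)),
            strata=tuple(
                StratumFactor(s["name"], tuple(map(str, s["levels"])), tuple(map(float, s["probs"])))
                for s in d.get("strata", [])
            ),
            covariates=tuple(
                Covariate(c["name"], c["kind"], tuple(map(float, c["params"])), float(c.get("coefficient", 0.0)))
                for c in d.get("covariates", [])
            ),
            outcome_family=d.get("outcome_family", "gaussian"),
            sd=float(d.get("sd", 1.0)),
            baseline_rate=float(d.get("baseline_rate", 0.1)),
            censoring_rate=float(d.get("censoring_rate", 0.02)),
            intercept=float(d.get("intercept", 0.0)),
            delta=float(d.get("delta", 0.0)),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_schema(cfg: SimulationConfig) -> TrialSchema:
    """The TrialSchema a simulated trial conforms to."""
    specs: list[VariableSpec] = [VariableSpec("order", "continuous", "recruitment-index")]
    for s in cfg.strata:
        specs.append(VariableSpec(s.name, "categorical", "stratum", levels=s.levels))
    specs.append(VariableSpec("arm", "binary", "treatment", levels=("control", "treated")))
    for c in cfg.covariates:
        if c.kind == "binary":
            specs.append(VariableSpec(c.name, "binary", "covariate", levels=("0", "1")))
        else:
            specs.append(VariableSpec(c.name, "continuous", "covariate"))
    if cfg.outcome_family == "exponential-ph":
        specs.append(VariableSpec("event", "binary", "event-indicator", levels=("0", "1")))
        specs.append(VariableSpec("time", "event-time", "outcome", event_indicator="event"))
    else:
        kind = "continuous" if cfg.outcome_family == "gaussian" else "binary"
        levels = ("0", "1") if kind == "binary" else None
        specs.append(VariableSpec("y", kind, "outcome", levels=levels))
    return TrialSchema(tuple(specs))


def _assign_arms(stratum_key: pd.Series, n: int, p_treat: float, rng) -> np.ndarray:
    """Exact per-stratum quotas with largest-remainder rounding."""
    treat = np.zeros(n, dtype=int)
    for _, idx in stratum_key.groupby(stratum_key, sort=True).groups.items():
        pos = np.asarray(idx)
        g = pos.size
        n_treat = int(largest_remainder([1.0 - p_treat, p_treat], g)[1])
        chosen = rng.permutation(g)[:n_treat]
        treat[pos[chosen]] = 1
    return treat


def simulate_trial(cfg: SimulationConfig) -> TrialDataset:
    """Draw one trial from the configured design.

    Reproducible: identical config (including ``seed``) yields an identical
    dataset. Records carry recruitment index 1..n.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    cols: dict[str, object] = {"order": np.arange(1, n + 1)}

    strat_cols = {}
    for s in cfg.strata:
        draws = rng.choice(len(s.levels), size=n, p=np.asarray(s.probs))
        strat_cols[s.name] = pd.Series([s.levels[i] for i in draws], dtype=str)
    cols.update(strat_cols)

    if strat_cols:
        key = pd.Series(["|".join(t) for t in zip(*strat_cols.values())])
    else:
        key = pd.Series(["" for _ in range(n)])
    treat = _assign_arms(key, n, cfg.p_treat, rng)
    cols["arm"] = np.where(treat == 1, "treated", "control")

    lp = np.full(n, float(cfg.intercept))
    for c in cfg.covariates:
        if c.kind == "continuous":
            x = rng.normal(c.params[0], c.params[1], size=n)
            cols[c.name] = x
            lp += c.coefficient * x
        else:
            x = (rng.random(n) < c.params[0]).astype(int)
            cols[c.name] = np.char.mod("%d", x)
            lp += c.coefficient * x

    order_norm = np.arange(1, n + 1) / n
    lp = lp + (cfg.beta + cfg.delta * order_norm) * treat

    if cfg.outcome_family == "gaussian":
        cols["y"] = lp + rng.normal(0.0, cfg.sd, size=n)
    elif cfg.outcome_family == "bernoulli-logit":
        y = (rng.random(n) < expit(lp)).astype(int)
        cols["y"] = np.char.mod("%d", y)
    else:  # exponential proportional hazards with independent censoring
        rate = cfg.baseline_rate * np.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=n)
        cols["time"] = np.minimum(t_event, t_cens)
        cols["event"] = np.char.mod("%d", (t_event <= t_cens).astype(int))

    schema = build_schema(cfg)
    df = pd.DataFrame(cols)
    for v in schema.variables:
        if v.is_discrete:
            df[v.name] = df[v.name].astype(str)
    return TrialDataset(schema, df)


def required_n_per_arm(
    beta: float, sd: float = 1.0, power: float = 0.8, alpha: float = 0.05
) -> int:
    """Smallest per-arm n giving the target power for a two-sample z test.

    n = ceil( 2 * sd^2 * (z_{1-alpha/2} + z_{power})^2 / beta^2 ).
    """
    if beta == 0:
        raise ValueError("beta must be nonzero")
    if not 0 < power < 1:
        raise ValueError("power must be in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return int(np.ceil(2 * sd**2 * z**2 / beta**2))


__all__ = [
    "SimulationConfig",
    "StratumFactor",
    "Covariate",
    "simulate_trial",
    "build_schema",
    "required_n_per_arm",
    "OUTCOME_FAMILIES",
]
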