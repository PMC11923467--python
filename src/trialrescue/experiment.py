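"""Configuration-driven rescue experiments: the r-sweep and simulation study.

``run_sweep`` reproduces the full rescue workflow on one dataset: for every
(generator, r) cell it reduces accrual, trains the generator on the reduced
records, fills the missing patients under stratum-by-arm quotas, analyzes
each of the m augmented replicates with the published-style analysis, pools
them with the partial-synthesis combining rules, and scores the four
replicability criteria against the full-data result plus Hellinger
fidelity. Generator refusals (e.g. too few training records) become
*failure rows*, not crashes, and are excluded from any aggregate
denominator.

``run_simulation_study`` repeats simulate -> sweep over many trial draws
and aggregates per-cell metric rates with Monte-Carlo standard errors —
the harness used to check the pipeline's operating characteristics
(decision-agreement rate at the design power, combined-CI coverage of the
true effect, ...).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import child_seed
from .augment import QuotaError, augment, derive_quotas, reduce_by_accrual
from .combining import combine, combined_from_wald
from .estimation import FitFailure, analyze
from .evaluation import fidelity_report, replicability
from .generators import (
    SynthesisConfig,
    TrainingSizeError,
    fit_bootstrap,
    fit_sequential_trees,
)
from .schema import AnalysisSpec, TrialDataset
from .simulate import SimulationConfig, simulate_trial

DEFAULT_R_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)


def _fit(method: str, train: TrialDataset, scfg: SynthesisConfig):
    if method == "bootstrap":
        return fit_bootstrap(train)
    if method == "sequential-trees":
        return fit_sequential_trees(train, scfg)
    if method == "bayes-net":
        from .bayesnet import fit_bayes_net

        return fit_bayes_net(train, scfg)
    raise ValueError(f"unknown generator {method!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """One r-sweep: which generators, which r values, how many replicates."""

    analysis: AnalysisSpec
    r_grid: tuple[float, ...] = DEFAULT_R_GRID
    generators: tuple[str, ...] = ("bootstrap", "sequential-trees", "bayes-net")
    m: int = 10
    seed: int = 0
    fidelity_bins: int = 10
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    max_factor: int = 1000

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if any(not 0 < r <= 0.5 for r in self.r_grid):
            raise ValueError("r_grid values must lie in (0, 0.5]")


def _metric_row(base: dict, real, aug, fidelity=None) -> dict:
    rep = replicability(real, aug)
    row = dict(base)
    row.update(
        status="ok",
        reason="",
        q=aug.q_bar,
        se=float(np.sqrt(aug.T)),
        ci_low=aug.ci_low,
        ci_high=aug.ci_high,
        estimate_agreement=rep.estimate_agreement,
        decision_agreement=rep.decision_agreement,
        std_diff_z=rep.std_diff_z,
        std_diff_ok=rep.std_diff_ok,
        ci_overlap=rep.ci_overlap,
        fidelity_mean=fidelity.dataset_mean if fidelity is not None else np.nan,
    )
    return row


def run_sweep(ds: TrialDataset, cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the full rescue sweep on one dataset.

    Returns a tidy table with a ``full`` baseline row, a ``reduced``
    (no-augmentation) baseline row per r, and one row per (generator, r).
    Deterministic given (dataset, config, seed).
    """
    real = analyze(ds, cfg.analysis)
    rows: list[dict] = [
        dict(
            generator="full",
            r=0.0,
            n=ds.n,
            status="ok",
            reason="",
            q=real.estimate,
            se=real.se,
            ci_low=real.ci_low,
            ci_high=real.ci_high,
        )
    ]
    for r in cfg.r_grid:
        reduced, scen = reduce_by_accrual(ds, r)
        base = dict(generator="reduced", r=r, n=reduced.n)
        try:
            red_est = analyze(reduced, cfg.analysis)
            rows.append(_metric_row(base, real, combined_from_wald(red_est.estimate, red_est.se, red_est.family, red_est.alpha)))
        except (FitFailure, ValueError) as e:
            rows.append(dict(base, status="failed", reason=str(e)))
            red_est = None
        quotas = derive_quotas(reduced, scen.n_removed)
        for gen in cfg.generators:
            base = dict(generator=gen, r=r, n=ds.n)
            cell_seed = child_seed(cfg.seed, gen, round(r, 6))
            try:
                model = _fit(gen, reduced, cfg.synthesis)
                reps = augment(reduced, model, quotas, m=cfg.m, seed=cell_seed, max_factor=cfg.max_factor)
                ests = [analyze(rep, cfg.analysis) for rep in reps]
                pooled = combine(ests, alpha=cfg.analysis.alpha)
                chunks = [rep.data.iloc[reduced.n :] for rep in reps]
                fid = (
                    fidelity_report(reduced, chunks, n_bins=cfg.fidelity_bins)
                    if scen.n_removed > 0
                    else None
                )
                rows.append(_metric_row(base, real, pooled, fid))
            except (TrainingSizeError, QuotaError, FitFailure) as e:
                rows.append(dict(base, status="failed", reason=str(e)))
    df = pd.DataFrame(rows)
    return df


def write_report(df: pd.DataFrame, cfg: ExperimentConfig, out_dir: str | Path) -> None:
    """CSV report plus a JSON manifest echoing the configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "sweep.csv", index=False)
    manifest = {
        "r_grid": list(cfg.r_grid),
        "generators": list(cfg.generators),
        "m": cfg.m,
        "seed": cfg.seed,
        "analysis": {
            "family": cfg.analysis.family,
            "outcome": cfg.analysis.outcome,
            "covariates": list(cfg.analysis.covariates),
            "horizon": cfg.analysis.horizon,
            "alpha": cfg.analysis.alpha,
        },
        "failures": df.loc[df["status"] == "failed", ["generator", "r", "reason"]].to_dict(
            "records"
        ),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_simulation_study(
    sim: SimulationConfig, cfg: ExperimentConfig, n_reps: int
) -> pd.DataFrame:
    """Repeat simulate -> rescue over ``n_reps`` trial draws; aggregate rates.

    Per (generator, r) cell, reports the rate of each Boolean criterion with
    its binomial Monte-Carlo SE, the mean CI overlap, the coverage of the
    true simulated effect by the combined CI, and the failure count. Model
    failures are excluded from every denominator.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    records: list[dict] = []
    for rep in range(n_reps):
        sim_rep = SimulationConfig.from_dict({**sim.to_dict(), "seed": child_seed(cfg.seed, "sim", rep)})
        ds = simulate_trial(sim_rep)
        try:
            real = analyze(ds, cfg.analysis)
        except (FitFailure, ValueError):
            continue
        for r in cfg.r_grid:
            reduced, scen = reduce_by_accrual(ds, r)
            quotas = derive_quotas(reduced, scen.n_removed)
            for gen in cfg.generators:
                cell_seed = child_seed(cfg.seed, "study", rep, gen, round(r, 6))
                rec = dict(generator=gen, r=r, rep=rep)
                try:
                    model = _fit(gen, reduced, cfg.synthesis)
                    reps_ds = augment(
                        reduced, model, quotas, m=cfg.m, seed=cell_seed, max_factor=cfg.max_factor
                    )
                    pooled = combine(
                        [analyze(a, cfg.analysis) for a in reps_ds], alpha=cfg.analysis.alpha
                    )
                    met = replicability(real, pooled)
                    rec.update(
                        failed=0,
                        estimate_agreement=met.estimate_agreement,
                        decision_agreement=met.decision_agreement,
                        std_diff_ok=met.std_diff_ok,
                        ci_overlap=met.ci_overlap,
                        covered=int(pooled.ci_low <= sim.beta <= pooled.ci_high),
                    )
                except (TrainingSizeError, QuotaError, FitFailure) as e:
                    rec.update(failed=1, reason=str(e))
                records.append(rec)
    raw = pd.DataFrame(records)
    rows = []
    for (gen, r), grp in raw.groupby(["generator", "r"], sort=True):
        ok = grp[grp["failed"] == 0]
        row = dict(generator=gen, r=r, n_ok=len(ok), n_fail=int(grp["failed"].sum()))
        for metric in ("estimate_agreement", "decision_agreement", "std_diff_ok", "covered"):
            vals = ok[metric].dropna() if metric in ok else pd.Series(dtype=float)
            if len(vals):
                p = float(vals.mean())
                row[f"{metric}_rate"] = p
                row[f"{metric}_mc_se"] = float(np.sqrt(p * (1 - p) / len(vals)))
            else:
                row[f"{metric}_rate"] = np.nan
                row[f"{metric}_mc_se"] = np.nan
        row["ci_overlap_mean"] = float(ok["ci_overlap"].mean()) if len(ok) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "ExperimentConfig",
    "run_sweep",
    "run_simulation_study",
    "write_report",
    "DEFAULT_R_GRID",
]
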