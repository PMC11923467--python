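"""Accrual reduction, stratum-by-arm quotas, rejection-sampling fill,
and assembly of the m augmented replicates.

The rescue scenario removes the last-recruited fraction ``r`` of patients
(k = round(r*N), half-up), trains a synthesizer on the remaining (1-r)*N,
and refills the k missing patients so that the stratum-by-arm composition
of the augmented dataset matches target proportions. Candidate synthetic
records are drawn from the generator and *rejected* unless their
stratum-by-arm cell still has unmet quota; the fill therefore matches the
quota table exactly. Repeating the fill m times (m >= 2; default 10
downstream) yields the augmented replicates the partial-synthesis combining
rules pool.

By default quota proportions come from the reduced dataset itself — the
only data guaranteed to exist in a real rescue — but a design-target
reference dataset can be supplied instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import child_seed, largest_remainder, spawn_rng
from .generators import SynthesizerModel
from .schema import TrialDataset, TrialSchema


class QuotaError(RuntimeError):
    """A quota cell cannot be filled by the generator (starvation)."""


@dataclass(frozen=True)
class AccrualScenario:
    """Bookkeeping for one reduction: N, k = round(r*N) and N-k."""

    r: float
    n_original: int
    n_removed: int
    n_reduced: int


@dataclass(frozen=True)
class QuotaTable:
    """Required synthetic-record count per stratum-by-arm cell."""

    cells: dict[tuple, int]
    total: int

    def __post_init__(self):
        if any(c < 0 for c in self.cells.values()):
            raise ValueError("quota counts must be >= 0")
        if sum(self.cells.values()) != self.total:
            raise ValueError("quota cells must sum to the total")


def cell_columns(schema: TrialSchema) -> list[str]:
    """Columns defining the quota cells: strata then arm; may be empty."""
    cols = list(schema.strata_names)
    if schema.arm_name is not None:
        cols.append(schema.arm_name)
    return cols


def _cell_keys(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    if not cols:
        return pd.Series([("all",)] * len(df), index=df.index)
    return pd.Series(list(zip(*(df[c].astype(str) for c in cols))), index=df.index)


def reduce_by_accrual(ds: TrialDataset, r: float) -> tuple[TrialDataset, AccrualScenario]:
    """Drop the last-recruited k = round(r*N) patients (half-up rounding).

    The dataset must be accrual-sorted; the retained records keep their
    order, and every retained recruitment index precedes every removed one.
    """
    if not 0 <= r <= 0.5:
        raise ValueError("r must be in [0, 0.5]")
    n = ds.n
    k = int(math.floor(r * n + 0.5))
    if n - k < 1:
        raise ValueError("reduction would leave an empty dataset")
    reduced = TrialDataset(ds.schema, ds.data.iloc[: n - k])
    return reduced, AccrualScenario(r=r, n_original=n, n_removed=k, n_reduced=n - k)


def derive_quotas(reference: TrialDataset, k: int) -> QuotaTable:
    """Allocate k synthetic records across observed stratum-by-arm cells.

    Proportional to the reference dataset's cell frequencies, integerized by
    the largest-remainder rule. Unstratified schemas collapse to arm-only
    cells; schemas with no arm to a single cell.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if reference.n == 0:
        raise ValueError("reference dataset is empty")
    cols = cell_columns(reference.schema)
    keys = _cell_keys(reference.data, cols)
    counts = keys.value_counts().sort_index()
    alloc = largest_remainder(counts.to_numpy(), k)
    return QuotaTable(dict(zip(counts.index, (int(a) for a in alloc))), k)


def rejection_fill(
    model: SynthesizerModel,
    quotas: QuotaTable,
    seed: int = 0,
    max_factor: int = 1000,
) -> pd.DataFrame:
    """Draw from the generator, keeping only records whose cell is unfilled.

    Returns exactly ``quotas.total`` records whose stratum-by-arm cell
    counts equal the quota table. If more than ``max_factor * total``
    candidates are drawn before the quotas fill, raises :class:`QuotaError`
    naming a starving cell (a cell the generator evidently cannot reach).
    """
    k = quotas.total
    cols = cell_columns(model.schema)
    if k == 0:
        return pd.DataFrame({c: [] for c in model.schema.synth_names})
    need = {cell: cnt for cell, cnt in quotas.cells.items() if cnt > 0}
    accepted: list[pd.DataFrame] = []
    drawn = 0
    batch_no = 0
    remaining = k
    while remaining > 0:
        batch = max(64, 2 * remaining)
        if drawn + batch > max_factor * k:
            batch = max_factor * k - drawn
            if batch <= 0:
                starving = min(cell for cell, cnt in need.items() if cnt > 0)
                raise QuotaError(
                    f"quota cell {starving!r} still needs {need[starving]} record(s) "
                    f"after {drawn} draws (max_factor={max_factor})"
                )
        cand = model.sample(batch, seed=child_seed(seed, "fill-batch", batch_no))
        batch_no += 1
        drawn += batch
        keys = _cell_keys(cand, cols)
        take = np.zeros(len(cand), dtype=bool)
        for i, cell in enumerate(keys):
            cnt = need.get(cell, 0)
            if cnt > 0:
                need[cell] = cnt - 1
                take[i] = True
        if take.any():
            accepted.append(cand.loc[take])
            remaining = sum(need.values())
    out = pd.concat(accepted, ignore_index=True) if accepted else pd.DataFrame()
    return out.iloc[:k].reset_index(drop=True)


def augment(
    reduced: TrialDataset,
    model: SynthesizerModel,
    quotas: QuotaTable,
    m: int = 10,
    seed: int = 0,
    max_factor: int = 1000,
) -> list[TrialDataset]:
    """Build the m augmented replicates: reduced records + a fresh fill each.

    Every replicate has n = n_reduced + quota total; the real records are a
    common prefix and only the generated tail differs. Replicate seeds are
    derived deterministically from the master seed, so the whole list
    replays bitwise given the same inputs.
    """
    if m < 2:
        raise ValueError("m must be >= 2 (combining rules are undefined for m < 2)")
    schema = reduced.schema
    idx_name = schema.index_name
    start = int(reduced.data[idx_name].max()) if reduced.n else 0
    out = []
    for i in range(m):
        fill = rejection_fill(model, quotas, seed=child_seed(seed, "replicate", i), max_factor=max_factor)
        fill = fill.copy()
        fill[idx_name] = np.arange(start + 1, start + 1 + len(fill))
        combined = pd.concat([reduced.data, fill], ignore_index=True)
        out.append(TrialDataset(schema, combined))
    return out


__all__ = [
    "AccrualScenario",
    "QuotaTable",
    "QuotaError",
    "reduce_by_accrual",
    "derive_quotas",
    "rejection_fill",
    "augment",
    "cell_columns",
]
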