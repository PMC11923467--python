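"""Discrete Bayesian-network synthesizer.

Continuous (and event-time) variables are quantile-discretized into at most
``n_bins`` states; categorical/binary variables keep their declared levels.
Structure is learned by greedy hill climbing over single-arc add / remove /
reverse moves on a BIC-penalized log-likelihood (a decomposable score, so
each move re-evaluates at most two family scores), starting from the empty
graph and stopping when no move improves the score. Conditional probability
tables are the posterior mean under a symmetric Dirichlet(alpha) prior,
i.e. pseudo-count smoothing, so every parent configuration has a proper
distribution even if unobserved.

Sampling is ancestral: roots from their (smoothed) marginals, children from
the CPT row selected by their sampled parents. A sampled bin of a
continuous variable is back-transformed by a uniform draw from the training
values that fell in that bin, so generated continuous values always lie
within the training range of their bin.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from ._util import spawn_rng
from .generators import SynthesisConfig, SynthesizerModel, TrainingSizeError
from .schema import TrialDataset, TrialSchema


@dataclass
class _Node:
    name: str
    n_states: int
    levels: tuple[str, ...] | None  # discrete variables: original labels
    bin_pools: list[np.ndarray] | None  # continuous: training values per bin


@dataclass
class _BayesNetState:
    nodes: dict[str, _Node]
    order: tuple[str, ...]  # topological order of the DAG
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]  # shape (prod(parent cards), n_states)


def _discretize(train: TrialDataset, names, n_bins):
    """Return (state-index DataFrame, node metadata)."""
    schema = train.schema
    disc = {}
    nodes: dict[str, _Node] = {}
    for name in names:
        spec = schema.get(name)
        col = train.data[name]
        if spec.is_discrete:
            lut = {lev: i for i, lev in enumerate(spec.levels)}
            disc[name] = col.map(lut).to_numpy(dtype=int)
            nodes[name] = _Node(name, len(spec.levels), spec.levels, None)
        else:
            x = col.to_numpy(dtype=float)
            qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
            edges = np.unique(qs)
            if edges.size < 2:  # constant column: a single state
                states = np.zeros(x.size, dtype=int)
                pools = [x.copy()]
            else:
                inner = edges[1:-1]
                states = np.searchsorted(inner, x, side="right")
                pools = [x[states == b] for b in range(edges.size - 1)]
                # guard: every bin that can be sampled must have donors
                pools = [p if p.size else x for p in pools]
            disc[name] = states
            nodes[name] = _Node(name, len(pools), None, pools)
    return pd.DataFrame(disc), nodes


def _local_bic(disc: pd.DataFrame, var: str, parents: tuple[str, ...], cards) -> float:
    """BIC family score: max log-likelihood minus 0.5*ln(n)*free params."""
    n = len(disc)
    r = cards[var]
    if parents:
        q = int(np.prod([cards[p] for p in parents]))
        tab = pd.crosstab(
            [disc[p] for p in parents] if len(parents) > 1 else disc[parents[0]],
            disc[var],
        ).to_numpy()
    else:
        q = 1
        tab = disc[var].value_counts().to_numpy()[None, :]
    row = tab.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(tab > 0, tab * np.log(tab / row), 0.0).sum()
    return float(ll - 0.5 * np.log(n) * (r - 1) * q)


def _hill_climb(disc: pd.DataFrame, cards: dict[str, int]) -> nx.DiGraph:
    names = list(disc.columns)
    g = nx.DiGraph()
    g.add_nodes_from(names)
    cache: dict[tuple, float] = {}

    def score(var, parents) -> float:
        key = (var, tuple(sorted(parents)))
        if key not in cache:
            cache[key] = _local_bic(disc, var, tuple(sorted(parents)), cards)
        return cache[key]

    current = {v: score(v, ()) for v in names}
    while True:
        best_gain, best_apply = 1e-9, None
        for a in names:
            for b in names:
                if a == b:
                    continue
                pa_b = tuple(g.predecessors(b))
                if g.has_edge(a, b):
                    # removal
                    new_b = tuple(p for p in pa_b if p != a)
                    gain = score(b, new_b) - current[b]
                    if gain > best_gain:
                        best_gain, best_apply = gain, ("del", a, b)
                    # reversal: remove a->b, add b->a
                    if not _would_cycle(g, b, a, ignore=(a, b)):
                        pa_a = tuple(g.predecessors(a))
                        gain = (
                            score(b, new_b)
                            - current[b]
                            + score(a, pa_a + (b,))
                            - current[a]
                        )
                        if gain > best_gain:
                            best_gain, best_apply = gain, ("rev", a, b)
                elif not g.has_edge(b, a):
                    # addition
                    if not _would_cycle(g, a, b):
                        gain = score(b, pa_b + (a,)) - current[b]
                        if gain > best_gain:
                            best_gain, best_apply = gain, ("add", a, b)
        if best_apply is None:
            return g
        op, a, b = best_apply
        if op == "add":
            g.add_edge(a, b)
        elif op == "del":
            g.remove_edge(a, b)
        else:
            g.remove_edge(a, b)
            g.add_edge(b, a)
        current[b] = score(b, tuple(g.predecessors(b)))
        current[a] = score(a, tuple(g.predecessors(a)))


def _would_cycle(g: nx.DiGraph, a: str, b: str, ignore=None) -> bool:
    """Would adding a->b (optionally ignoring existing edge ``ignore``) cycle?"""
    h = g.copy()
    if ignore is not None and h.has_edge(*ignore):
        h.remove_edge(*ignore)
    h.add_edge(a, b)
    return not nx.is_directed_acyclic_graph(h)


def _fit_cpts(disc, g, cards, alpha):
    cpts = {}
    for var in disc.columns:
        parents = tuple(sorted(g.predecessors(var)))
        r = cards[var]
        if parents:
            pcards = [cards[p] for p in parents]
            q = int(np.prod(pcards))
            counts = np.zeros((q, r))
            # mixed-radix parent configuration index
            idx = np.zeros(len(disc), dtype=int)
            for p, c in zip(parents, pcards):
                idx = idx * c + disc[p].to_numpy()
            np.add.at(counts, (idx, disc[var].to_numpy()), 1)
        else:
            counts = np.zeros((1, r))
            np.add.at(counts[0], disc[var].to_numpy(), 1)
        cpts[var] = (counts + alpha) / (counts.sum(axis=1, keepdims=True) + alpha * r)
    return cpts


def fit_bayes_net(train: TrialDataset, cfg: SynthesisConfig) -> SynthesizerModel:
    """Learn structure and Dirichlet-smoothed CPTs from a training dataset."""
    if train.n < cfg.min_train:
        raise TrainingSizeError(
            f"bayes-net refuses to train on {train.n} records: "
            f"minimum admissible training size is {cfg.min_train}"
        )
    names = train.schema.synth_names
    disc, nodes = _discretize(train, names, cfg.n_bins)
    cards = {n: nodes[n].n_states for n in names}
    g = _hill_climb(disc, cards)
    cpts = _fit_cpts(disc, g, cards, cfg.dirichlet_alpha)
    order = tuple(nx.topological_sort(g))
    parents = {v: tuple(sorted(g.predecessors(v))) for v in names}
    state = _BayesNetState(nodes, order, parents, cpts)
    return SynthesizerModel("bayes-net", train.schema, train.n, state)


def arcs(model: SynthesizerModel) -> set[tuple[str, str]]:
    """The learned arc set, for inspection and testing."""
    st: _BayesNetState = model.state
    return {(p, v) for v, ps in st.parents.items() for p in ps}


def sample_bayes_net(model: SynthesizerModel, k: int, seed: int) -> pd.DataFrame:
    st: _BayesNetState = model.state
    rng = spawn_rng(seed, "bn-sample")
    states: dict[str, np.ndarray] = {}
    for var in st.order:
        node = st.nodes[var]
        cpt = st.cpts[var]
        parents = st.parents[var]
        if parents:
            idx = np.zeros(k, dtype=int)
            for p in parents:
                idx = idx * st.nodes[p].n_states + states[p]
            rows = cpt[idx]
        else:
            rows = np.broadcast_to(cpt[0], (k, node.n_states))
        u = rng.random(k)
        cdf = np.cumsum(rows, axis=1)
        states[var] = (u[:, None] < cdf).argmax(axis=1)

    out = {}
    for var, s in states.items():
        node = st.nodes[var]
        if node.levels is not None:
            out[var] = np.asarray(node.levels, dtype=object)[s].astype(str)
        else:
            vals = np.empty(k, dtype=float)
            for b in np.unique(s):
                rows = np.flatnonzero(s == b)
                pool = node.bin_pools[int(b)]
                vals[rows] = rng.choice(pool, size=rows.size, replace=True)
            out[var] = vals
    return pd.DataFrame(out)


__all__ = ["fit_bayes_net", "sample_bayes_net", "arcs"]
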