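"""Forward assembly simulation of linear polymers.

Starting from a single monomer in the assembly pool, each step combines two
polymers into a longer one (lengths add) and returns the product to the pool
if it is new.  Undirected exploration draws both operands uniformly at random
from the pool; directed exploration always uses the most recently created
polymer as one operand — a minimal, hand-imposed form of selection.  The
joint assembly space of a run is the union of minimal addition-chain
pathways of every observed polymer; its exploration ratio (observed nodes
over all nodes) drops, and the maximum assembly index rises, when the
process is selective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx
import numpy as np
import pandas as pd

from . import chains

__all__ = [
    "AssemblyPool",
    "AssemblySpaceDAG",
    "SimulationConfig",
    "ExperimentResult",
    "step_undirected",
    "step_directed",
    "run_single",
    "run_experiment",
    "joint_assembly_space",
    "exploration_ratio",
]


@dataclass
class AssemblyPool:
    """Unique polymer lengths discovered so far, with discovery order."""

    members: set[int] = field(default_factory=lambda: {1})
    order: list[int] = field(default_factory=lambda: [1])
    counts: dict[int, int] = field(default_factory=lambda: {1: 1})

    @property
    def most_recent(self) -> int:
        return self.order[-1]

    def add(self, length: int) -> bool:
        """Record one product instance; True if the length is new."""
        self.counts[length] = self.counts.get(length, 0) + 1
        if length in self.members:
            return False
        self.members.add(length)
        self.order.append(length)
        return True

    def sample(self, rng: np.random.Generator, k: int, replacement: bool = True,
               abundance_weighted: bool = False) -> list[int]:
        pool = self.order  # discovery order: stable indexing for reproducibility
        if abundance_weighted:
            w = np.array([self.counts[x] for x in pool], dtype=float)
            w /= w.sum()
            idx = rng.choice(len(pool), size=k, replace=replacement, p=w)
        else:
            idx = rng.choice(len(pool), size=k, replace=replacement)
        return [pool[i] for i in idx]


def step_undirected(pool: AssemblyPool, rng: np.random.Generator,
                    replacement: bool = True, abundance_weighted: bool = False) -> AssemblyPool:
    """Join two randomly selected polymers; add the product back if new."""
    if not replacement and len(pool.members) < 2:
        replacement = True  # a lone monomer can only self-join
    x, y = pool.sample(rng, 2, replacement=replacement, abundance_weighted=abundance_weighted)
    pool.add(x + y)
    return pool


def step_directed(pool: AssemblyPool, rng: np.random.Generator,
                  abundance_weighted: bool = False) -> AssemblyPool:
    """Join the most recently created polymer with a random pool member."""
    (y,) = pool.sample(rng, 1, abundance_weighted=abundance_weighted)
    pool.add(pool.most_recent + y)
    return pool


# ---------------------------------------------------------------------------
# joint assembly space
# ---------------------------------------------------------------------------


@dataclass
class AssemblySpaceDAG:
    """Union of minimal pathways: observed polymers plus contingent
    intermediates that the pathways pass through but the process never made."""

    graph: nx.DiGraph
    exact: bool = True  # False if any pathway used the binary-chain fallback

    @property
    def observed(self) -> set[int]:
        return {n for n, d in self.graph.nodes(data=True) if d["flag"] == "observed"}

    @property
    def contingent(self) -> set[int]:
        return {n for n, d in self.graph.nodes(data=True) if d["flag"] == "contingent"}


def joint_assembly_space(
    observed: Iterable[int],
    exact_limit: int = chains.DEFAULT_EXACT_LIMIT,
    over_limit: Literal["refuse", "binary"] = "refuse",
) -> AssemblySpaceDAG:
    """Union of one minimal addition chain per observed polymer.

    Tie-breaking among co-minimal chains is deterministic (lexicographically
    smallest increasing chain), so the contingent node set is a function of
    the observed set alone.  Polymers beyond ``exact_limit`` are refused
    unless ``over_limit='binary'``, in which case the binary-method chain is
    used and the DAG is flagged approximate.
    """
    observed = set(observed)
    if not observed:
        raise ValueError("observed set must be non-empty")
    bad = sorted(x for x in observed if x < 1)
    if bad:
        raise ValueError(f"polymer lengths must be >= 1: {bad}")
    g = nx.DiGraph()
    g.add_node(1, flag="observed" if 1 in observed else "contingent")
    exact = True
    for n in sorted(observed):
        if n > exact_limit:
            if over_limit == "refuse":
                raise ValueError(
                    f"observed polymer {n} exceeds the exact-chain limit {exact_limit}"
                )
            chain = chains.binary_chain(n)
            exact = False
        else:
            chain = chains.addition_chain_min(n, exact_limit).chain
        prior = set(chain[:1])
        for value in chain[1:]:
            if value not in g:
                g.add_node(value, flag="contingent")
                # deterministic parent assignment: largest feasible left operand
                left = max(a for a in prior if value - a in prior)
                g.nodes[value]["parents"] = (left, value - left)
                g.add_edge(left, value)
                g.add_edge(value - left, value)
            prior.add(value)
    for n in observed:
        g.nodes[n]["flag"] = "observed"
    return AssemblySpaceDAG(graph=g, exact=exact)


def exploration_ratio(dag: AssemblySpaceDAG) -> float:
    """Observed nodes over all (observed + contingent) nodes, in (0, 1]."""
    total = dag.graph.number_of_nodes()
    if total == 0:
        raise ValueError("empty assembly-space DAG")
    return len(dag.observed) / total


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation settings.

    ``exact_chain_limit`` bounds the polymer length up to which minimal
    addition chains are computed exactly when building joint assembly spaces
    and maximum assembly indices; longer polymers (directed runs reach
    astronomical lengths) fall back to the binary-method chain, flagged
    approximate, mirroring the log2(n) leading-order treatment.
    """

    mode: Literal["undirected", "directed"]
    steps: int = 10_000
    runs: int = 25
    seed: int = 0
    exact_chain_limit: int = 256
    replacement: bool = True
    abundance_weighted: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("undirected", "directed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.steps < 1 or self.runs < 1:
            raise ValueError("steps and runs must be >= 1")


def run_single(config: SimulationConfig, run_idx: int = 0) -> tuple[AssemblyPool, dict]:
    """One seeded trajectory plus its end-of-run statistics.

    The per-run generator depends only on (seed, run index), so runs are
    paired across modes at matched seeds.
    """
    rng = np.random.default_rng([config.seed, run_idx])
    pool = AssemblyPool()
    for _ in range(config.steps):
        if config.mode == "undirected":
            step_undirected(pool, rng, replacement=config.replacement,
                            abundance_weighted=config.abundance_weighted)
        else:
            step_directed(pool, rng, abundance_weighted=config.abundance_weighted)
    dag = joint_assembly_space(pool.members, exact_limit=config.exact_chain_limit,
                               over_limit="binary")
    n_max = max(pool.members)
    if n_max <= config.exact_chain_limit:
        res = chains.addition_chain_min(n_max, config.exact_chain_limit)
    else:
        res = chains.AdditionChain(
            n=n_max, index=len(chains.binary_chain(n_max)) - 1,
            chain=chains.binary_chain(n_max), exact=False,
        )
    stats = {
        "run": run_idx,
        "mode": config.mode,
        "seed": config.seed,
        "pool_size": len(pool.members),
        "max_length": n_max,
        "log2_max_length": math.log2(n_max) if n_max > 1 else 0.0,
        "max_assembly_index": res.index,
        "max_ai_exact": res.exact,
        "exploration_ratio": exploration_ratio(dag),
        "dag_nodes": dag.graph.number_of_nodes(),
    }
    return pool, stats


@dataclass
class ExperimentResult:
    config: SimulationConfig
    per_run: pd.DataFrame
    summary: pd.DataFrame


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """Repeat the forward process ``runs`` times and summarize.

    Reports mean and standard deviation of pool size, exploration ratio and
    maximum assembly index (exact addition-chain value where feasible, the
    flagged binary-chain bound otherwise, with log2(n_max) alongside as the
    leading-order approximation).
    """
    rows = [run_single(config, i)[1] for i in range(config.runs)]
    per_run = pd.DataFrame(rows)
    numeric = ["pool_size", "log2_max_length", "max_assembly_index", "exploration_ratio",
               "dag_nodes"]
    summary = per_run[numeric].agg(["mean", "std"]).T.reset_index(names="statistic")
    return ExperimentResult(config=config, per_run=per_run, summary=summary)
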