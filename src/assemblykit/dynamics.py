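"""Discovery and production dynamics in assembly space.

Discovery of new unique objects at assembly index a+1 proceeds at rate

    dN_{a+1}/dt = k_d * (N_a)^alpha

where N_a counts unique objects at index a and alpha in [0, 1] is the
selectivity: alpha = 1 is undirected, history-dependent expansion (every
assembled object is available for reuse); alpha < 1 means only a sublinearly
growing subset is reused — selection.  k_d sets the discovery timescale
tau_d ~ 1/k_d; a second rate k_p (production of additional copies of
existing objects, timescale tau_p ~ 1/k_p) competes with discovery for a
finite mass budget.  Selection can only emerge when the two timescales are
comparable: fast discovery yields a combinatorial explosion of singletons,
fast production yields high copy numbers of low-index objects, and both
leave the ensemble assembly A low.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .ensemble import Ensemble, EnsembleRecord

__all__ = [
    "SelectionParams",
    "GrowthTrajectory",
    "integrate_growth",
    "poisson_cascade",
    "stochastic_growth",
    "discovery_production_sim",
    "regime_classify",
    "estimate_selection_params",
]


@dataclass(frozen=True)
class SelectionParams:
    """Selectivity alpha in [0, 1]; discovery rate k_d and production rate
    k_p in 1/time; tau_d = 1/k_d and tau_p = 1/k_p."""

    alpha: float = 1.0
    k_d: float = 1.0
    k_p: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not math.isfinite(self.k_d) or self.k_d <= 0:
            raise ValueError(f"k_d must be positive and finite, got {self.k_d}")
        if not math.isfinite(self.k_p) or self.k_p < 0:
            raise ValueError(f"k_p must be >= 0 and finite, got {self.k_p}")

    @property
    def tau_d(self) -> float:
        return 1.0 / self.k_d

    @property
    def tau_p(self) -> float:
        if self.k_p == 0:
            return math.inf
        return 1.0 / self.k_p


@dataclass
class GrowthTrajectory:
    """Time series of unique-object counts per assembly index, optionally
    with total copies per index and the ensemble assembly A(t)."""

    t: np.ndarray
    a_levels: np.ndarray  # assembly indices, starting at 1
    counts: np.ndarray  # shape (len(t), len(a_levels)): N_a(t)
    copies: np.ndarray | None = None  # total copy numbers per level
    A: np.ndarray | None = None  # ensemble assembly over time
    params: SelectionParams | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def total_unique(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ti, tv in enumerate(self.t):
            for ai, a in enumerate(self.a_levels):
                rows.append(
                    {
                        "t": tv,
                        "a": int(a),
                        "N_a": self.counts[ti, ai],
                        "copies": None if self.copies is None else self.copies[ti, ai],
                        "A": None if self.A is None else self.A[ti],
                    }
                )
        return pd.DataFrame(rows)


def poisson_cascade(N1: float, k_d: float, t, a: int):
    """Closed-form alpha=1 cascade solution N_a(t) = N1 (k_d t)^{a-1}/(a-1)!.

    With a constant source N_1 and linear rates, the mean of the discovery
    process solves the linear cascade exactly; used as the analytic check for
    both the ODE integrator and the stochastic engine.
    """
    t = np.asarray(t, dtype=float)
    return N1 * (k_d * t) ** (a - 1) / math.factorial(a - 1)


def integrate_growth(
    params: SelectionParams,
    N1: float,
    t_grid: Sequence[float],
    a_max: int = 10,
    activation_threshold: float = 1.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> GrowthTrajectory:
    """Numerically integrate the discovery cascade over a = 1..a_max.

    N_1 is a constant source.  For alpha = 1 the plain cascade is integrated
    (rates are linear and well behaved at zero).  For alpha < 1 a level feeds
    the next only once it holds at least ``activation_threshold`` objects
    (default one whole object): sublinear reuse presupposes an assembled
    object to reuse, and the threshold removes the non-Lipschitz corner of
    N^alpha at zero.  Integration is adaptive-step (RK45) and restarted at
    each activation event.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if not np.all(np.isfinite(t_grid)) or N1 <= 0 or not math.isfinite(N1):
        raise ValueError("t_grid must be finite and N1 positive")
    if np.any(t_grid < 0):
        raise ValueError("t_grid must be >= 0 (initial condition is set at t = 0)")
    if a_max < 1:
        raise ValueError("a_max must be >= 1")
    a_levels = np.arange(1, a_max + 1)
    counts = np.zeros((len(t_grid), a_max))
    counts[:, 0] = N1
    if a_max == 1:
        return GrowthTrajectory(t=t_grid, a_levels=a_levels, counts=counts, params=params)

    alpha, k_d = params.alpha, params.k_d

    if alpha == 1.0:

        def rhs(t, y):
            dy = np.empty_like(y)
            dy[0] = k_d * N1
            dy[1:] = k_d * y[:-1]
            return dy

        sol = solve_ivp(
            rhs, (0.0, t_grid[-1]), np.zeros(a_max - 1), t_eval=t_grid,
            method="DOP853", rtol=rtol, atol=atol,
        )
        counts[:, 1:] = np.clip(sol.y.T, 0.0, None)
        return GrowthTrajectory(t=t_grid, a_levels=a_levels, counts=counts, params=params)

    # alpha < 1: event-driven activation, level by level
    thr = activation_threshold
    y = np.zeros(a_max - 1)  # N_2 .. N_{a_max}
    active = [N1 >= thr] + [False] * (a_max - 2)  # feeding flags for levels 1..a_max-1
    out = np.zeros((len(t_grid), a_max - 1))
    t_now = 0.0
    while t_now < t_grid[-1]:
        feed = np.array([N1] + list(y[:-1]))
        gate = np.array(active, dtype=float)

        def rhs(t, yy):
            f = np.concatenate(([N1], yy[:-1]))
            return k_d * gate * np.clip(f, 0.0, None) ** alpha

        # next activation: lowest inactive level whose feeder is active
        events = []
        for j in range(1, a_max - 1):
            if not active[j] and active[j - 1]:

                def make_ev(jj):
                    def ev(t, yy):
                        return yy[jj - 1] - thr

                    ev.terminal = True
                    ev.direction = 1.0
                    return ev

                events.append(make_ev(j))
        mask = (t_grid > t_now) & (t_grid <= t_grid[-1])
        sol = solve_ivp(
            rhs, (t_now, t_grid[-1]), y, t_eval=t_grid[mask], events=events,
            method="DOP853", rtol=rtol, atol=atol,
        )
        for k, tv in enumerate(sol.t):
            out[np.searchsorted(t_grid, tv)] = sol.y[:, k]
        if sol.status == 1:  # an activation event fired: restart from there
            t_now = sol.t_events[[i for i, te in enumerate(sol.t_events) if len(te)][0]][0]
            y = np.array([ye[0] for ye in sol.y_events if len(ye)][0])
            for j in range(1, a_max - 1):
                if not active[j] and active[j - 1] and y[j - 1] >= thr - 1e-12:
                    active[j] = True
        else:
            break
    counts[:, 1:] = np.clip(out, 0.0, None)
    return GrowthTrajectory(t=t_grid, a_levels=a_levels, counts=counts, params=params)


def stochastic_growth(
    params: SelectionParams,
    seed: int,
    n_events: int | None = None,
    t_end: float | None = None,
    N1: int = 1,
    a_max: int = 64,
) -> GrowthTrajectory:
    """Discrete-event realization of the discovery cascade (Gillespie).

    At each event a level a is chosen with probability proportional to
    (N_a)^alpha and one new unique object appears at level a+1; waiting times
    are exponential with the total rate.  For alpha = 1 the ensemble mean of
    N_a(t) equals the Poisson-cascade closed form.
    """
    if n_events is None and t_end is None:
        raise ValueError("provide n_events and/or t_end")
    rng = np.random.default_rng(seed)
    N = np.zeros(a_max, dtype=float)
    N[0] = N1
    t = 0.0
    times = [0.0]
    snapshots = [N.copy()]
    events = 0
    while True:
        if n_events is not None and events >= n_events:
            break
        rates = params.k_d * np.where(N > 0, N, 0.0) ** params.alpha
        rates[-1] = 0.0  # the top level does not feed anything tracked
        total = rates.sum()
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        if t_end is not None and t + dt > t_end:
            t = t_end
            times.append(t)
            snapshots.append(N.copy())
            break
        t += dt
        a = rng.choice(a_max, p=rates / total)
        N[a + 1] += 1
        events += 1
        times.append(t)
        snapshots.append(N.copy())
    return GrowthTrajectory(
        t=np.array(times),
        a_levels=np.arange(1, a_max + 1),
        counts=np.array(snapshots),
        params=params,
        seed=seed,
        meta={"events": events},
    )


def discovery_production_sim(
    params: SelectionParams,
    seed: int,
    t_end: float = math.inf,
    mass_budget: int = 100,
    a_max: int = 64,
) -> GrowthTrajectory:
    """Coupled discovery and production kinetics under a finite mass budget.

    Discovery events (rate k_d (N_a)^alpha per level) create a new unique
    object at level a+1 with copy number 1; production events (rate k_p per
    discovered object, object drawn uniformly) add one copy of an existing
    object.  Both consume one unit of the shared mass budget; the simulation
    ends cleanly when the budget is spent, t_end is reached, or all rates
    vanish.  A(t) is evaluated with the assembly equation after every event.
    """
    if mass_budget < 1:
        raise ValueError("mass_budget must be >= 1")
    rng = np.random.default_rng(seed)
    # levels are assembly indices 0..a_max-1; the seed object is elementary (a = 0)
    objects: list[list[int]] = [[0, 1]]  # (assembly index, copy number)
    N = np.zeros(a_max, dtype=float)
    N[0] = 1
    mass = 1
    t = 0.0
    times = [0.0]
    snapshots = [N.copy()]
    A_series = [0.0]
    copies_snap = [_copies_by_level(objects, a_max)]
    while mass < mass_budget and t < t_end:
        disc = params.k_d * np.where(N > 0, N, 0.0) ** params.alpha
        disc[-1] = 0.0
        prod_total = params.k_p * len(objects)
        total = disc.sum() + prod_total
        if total <= 0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > t_end:
            t = t_end
            break
        t += dt
        if rng.random() < prod_total / total:
            idx = rng.integers(len(objects))
            objects[idx][1] += 1
        else:
            a = rng.choice(a_max, p=disc / disc.sum())
            objects.append([a + 1, 1])  # discovery from index a creates an object at a+1
            N[a + 1] += 1
        mass += 1
        times.append(t)
        snapshots.append(N.copy())
        copies_snap.append(_copies_by_level(objects, a_max))
        A_series.append(_assembly_of(objects))
    traj = GrowthTrajectory(
        t=np.array(times),
        a_levels=np.arange(0, a_max),
        counts=np.array(snapshots),
        copies=np.array(copies_snap),
        A=np.array(A_series),
        params=params,
        seed=seed,
        meta={"mass": mass, "mass_budget": mass_budget, "objects": [tuple(o) for o in objects]},
    )
    return traj


def _copies_by_level(objects: list[list[int]], a_max: int) -> np.ndarray:
    out = np.zeros(a_max)
    for a, n in objects:
        out[a] += n
    return out


def _assembly_of(objects: list[list[int]]) -> float:
    ens = Ensemble(
        records=tuple(
            EnsembleRecord(object_id=f"obj{i}", assembly_index=a, copy_number=n)
            for i, (a, n) in enumerate(objects)
        )
    )
    return ens.assembly()


def final_ensemble(traj: GrowthTrajectory) -> Ensemble:
    """The end-of-run ensemble of a discovery+production trajectory."""
    objects = traj.meta.get("objects")
    if objects is None:
        raise ValueError("trajectory carries no per-object copy numbers")
    return Ensemble(
        records=tuple(
            EnsembleRecord(object_id=f"obj{i}", assembly_index=a, copy_number=n)
            for i, (a, n) in enumerate(objects)
        )
    )


def regime_classify(tau_d: float, tau_p: float, r_low: float = 0.1, r_high: float = 10.0) -> int:
    """Phase regime from the timescale ratio tau_d/tau_p.

    1: discovery much faster than production (combinatorial explosion of
    singletons); 2: production much faster (high copies of low-index
    objects); 3: comparable timescales — the only regime where selection can
    emerge.
    """
    if tau_d <= 0 or tau_p <= 0 or not math.isfinite(tau_d):
        raise ValueError("timescales must be positive and tau_d finite")
    ratio = tau_d / tau_p  # tau_p may be inf (k_p = 0): ratio 0 -> regime 1
    if ratio < r_low:
        return 1
    if ratio > r_high:
        return 2
    return 3


def estimate_selection_params(times, counts):
    """Fit (alpha, k_d) to observed per-index discovery time series.

    Interface stub: estimation on real instrument data is out of scope for
    this release.
    """
    raise NotImplementedError(
        "fitting (alpha, k_d) to empirical time series is not implemented yet"
    )
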