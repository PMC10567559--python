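"""Shared exact minimal-pathway search engine.

An assembly pathway for a target is a sequence of joins, each combining two
structures that are elementary units or earlier products; once built, a
structure can be reused at no extra cost.  The minimal number of joins (the
assembly index) equals the minimal number of *distinct* intermediate
structures (including the target) in any recursive decomposition.

The engine searches top-down.  A state is the set of structures still to be
built ("pending"), deduplicated by canonical key — building one copy serves
every use.  One move splits the largest pending structure into two parts
(reversing a join) and adds the non-elementary parts to the pending set.
Splitting a largest structure first is lossless: parts are strictly smaller
than every structure already split, so an already-built structure can never
reappear, and the number of splits performed equals the number of distinct
structures on the pathway.

Two bounds close the search quickly:

* if no two disjoint isomorphic motifs of >= 2 units exist anywhere in the
  pending set, no reuse is possible and the cost is exactly
  ``sum(size - 1)`` (unit-by-unit construction);
* any state needs at least ``max(#pending, ceil(log2 max_size))`` further
  joins.
"""

from __future__ import annotations

import math
from typing import Any, Callable, Generic, Hashable, Iterable, Sequence, TypeVar

T = TypeVar("T")

INF = float("inf")


class SplitProblem(Generic[T]):
    """Domain adapter for the split search (strings, molecular graphs)."""

    def size(self, item: T) -> int:
        raise NotImplementedError

    def key(self, item: T) -> Hashable:
        """Canonical certificate; equal iff the structures are interchangeable."""
        raise NotImplementedError

    def splits(self, item: T) -> Iterable[tuple[T, T]]:
        """All ways to reverse one join: both parts valid sub-structures."""
        raise NotImplementedError

    def has_duplicate_pair(self, items: Sequence[T]) -> bool:
        """True if two disjoint isomorphic >=2-unit motifs exist in ``items``."""
        raise NotImplementedError

    def linear_steps(self, item: T) -> list[tuple[T, T, T]]:
        """Unit-by-unit join steps ``(left, right, product)`` building ``item``."""
        raise NotImplementedError

    #: When False the unit-by-unit upper bound / no-duplicate shortcut is not
    #: available (e.g. molecular search with ring-closing joins disabled).
    linear_available: bool = True


class SplitSolver(Generic[T]):
    def __init__(self, problem: SplitProblem[T]):
        self.problem = problem
        # key -> (value, exact, split_choice); non-exact values are lower bounds.
        # split_choice None with exact=True means the unit-by-unit base case.
        self._memo: dict[frozenset, tuple[float, bool, Any]] = {}

    # -- main entry -------------------------------------------------------

    def solve(self, target: T) -> tuple[int, list[tuple[T, T, T]]]:
        """Return (minimal join count, join schedule in executable order)."""
        p = self.problem
        if p.size(target) < 1:
            raise ValueError("target must contain at least one elementary unit")
        if p.size(target) == 1:
            return 0, []
        state = {p.key(target): target}
        if p.linear_available:
            budget = sum(p.size(t) - 1 for t in state.values())
        else:
            # no closed-form upper bound: iterative deepening up to 2*size
            budget = 2 * p.size(target)
        value = self._solve(state, budget)
        if value > budget:
            raise ValueError("no valid assembly pathway exists under the configured join rules")
        return int(value), self._reconstruct(state)

    # -- search -----------------------------------------------------------

    def _lower_bound(self, state: dict) -> int:
        p = self.problem
        max_size = max(p.size(t) for t in state.values())
        return max(len(state), max(1, (max_size - 1).bit_length()))

    def _solve(self, state: dict, budget: float) -> float:
        if not state:
            return 0
        p = self.problem
        k = frozenset(state)
        hit = self._memo.get(k)
        if hit is not None:
            v, exact, _ = hit
            if exact or v > budget:
                return v
        lb = self._lower_bound(state)
        if lb > budget:
            self._store_lb(k, lb)
            return lb
        items = list(state.values())
        if p.linear_available:
            linear = sum(p.size(t) - 1 for t in items)
            if not p.has_duplicate_pair(items):
                self._memo[k] = (linear, True, None)
                return linear
            best: float = linear
        else:
            best = INF
        best_split = None
        t = self._pick(state)
        for x, y in self._ordered_splits(t):
            cb = min(budget, best - 1) - 1
            if cb < 0:
                break
            child = dict(state)
            del child[p.key(t)]
            for part in (x, y):
                if p.size(part) > 1:
                    child.setdefault(p.key(part), part)
            v = self._solve(child, cb)
            if v <= cb and 1 + v < best:
                best = 1 + v
                best_split = (x, y)
        if best <= budget:
            if best_split is None and p.linear_available:
                # linear construction is optimal here even though duplicates exist
                self._memo[k] = (best, True, None)
            else:
                self._memo[k] = (best, True, best_split)
            return best
        self._store_lb(k, budget + 1)
        return budget + 1

    def _store_lb(self, k: frozenset, lb: float) -> None:
        hit = self._memo.get(k)
        if hit is None or (not hit[1] and hit[0] < lb):
            self._memo[k] = (lb, False, None)

    def _pick(self, state: dict) -> T:
        p = self.problem
        return max(state.values(), key=lambda it: (p.size(it), repr(p.key(it))))

    def _ordered_splits(self, t: T) -> list[tuple[T, T]]:
        p = self.problem
        seen = set()
        out = []
        for x, y in p.splits(t):
            sig = (p.key(x), p.key(y))
            if sig in seen:
                continue
            seen.add(sig)
            out.append((x, y))
        # doubling splits (both parts interchangeable) first, then balanced
        out.sort(
            key=lambda xy: (
                p.key(xy[0]) != p.key(xy[1]),
                abs(p.size(xy[0]) - p.size(xy[1])),
                repr((p.key(xy[0]), p.key(xy[1]))),
            )
        )
        return out

    # -- pathway reconstruction -------------------------------------------

    def _reconstruct(self, state: dict) -> list[tuple[T, T, T]]:
        """Walk stored split choices; emit joins in executable (bottom-up) order."""
        p = self.problem
        splits: list[tuple[T, T, T]] = []
        linear: list[tuple[T, T, T]] = []
        state = dict(state)
        while state:
            k = frozenset(state)
            value, exact, choice = self._memo[k]
            assert exact, "reconstruction reached an unsolved state"
            if choice is None:
                for it in sorted(state.values(), key=lambda it: (p.size(it), repr(p.key(it)))):
                    linear.extend(p.linear_steps(it))
                break
            t = self._pick(state)
            x, y = choice
            splits.append((x, y, t))
            del state[p.key(t)]
            for part in (x, y):
                if p.size(part) > 1:
                    state.setdefault(p.key(part), part)
        # deduplicate: a structure may be produced once and reused
        steps = linear + list(reversed(splits))
        seen_products = set()
        out = []
        for x, y, z in steps:
            zk = p.key(z)
            if zk in seen_products:
                continue
            seen_products.add(zk)
            out.append((x, y, z))
        return out
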