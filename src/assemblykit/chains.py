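"""Minimal addition chains.

The assembly index of a homopolymer of length ``n`` equals the length of a
minimal addition chain for ``n``: a sequence ``1 = c_0 < c_1 < ... < c_r = n``
in which every element is the sum of two (not necessarily distinct) earlier
elements.  Each sum is one join of two polymers already in the assembly pool,
so ``r`` is the minimal number of joins needed to reach length ``n`` from the
monomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

__all__ = ["AdditionChain", "addition_chain_min", "binary_chain", "chain_lower_bound"]

#: Largest n for which the exact search is attempted by default.
DEFAULT_EXACT_LIMIT = 1 << 16


@dataclass(frozen=True)
class AdditionChain:
    """Result of an addition-chain search.

    ``index`` is the chain length (number of additions); ``chain`` the full
    sequence starting at 1 and ending at ``n``.  ``exact`` is False when the
    result comes from the binary-method fallback for over-limit ``n`` and is
    therefore only an upper bound on the true index.
    """

    n: int
    index: int
    chain: tuple[int, ...]
    exact: bool = True

    def __post_init__(self) -> None:
        assert self.chain[0] == 1 and self.chain[-1] == self.n
        assert self.index == len(self.chain) - 1


def chain_lower_bound(n: int) -> int:
    """Lower bound on the minimal chain length.

    Each addition at most doubles the largest element (ceil(log2 n)), and a
    chain must also pay for the binary weight of n: l(n) >= log2(n) +
    log2(v(n)) - 2.13 with v the popcount (Schonhage's bound).
    """
    if n < 1:
        raise ValueError(f"homopolymer length must be >= 1, got {n}")
    if n == 1:
        return 0
    simple = (n - 1).bit_length()
    v = bin(n).count("1")
    schonhage = math.ceil(math.log2(n) + math.log2(v) - 2.13)
    return max(simple, schonhage)


def binary_chain(n: int) -> tuple[int, ...]:
    """Addition chain from the binary method (square-and-multiply order).

    Length ~ log2(n) + popcount(n) - 1; valid for arbitrarily large n.
    """
    if n < 1:
        raise ValueError(f"homopolymer length must be >= 1, got {n}")
    chain = [1]
    acc = 1
    for bit in bin(n)[3:]:
        acc *= 2
        chain.append(acc)
        if bit == "1":
            acc += 1
            chain.append(acc)
    return tuple(chain)


@lru_cache(maxsize=100_000)
def _min_chain_cached(n: int) -> tuple[int, ...]:
    # Iterative-deepening DFS over strictly increasing chains.  A minimal
    # addition chain can always be taken strictly increasing, and pruning with
    # the doubling bound c_k * 2^(r-k) >= n keeps the search small.
    if n == 1:
        return (1,)
    ub_chain = binary_chain(n)
    depth = chain_lower_bound(n)
    while depth < len(ub_chain) - 1:
        found = _dfs_chain([1], {1}, n, depth)
        if found is not None:
            return tuple(found)
        depth += 1
    return ub_chain


def _dfs_chain(chain: list[int], members: set[int], n: int, remaining: int) -> list[int] | None:
    last = chain[-1]
    if last == n:
        return list(chain)
    if remaining == 0 or last << remaining < n:
        return None
    if remaining == 1:
        # the final element must be n itself: check n = a + b directly
        for a in chain:
            if n - a in members and n - a <= last:
                return list(chain) + [n]
        return None
    # descending candidate order: doubling-heavy chains are found first
    cands = sorted(
        {a + b for i, a in enumerate(chain) for b in chain[i:] if last < a + b <= n},
        reverse=True,
    )
    for c in cands:
        chain.append(c)
        members.add(c)
        res = _dfs_chain(chain, members, n, remaining - 1)
        chain.pop()
        members.discard(c)
        if res is not None:
            return res
    return None


def addition_chain_min(n: int, exact_limit: int = DEFAULT_EXACT_LIMIT) -> AdditionChain:
    """Minimal addition chain for ``n`` (exact up to ``exact_limit``).

    Beyond the limit the binary-method chain is returned with ``exact=False``
    rather than refusing: forward simulations routinely discover polymers far
    beyond any exact-search horizon and still need a certified upper bound.
    """
    if n < 1:
        raise ValueError(f"homopolymer length must be >= 1, got {n}")
    if n > exact_limit:
        chain = binary_chain(n)
        return AdditionChain(n=n, index=len(chain) - 1, chain=chain, exact=False)
    chain = _min_chain_cached(n)
    return AdditionChain(n=n, index=len(chain) - 1, chain=chain, exact=True)
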