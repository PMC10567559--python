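"""Independent brute-force oracles used only by the test suite.

These deliberately take the opposite route from the package's top-down
split search: they enumerate forward (bottom-up) pool states, adding one
joined structure per step, and find the minimal number of steps by
breadth-first / iterative-deepening search.
"""

from __future__ import annotations

from collections import deque
from functools import lru_cache


# ---------------------------------------------------------------------------
# strings
# ---------------------------------------------------------------------------


def string_index_oracle(target: str) -> int:
    """Minimal joins to build ``target``: BFS over pools of built substrings.

    Any structure used on a minimal pathway is a substring of the target, so
    products are restricted to substrings; elementary characters are free.
    """
    if len(target) == 1:
        return 0
    subs = {target[i:j] for i in range(len(target)) for j in range(i + 2, len(target) + 1)}
    elementary = sorted(set(target))
    start: frozenset = frozenset()
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        built, depth = queue.popleft()
        pool = list(built) + elementary
        products = set()
        for x in pool:
            for y in pool:
                z = x + y
                if z in subs and z not in built:
                    products.add(z)
        if target in products:
            return depth + 1
        for z in products:
            nxt = built | {z}
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, depth + 1))
    raise RuntimeError("unreachable: unit-by-unit construction always exists")


# ---------------------------------------------------------------------------
# homopolymers / addition chains
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def chain_index_oracle(n: int) -> int:
    """Naive iterative-deepening search over increasing addition chains."""
    if n == 1:
        return 0
    depth = 1
    while True:
        if _chain_dfs((1,), n, depth):
            return depth
        depth += 1


def _chain_dfs(chain: tuple[int, ...], n: int, remaining: int) -> bool:
    last = chain[-1]
    if last == n:
        return True
    if remaining == 0 or last * (2**remaining) < n:
        return False
    sums = sorted({a + b for a in chain for b in chain if last < a + b <= n})
    return any(_chain_dfs(chain + (c,), n, remaining - 1) for c in sums)


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------


def mol_index_oracle(mol) -> int:
    """Minimal joins for a small molecule: BFS over pools of built fragment
    isomorphism classes.

    All connected edge-induced subgraphs of the target are enumerated and
    grouped into classes by certificate; a class is buildable in one step
    when some member splits into two connected halves whose classes are
    already available (elementary bonds are always available).
    """
    n_edges = mol.n_bonds
    if n_edges == 1:
        return 0
    # edge adjacency
    adj = [set() for _ in range(n_edges)]
    atom_edges: dict[int, list[int]] = {}
    for e, (i, j, _) in enumerate(mol.bonds):
        atom_edges.setdefault(i, []).append(e)
        atom_edges.setdefault(j, []).append(e)
    for es in atom_edges.values():
        for a in es:
            for b in es:
                if a != b:
                    adj[a].add(b)

    def connected(subset: frozenset) -> bool:
        start = next(iter(subset))
        seen = {start}
        stack = [start]
        while stack:
            for f in adj[stack.pop()]:
                if f in subset and f not in seen:
                    seen.add(f)
                    stack.append(f)
        return len(seen) == len(subset)

    from itertools import combinations

    all_edges = list(range(n_edges))
    subsets = [
        frozenset(c)
        for k in range(1, n_edges + 1)
        for c in combinations(all_edges, k)
        if connected(frozenset(c))
    ]
    cls = {s: mol.subgraph(s).certificate for s in subsets}
    target_cls = cls[frozenset(all_edges)]
    elementary = {cls[s] for s in subsets if len(s) == 1}
    # ways[z] = set of frozenset({cx, cy}) able to produce class z in one join
    ways: dict = {}
    for s in subsets:
        if len(s) < 2:
            continue
        for k in range(1, len(s) // 2 + 1):
            for xs in combinations(sorted(s), k):
                x = frozenset(xs)
                y = s - x
                if connected(x) and connected(y):
                    ways.setdefault(cls[s], set()).add(frozenset({cls[x], cls[y]}))
    start: frozenset = frozenset()
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        built, depth = queue.popleft()
        avail = elementary | built
        for z, recipes in ways.items():
            if z in built:
                continue
            if any(r <= avail for r in recipes):
                if z == target_cls:
                    return depth + 1
                nxt = built | {z}
                if nxt not in seen:
                    seen.add(nxt)
                    queue.append((nxt, depth + 1))
    raise RuntimeError("unreachable: bond-by-bond construction always exists")
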