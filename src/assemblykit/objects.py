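"""Core assembly objects: strings, homopolymers, and their assembly indices.

An object here is anything finite and breakable into elementary units — a
character string (units: characters), a homopolymer (units: monomers, so the
object is just its length), or a molecular graph (units: bonds; see
:mod:`assemblykit.molecules`).  The assembly index of an object is the length
of the shortest pathway of recursive joins that builds it from elementary
units, where every structure formed along the pathway is available for reuse
at no extra cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

from . import chains
from ._search import SplitProblem, SplitSolver

__all__ = [
    "AssemblyObject",
    "AssemblyStep",
    "AssemblyPathway",
    "canonicalize",
    "join",
    "assembly_index",
    "assembly_index_string",
    "assembly_index_bounds",
    "DEFAULT_STRING_LIMIT",
]

#: Largest string length for which the exact search is attempted by default.
DEFAULT_STRING_LIMIT = 25

KINDS = ("string", "homopolymer", "molgraph")


@dataclass(frozen=True)
class AssemblyObject:
    """A canonicalized discrete object with its elementary-unit count."""

    kind: str
    payload: Any
    size: int

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown object kind {self.kind!r}; expected one of {KINDS}")
        if self.size < 1:
            raise ValueError(f"{self.kind} object must have size >= 1, got {self.size}")

    @property
    def is_elementary(self) -> bool:
        return self.size == 1

    def __str__(self) -> str:  # compact form used in serialized pathways
        if self.kind == "string":
            return self.payload
        if self.kind == "homopolymer":
            return f"<{self.payload}>"
        return f"[{self.payload.formula}|{self.payload.n_bonds} bonds]"


def canonicalize(raw: Any, kind: str | None = None) -> AssemblyObject:
    """Map a raw object to its canonical :class:`AssemblyObject`.

    Strings map to themselves (string equality is the object equality),
    integers to homopolymer lengths, and molecular graphs to their
    isomorphism-invariant certificate form.  Idempotent.
    """
    if isinstance(raw, AssemblyObject):
        return raw
    if isinstance(raw, str) and kind in (None, "string"):
        if not raw:
            raise ValueError("string object must be non-empty")
        return AssemblyObject(kind="string", payload=raw, size=len(raw))
    if isinstance(raw, int) and kind in (None, "homopolymer"):
        if raw < 1:
            raise ValueError("homopolymer object must have length >= 1")
        return AssemblyObject(kind="homopolymer", payload=raw, size=raw)
    from .molecules import MolGraph  # local import: molecules depends on this module

    if isinstance(raw, MolGraph) and kind in (None, "molgraph"):
        if raw.n_bonds < 1:
            raise ValueError("molgraph object must contain at least one bond")
        return AssemblyObject(kind="molgraph", payload=raw, size=raw.n_bonds)
    raise TypeError(f"cannot canonicalize {type(raw).__name__} as kind {kind!r}")


def join(x: AssemblyObject, y: AssemblyObject) -> AssemblyObject:
    """Join two objects of the same kind: concatenation for strings (ordered),
    length addition for homopolymers (commutative)."""
    if x.kind != y.kind:
        raise ValueError(f"cannot join objects of different kinds: {x.kind} vs {y.kind}")
    if x.kind == "string":
        return canonicalize(x.payload + y.payload)
    if x.kind == "homopolymer":
        return canonicalize(x.payload + y.payload)
    raise ValueError(
        "molecular joins need an atom-fusion map; use assemblykit.molecules.join_graphs"
    )


@dataclass(frozen=True)
class AssemblyStep:
    left: AssemblyObject
    right: AssemblyObject
    product: AssemblyObject

    def __str__(self) -> str:
        return f"{self.left}+{self.right}={self.product}"


@dataclass(frozen=True)
class AssemblyPathway:
    """An ordered join sequence from elementary units to ``target``.

    Every operand must be an elementary unit of the target or the product of
    a strictly earlier step; the last step produces the target.
    """

    target: AssemblyObject
    steps: tuple[AssemblyStep, ...]

    @property
    def length(self) -> int:
        return len(self.steps)

    def validate(self) -> None:
        """Replay the pathway; raise ``ValueError`` on any inconsistency."""
        pool: set = set(_elementary_keys(self.target))
        for i, step in enumerate(self.steps):
            for operand in (step.left, step.right):
                if _obj_key(operand) not in pool:
                    raise ValueError(
                        f"step {i}: operand {operand} is neither elementary nor an earlier product"
                    )
            _check_join(step, i)
            pool.add(_obj_key(step.product))
        if self.steps:
            if _obj_key(self.steps[-1].product) != _obj_key(self.target):
                raise ValueError("final step does not produce the target")
        elif not self.target.is_elementary:
            raise ValueError("empty pathway for a non-elementary target")

    def serialize(self) -> str:
        return ";".join(str(s) for s in self.steps)


def _obj_key(obj: AssemblyObject):
    if obj.kind == "molgraph":
        return ("molgraph", obj.payload.certificate)
    return (obj.kind, obj.payload)


def _elementary_keys(target: AssemblyObject) -> Iterable:
    if target.kind == "string":
        return {("string", c) for c in set(target.payload)}
    if target.kind == "homopolymer":
        return {("homopolymer", 1)}
    return {("molgraph", b) for b in target.payload.elementary_certificates()}


def _check_join(step: AssemblyStep, i: int) -> None:
    if step.product.kind == "molgraph":
        from .molecules import is_valid_join

        if not is_valid_join(step.left.payload, step.right.payload, step.product.payload):
            raise ValueError(f"step {i}: product is not an edge-disjoint union of its operands")
        return
    expected = join(step.left, step.right)
    ok = _obj_key(expected) == _obj_key(step.product)
    if step.product.kind == "homopolymer":
        ok = step.left.payload + step.right.payload == step.product.payload
    if not ok:
        raise ValueError(f"step {i}: product does not equal join(left, right)")


def assembly_index_bounds(obj: AssemblyObject | str | int) -> tuple[int, int]:
    """(ceil(log2 size), size - 1): joins at most double the size, and
    unit-by-unit growth always succeeds."""
    obj = canonicalize(obj)
    lower = max(0, (obj.size - 1).bit_length())
    return lower, obj.size - 1


# ---------------------------------------------------------------------------
# string assembly index: top-down split search
# ---------------------------------------------------------------------------


class _StringProblem(SplitProblem[str]):
    def size(self, s: str) -> int:
        return len(s)

    def key(self, s: str) -> str:
        return s

    def splits(self, s: str):
        for i in range(1, len(s)):
            yield s[:i], s[i:]

    def has_duplicate_pair(self, items) -> bool:
        # two disjoint occurrences of some 2-gram, within or across strings
        seen: dict[str, tuple[int, int]] = {}  # gram -> (item idx, first pos)
        for idx, s in enumerate(items):
            for pos in range(len(s) - 1):
                gram = s[pos : pos + 2]
                prev = seen.get(gram)
                if prev is None:
                    seen[gram] = (idx, pos)
                elif prev[0] != idx or pos - prev[1] >= 2:
                    return True
        return False

    def linear_steps(self, s: str):
        steps = []
        for i in range(1, len(s)):
            steps.append((s[:i], s[i], s[: i + 1]))
        return steps


def assembly_index_string(
    s: str | AssemblyObject, max_len: int = DEFAULT_STRING_LIMIT
) -> tuple[int, AssemblyPathway]:
    """Exact string assembly index with an attaining pathway.

    Refuses (rather than silently approximating) above ``max_len``.
    """
    obj = canonicalize(s, kind="string")
    if obj.size > max_len:
        raise ValueError(
            f"string of length {obj.size} exceeds the exact-search limit {max_len}; "
            f"raise max_len explicitly to search anyway"
        )
    solver = SplitSolver(_StringProblem())
    index, schedule = solver.solve(obj.payload)
    steps = tuple(
        AssemblyStep(canonicalize(x), canonicalize(y), canonicalize(z)) for x, y, z in schedule
    )
    pathway = AssemblyPathway(target=obj, steps=steps)
    pathway.validate()
    assert pathway.length == index
    return index, pathway


def assembly_index(obj: AssemblyObject | str | int, **kwargs) -> tuple[int, AssemblyPathway]:
    """Assembly index of any supported object kind, with pathway."""
    obj = canonicalize(obj)
    if obj.kind == "string":
        return assembly_index_string(obj, **kwargs)
    if obj.kind == "homopolymer":
        res = chains.addition_chain_min(obj.payload, **kwargs)
        steps = []
        built = {1}
        for value in res.chain[1:]:
            # deterministic operand choice: largest feasible left part
            left = max(a for a in built if value - a in built)
            steps.append(
                AssemblyStep(canonicalize(left), canonicalize(value - left), canonicalize(value))
            )
            built.add(value)
        pathway = AssemblyPathway(target=obj, steps=tuple(steps))
        pathway.validate()
        return res.index, pathway
    from .molecules import molecular_assembly_index

    return molecular_assembly_index(obj.payload, **kwargs)
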