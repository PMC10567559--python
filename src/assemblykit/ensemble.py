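"""The assembly equation.

For an ensemble of N unique objects with assembly indices a_i and integer
copy numbers n_i (N_T = sum n_i total objects), the assembly of the ensemble
is

    A = sum_i  e^{a_i} (n_i - 1) / N_T

A is zero exactly when every object is a singleton: copies of a high-index
object are what signal a non-random generative process, and each additional
copy contributes a fixed e^{a_i}/N_T once the object has been discovered.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

__all__ = ["EnsembleRecord", "Ensemble", "assembly_A", "ensemble_from_objects"]


@dataclass(frozen=True)
class EnsembleRecord:
    object_id: str
    assembly_index: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.assembly_index < 0:
            raise ValueError(f"{self.object_id}: assembly index must be >= 0")
        if self.copy_number < 1:
            raise ValueError(f"{self.object_id}: copy number must be >= 1")


@dataclass(frozen=True)
class Ensemble:
    """Unique objects with copy numbers; the input to the assembly equation."""

    records: tuple[EnsembleRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("ensemble must contain at least one record")
        ids = [r.object_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("ensemble object ids must be unique")

    @property
    def N(self) -> int:
        """Number of unique objects."""
        return len(self.records)

    @property
    def N_T(self) -> int:
        """Total object count, sum of copy numbers."""
        return sum(r.copy_number for r in self.records)

    def contributions(self) -> list[tuple[str, float]]:
        """Per-record terms e^{a_i} (n_i - 1) / N_T."""
        nt = self.N_T
        return [
            (r.object_id, math.exp(r.assembly_index) * (r.copy_number - 1) / nt)
            for r in self.records
        ]

    def assembly(self) -> float:
        return sum(c for _, c in self.contributions())


def assembly_A(ens: Ensemble) -> float:
    """Assembly of the ensemble (>= 0; zero iff all copy numbers are 1)."""
    return ens.assembly()


def ensemble_from_objects(
    objects: Sequence, index_fn: Callable, ids: Sequence[str] | None = None
) -> Ensemble:
    """Group raw objects (with multiplicity) into an ensemble.

    ``index_fn`` maps one canonical object to its assembly index; it is
    called once per unique object.  Identical objects are detected via
    :func:`assemblykit.objects.canonicalize`.
    """
    from .objects import canonicalize
    from .objects import _obj_key  # canonical equality key

    if not objects:
        raise ValueError("cannot build an ensemble from an empty object list")
    groups: dict = {}
    for obj in objects:
        canon = canonicalize(obj)
        key = _obj_key(canon)
        if key in groups:
            groups[key][1] += 1
        else:
            groups[key] = [canon, 1]
    records = []
    for canon, count in groups.values():
        try:
            a = index_fn(canon)
        except Exception as exc:
            raise RuntimeError(f"assembly index computation failed for {canon}: {exc}") from exc
        if isinstance(a, tuple):  # allow (index, pathway) returns
            a = a[0]
        records.append(
            EnsembleRecord(object_id=str(canon), assembly_index=int(a), copy_number=count)
        )
    return Ensemble(records=tuple(records))


def coerce_copy_number(value: float, object_id: str = "?") -> int:
    """Round a fractional abundance down to an integer count, with a warning.

    Copy numbers are counts of identical objects; fractional abundances from
    instruments must be floored to the number of whole copies observed.
    """
    n = int(value)
    if n != value:
        warnings.warn(
            f"{object_id}: fractional copy number {value} floored to {n}", stacklevel=2
        )
    if n < 1:
        raise ValueError(f"{object_id}: copy number must be >= 1, got {value}")
    return n
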