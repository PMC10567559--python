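"""Bond-based molecular assembly index.

A molecule is a connected heavy-atom graph whose elementary units are its
bonds, labelled by the element pair and bond order.  A join fuses two
previously built structures on a shared set of atoms; every bond of the
product comes from exactly one operand.  The assembly index is the minimal
number of joins needed to build the molecule from single bonds, reusing any
structure already built on the pathway (duplicated substructures are the
entire source of shortcuts below the bond-by-bond upper bound of E - 1).

The exact search runs top-down (see :mod:`assemblykit._search`): reverse one
join at a time by splitting the largest pending fragment into two connected,
edge-disjoint parts, deduplicating isomorphic fragments.  Isomorphism is
decided by BLISS canonical certificates with bond orders encoded as coloured
edge-vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import igraph as ig

from ._search import SplitProblem, SplitSolver

__all__ = [
    "MolGraph",
    "parse_molecule",
    "molecular_assembly_index",
    "join_graphs",
    "is_valid_join",
    "DEFAULT_BOND_LIMIT",
]

#: Largest bond count for which the exact search is attempted by default.
DEFAULT_BOND_LIMIT = 30

_RDKIT_BOND_LABELS = {"SINGLE": "1", "DOUBLE": "2", "TRIPLE": "3", "AROMATIC": "a"}


def _compute_certificate(atoms: Sequence[str], bonds: Sequence[tuple[int, int, str]]):
    """Isomorphism-invariant certificate of a labelled graph.

    Bond labels are encoded by inserting one coloured vertex per bond, then
    the coloured graph is canonicalized with BLISS.  Certificates of two
    graphs are equal iff the graphs are isomorphic with matching element and
    bond-order labels.
    """
    n = len(atoms)
    elems = tuple(sorted(set(atoms)))
    blabs = tuple(sorted({lab for _, _, lab in bonds}))
    e_code = {e: i for i, e in enumerate(elems)}
    b_code = {b: i for i, b in enumerate(blabs)}
    colors = [e_code[a] for a in atoms] + [len(elems) + b_code[lab] for _, _, lab in bonds]
    edges = []
    for k, (i, j, _) in enumerate(bonds):
        bv = n + k
        edges.append((i, bv))
        edges.append((j, bv))
    g = ig.Graph(n=n + len(bonds), edges=edges)
    perm = g.canonical_permutation(color=colors)
    new_colors = [0] * len(colors)
    for v, c in enumerate(colors):
        new_colors[perm[v]] = c
    new_edges = tuple(sorted(tuple(sorted((perm[a], perm[b]))) for a, b in edges))
    return (elems, blabs, tuple(new_colors), new_edges)


@dataclass(frozen=True)
class MolGraph:
    """Connected heavy-atom molecular graph (hydrogens suppressed).

    ``atoms`` are element symbols; ``bonds`` are ``(i, j, order_label)`` with
    ``i < j``.  ``edge_ids`` optionally records which bonds of a parent
    molecule this fragment covers (set for pathway intermediates).
    """

    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]
    edge_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.bonds) < 1:
            raise ValueError("molgraph must contain at least one bond")
        if not self._is_connected():
            raise ValueError("molgraph must be connected")

    def _is_connected(self) -> bool:
        adj: dict[int, list[int]] = {}
        for i, j, _ in self.bonds:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        used = set(adj)
        if set(range(len(self.atoms))) - used:
            return False  # isolated atom
        start = next(iter(used))
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return seen == used

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    @property
    def formula(self) -> str:
        counts: dict[str, int] = {}
        for a in self.atoms:
            counts[a] = counts.get(a, 0) + 1
        return "".join(f"{e}{counts[e] if counts[e] > 1 else ''}" for e in sorted(counts))

    @cached_property
    def certificate(self):
        return _compute_certificate(self.atoms, self.bonds)

    def is_isomorphic(self, other: "MolGraph") -> bool:
        return self.certificate == other.certificate

    def elementary_certificates(self) -> set:
        """Certificates of the single-bond structures occurring in this graph."""
        out = set()
        for i, j, lab in self.bonds:
            out.add(_compute_certificate((self.atoms[i], self.atoms[j]), ((0, 1, lab),)))
        return out

    def subgraph(self, edge_ids: Iterable[int]) -> "MolGraph":
        """Edge-induced subgraph, remembering the parent bond indices."""
        edge_ids = tuple(sorted(edge_ids))
        atom_ids = sorted({a for e in edge_ids for a in self.bonds[e][:2]})
        remap = {a: k for k, a in enumerate(atom_ids)}
        bonds = []
        for e in edge_ids:
            i, j, lab = self.bonds[e]
            bonds.append((min(remap[i], remap[j]), max(remap[i], remap[j]), lab))
        return MolGraph(
            atoms=tuple(self.atoms[a] for a in atom_ids),
            bonds=tuple(sorted(bonds)),
            edge_ids=edge_ids,
        )


def parse_molecule(text: str) -> MolGraph:
    """Parse a SMILES string or a V2000 molfile into a heavy-atom graph.

    Aromatic bonds carry a single uniform label; stereochemistry is ignored.
    """
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
    if "V2000" in text or "\n" in text.strip():
        mol = Chem.MolFromMolBlock(text, sanitize=True)
    else:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise ValueError(f"could not parse molecule input: {text[:80]!r}")
    mol = Chem.RemoveHs(mol)
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    remap = {idx: k for k, idx in enumerate(heavy)}
    atoms = tuple(mol.GetAtomWithIdx(idx).GetSymbol() for idx in heavy)
    bonds = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in remap or j not in remap:
            continue
        lab = _RDKIT_BOND_LABELS.get(str(b.GetBondType()), str(b.GetBondType()))
        bonds.append((min(remap[i], remap[j]), max(remap[i], remap[j]), lab))
    if not bonds:
        raise ValueError(f"molecule has no heavy-atom bonds: {text[:80]!r}")
    return MolGraph(atoms=atoms, bonds=tuple(sorted(bonds)))


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------


class _MolProblem(SplitProblem[frozenset]):
    """Split search over edge-index subsets of one root molecule.

    Every pathway intermediate is (isomorphic to) an edge-induced subgraph of
    the target, so fragments are represented as frozensets of root bond
    indices; certificates are cached per subset.
    """

    def __init__(self, root: MolGraph, allow_ring_closure: bool = True):
        self.root = root
        self.allow_ring_closure = allow_ring_closure
        self.linear_available = allow_ring_closure
        n_edges = root.n_bonds
        self._adj: list[set[int]] = [set() for _ in range(n_edges)]
        atom_edges: dict[int, list[int]] = {}
        for e, (i, j, _) in enumerate(root.bonds):
            atom_edges.setdefault(i, []).append(e)
            atom_edges.setdefault(j, []).append(e)
        for es in atom_edges.values():
            for a in es:
                for b in es:
                    if a != b:
                        self._adj[a].add(b)
        self._cert_cache: dict[frozenset, object] = {}
        self._motif_cache: dict[frozenset, list[tuple[object, frozenset]]] = {}

    # -- SplitProblem interface -------------------------------------------

    def size(self, item: frozenset) -> int:
        return len(item)

    def key(self, item: frozenset):
        cert = self._cert_cache.get(item)
        if cert is None:
            cert = self.root.subgraph(item).certificate
            self._cert_cache[item] = cert
        return cert

    def splits(self, item: frozenset):
        for x in self._connected_bipartitions(item):
            y = item - x
            if not self.allow_ring_closure and (
                self._is_double_fused_single(x, y) or self._is_double_fused_single(y, x)
            ):
                continue
            yield x, y

    def has_duplicate_pair(self, items) -> bool:
        motifs: dict[object, list[tuple[int, frozenset]]] = {}
        for idx, item in enumerate(items):
            for cert, pair in self._two_edge_motifs(item):
                bucket = motifs.setdefault(cert, [])
                for prev_idx, prev_pair in bucket:
                    if prev_idx != idx or not (prev_pair & pair):
                        return True
                bucket.append((idx, pair))
        return False

    def linear_steps(self, item: frozenset):
        order = self._connected_edge_order(item)
        steps = []
        for k in range(1, len(order)):
            prefix = frozenset(order[:k])
            steps.append((prefix, frozenset({order[k]}), frozenset(order[: k + 1])))
        return steps

    # -- helpers -----------------------------------------------------------

    def _atoms_of(self, item: frozenset) -> set[int]:
        return {a for e in item for a in self.root.bonds[e][:2]}

    def _is_double_fused_single(self, side: frozenset, other: frozenset) -> bool:
        # ring closure: a lone bond both of whose endpoints already exist in
        # the partner structure
        if len(side) != 1:
            return False
        (e,) = side
        i, j, _ = self.root.bonds[e]
        other_atoms = self._atoms_of(other)
        return i in other_atoms and j in other_atoms

    def _two_edge_motifs(self, item: frozenset):
        cached = self._motif_cache.get(item)
        if cached is not None:
            return cached
        out = []
        bonds = self.root.bonds
        atoms = self.root.atoms
        for e in item:
            for f in self._adj[e]:
                if f <= e or f not in item:
                    continue
                i1, j1, l1 = bonds[e]
                i2, j2, l2 = bonds[f]
                shared = ({i1, j1} & {i2, j2}).pop()
                end1 = i1 + j1 - shared
                end2 = i2 + j2 - shared
                cert = (atoms[shared], tuple(sorted(((l1, atoms[end1]), (l2, atoms[end2])))))
                out.append((cert, frozenset({e, f})))
        self._motif_cache[item] = out
        return out

    def _connected_edge_order(self, item: frozenset) -> list[int]:
        start = min(item)
        order = [start]
        seen = {start}
        frontier = [start]
        while frontier:
            e = frontier.pop(0)
            for f in sorted(self._adj[e]):
                if f in item and f not in seen:
                    seen.add(f)
                    order.append(f)
                    frontier.append(f)
        return order

    def _is_connected_subset(self, subset: frozenset) -> bool:
        start = next(iter(subset))
        seen = {start}
        stack = [start]
        while stack:
            for f in self._adj[stack.pop()]:
                if f in subset and f not in seen:
                    seen.add(f)
                    stack.append(f)
        return len(seen) == len(subset)

    def _connected_bipartitions(self, item: frozenset):
        """Connected subsets X containing min(item) with connected complement."""
        start = min(item)
        results: list[frozenset] = []

        def grow(cur: frozenset, ext: list[int], banned: frozenset) -> None:
            if len(cur) < len(item):
                comp = item - cur
                if self._is_connected_subset(comp):
                    results.append(cur)
            local_banned = banned
            while ext:
                c = ext[0]
                ext = ext[1:]
                new_ext = ext + [
                    f
                    for f in sorted(self._adj[c])
                    if f in item and f not in cur and f not in local_banned and f not in ext and f != c
                ]
                grow(cur | {c}, new_ext, local_banned)
                local_banned = local_banned | {c}

        init_ext = sorted(f for f in self._adj[start] if f in item)
        grow(frozenset({start}), init_ext, frozenset())
        return results


def molecular_assembly_index(
    mol: MolGraph | str,
    max_bonds: int = DEFAULT_BOND_LIMIT,
    allow_ring_closure: bool = True,
):
    """Exact molecular assembly index with an attaining pathway.

    ``allow_ring_closure`` toggles whether a lone bond may be fused onto both
    of its endpoints at once (closing a ring in a single join); with the
    toggle off, molecules whose every decomposition needs that move (e.g. a
    bare three-membered ring) are reported unassemblable.
    """
    from .objects import AssemblyPathway, AssemblyStep, canonicalize

    if isinstance(mol, str):
        mol = parse_molecule(mol)
    if mol.n_bonds > max_bonds:
        from .objects import assembly_index_bounds

        lo, hi = assembly_index_bounds(canonicalize(mol))
        raise ValueError(
            f"molecule has {mol.n_bonds} bonds, above the exact-search limit {max_bonds}; "
            f"assembly index is within [{lo}, {hi}]"
        )
    problem = _MolProblem(mol, allow_ring_closure=allow_ring_closure)
    solver = SplitSolver(problem)
    all_edges = frozenset(range(mol.n_bonds))
    index, schedule = solver.solve(all_edges)

    def to_obj(edge_set: frozenset):
        return canonicalize(mol.subgraph(edge_set))

    steps = tuple(AssemblyStep(to_obj(x), to_obj(y), to_obj(z)) for x, y, z in schedule)
    pathway = AssemblyPathway(target=canonicalize(mol), steps=steps)
    pathway.validate()
    return index, pathway


# ---------------------------------------------------------------------------
# joins
# ---------------------------------------------------------------------------


def join_graphs(x: MolGraph, y: MolGraph, fuse: dict[int, int]) -> MolGraph:
    """Join two structures by fusing atoms ``fuse[y_atom] = x_atom``.

    Every bond of the product comes from exactly one operand; fusing must not
    make two operand bonds coincide.  Fused atoms must carry the same element.
    """
    for ya, xa in fuse.items():
        if y.atoms[ya] != x.atoms[xa]:
            raise ValueError(f"cannot fuse {y.atoms[ya]} onto {x.atoms[xa]}")
    remap: dict[int, int] = {}
    atoms = list(x.atoms)
    for ya in range(len(y.atoms)):
        if ya in fuse:
            remap[ya] = fuse[ya]
        else:
            remap[ya] = len(atoms)
            atoms.append(y.atoms[ya])
    bonds = list(x.bonds)
    existing = {(i, j) for i, j, _ in x.bonds}
    for i, j, lab in y.bonds:
        a, b = sorted((remap[i], remap[j]))
        if (a, b) in existing:
            raise ValueError("join would collapse two operand bonds onto one")
        bonds.append((a, b, lab))
    return MolGraph(atoms=tuple(atoms), bonds=tuple(sorted(bonds)))


def is_valid_join(x: MolGraph, y: MolGraph, product: MolGraph) -> bool:
    """Does some atom fusion of ``x`` and ``y`` yield ``product``?

    Fast path when all three fragments carry parent bond indices (pathway
    intermediates): the product's bond set must be the disjoint union of the
    operands'.  Otherwise search for an edge bipartition of the product whose
    parts are isomorphic to the operands.
    """
    if x.edge_ids is not None and y.edge_ids is not None and product.edge_ids is not None:
        xs, ys, ps = set(x.edge_ids), set(y.edge_ids), set(product.edge_ids)
        return not (xs & ys) and (xs | ys) == ps
    if x.n_bonds + y.n_bonds != product.n_bonds:
        return False
    problem = _MolProblem(product)
    whole = frozenset(range(product.n_bonds))
    cx, cy = x.certificate, y.certificate
    for a in problem._connected_bipartitions(whole):
        b = whole - a
        ca, cb = problem.key(a), problem.key(b)
        if (ca, cb) == (cx, cy) or (ca, cb) == (cy, cx):
            return True
    return False
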