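"""Seeded synthetic inputs: strings, homopolymers, molecules, ensembles.

Everything is generated from an explicit seed — no external data is needed
anywhere in the package.  Strings can be produced by a random forward
assembly process, which yields a constructive upper bound on their assembly
index (the number of joins used to build them).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import Ensemble, EnsembleRecord
from .molecules import MolGraph

__all__ = [
    "random_strings",
    "assembled_strings",
    "homopolymer_lengths",
    "random_molecules",
    "random_ensemble",
    "make_fixtures",
]

# heavy-atom valence caps used when growing random molecules
_VALENCE = {"C": 4, "N": 3, "O": 2}
_BOND_ORDER_VAL = {"1": 1, "2": 2}


def random_strings(n: int, length: int, alphabet: str = "AB",
                   rng: np.random.Generator | None = None) -> list[str]:
    rng = rng or np.random.default_rng(0)
    return ["".join(rng.choice(list(alphabet), size=length)) for _ in range(n)]


def assembled_strings(n: int, joins: int, alphabet: str = "AB",
                      rng: np.random.Generator | None = None) -> list[tuple[str, int]]:
    """Strings built by a random forward assembly process.

    Each string is the product of ``joins`` recorded join steps starting from
    single characters, so its assembly index is at most ``joins`` by
    construction.  Returns (string, upper_bound) pairs.
    """
    rng = rng or np.random.default_rng(0)
    out = []
    for _ in range(n):
        pool = list(alphabet)
        product = pool[0]
        for _ in range(joins):
            x = pool[rng.integers(len(pool))]
            y = pool[rng.integers(len(pool))]
            product = x + y
            pool.append(product)
        out.append((product, joins))
    return out


def homopolymer_lengths(n: int, max_len: int = 64,
                        rng: np.random.Generator | None = None) -> list[int]:
    rng = rng or np.random.default_rng(0)
    return [int(v) for v in rng.integers(1, max_len + 1, size=n)]


def random_molecules(n: int, max_bonds: int = 12,
                     rng: np.random.Generator | None = None) -> list[MolGraph]:
    """Random connected heavy-atom graphs respecting element valence caps.

    Grown as a random tree of C/N/O atoms with single/double bonds, with an
    occasional ring-closing bond when valences allow; always sanitizable, so
    the graphs can round-trip through molfile writers.
    """
    rng = rng or np.random.default_rng(0)
    mols = []
    for _ in range(n):
        n_bonds = int(rng.integers(1, max_bonds + 1))
        elements = ["C", "N", "O"]
        atoms = [elements[rng.integers(3)]]
        used = [0]  # valence used per atom
        bonds: list[tuple[int, int, str]] = []
        while len(bonds) < n_bonds:
            order = "2" if rng.random() < 0.2 else "1"
            need = _BOND_ORDER_VAL[order]
            anchors = [i for i, a in enumerate(atoms) if _VALENCE[a] - used[i] >= need]
            if not anchors:
                break
            i = int(anchors[rng.integers(len(anchors))])
            closable = [
                j
                for j in anchors
                if j != i
                and _VALENCE[atoms[j]] - used[j] >= need
                and not any({i, j} == {b[0], b[1]} for b in bonds)
            ]
            if closable and len(atoms) > 3 and rng.random() < 0.15:
                j = int(closable[rng.integers(len(closable))])
            else:
                elem = elements[rng.integers(3)]
                if _VALENCE[elem] < need:
                    elem = "C"
                atoms.append(elem)
                used.append(0)
                j = len(atoms) - 1
            bonds.append((min(i, j), max(i, j), order))
            used[i] += need
            used[j] += need
        if not bonds:
            bonds = [(0, 1, "1")]
            atoms = ["C", "C"]
        mols.append(MolGraph(atoms=tuple(atoms), bonds=tuple(sorted(bonds))))
    return mols


def random_ensemble(n: int, max_index: int = 8, max_copies: int = 10,
                    rng: np.random.Generator | None = None,
                    singletons: bool = False) -> Ensemble:
    rng = rng or np.random.default_rng(0)
    records = tuple(
        EnsembleRecord(
            object_id=f"obj{i}",
            assembly_index=int(rng.integers(0, max_index + 1)),
            copy_number=1 if singletons else int(rng.integers(1, max_copies + 1)),
        )
        for i in range(n)
    )
    return Ensemble(records=records)


def _mol_to_molblock(mol: MolGraph, name: str) -> str:
    from rdkit import Chem

    rw = Chem.RWMol()
    for a in mol.atoms:
        rw.AddAtom(Chem.Atom(a))
    order_map = {"1": Chem.BondType.SINGLE, "2": Chem.BondType.DOUBLE,
                 "3": Chem.BondType.TRIPLE, "a": Chem.BondType.AROMATIC}
    for i, j, lab in mol.bonds:
        rw.AddBond(i, j, order_map[lab])
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    m.SetProp("_Name", name)
    return Chem.MolToMolBlock(m)


def make_fixtures(kind: str, outdir, seed: int = 0, n: int = 10, **params) -> list[Path]:
    """Write seeded fixture files; identical seeds give identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []
    if kind == "strings":
        pairs = assembled_strings(n, joins=params.get("joins", 7),
                                  alphabet=params.get("alphabet", "AB"), rng=rng)
        path = outdir / "strings.fasta"
        with open(path, "w") as fh:
            for i, (s, bound) in enumerate(pairs):
                fh.write(f">str{i} max_index={bound}\n{s}\n")
        written.append(path)
    elif kind == "homopolymers":
        lengths = homopolymer_lengths(n, max_len=params.get("max_len", 64), rng=rng)
        path = outdir / "homopolymers.tsv"
        pd.DataFrame({"length": lengths}).to_csv(path, sep="\t", index=False)
        written.append(path)
    elif kind == "molecules":
        mols = random_molecules(n, max_bonds=params.get("max_bonds", 12), rng=rng)
        path = outdir / "molecules.sdf"
        with open(path, "w") as fh:
            for i, mol in enumerate(mols):
                fh.write(_mol_to_molblock(mol, f"mol{i}"))
                fh.write("$$$$\n")
        written.append(path)
    elif kind == "ensembles":
        from .io import write_ensemble_tsv

        ens = random_ensemble(n, max_index=params.get("max_index", 8),
                              max_copies=params.get("max_copies", 10), rng=rng,
                              singletons=params.get("singletons", False))
        path = outdir / "ensemble.tsv"
        write_ensemble_tsv(ens, path)
        written.append(path)
    else:
        raise ValueError(
            f"unknown fixture kind {kind!r}; "
            "expected strings|homopolymers|molecules|ensembles"
        )
    return written
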