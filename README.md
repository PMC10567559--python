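# assemblykit

A toolkit for assembly theory: exact assembly indices and shortest assembly
pathways for discrete objects (character strings, homopolymers, small
molecular graphs), the ensemble assembly measure, and stochastic forward
simulations of assembly processes with and without selection.

Assembly theory treats an object not as a point particle but as something
finite, distinguishable and breakable, characterized by how it can be built:
starting from elementary building blocks (characters, monomers, chemical
bonds), structures are joined recursively, and anything built along the way
can be reused at no extra cost. The **assembly index** `a_i` of an object is
the length of its shortest such pathway. A single complex object can arise by
chance; many identical copies of a high-index object cannot. The **assembly**
of an ensemble of `N` unique objects with copy numbers `n_i` (total count
`N_T = Σ n_i`) quantifies that:

    A = Σ_{i=1..N}  e^{a_i} · (n_i − 1) / N_T

`A` is zero exactly when every object is a singleton and grows with both
copy number and assembly index, making it a measure of how much selection a
generative process must have exerted.

The package is aimed at researchers in cheminformatics, origins-of-life
chemistry and complexity science who want to compute assembly indices for
molecules and sequences, evaluate `A` on observed ensembles, or reproduce
the canonical simulation results of the theory: directed (selective)
exploration of a polymer assembly space yields a lower exploration ratio and
higher maximum assembly index than undirected exploration, and coupling a
discovery rate `k_d` (timescale τ_d) with a copy-production rate `k_p`
(timescale τ_p) shows that high-assembly ensembles only emerge when the two
timescales are comparable.

## What is inside

| module | contents |
| --- | --- |
| `assemblykit.objects` | `AssemblyObject`/`AssemblyPathway` types, joins, exact string assembly index |
| `assemblykit.chains` | minimal addition chains = homopolymer assembly indices |
| `assemblykit.molecules` | heavy-atom `MolGraph`, SMILES/molfile parsing (RDKit), exact bond-based molecular assembly index (branch-and-bound with substructure reuse) |
| `assemblykit.ensemble` | the assembly equation and ensemble bookkeeping |
| `assemblykit.simulate` | undirected/directed forward polymer assembly, joint assembly spaces, exploration ratio |
| `assemblykit.dynamics` | discovery cascade `dN_{a+1}/dt = k_d N_a^α`, stochastic engine, discovery+production kinetics under a mass budget, regime classification |
| `assemblykit.io`, `assemblykit.fixtures`, `assemblykit.cli` | TSV/FASTA/SDF/GraphML/JSON formats, run manifests, seeded synthetic fixtures, `assembly` command-line tool |

## Worked example

Assembly index of diethyl phthalate — a benzene ring with two ethyl ester
arms, 16 heavy-atom bonds:

```python
from assemblykit import molecular_assembly_index, parse_molecule

mol = parse_molecule("CCOC(=O)c1ccccc1C(=O)OCC")
index, pathway = molecular_assembly_index(mol)
print(f"diethyl phthalate ({mol.formula}, {mol.n_bonds} bonds): assembly index {index}")
for i, step in enumerate(pathway.steps, 1):
    print(f"  step {i}: {step.left} + {step.right} -> {step.product}")
```

prints

```
diethyl phthalate (C12O4, 16 bonds): assembly index 8
  step 1: [CO|1 bonds] + [C2|1 bonds] -> [C2O|2 bonds]
  step 2: [C2|1 bonds] + [C2|1 bonds] -> [C3|2 bonds]
  step 3: [C2O|2 bonds] + [CO|1 bonds] -> [C2O2|3 bonds]
  step 4: [C3|2 bonds] + [C2|1 bonds] -> [C4|3 bonds]
  step 5: [C2O2|3 bonds] + [C2O|2 bonds] -> [C4O2|5 bonds]
  step 6: [C4O2|5 bonds] + [C4|3 bonds] -> [C7O2|8 bonds]
  step 7: [C4|3 bonds] + [C4O2|5 bonds] -> [C7O2|8 bonds]
  step 8: [C7O2|8 bonds] + [C7O2|8 bonds] -> [C12O4|16 bonds]
```

Sixteen bonds would need 15 joins one at a time; reuse of duplicated motifs
(the two identical ester arms, repeated aromatic segments) compresses the
shortest pathway to 8 joins. The final step fuses two 8-bond halves of the
molecule, each assembled from the shared intermediates built in steps 1–5.
(Shortest pathways need not be unique; the solver returns one deterministic
minimal pathway, here with two non-isomorphic halves that share their
intermediates.)

Measuring an ensemble from a TSV of (object, assembly index, copy number):

```sh
$ printf 'object_id\tassembly_index\tcopy_number\nATP\t7\t20\nglycine\t3\t15\ntar_1\t9\t1\n' > ens.tsv
$ assembly measure --in ens.tsv
N	3
N_T	36
A	586.59
contribution	ATP	578.779
contribution	glycine	7.81104
contribution	tar_1	0
```

Twenty copies of a 7-step molecule dominate `A`; the complex but unreplicated
`tar_1` contributes nothing — copy number, not rarity, is the signal of
selection.

Other entry points work the same way (`assembly ai` for FASTA/SDF files of
objects, `assembly simulate` for directed/undirected exploration
experiments, `assembly dynamics` for discovery+production kinetics,
`assembly jspace` for joint assembly spaces, `assembly fixtures` for seeded
synthetic inputs). Every stochastic command records its seed in a manifest
and reruns bit-identically.

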