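# Methods

## Objects, joins, and the assembly index

An object is anything finite and breakable into elementary units drawn from a
declared set. Three kinds are implemented:

* **strings** — units are characters; a join is ordered concatenation of two
  available structures;
* **homopolymers** — an object is its length `n`; units are monomers and a
  join adds two available lengths (commutative);
* **molecular graphs** — connected heavy-atom graphs with element labels and
  bond-order labels (single/double/triple, aromatic as its own uniform
  label; stereochemistry ignored); units are bonds. A join forms the union
  of two available structures fused on a shared atom set; every bond of the
  product comes from exactly one operand.

An assembly pathway is an ordered sequence of joins whose operands are
elementary units or products of strictly earlier steps, ending at the
target; once built, a structure is reusable at no extra cost. The assembly
index is the minimal pathway length. General bounds: `ceil(log2 size) <=
a <= size - 1` (a join at most doubles the size; unit-by-unit growth always
works).

### Exact search

The minimal pathway length equals the minimal number of *distinct*
structures (up to the kind's equality: string identity, length equality,
labelled-graph isomorphism) appearing in any recursive decomposition of the
target. The solver exploits this directly and searches top-down:

* a state is the set of structures still to be built, deduplicated by
  canonical form — building one copy serves every use;
* one move reverses a join: the largest pending structure is split into two
  valid parts (strings: a cut position; graphs: a connected edge bipartition),
  and non-elementary parts enter the pending set;
* splitting a largest structure first is lossless: parts are strictly
  smaller than everything already split, so no structure is ever rebuilt,
  and the number of moves equals the number of distinct structures on the
  pathway.

Two results close the search quickly. If the pending set contains no two
disjoint isomorphic motifs of two or more units, reuse is impossible and the
remaining cost is exactly `Σ (size − 1)` (checked via 2-unit motifs: any
larger duplicated pair contains a duplicated 2-unit pair). Otherwise the
state cost is bounded below by `max(#pending, ceil(log2 max_size))`.
Branch-and-bound with memoization on the pending-set certificate does the
rest; split candidates are tried doubling-first (both parts isomorphic),
then by balance. Pathways are reconstructed from the stored optimal split
per state and replay-validated.

This search replaces a bottom-up iterative-deepening pool search as the
production algorithm because it is equivalent (the max-first scheduling
argument above) and orders of magnitude faster; the bottom-up pool search
survives in the test suite as the independent oracle for all three kinds.

Shortest pathways are generally not unique. The solver's tie-break is the
fixed, deterministic exploration order of splits, so repeated runs return
the identical pathway; no claim is made that it is the lexicographically
smallest among co-minimal pathways.

Graph isomorphism is decided by canonical certificates: bond-order labels
are encoded as coloured edge-vertices and the coloured graph is
canonicalized with BLISS (python-igraph). Certificates are cached per edge
subset of the root molecule.

### Homopolymers and addition chains

The homopolymer assembly index of length `n` is the minimal addition-chain
length for `n` (a chain `1 = c_0 < ... < c_r = n`, each element a sum of two
earlier ones). The search is iterative-deepening DFS over strictly
increasing chains, pruned by the doubling bound `c_k · 2^(r−k) >= n` and
started at `max(ceil(log2 n), ceil(log2 n + log2 v(n) − 2.13))` with `v`
the binary weight (Schönhage's lower bound). Exact by default up to
`n = 2^16`; beyond that the binary-method chain (length `~ log2 n +
popcount(n) − 1`) is returned, explicitly flagged `exact=False`. Exact
search cost is very uneven in `n` — adversarial values near `2^k − 1`
take orders of magnitude longer than typical ones — which motivates the
smaller default limit used inside simulations (below).

### Ring closures

For molecular graphs, a join that fuses a lone bond onto both of its
endpoints closes a ring in one step. This move is allowed by default and
can be disabled (`allow_ring_closure=False`); with it disabled a bare
three-membered ring has no valid decomposition at all (its only split is a
2-path plus a double-fused single bond) and the solver reports the molecule
unassemblable rather than guessing. Rings closed by motifs of two or more
bonds (e.g. benzene from a 4-path and a 2-path) are unaffected by the
toggle.

## The assembly equation

`A = Σ e^{a_i} (n_i − 1)/N_T` over the ensemble's unique objects. Copy
numbers are integer counts; fractional abundances are floored with a
warning. `A = 0` iff every object is a singleton. Because of the `1/N_T`
normalization, `A` itself is not monotone in a single copy number (adding
copies of a low-index object can dilute the ensemble); what is exactly
affine is the unnormalized assembly: one extra copy of object `j` adds
`e^{a_j}` to `A · N_T`, the fixed per-copy cost once an object has been
discovered. The tests check that identity, plus strict growth of `A` in any
`a_i` with `n_i >= 2`. Objects with `n_i = 0` (never observed) are excluded
from ensembles. The joint/co-assembly correction for ensembles with shared
history is deliberately not implemented; `ensemble_from_objects` is the
extension point where a shared-pathway-aware index function would plug in.

## Forward polymer simulation

The pool starts as `{1}` (the monomer). Undirected mode joins two polymers
drawn uniformly at random (with replacement by default; both
without-replacement and abundance-weighted sampling are config options)
from the set of unique discovered lengths; directed mode joins the most
recently created polymer with a uniform random member. Products re-enter
the pool only if new, so the pool after `s` steps has at most `s + 1`
members; "observed" means ever discovered during the run.

The joint assembly space of a run is the union of one minimal addition
chain per observed polymer, with deterministic tie-breaking
(lexicographically smallest increasing chain), so the contingent node set is
a function of the observed set alone. The exploration ratio is observed
nodes over all nodes.

Directed runs reach astronomical lengths (doubling per novel creation), so
inside simulations exact chains are computed up to `exact_chain_limit = 256`
by default and the binary-method chain is used above it, flagged
approximate — mirroring the leading-order `log2(n)` treatment of the
maximum assembly index, which is reported alongside. Defaults follow the
canonical experiment (25 runs, up to 10^4 steps; per-run generators depend
only on (seed, run index) so modes are paired at matched seeds); the
distribution-level tests use 25 paired runs of 10^3 steps, which already
separates the modes by orders of magnitude in both statistics.

## Selection dynamics

Discovery follows the cascade `dN_{a+1}/dt = k_d (N_a)^α` with `N_1`
a constant source, `α = 1` undirected expansion, `α < 1` selective reuse.

* **ODE integrator** — adaptive RK (DOP853), default `rtol 1e-10`,
  `atol 1e-12`. For `α = 1` the plain linear cascade is integrated and
  matches the closed form `N_a(t) = N_1 (k_d t)^{a−1}/(a−1)!`. For `α < 1`,
  `N^α` is non-Lipschitz at zero and the model is given an activation rule:
  a level feeds the next only once it holds at least one whole object
  (`activation_threshold = 1.0`, configurable). Sub-linear reuse presupposes
  an assembled object to reuse; with `α = 0` this reproduces a discovery
  front advancing one level per `1/k_d`. Activations are located by event
  detection and the integration restarts at each.
* **Stochastic engine** — Gillespie: each event picks a level with
  probability `∝ (N_a)^α` and increments `N_{a+1}`; waiting times are
  exponential in the total rate. For `α = 1` propensities are linear, so
  replicate means reproduce the closed form exactly (tested to 3 Monte
  Carlo standard errors). Since every event creates exactly one object,
  selection signatures are compared at matched *time* horizons with matched
  `k_d`, where `α < 1` yields fewer unique objects and a log-growth slope
  that decreases over successive windows (slower than exponential).
* **Discovery + production** — discovery events as above; each discovered
  object additionally produces copies at the homogeneous rate `k_p`
  (production events pick a discovered object uniformly). Every discovery
  or production consumes one unit of a shared mass budget (default 100);
  the run ends cleanly when the budget is spent, `t_end` is reached, or all
  rates vanish. The seed object is elementary (`a = 0`, one copy). `A(t)`
  is evaluated with the assembly equation after every event. This coupling
  is a phenomenological choice — the mass-action treatment fixes only the
  two rates and the budget, not a unique microscopic scheme — and is
  validated against the qualitative regime claims: `k_p = 0` gives
  `A ≡ 0`; `τ_p/τ_d ≫ 1` gives a combinatorial explosion of singletons;
  `τ_p/τ_d ≪ 1` concentrates mass in copies of low-index objects; the final
  `A` over a timescale-ratio grid peaks at an interior ratio.
* **Regimes** — `regime_classify` thresholds `τ_d/τ_p` at `r_low = 0.1`
  and `r_high = 10` (configurable): 1 = discovery-dominated, 2 =
  production-dominated, 3 = comparable timescales, the only regime where
  selection can emerge.

Fitting `(α, k_d)` to empirical time series is exposed as a stub
(`estimate_selection_params`) and intentionally unimplemented.

## Synthetic data

`assemblykit.fixtures` generates all test inputs from explicit seeds:
uniform random strings; strings built by a recorded random join process
(their join count is a constructive upper bound on the assembly index);
homopolymer length sets; random connected C/N/O graphs grown under valence
caps (so they sanitize and round-trip through molfile writers) with
occasional ring closures; ensembles with controlled index/copy mixtures.
These fixtures probe the combinatorics of the methods, not chemistry: random
valence-respecting graphs are not drawn from any realistic molecular
distribution, string fixtures have no sequence statistics of real
biopolymers, and passing tests therefore certify algorithmic correctness
and the theory's internal predictions, not behaviour on laboratory data.

## Numerical and scale choices

* Exact-search defaults: strings ≤ 25 characters, molecules ≤ 30 bonds,
  chains ≤ 2^16 — beyond them the string and molecule searches refuse
  explicitly (no silent heuristic) and chains fall back to the flagged
  binary method.
* Oracle-equivalence tests cover all binary strings to length 8, all
  `n ≤ 64`, and every connected unlabeled graph shape with ≤ 5 edges under
  several seeded C/N/O + single/double labelings (the full labeled
  enumeration is combinatorially enormous at no extra informational value).
* Stochastic property tests use 10–60 seeded replicates; paired-seed
  designs and one-sided sign tests at `p < 0.01` for the
  directed-vs-undirected contrast.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; reruns are bit-identical, and manifests record the seed next to
  every output.

## Known limitations

* Exact molecular search is practical to a few tens of bonds (the worked
  16-bond example solves in about a second; cost grows steeply with bond
  count and symmetry); there is no approximate mode for larger molecules by
  design.
* Minimal addition chains for adversarial `n` (high binary weight) are
  slow near the 2^16 default limit; simulations therefore use the smaller
  exact limit with the flagged fallback.
* String joining is concatenation only (no reversal or other operators);
  heteropolymer forward simulation and spatial/compartment models are out
  of scope.
* Copy-number production is homogeneous across objects; no fitness
  differences, degradation, or object-specific kinetics.
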