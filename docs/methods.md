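# Methods

## Model and assumptions

The engine treats a protein structure as an ordered list of point
residues: each residue is collapsed to the unweighted mean coordinate of
its side-chain heavy atoms (all non-hydrogen atoms except the backbone
N, CA, C, O and OXT). Glycine, having no side-chain heavy atom, uses its
CA. Hydrogens never contribute — they are usually absent from X-ray
models anyway — and neither do waters, ligands, cofactors or any other
non-amino-acid heteroatom: ligand independence is a structural property
of the input model, not a post-hoc filter. Multi-model files contribute
only their first model, and alternate conformations collapse to the
first-listed conformer of each atom, so the geometry of a given file is
a single deterministic point set. Modified residues with a standard
parent (e.g. selenomethionine) map to the parent code; residues with no
standard parent are skipped with a warning.

A *3D pattern* is a set of residues anchored to one reference
coordinate. Reference coordinates form the "virtual grid": the midpoint
of every unordered residue pair whose centers lie within the grid radius
G<sub>r</sub> of each other (inclusive comparison). Midpoints are not
deduplicated — two residue pairs that happen to bisect at the same point
yield two grid points — so the grid size equals the number of
qualifying pairs and the all-vs-all comparison size is exactly the
product of the two structures' pattern counts. Anchors are labelled
`Atom1 … AtomN` in pair enumeration order (file order, i < j), and
patterns inherit their anchor's label in every report.

Pattern growth at an anchor admits residues whose center-to-anchor
distance lies in [N<sub>t</sub>, F<sub>t</sub>] (both inclusive), then
enforces the mutual constraint that every residue lie within
F<sub>t</sub> of every other. F<sub>t</sub> deliberately plays both
roles — maximum anchor distance and maximum pairwise distance — which is
the only reading under which both constraints can be satisfied
simultaneously by one parameter pair. Mutual violations are resolved by
greedy deletion: repeatedly remove the residue with the most pairwise
violations, breaking ties toward the residue farther from the anchor and
then toward later file order. The procedure terminates, never touches a
feasible input, and on small instances produces a maximal feasible
subset (property-tested by brute force). It is *not* monotone in
F<sub>t</sub>: tightening F<sub>t</sub> changes violation counts and can
re-order deletions, so a residue pruned at a large F<sub>t</sub> may
survive at a smaller one. The monotone statements that do hold — the
anchor-qualified candidate pool shrinks with F<sub>t</sub>, and patterns
nest when no pruning fires — are the ones the test suite asserts.

## Descriptors

For a pattern of n residues:

* **Dist** — one token per unordered residue pair (n(n−1)/2 tokens). A
  token is the two one-letter codes in lexicographic order around the
  inter-center distance rounded half-up to integer Ångström (`L5R`).
  Canonical letter order and a fixed rounding rule are required for
  token multisets from different structures to be intersectable at all;
  without them the descriptor would depend on arbitrary residue order.
* **NbE** — the sum of per-residue short+medium-range non-bonded energy
  values from a lookup table. The packaged table
  (`src/geompatterns/data/nonbonded_energies.tsv`) carries approximate
  values that track the accepted ordering of average residue non-bonded
  interaction strength; it is a two-column text file and fully
  user-overridable (`--energy-table`). Because the similarity built on
  NbE is a ratio of two sums, any monotone-consistent table produces
  sensible relative scores, and identical residue compositions score
  exactly 100 % under *every* table.
* **Sc** — the multiset of n physicochemical category letters over eight
  classes: A aliphatic {G,A,V,L,I}, B aromatic {F,Y,W}, C hydroxyl
  {S,T}, D acidic {D,E}, E acid amide {N,Q}, F basic {R,K,H}, G sulphur
  {C,M}, H cyclic {P}.
* **Tsp** — the "perimeter": the n edges of a shortest closed tour
  through the residue centers, emitted as pair tokens. The tour is a
  cycle because a perimeter of n vertices has n edges. For n ≤ 10 the
  tour is provably optimal (Held–Karp dynamic programming, with
  deterministic tie-breaks); above that, nearest-neighbor construction
  from the first residue followed by first-improvement 2-opt to a local
  optimum. Storing edges as a multiset makes the descriptor independent
  of tour start and direction; in the exact regime it is also
  independent of residue input order up to ties between distinct optimal
  tours, and in the heuristic regime input order can matter — one reason
  the default minimum pattern size keeps patterns small.

All descriptors are multisets or scalars; nothing downstream ever sees
residue order.

## Scoring

Partial similarities are multiset-overlap percentages normalized by the
larger cardinality (so comparing patterns of different sizes penalizes
the size gap), except SNbE which is the ratio of absolute energy sums.
Multiset (not set) semantics preserve duplicate tokens; the normalizers
n(n−1)/2 and n only make sense with multiplicity counted. Two edge
cases are defined explicitly: SNbE(0, 0) = 100 (identical energies) and
SNbE(0, x≠0) = 0; an empty token multiset has undefined similarity and
raises. GScore is the weighted mean of the four partials with weights
summing to 100 %. Setting one weight to 100 reduces GScore to that
partial exactly.

Scores are carried as exact floating ratios throughout and rounded to
one decimal only at report time. The ratio in SNbE is computed before
scaling by 100 so equal magnitudes give exactly 100.0. Pair retention
uses a strict comparison (GScore > threshold). Output is sorted by
GScore descending with ties broken by the numeric anchor labels, so the
result is identical however the all-vs-all loop is executed.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| G<sub>r</sub> | 10 | Å | max center–center distance for a pair to seed a grid point; the canonical worked setting |
| N<sub>t</sub> | 3 | Å | min residue–anchor distance; this package's own default |
| F<sub>t</sub> | 10 | Å | max residue–anchor and residue–residue distance; this package's own default |
| min_residues | 3 | – | smallest pattern described; below 3 the perimeter degenerates |
| Dp, Cp, Tp, Sp | 25 each | % | descriptor weights, must sum to 100 |
| threshold | 50 | % | strict retention cut-off, the conventional results filter |

N<sub>t</sub>/F<sub>t</sub> bound the physical size of the patterns: for
drug-binding-site work choose them to enclose a cavity that fits the
ligand size of interest; G<sub>r</sub> controls only how densely the
structure is probed (grid size grows steeply with it). Chain selection
defaults to all protein chains and is user-filterable; for multimeric
structures a single-chain filter can change grid sizes substantially.

## Synthetic fixtures

The fixture generator plants side-chain centers exactly: every
non-glycine residue is realized as a backbone plus a single CB at the
requested coordinate, so the parsed center reproduces the plant to
numerical precision, and glycine is planted through its CA. Decoy
waters, unknown-ligand heteroatoms, B-conformers and second models
exercise the parser's filters. Twin pairs (a structure plus a jittered,
category-preservingly mutated copy) provide controlled ground truth:
zero perturbation must give all-100 matches, same-category swaps must
leave SSc at 100, and jitter beyond the 1 Å token rounding must erode
SDist. What the fixtures deliberately do not emulate: real side-chain
rotamers, backbone stereochemistry, secondary structure, crystal
contacts, or realistic residue packing densities. Passing tests
therefore demonstrate the correctness of the geometry, descriptor and
scoring machinery, not biological plausibility of any particular
pattern; conclusions about real binding sites still require real
structures.

Test and demonstration problem sizes are kept small (tens of residues,
hundreds to thousands of pattern pairs), which exercises every code path
including the heuristic TSP regime; full-size structure pairs (tens of
millions of pattern pairs) run through the identical code but are
minutes-to-hours scale and are exercised only by the optional
network-dependent regression test.

## Numerical conventions and degenerate inputs

* distance comparisons at module boundaries are inclusive (≤ G<sub>r</sub>,
  [N<sub>t</sub>, F<sub>t</sub>], ≤ F<sub>t</sub>), so boundary ties are
  deterministic;
* token distances round half-up (`floor(d + 0.5)`), giving `A4A` at
  4.49 Å and `G8W` at 7.5 Å;
* a model with fewer than two residues yields an empty grid with a
  warning, not an error; an empty pattern list is a valid comparison
  input on either side and produces an explicit diagnostic;
* a structure with zero amino acids after filtering is an error, as is a
  residue missing from a user-supplied energy table (reported by name);
* reports serialize with stable key order and fixed precision
  (percentages 1 decimal, coordinates 3), so identical runs are
  byte-identical.

## Known limitations

* The packaged energy table is an approximation assembled for this
  package; absolute NbE values are not comparable to any published
  force-field quantity, only SNbE ratios are meaningful.
* The heuristic TSP regime (n > 10) guarantees a 2-opt local optimum,
  not the global one, and is order-sensitive in principle.
* Greedy pruning is deterministic and maximal but not globally optimal:
  it may keep fewer residues than the largest feasible subset, and is
  not monotone in F<sub>t</sub> (see above).
* No superposition, RMSD, or alignment is ever computed — by design the
  method reports descriptor similarity, not geometric superposability.
* Cross-size pattern comparison follows the formulas literally: the
  max-cardinality normalizer is the only size penalty.
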