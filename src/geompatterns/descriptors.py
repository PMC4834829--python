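"""The four per-pattern descriptors.

Every 3D pattern of n residues is summarized, independent of residue input
order, by:

Dist
    multiset of n(n-1)/2 tokens, one per unordered residue pair.  A token
    packs the rounded inter-center distance between the two one-letter
    codes, e.g. ``L5R`` for Leu and Arg 5 A apart.  Letters are placed in
    lexicographic order so the token does not depend on pair orientation,
    and distances round half-up to the nearest integer Angstrom.
NbE
    a single scalar: the sum over residues of tabulated short+medium-range
    non-bonded energies (see :class:`EnergyTable`).
Sc
    the "sequence component": multiset of n physicochemical category
    letters, using eight classes — A aliphatic {G,A,V,L,I}, B aromatic
    {F,Y,W}, C hydroxyl {S,T}, D acidic {D,E}, E acid amide {N,Q},
    F basic {R,K,H}, G sulphur {C,M}, H cyclic {P}.
Tsp
    the "perimeter": the edges of the shortest closed tour visiting every
    side-chain center once (a travelling-salesman tour), emitted as n pair
    tokens.  Storing edges as a multiset makes the descriptor independent
    of tour starting point and direction.

All four are multisets or scalars, never sequences: comparison downstream
is pure multiset intersection, which is what makes the method
sequence-order-independent.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .patterns import Pattern3D
from .structure_io import STANDARD_AA1

#: the eight physicochemical categories of the sequence component
CATEGORIES: dict[str, str] = {
    **{aa: "A" for aa in "GAVLI"},   # aliphatic
    **{aa: "B" for aa in "FYW"},     # aromatic
    **{aa: "C" for aa in "ST"},      # hydroxyl
    **{aa: "D" for aa in "DE"},      # acidic
    **{aa: "E" for aa in "NQ"},      # acid amide
    **{aa: "F" for aa in "RKH"},     # basic
    **{aa: "G" for aa in "CM"},      # sulphur
    "P": "H",                        # cyclic
}


class EnergyTable:
    """Per-residue short+medium-range non-bonded energy lookup.

    Loaded from a two-column plain-text file (one-letter code, value;
    ``#`` comments allowed).  The packaged default ships approximate
    literature-derived values and is user-overridable; see the file header
    and the methods note.
    """

    def __init__(self, values: dict[str, float]):
        missing = STANDARD_AA1 - values.keys()
        if missing:
            raise ValueError(f"energy table missing residues: {sorted(missing)}")
        bad = [k for k, v in values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite energy values for: {bad}")
        self.values = dict(values)

    def __getitem__(self, aa1: str) -> float:
        try:
            return self.values[aa1]
        except KeyError:
            raise KeyError(f"residue {aa1!r} not present in energy table") from None

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyTable":
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed energy-table line: {line!r}")
            values[parts[0].upper()] = float(parts[1])
        return cls(values)

    @classmethod
    def default(cls) -> "EnergyTable":
        ref = resources.files("geompatterns").joinpath("data/nonbonded_energies.tsv")
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass(frozen=True)
class DescriptorSet:
    """The four descriptors of one pattern, keyed by its anchor label."""

    pattern_ref: str
    structure_id: str
    n: int
    dist: Counter
    nbe: float
    sc: Counter
    tsp: Counter

    def __post_init__(self):
        assert sum(self.dist.values()) == self.n * (self.n - 1) // 2
        assert sum(self.sc.values()) == self.n
        assert sum(self.tsp.values()) == self.n


def pair_token(aa1_a: str, aa1_b: str, distance: float) -> str:
    """Canonical pair token: letters in lexicographic order, distance
    rounded half-up to integer Angstrom.  (R, L, 5.0) -> ``L5R``."""
    for aa in (aa1_a, aa1_b):
        if aa not in STANDARD_AA1:
            raise ValueError(f"unknown one-letter code {aa!r}")
    if distance < 0:
        raise ValueError("distance must be non-negative")
    d = math.floor(distance + 0.5)  # round half up
    a, b = sorted((aa1_a, aa1_b))
    return f"{a}{d}{b}"


def dist_descriptor(pattern: Pattern3D) -> Counter:
    """One token per unordered residue pair: n(n-1)/2 in total."""
    if pattern.n < 2:
        raise ValueError("Dist descriptor needs at least 2 residues")
    c = pattern.centers()
    tokens = Counter()
    for i, j in itertools.combinations(range(pattern.n), 2):
        tokens[
            pair_token(
                pattern.residues[i].aa1,
                pattern.residues[j].aa1,
                math.dist(c[i], c[j]),
            )
        ] += 1
    return tokens


def nbe_descriptor(pattern: Pattern3D, table: EnergyTable) -> float:
    """Sum of tabulated per-residue non-bonded energies."""
    return float(sum(table[r.aa1] for r in pattern.residues))


def residue_category(aa1: str) -> str:
    """Physicochemical class letter (A-H) of a standard residue."""
    try:
        return CATEGORIES[aa1]
    except KeyError:
        raise ValueError(f"unknown one-letter code {aa1!r}") from None


def sc_descriptor(pattern: Pattern3D) -> Counter:
    """Multiset of the n category letters of the pattern's residues."""
    return Counter(residue_category(r.aa1) for r in pattern.residues)


def tour_length(points: np.ndarray, order: list[int]) -> float:
    n = len(order)
    return float(
        sum(math.dist(points[order[k]], points[order[(k + 1) % n]]) for k in range(n))
    )


def _held_karp(points: np.ndarray) -> list[int]:
    """Exact minimum closed tour by dynamic programming (n <= ~12)."""
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    # dp[(mask, j)] = (cost of best path 0 -> ... -> j over set mask, parent)
    dp: dict[tuple[int, int], tuple[float, int]] = {(1 | (1 << j), j): (d[0, j], 0) for j in range(1, n)}
    for size in range(3, n + 1):
        for subset in itertools.combinations(range(1, n), size - 1):
            mask = 1
            for j in subset:
                mask |= 1 << j
            for j in subset:
                prev_mask = mask ^ (1 << j)
                best = None
                for k in subset:
                    if k == j:
                        continue
                    cand = (dp[(prev_mask, k)][0] + d[k, j], k)
                    if best is None or cand < best:
                        best = cand
                dp[(mask, j)] = best
    full = (1 << n) - 1
    best_j, best_cost = None, None
    for j in range(1, n):
        cost = dp[(full, j)][0] + d[j, 0]
        if best_cost is None or (cost, j) < (best_cost, best_j):
            best_cost, best_j = cost, j
    # reconstruct
    order = [best_j]
    mask, j = full, best_j
    while j != 0:
        _, parent = dp[(mask, j)]
        mask ^= 1 << j
        j = parent
        order.append(j)
    order.reverse()
    return order


def _nn_two_opt(points: np.ndarray) -> list[int]:
    """Nearest-neighbor tour from point 0, improved by 2-opt to a local
    optimum; fully deterministic given input order."""
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    unvisited = set(range(1, n))
    order = [0]
    while unvisited:
        last = order[-1]
        nxt = min(unvisited, key=lambda j: (d[last, j], j))
        order.append(nxt)
        unvisited.remove(nxt)
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue  # same edge pair
                a, b = order[i], order[i + 1]
                c, e = order[j], order[(j + 1) % n]
                if d[a, c] + d[b, e] < d[a, b] + d[c, e] - 1e-12:
                    order[i + 1 : j + 1] = reversed(order[i + 1 : j + 1])
                    improved = True
    return order


def solve_tsp(points: np.ndarray | list) -> list[int]:
    """Closed tour over all points: exact for n <= 10, heuristic above.

    Returns the visiting order as a list of indices (the tour closes back
    to the first).  For n <= 10 the tour is provably optimal (Held-Karp
    dynamic programming); larger instances use nearest-neighbor
    construction plus 2-opt.  Deterministic for a fixed input order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise ValueError("a closed tour needs at least 3 points")
    if n == 3:
        return [0, 1, 2]
    if n <= 10:
        return _held_karp(points)
    return _nn_two_opt(points)


def tsp_descriptor(pattern: Pattern3D) -> Counter:
    """Perimeter tokens: one pair token per edge of the optimal-ish tour."""
    if pattern.n < 3:
        raise ValueError("Tsp descriptor needs at least 3 residues")
    c = pattern.centers()
    order = solve_tsp(c)
    tokens = Counter()
    for k in range(len(order)):
        i, j = order[k], order[(k + 1) % len(order)]
        tokens[
            pair_token(pattern.residues[i].aa1, pattern.residues[j].aa1, math.dist(c[i], c[j]))
        ] += 1
    return tokens


def describe(pattern: Pattern3D, table: EnergyTable) -> DescriptorSet:
    """Compute all four descriptors of one pattern."""
    return DescriptorSet(
        pattern_ref=pattern.anchor_label,
        structure_id=pattern.structure_id,
        n=pattern.n,
        dist=dist_descriptor(pattern),
        nbe=nbe_descriptor(pattern, table),
        sc=sc_descriptor(pattern),
        tsp=tsp_descriptor(pattern),
    )
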