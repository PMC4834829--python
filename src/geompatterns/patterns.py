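"""Grow one candidate 3D pattern from each grid reference coordinate.

A pattern is the set of residues whose side-chain centers lie between the
near threshold Nt and the far threshold Ft from the reference coordinate,
additionally constrained so that every residue is at most Ft from every
other residue of the pattern.  Nt and Ft are therefore the dimensional
limits of the patterns being unveiled: small Nt admits residues hugging the
reference point, Ft caps the overall pattern size.

Candidates that violate the mutual-Ft constraint are resolved by greedy
deletion: repeatedly drop the residue with the most pairwise violations
(ties: larger anchor distance, then later file order) until the remaining
set is feasible.  The procedure is deterministic and leaves feasible inputs
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .grid import GridPoint
from .structure_io import ResidueCenter, StructureModel


@dataclass(frozen=True)
class DetectionParams:
    """Pattern-growth parameters (Angstrom).

    nt: minimum residue-to-anchor distance (>= 0).
    ft: maximum residue-to-anchor distance and maximum residue-to-residue
        distance (> nt).
    min_residues: smallest pattern worth describing; below 3 the perimeter
        descriptor degenerates, so 3 is the default.
    """

    nt: float = 3.0
    ft: float = 10.0
    min_residues: int = 3

    def __post_init__(self):
        if self.nt < 0:
            raise ValueError(f"near threshold Nt must be >= 0, got {self.nt}")
        if not self.ft > self.nt:
            raise ValueError(f"far threshold Ft ({self.ft}) must exceed Nt ({self.nt})")
        if self.min_residues < 1:
            raise ValueError("min_residues must be >= 1")


@dataclass(frozen=True)
class Pattern3D:
    """A set of residues anchored to one grid point."""

    structure_id: str
    anchor: GridPoint
    residues: tuple[ResidueCenter, ...]

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def anchor_label(self) -> str:
        return self.anchor.label

    def centers(self) -> np.ndarray:
        return np.array([r.center for r in self.residues], dtype=float)

    def residue_labels(self) -> list[str]:
        return [r.label for r in self.residues]


def pairwise_prune(
    candidates: list[ResidueCenter],
    ft: float,
    anchor_xyz: np.ndarray | None = None,
) -> list[ResidueCenter]:
    """Reduce a candidate set until all pairwise distances are <= Ft.

    Greedy max-violation deletion.  Tie-breaks, in order: larger distance
    to the anchor (when given), later position in file order.  Feasible
    inputs are returned unchanged, and a distance of exactly Ft is not a
    violation.
    """
    kept = list(range(len(candidates)))
    if len(kept) < 2:
        return list(candidates)
    coords = np.array([c.center for c in candidates], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=-1))
    if anchor_xyz is not None:
        anchor_d = np.linalg.norm(coords - anchor_xyz, axis=1)
    else:
        anchor_d = np.zeros(len(candidates))

    while len(kept) >= 2:
        sub = dmat[np.ix_(kept, kept)]
        viol = (sub > ft).sum(axis=1)
        if viol.max() == 0:
            break
        # worst offender; ties -> farther from anchor, then later file order
        worst = max(
            range(len(kept)),
            key=lambda k: (viol[k], anchor_d[kept[k]], kept[k]),
        )
        kept.pop(worst)
    return [candidates[i] for i in kept]


def detect_patterns(
    model: StructureModel, grid: list[GridPoint], params: DetectionParams
) -> list[Pattern3D]:
    """Grow one pattern per grid point; drop those below ``min_residues``.

    Output order follows grid order, so results are deterministic for a
    fixed model and grid.
    """
    centers = model.centers()
    patterns: list[Pattern3D] = []
    for gp in grid:
        d = np.linalg.norm(centers - gp.xyz, axis=1)
        idx = np.nonzero((d >= params.nt) & (d <= params.ft))[0]
        if len(idx) < params.min_residues:
            continue
        candidates = [model.residues[i] for i in idx]
        kept = pairwise_prune(candidates, params.ft, anchor_xyz=gp.xyz)
        if len(kept) < params.min_residues:
            continue
        patterns.append(
            Pattern3D(structure_id=model.id, anchor=gp, residues=tuple(kept))
        )
    return patterns


def dedup_patterns(patterns: list[Pattern3D]) -> list[Pattern3D]:
    """Collapse patterns with identical residue sets, keeping the first anchor."""
    seen: set[frozenset[str]] = set()
    out = []
    for p in patterns:
        key = frozenset((r.chain, r.seq_id) for r in p.residues)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def check_pattern(pattern: Pattern3D, params: DetectionParams) -> bool:
    """Brute-force re-check of the pattern invariants (used by tests)."""
    c = pattern.centers()
    a = pattern.anchor.xyz
    if pattern.n < params.min_residues:
        return False
    for i in range(pattern.n):
        da = math.dist(c[i], a)
        if not (params.nt <= da <= params.ft + 1e-9):
            return False
        for j in range(i + 1, pattern.n):
            if math.dist(c[i], c[j]) > params.ft + 1e-9:
                return False
    return True
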