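"""Virtual grid of reference coordinates.

The search grid is not a Cartesian lattice: it is the cloud of midpoints of
every pair of residue side-chain centers lying within the grid radius Gr of
each other.  Each midpoint becomes one reference coordinate ("AtomN") from
which one candidate 3D pattern is later grown, so the grid density directly
controls how exhaustively the structure is explored.  Coincident midpoints
are deliberately kept as distinct grid points: the all-vs-all pair count of
a comparison is the product of the two grid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import StructureModel


@dataclass(frozen=True)
class GridParams:
    """Grid construction parameter: the grid radius Gr in Angstrom."""

    gr: float = 10.0

    def __post_init__(self):
        if not self.gr > 0:
            raise ValueError(f"grid radius Gr must be positive, got {self.gr}")


@dataclass(frozen=True)
class GridPoint:
    """One reference coordinate: the midpoint of a qualifying residue pair.

    ``atom_index`` is the 1-based sequential label used everywhere a
    pattern is reported ("Atom459").  ``parent_pair`` holds the residue
    indices (file order, i < j) whose side-chain centers this point bisects.
    """

    atom_index: int
    coord: tuple[float, float, float]
    parent_pair: tuple[int, int]

    @property
    def label(self) -> str:
        return f"Atom{self.atom_index}"

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


def build_grid(model: StructureModel, params: GridParams) -> list[GridPoint]:
    """Enumerate all midpoints of residue pairs within Gr of each other.

    Pairs are enumerated deterministically in (i, j) file order with i < j;
    the comparison is inclusive (distance <= Gr).  Returns an empty list
    with a warning if the model has fewer than two residues.
    """
    centers = model.centers()
    n = len(centers)
    if n < 2:
        import logging

        logging.getLogger(__name__).warning(
            "model %s has %d residue(s); grid is empty", model.id, n
        )
        return []
    pairs = cKDTree(centers).query_pairs(params.gr, output_type="ndarray")
    # query_pairs is inclusive (distance <= r) but unordered; sort for determinism
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    mids = (centers[pairs[:, 0]] + centers[pairs[:, 1]]) / 2.0
    return [
        GridPoint(
            atom_index=k + 1,
            coord=tuple(float(x) for x in mids[k]),
            parent_pair=(int(pairs[k, 0]), int(pairs[k, 1])),
        )
        for k in range(len(pairs))
    ]


def grid_census(model: StructureModel, gr_values: Iterable[float]) -> pd.DataFrame:
    """Grid size as a function of Gr; counts are non-decreasing in Gr."""
    rows = [
        {"gr": float(gr), "n_grid_points": len(build_grid(model, GridParams(gr=gr)))}
        for gr in gr_values
    ]
    return pd.DataFrame(rows)


def write_grid_pdb(grid: list[GridPoint], path: str | Path) -> Path:
    """Export the grid as HETATM pseudo-atoms for visualization."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for gp in grid:
            x, y, z = gp.coord
            fh.write(
                f"HETATM{gp.atom_index % 100000:5d}  C   GRD X{gp.atom_index % 10000:4d}"
                f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
    return path
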