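import numpy as np
import pytest

from geompatterns.fixtures import AA1_TO_AA3
from geompatterns.grid import GridPoint
from geompatterns.patterns import Pattern3D
from geompatterns.structure_io import ResidueCenter, StructureModel


def residue(aa1: str, center, chain: str = "A", seq: int = 1) -> ResidueCenter:
    return ResidueCenter(
        chain=chain,
        seq_id=str(seq),
        aa3=AA1_TO_AA3[aa1],
        aa1=aa1,
        center=tuple(float(x) for x in center),
    )


def model_from(aa1s, centers, structure_id="synthetic") -> StructureModel:
    """In-memory StructureModel from parallel residue-letter/center lists."""
    residues = [
        residue(aa, c, seq=i + 1) for i, (aa, c) in enumerate(zip(aa1s, centers))
    ]
    return StructureModel(id=structure_id, residues=residues)


def pattern_from(aa1s, centers, structure_id="synthetic", anchor_index=1) -> Pattern3D:
    """Pattern with a synthetic anchor at the centroid of its residues."""
    centers = np.asarray(centers, dtype=float)
    anchor = GridPoint(
        atom_index=anchor_index,
        coord=tuple(float(x) for x in centers.mean(axis=0)),
        parent_pair=(0, 1),
    )
    return Pattern3D(
        structure_id=structure_id,
        anchor=anchor,
        residues=tuple(
            residue(aa, c, seq=i + 1) for i, (aa, c) in enumerate(zip(aa1s, centers))
        ),
    )


@pytest.fixture
def write_pdb(tmp_path):
    """Write PDB text to a temp file and return its path."""

    def _write(text: str, name: str = "fixture.pdb"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
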