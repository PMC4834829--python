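"""Parsing, side-chain centers, pattern excerpts and fetch plumbing."""

import numpy as np
import pytest

from geompatterns import fixtures, parse_structure, side_chain_center, write_pattern_pdb
from geompatterns.structure_io import StructureError, fetch_structure
from tests.conftest import pattern_from

ALA_WATER_PDB = """\
ATOM      1  N   ALA A   1       0.500   1.400   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       0.600  -1.300   0.400  1.00  0.00           C
ATOM      4  O   ALA A   1       0.800  -2.400   0.700  1.00  0.00           O
ATOM      5  CB  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      6  N   ALA A   2       5.500   1.400   0.000  1.00  0.00           N
ATOM      7  CA  ALA A   2       5.000   0.000   0.000  1.00  0.00           C
ATOM      8  C   ALA A   2       5.600  -1.300   0.400  1.00  0.00           C
ATOM      9  O   ALA A   2       5.800  -2.400   0.700  1.00  0.00           O
ATOM     10  CB  ALA A   2       6.000   2.000   3.000  1.00  0.00           C
HETATM   11  O   HOH W 901      10.000  10.000  10.000  1.00  0.00           O
END
"""

SER_PDB = """\
ATOM      1  N   SER A   1       0.500   1.400   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   SER A   1       0.600  -1.300   0.400  1.00  0.00           C
ATOM      4  O   SER A   1       0.800  -2.400   0.700  1.00  0.00           O
ATOM      5  CB  SER A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      6  OG  SER A   1       2.000   0.000   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   CYS A   1       0.500   1.400   0.000  1.00  0.00           N
ATOM      2  CA  CYS A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  C   CYS A   1       0.600  -1.300   0.400  1.00  0.00           C
ATOM      4  O   CYS A   1       0.800  -2.400   0.700  1.00  0.00           O
ATOM      5  CB ACYS A   1       1.000   1.000   1.000  0.50  0.00           C
ATOM      6  SG ACYS A   1       3.000   1.000   1.000  0.50  0.00           S
ATOM      7  CB BCYS A   1       9.000   9.000   9.000  0.50  0.00           C
ATOM      8  SG BCYS A   1       9.000   9.000   7.000  0.50  0.00           S
END
"""


def test_waters_and_unknown_ligands_are_excluded(write_pdb):
    model = parse_structure(write_pdb(ALA_WATER_PDB))
    assert len(model) == 2
    assert all(r.aa3 == "ALA" for r in model.residues)


def test_side_chain_center_is_mean_of_side_chain_heavy_atoms(write_pdb):
    # ALA: lone CB is the center; SER: midpoint of CB and OG
    model = parse_structure(write_pdb(ALA_WATER_PDB))
    assert np.allclose(model.residues[0].center, (1.0, 2.0, 3.0))
    model = parse_structure(write_pdb(SER_PDB, "ser.pdb"))
    assert np.allclose(model.residues[0].center, (1.0, 0.0, 0.0))


def test_altloc_collapses_to_first_listed_conformer(write_pdb):
    model = parse_structure(write_pdb(ALTLOC_PDB))
    assert len(model) == 1
    # mean of the A-conformer CB (1,1,1) and SG (3,1,1) records
    assert np.allclose(model.residues[0].center, (2.0, 1.0, 1.0))


def test_first_model_only():
    spec = fixtures.FixtureSpec(extra_model=True)
    for i, aa in enumerate(["ALA", "SER", "LEU"]):
        spec.add(aa, "A", i + 1, (5.0 * i, 0.0, 0.0))
    text = fixtures.make_structure(spec)
    import tempfile, pathlib

    p = pathlib.Path(tempfile.mkdtemp()) / "m.pdb"
    p.write_text(text)
    model = parse_structure(p)
    assert len(model) == 3
    assert np.allclose(model.residues[0].center, (0.0, 0.0, 0.0))


def test_glycine_falls_back_to_ca(write_pdb):
    spec = fixtures.FixtureSpec().add("GLY", "A", 1, (5.0, 5.0, 5.0)).add(
        "ALA", "A", 2, (9.0, 5.0, 5.0)
    )
    model = parse_structure(write_pdb(fixtures.make_structure(spec)))
    gly = next(r for r in model.residues if r.aa3 == "GLY")
    assert np.allclose(gly.center, (5.0, 5.0, 5.0))


def test_mse_maps_to_met(write_pdb):
    text = """\
HETATM    1  N   MSE A   1       0.500   1.400   0.000  1.00  0.00           N
HETATM    2  CA  MSE A   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    3  C   MSE A   1       0.600  -1.300   0.400  1.00  0.00           C
HETATM    4  O   MSE A   1       0.800  -2.400   0.700  1.00  0.00           O
HETATM    5  CB  MSE A   1       2.000   2.000   2.000  1.00  0.00           C
END
"""
    model = parse_structure(write_pdb(text))
    assert len(model) == 1
    assert model.residues[0].aa1 == "M"


def test_chain_filter(write_pdb):
    spec = fixtures.FixtureSpec()
    spec.add("ALA", "A", 1, (0, 0, 0)).add("LEU", "B", 1, (10, 0, 0))
    model = parse_structure(write_pdb(fixtures.make_structure(spec)), chains=["B"])
    assert [r.chain for r in model.residues] == ["B"]


def test_empty_or_protein_free_file_raises(write_pdb):
    with pytest.raises(StructureError):
        parse_structure(write_pdb("END\n", "empty.pdb"))


def test_parse_is_deterministic(write_pdb):
    path = write_pdb(fixtures.make_structure(fixtures.random_spec(30, seed=7)))
    assert parse_structure(path).residues == parse_structure(path).residues


def test_center_matches_brute_force_recomputation(write_pdb):
    """Every parsed center equals the raw-record heavy-atom mean to 1e-6."""
    path = write_pdb(fixtures.make_structure(fixtures.random_spec(25, seed=3)))
    model = parse_structure(path)
    raw: dict[tuple, dict[str, list]] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        key = (line[21], line[22:26].strip())
        name = line[12:16].strip()
        xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        raw.setdefault(key, {})[name] = xyz
    backbone = {"N", "CA", "C", "O", "OXT"}
    for r in model.residues:
        atoms = raw[(r.chain, r.seq_id)]
        side = [xyz for name, xyz in atoms.items() if name not in backbone]
        expected = np.mean(side, axis=0) if side else np.asarray(atoms["CA"])
        assert np.allclose(r.center, expected, atol=1e-6)


def test_pattern_pdb_round_trip(write_pdb, tmp_path):
    path = write_pdb(fixtures.make_structure(fixtures.random_spec(10, seed=5)))
    model = parse_structure(path)
    pat = pattern_from(
        [r.aa1 for r in model.residues[:3]], [r.center for r in model.residues[:3]]
    )
    # pattern_from renumbers; rebuild with the model's own residues instead
    pat = pat.__class__(
        structure_id=model.id, anchor=pat.anchor, residues=tuple(model.residues[:3])
    )
    out = write_pattern_pdb(pat, model, tmp_path / "pattern.pdb")
    again = parse_structure(out)
    assert [(r.chain, r.seq_id, r.aa3) for r in again.residues] == [
        (r.chain, r.seq_id, r.aa3) for r in model.residues[:3]
    ]


def test_empty_pattern_refuses_to_write(write_pdb, tmp_path):
    path = write_pdb(fixtures.make_structure(fixtures.random_spec(4, seed=2)))
    model = parse_structure(path)
    empty = pattern_from(["A"], [(0, 0, 0)])
    empty = empty.__class__(structure_id=model.id, anchor=empty.anchor, residues=())
    with pytest.raises(ValueError):
        write_pattern_pdb(empty, model, tmp_path / "nope.pdb")
    assert not (tmp_path / "nope.pdb").exists()


@pytest.mark.parametrize("bad_id", ["XX", "12345", "O3P", "_O3P"])
def test_fetch_rejects_malformed_ids(bad_id, tmp_path):
    with pytest.raises(ValueError):
        fetch_structure(bad_id, tmp_path)


def test_fetch_warm_cache_is_case_insensitive_and_offline(tmp_path):
    (tmp_path / "2O3P.pdb").write_text("END\n")
    assert fetch_structure("2o3p", tmp_path) == tmp_path / "2O3P.pdb"
    assert fetch_structure("2O3P", tmp_path) == tmp_path / "2O3P.pdb"
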