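"""Synthetic PDB fixtures with exactly planted side-chain geometry.

Real structures are large and must be downloaded, so every algorithmic
stage here is exercised on miniature synthetic PDB files whose side-chain
centers are planted at exact coordinates.  Each non-glycine residue is
realized with a full backbone plus a single CB atom placed exactly at the
requested center — since the side-chain center is the mean of side-chain
heavy atoms, a lone CB recovers the planted coordinate exactly.  Glycine is
realized through its CA (the glycine fallback rule).  Optional decoys
(waters, unknown-ligand heteroatoms, alternate conformers, extra models)
verify the parser's filtering contracts.

No attempt is made to mimic real folds or stereochemistry: only the
planted centers matter to the algorithms under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}

_CATEGORY_MEMBERS = {
    "A": "GAVLI", "B": "FYW", "C": "ST", "D": "DE",
    "E": "NQ", "F": "RKH", "G": "CM", "H": "P",
}
_AA1_CATEGORY = {aa: cat for cat, members in _CATEGORY_MEMBERS.items() for aa in members}


@dataclass
class PlantedResidue:
    aa3: str
    chain: str
    seq: int
    center: tuple[float, float, float]


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic structure."""

    residues: list[PlantedResidue] = field(default_factory=list)
    waters: list[tuple[float, float, float]] = field(default_factory=list)
    ligand_atoms: list[tuple[float, float, float]] = field(default_factory=list)
    altloc_residues: set[tuple[str, int]] = field(default_factory=set)
    extra_model: bool = False

    def add(self, aa3: str, chain: str, seq: int, center) -> "FixtureSpec":
        self.residues.append(PlantedResidue(aa3, chain, seq, tuple(float(x) for x in center)))
        return self

    def validate(self) -> None:
        seen = set()
        for r in self.residues:
            if r.aa3 not in AA3_TO_AA1:
                raise ValueError(f"unknown residue type {r.aa3!r}")
            key = (r.chain, r.seq)
            if key in seen:
                raise ValueError(f"duplicate residue identity {key}")
            seen.add(key)


def _atom_line(
    record: str, serial: int, name: str, alt: str, res: str, chain: str,
    seq: int, xyz, element: str, icode: str = " ",
) -> str:
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{alt:1s}{res:>3s} {chain:1s}"
        f"{seq:4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def _residue_lines(res: PlantedResidue, serial: int, spec: FixtureSpec,
                   shift: np.ndarray | None = None) -> tuple[list[str], int]:
    c = np.asarray(res.center, dtype=float)
    if shift is not None:
        c = c + shift
    lines = []
    if res.aa3 == "GLY":
        # CA carries the planted center; backbone around it
        backbone = [("N", c + (1.2, 0.8, 0.0)), ("CA", c),
                    ("C", c + (-1.0, 1.0, 0.3)), ("O", c + (-1.1, 2.2, 0.3))]
        for name, pos in backbone:
            lines.append(_atom_line("ATOM", serial, f" {name:<3s}"[:4], " ",
                                    res.aa3, res.chain, res.seq, pos, name[0]))
            serial += 1
    else:
        ca = c + (1.53, 0.0, 0.0)
        backbone = [("N", ca + (0.5, 1.4, 0.0)), ("CA", ca),
                    ("C", ca + (0.6, -1.3, 0.4)), ("O", ca + (0.8, -2.4, 0.7))]
        for name, pos in backbone:
            lines.append(_atom_line("ATOM", serial, f" {name:<3s}"[:4], " ",
                                    res.aa3, res.chain, res.seq, pos, name[0]))
            serial += 1
        if (res.chain, res.seq) in spec.altloc_residues:
            lines.append(_atom_line("ATOM", serial, " CB ", "A",
                                    res.aa3, res.chain, res.seq, c, "C"))
            serial += 1
            lines.append(_atom_line("ATOM", serial, " CB ", "B",
                                    res.aa3, res.chain, res.seq, c + (1.0, 1.0, 1.0), "C"))
            serial += 1
        else:
            lines.append(_atom_line("ATOM", serial, " CB ", " ",
                                    res.aa3, res.chain, res.seq, c, "C"))
            serial += 1
    return lines, serial


def make_structure(spec: FixtureSpec) -> str:
    """Render a FixtureSpec as standard-conformant PDB text."""
    spec.validate()
    body: list[str] = []
    serial = 1

    def emit_model(shift: np.ndarray | None) -> None:
        nonlocal serial
        for res in sorted(spec.residues, key=lambda r: (r.chain, r.seq)):
            lines, serial_new = _residue_lines(res, serial, spec, shift)
            serial = serial_new
            body.extend(lines)

    if spec.extra_model:
        body.append("MODEL        1")
        emit_model(None)
        body.append("ENDMDL")
        body.append("MODEL        2")
        emit_model(np.array([20.0, 0.0, 0.0]))
        body.append("ENDMDL")
    else:
        emit_model(None)

    het_seq = 900
    for w in spec.waters:
        body.append(_atom_line("HETATM", serial, " O  ", " ", "HOH", "W", het_seq, w, "O"))
        serial += 1
        het_seq += 1
    for a in spec.ligand_atoms:
        body.append(_atom_line("HETATM", serial, " C1 ", " ", "LIG", "X", het_seq, a, "C"))
        serial += 1
    body.append("END")
    return "\n".join(body) + "\n"


def random_spec(
    n_residues: int,
    seed: int,
    box: float = 30.0,
    chain: str = "A",
) -> FixtureSpec:
    """Random residue types at uniform random centers inside a cube."""
    rng = np.random.default_rng(seed)
    aa3s = list(AA3_TO_AA1)
    spec = FixtureSpec()
    for i in range(n_residues):
        spec.add(aa3s[int(rng.integers(len(aa3s)))], chain, i + 1, rng.uniform(0, box, 3))
    return spec


def make_twin_pair(
    spec: FixtureSpec,
    jitter: float = 0.0,
    n_mutations: int = 0,
    seed: int = 0,
) -> tuple[str, str]:
    """Structure A plus a perturbed copy B.

    B's side-chain centers are A's plus isotropic Gaussian jitter of the
    given standard deviation (Angstrom), and ``n_mutations`` randomly chosen
    residues are swapped for a different residue of the same physicochemical
    category (so the sequence component is preserved by construction).
    With zero jitter and zero mutations, B's geometry and composition are
    identical to A's and every pattern of A has a GScore-100 partner in B.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    spec.validate()
    rng = np.random.default_rng(seed)
    text_a = make_structure(spec)

    twin = FixtureSpec(
        waters=list(spec.waters),
        ligand_atoms=list(spec.ligand_atoms),
        altloc_residues=set(spec.altloc_residues),
        extra_model=spec.extra_model,
    )
    mutate_idx: set[int] = set()
    if n_mutations:
        # only residues whose category has an alternative member qualify
        eligible = [
            i for i, r in enumerate(spec.residues)
            if len(_CATEGORY_MEMBERS[_AA1_CATEGORY[AA3_TO_AA1[r.aa3]]]) > 1
        ]
        take = min(n_mutations, len(eligible))
        mutate_idx = set(rng.choice(eligible, size=take, replace=False).tolist())
    for i, r in enumerate(spec.residues):
        center = np.asarray(r.center) + (rng.normal(0.0, jitter, 3) if jitter > 0 else 0.0)
        aa3 = r.aa3
        if i in mutate_idx:
            aa1 = AA3_TO_AA1[r.aa3]
            others = [a for a in _CATEGORY_MEMBERS[_AA1_CATEGORY[aa1]] if a != aa1]
            aa3 = AA1_TO_AA3[others[int(rng.integers(len(others)))]]
        twin.add(aa3, r.chain, r.seq, center)
    return text_a, make_structure(twin)
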