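"""Read protein structures into a normalized residue model.

The whole comparison engine works on one geometric primitive per residue:
the unweighted mean coordinate of its side-chain heavy atoms (the
"side-chain geometric center"; glycine falls back to CA).  This module
parses PDB files with gemmi, collapses them to that representation, writes
per-pattern PDB excerpts, and optionally fetches entries from the Protein
Data Bank.

Normalization rules
-------------------
* only model 1 of multi-model files is used;
* waters, ligands, cofactors and other non-amino-acid heteroatoms are
  dropped (the method is ligand-independent by construction);
* alternate conformers collapse to the first-listed one;
* modified residues with a standard parent (e.g. MSE -> MET) are mapped to
  the parent one-letter code; unmappable residues are skipped with a
  warning.
"""

from __future__ import annotations

import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

log = logging.getLogger(__name__)

STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

#: backbone heavy atoms excluded from the side-chain center
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")
_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class StructureError(ValueError):
    """Raised for unreadable, empty, or otherwise unusable structures."""


class FetchError(RuntimeError):
    """Raised when a PDB entry cannot be retrieved from the wwPDB."""


@dataclass(frozen=True)
class ResidueCenter:
    """One residue reduced to its side-chain geometric center.

    ``seq_id`` is the author residue number with any insertion code
    appended (e.g. ``"114"`` or ``"52A"``).
    """

    chain: str
    seq_id: str
    aa3: str
    aa1: str
    center: tuple[float, float, float]

    @property
    def label(self) -> str:
        """Human-readable identity, e.g. ``A:ASP114``."""
        return f"{self.chain}:{self.aa3}{self.seq_id}"

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass
class StructureModel:
    """Ordered residue-center list for one protein structure."""

    id: str
    residues: list[ResidueCenter]
    source_path: Path | None = None
    _gemmi: gemmi.Structure | None = field(default=None, repr=False, compare=False)

    def __len__(self) -> int:
        return len(self.residues)

    def centers(self) -> np.ndarray:
        """(n, 3) array of side-chain centers in file order."""
        return np.array([r.center for r in self.residues], dtype=float)


def side_chain_center(residue: gemmi.Residue) -> np.ndarray | None:
    """Unweighted mean of side-chain heavy atoms; CA for glycine.

    Alternate conformers are collapsed beforehand: for every atom name only
    the first-listed location contributes.  Returns ``None`` when the
    residue has no usable heavy atom at all (caller drops it).
    """
    side, ca = [], None
    seen: set[str] = set()
    for atom in residue:
        if atom.is_hydrogen():
            continue
        if atom.name in seen:  # later altloc of an atom already taken
            continue
        seen.add(atom.name)
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        if atom.name == "CA":
            ca = pos
        if atom.name not in BACKBONE_ATOMS:
            side.append(pos)
    if side:
        return np.mean(side, axis=0)
    if ca is not None:
        return ca
    return None


def _one_letter(res_name: str) -> str | None:
    """Map a residue name to a standard one-letter code, or None."""
    info = gemmi.find_tabulated_residue(res_name)
    if info is None or not info.is_amino_acid():
        return None
    code = info.one_letter_code.upper()
    return code if code in STANDARD_AA1 else None


def parse_structure(
    path: str | Path, chains: list[str] | None = None, structure_id: str | None = None
) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        PDB-format file.
    chains
        Optional chain-ID whitelist; default is every protein chain.
    structure_id
        Identifier for reports; defaults to the file stem.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models found in {path}")

    model = st[0]  # first model only
    residues: list[ResidueCenter] = []
    for chain in model:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.is_water():
                continue
            aa1 = _one_letter(res.name)
            if aa1 is None:
                if res.het_flag == "H" and not res.is_water():
                    log.debug("skipping non-amino-acid residue %s", res.name)
                else:
                    log.warning(
                        "skipping unmappable residue %s %s%s", res.name, chain.name, res.seqid
                    )
                continue
            center = side_chain_center(res)
            if center is None:
                log.warning("residue %s %s%s has no usable atoms; skipped",
                            res.name, chain.name, res.seqid)
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                ResidueCenter(
                    chain=chain.name,
                    seq_id=f"{res.seqid.num}{icode}",
                    aa3=res.name,
                    aa1=aa1,
                    center=tuple(float(x) for x in center),
                )
            )
    if not residues:
        raise StructureError(f"no amino-acid residues in {path} after filtering")
    return StructureModel(
        id=structure_id or path.stem, residues=residues, source_path=path, _gemmi=st
    )


def write_pattern_pdb(pattern, model: StructureModel, path: str | Path) -> Path:
    """Write the full original atom records of a pattern's residues.

    Chain IDs and residue numbering are preserved so the excerpt overlays
    the parent structure in any viewer.
    """
    if not pattern.residues:
        raise ValueError("refusing to write an empty pattern")
    if model._gemmi is None:
        raise StructureError("model carries no atom records (not parsed from a file)")
    wanted = {(r.chain, r.seq_id) for r in pattern.residues}
    missing = wanted - {(r.chain, r.seq_id) for r in model.residues}
    if missing:
        raise ValueError(f"pattern residues absent from model: {sorted(missing)}")

    out = gemmi.Structure()
    out.name = getattr(pattern, "anchor_label", model.id)
    new_model = gemmi.Model(1)
    for chain in model._gemmi[0]:
        new_chain = gemmi.Chain(chain.name)
        for res in chain:
            icode = res.seqid.icode.strip()
            if (chain.name, f"{res.seqid.num}{icode}") in wanted:
                new_chain.add_residue(res)
        if len(new_chain) > 0:
            new_model.add_chain(new_chain)
    out.add_model(new_model)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.write_pdb(str(path))
    return path


def fetch_structure(pdb_id: str, cache_dir: str | Path, timeout: float = 30.0) -> Path:
    """Download a PDB entry (once) and return the cached file path.

    IDs are case-insensitive; ``2o3p`` and ``2O3P`` share one cache entry.
    """
    if not _PDB_ID_RE.match(pdb_id):
        raise ValueError(f"malformed PDB ID {pdb_id!r}: expected [0-9][A-Za-z0-9]{{3}}")
    pdb_id = pdb_id.upper()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    target = cache_dir / f"{pdb_id}.pdb"
    if target.exists():
        return target
    url = _RCSB_URL.format(pdb_id=pdb_id)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, TimeoutError) as exc:
        raise FetchError(f"could not fetch PDB entry {pdb_id}: {exc}") from exc
    tmp = target.with_suffix(".pdb.part")
    tmp.write_bytes(data)
    tmp.replace(target)
    return target
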