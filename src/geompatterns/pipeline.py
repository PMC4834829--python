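"""End-to-end comparison pipeline and machine-readable reporting.

``run`` executes the whole method for a pair of structures: parse -> build
the virtual grid -> grow patterns -> compute descriptors -> all-vs-all
GScore -> filtered pair list.  The method has no stochastic component, so
identical inputs and configuration reproduce the report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from . import descriptors, grid, patterns, scoring, structure_io

log = logging.getLogger(__name__)

_PDB_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


@dataclass
class RunConfig:
    """Full configuration of one comparison run.

    ``input_a``/``input_b`` are PDB file paths, or bare 4-character PDB IDs
    to fetch.  All geometric parameters are in Angstrom; weights and the
    threshold are percentages.  The grid radius default (10 A) follows the
    method's canonical worked setting; the near/far thresholds (3/10 A) and
    minimum pattern size (3) are this package's own defaults.
    """

    input_a: str = ""
    input_b: str = ""
    gr: float = 10.0
    nt: float = 3.0
    ft: float = 10.0
    min_residues: int = 3
    weights: scoring.Weights = field(default_factory=scoring.Weights)
    threshold: float = 50.0
    chains_a: list[str] | None = None
    chains_b: list[str] | None = None
    out_dir: Path | None = None
    dedup: bool = False
    energy_table: Path | None = None
    export_patterns: bool = False
    cache_dir: Path = Path("pdb_cache")

    def to_dict(self) -> dict:
        return {
            "input_a": str(self.input_a),
            "input_b": str(self.input_b),
            "grid_radius": self.gr,
            "near_threshold": self.nt,
            "far_threshold": self.ft,
            "min_residues": self.min_residues,
            "weights": dict(zip(("Dp", "Cp", "Tp", "Sp"), self.weights.as_tuple())),
            "threshold": self.threshold,
            "chains_a": self.chains_a,
            "chains_b": self.chains_b,
            "dedup": self.dedup,
            "energy_table": str(self.energy_table) if self.energy_table else None,
        }


@dataclass
class StructureSummary:
    structure_id: str
    n_residues: int
    n_grid_points: int
    n_patterns: int


@dataclass
class ComparisonReport:
    config: RunConfig
    summary_a: StructureSummary
    summary_b: StructureSummary
    total_pairs: int
    retained: list[scoring.PairScore]
    diagnostics: list[str]
    exported_pdbs: list[str] = field(default_factory=list)


def _resolve_input(spec: str, cache_dir: Path) -> Path:
    p = Path(spec)
    if p.exists():
        return p
    if _PDB_ID_RE.match(spec):
        return structure_io.fetch_structure(spec, cache_dir)
    raise FileNotFoundError(f"input {spec!r} is neither an existing file nor a PDB ID")


def _process_side(
    spec: str, chains: list[str] | None, config: RunConfig, side: str
) -> tuple[structure_io.StructureModel, list[grid.GridPoint], list[patterns.Pattern3D]]:
    try:
        path = _resolve_input(spec, config.cache_dir)
        model = structure_io.parse_structure(path, chains=chains)
        g = grid.build_grid(model, grid.GridParams(gr=config.gr))
        dp = patterns.DetectionParams(
            nt=config.nt, ft=config.ft, min_residues=config.min_residues
        )
        pats = patterns.detect_patterns(model, g, dp)
        if config.dedup:
            pats = patterns.dedup_patterns(pats)
    except Exception as exc:
        raise RuntimeError(f"stage failed for input {side} ({spec}): {exc}") from exc
    log.info(
        "%s: %d residues, %d grid points, %d patterns",
        model.id, len(model), len(g), len(pats),
    )
    return model, g, pats


def run(config: RunConfig) -> ComparisonReport:
    """Execute the full comparison described by ``config``."""
    table = (
        descriptors.EnergyTable.from_file(config.energy_table)
        if config.energy_table
        else descriptors.EnergyTable.default()
    )
    model_a, grid_a, pats_a = _process_side(config.input_a, config.chains_a, config, "A")
    model_b, grid_b, pats_b = _process_side(config.input_b, config.chains_b, config, "B")

    descs_a = [descriptors.describe(p, table) for p in pats_a]
    descs_b = [descriptors.describe(p, table) for p in pats_b]
    result = scoring.compare_all(descs_a, descs_b, config.weights, config.threshold)

    exported: list[str] = []
    if config.export_patterns and config.out_dir is not None:
        kept_a = {ps.pattern_a for ps in result.retained}
        kept_b = {ps.pattern_b for ps in result.retained}
        for model, pats, kept, tag in (
            (model_a, pats_a, kept_a, "A"),
            (model_b, pats_b, kept_b, "B"),
        ):
            for p in pats:
                if p.anchor_label in kept:
                    out = Path(config.out_dir) / f"patterns_{tag}" / f"{p.anchor_label}.pdb"
                    structure_io.write_pattern_pdb(p, model, out)
                    exported.append(str(out))

    report = ComparisonReport(
        config=config,
        summary_a=StructureSummary(model_a.id, len(model_a), len(grid_a), len(pats_a)),
        summary_b=StructureSummary(model_b.id, len(model_b), len(grid_b), len(pats_b)),
        total_pairs=result.total_pairs,
        retained=result.retained,
        diagnostics=result.diagnostics,
        exported_pdbs=exported,
    )
    if config.out_dir is not None:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        write_report(report, Path(config.out_dir) / "report.json")
    return report


def report_to_dict(report: ComparisonReport) -> dict:
    """JSON-ready dictionary: stable key order, percentages at 1 decimal."""
    return {
        "config": report.config.to_dict(),
        "structures": {
            side: {
                "id": s.structure_id,
                "n_residues": s.n_residues,
                "n_grid_points": s.n_grid_points,
                "n_patterns": s.n_patterns,
            }
            for side, s in (("A", report.summary_a), ("B", report.summary_b))
        },
        "total_pairs_evaluated": report.total_pairs,
        "n_retained": len(report.retained),
        "retained_pairs": [
            {
                "pattern_a": f"{p.structure_a}/{p.pattern_a}",
                "pattern_b": f"{p.structure_b}/{p.pattern_b}",
                "sdist": round(p.sdist, 1),
                "snbe": round(p.snbe, 1),
                "stsp": round(p.stsp, 1),
                "ssc": round(p.ssc, 1),
                "gscore": round(p.gscore, 1),
            }
            for p in report.retained
        ],
        "diagnostics": report.diagnostics,
        "exported_pattern_pdbs": report.exported_pdbs,
    }


def write_report(report: ComparisonReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")
    return path
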