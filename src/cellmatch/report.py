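"""Query orchestration and report rendering.

``run_query`` drives the full pipeline — parse the cell and space group,
reduce to the canonical P1 cell, scan the database, group hits into
families — and returns a :class:`QueryReport` that renders to a
fixed-width text table or to JSON (full precision, stable key order) for
pipeline embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from . import database as dbmod
from .cell_geometry import UnitCell, parse_cell
from .family_clustering import ClusteringParams, Family, group_families
from .reduction import P1Cell, reduce_to_p1
from .spacegroup import parse_space_group
from .superposition import default_cutoff, scan_database

REPORT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class QueryReport:
    query_cell: UnitCell
    space_group: str
    p1_cell: P1Cell
    cutoff: float
    hit_count: int
    families: tuple[Family, ...]


def run_query(
    cell_string: str,
    sg_string: str | None = None,
    cutoff: float | None = None,
    db: dbmod.Database | str | Path | None = None,
    identity_threshold: float | None = None,
) -> QueryReport:
    """Full pipeline: parse -> reduce -> scan -> family-group."""
    cell = parse_cell(cell_string) if isinstance(cell_string, str) else cell_string
    if db is None:
        raise ValueError("a database (object or path) is required")
    if not isinstance(db, dbmod.Database):
        db = dbmod.load(db)
    sg = parse_space_group(sg_string, db.aliases)
    p1 = reduce_to_p1(cell, sg)
    if cutoff is None:
        cutoff = default_cutoff(cell)
    hits = scan_database(p1, db, cutoff)
    params = (
        ClusteringParams(identity_threshold)
        if identity_threshold is not None
        else ClusteringParams()
    )
    families, _ = group_families(hits, params)
    return QueryReport(
        query_cell=cell,
        space_group=sg.canonical_symbol,
        p1_cell=p1,
        cutoff=cutoff,
        hit_count=len(hits),
        families=tuple(families),
    )


def _fmt_cell(cell: UnitCell) -> str:
    return "{:.2f} {:.2f} {:.2f}  {:.2f} {:.2f} {:.2f}".format(*cell.as_tuple())


def format_report_text(report: QueryReport, expand_families: bool = False) -> str:
    """Fixed-width report: one line per family, optionally expanded members."""
    lines = [
        f"Query cell : {_fmt_cell(report.query_cell)}",
        f"Space group: {report.space_group}",
        f"P1 cell    : {_fmt_cell(report.p1_cell.cell)}",
        f"Cutoff     : {report.cutoff:.2f} A",
        f"Hits       : {report.hit_count}",
        "",
    ]
    if not report.families:
        lines.append("No matches within cutoff.")
        return "\n".join(lines) + "\n"
    header = f"{'Family':>6}  {'Entry':<8} {'RMSD (A)':>8}  {'Space group':<12} {'Members':>7}  Organism"
    lines += [header, "-" * len(header)]
    for fam in report.families:
        rep = fam.representative
        lines.append(
            f"{fam.family_id:>6}  {rep.entry_id:<8} {rep.rmsd:>8.2f}  "
            f"{rep.record.space_group:<12} {len(fam.members):>7}  {rep.record.organism}"
        )
        if expand_families:
            for hit in fam.members:
                lines.append(
                    f"{'':>6}  - {hit.entry_id:<8} {hit.rmsd:>6.2f}  {hit.record.organism}"
                )
    return "\n".join(lines) + "\n"


def report_to_dict(report: QueryReport) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "query": {
            "cell": list(report.query_cell.as_tuple()),
            "space_group": report.space_group,
            "p1_cell": list(report.p1_cell.cell.as_tuple()),
            "cutoff": report.cutoff,
        },
        "hit_count": report.hit_count,
        "families": [
            {
                "family_id": fam.family_id,
                "composition": [list(pair) for pair in fam.composition],
                "representative": {
                    "entry_id": fam.representative.entry_id,
                    "rmsd": fam.representative.rmsd,
                    "space_group": fam.representative.record.space_group,
                    "organism": fam.representative.record.organism,
                },
                "members": [
                    {"entry_id": h.entry_id, "rmsd": h.rmsd} for h in fam.members
                ],
            }
            for fam in report.families
        ],
    }


def format_report_json(report: QueryReport) -> str:
    """Lossless JSON rendering with stable key order."""
    return json.dumps(report_to_dict(report), sort_keys=True, indent=2) + "\n"
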