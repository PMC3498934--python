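"""The local metadata store scanned at query time.

Each entry keeps the fields needed for matching and reporting — accession,
organism, experimental method, unit cell, space group, R factors, the
polymer chain sequences — plus two precomputed quantities: the canonical
primitive P1 cell (so the per-query scan is pure superposition, with no
reduction work per entry) and the space-group operator counts used by the
family-clustering step.

Entries come from mmCIF headers or from a simple one-row-per-entry TSV
bulk format.  Three-letter residue codes are mapped to one-letter codes
through an embedded static table of common modified residues (e.g. MSE,
selenomethionine, maps to M); anything unknown becomes 'X', so stored
sequences always use the 20 standard letters plus 'X'.

The store serializes to JSON Lines: a header object carrying the format
version and table checksums, then one entry per line sorted by accession —
diffable, lossless and byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from gemmi import cif

from .cell_geometry import UnitCell, validate_cell
from .errors import CellMatchError, DatabaseFormatError, IngestError
from .reduction import P1Cell, reduce_to_p1
from .spacegroup import SpaceGroupInfo, parse_space_group, symop_count  # noqa: F401

logger = logging.getLogger(__name__)

FORMAT_NAME = "cellmatch-db"
FORMAT_VERSION = 1

STANDARD_AA = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Common modified/nonstandard residues mapped to the one-letter code of
# their standard parent amino acid.  Unknown codes fall back to 'X'.
MODIFIED_AA = {
    "MSE": "M", "FME": "M", "MLY": "K", "M3L": "K", "KCX": "K",
    "LLP": "K", "ALY": "K", "MLZ": "K", "PYL": "K", "SEC": "C",
    "CSO": "C", "CME": "C", "CSD": "C", "OCS": "C", "CSX": "C",
    "SMC": "C", "SCY": "C", "CAS": "C", "HYP": "P", "TPO": "T",
    "SEP": "S", "PTR": "Y", "PCA": "E", "CGU": "E", "AIB": "A",
    "ABA": "A", "NLE": "L", "DAL": "A", "ORN": "A", "HIC": "H",
}

DEFAULT_RESIDUE_MAP = {**STANDARD_AA, **MODIFIED_AA}

SEQUENCE_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: TSV bulk-format column order (tab-separated, one entry per row).
TSV_COLUMNS = (
    "entry_id", "organism", "method",
    "a", "b", "c", "alpha", "beta", "gamma",
    "space_group", "r_work", "r_free", "chains",
)


@dataclass(frozen=True)
class EntryRecord:
    """One database entry with its precomputed P1 cell and operator counts."""

    entry_id: str
    organism: str
    method: str
    cell: UnitCell
    space_group: str
    r_work: float | None
    r_free: float | None
    p1_cell: P1Cell
    chains: tuple[tuple[str, str], ...]
    n_ops_conventional: int
    n_ops_primitive: int


@dataclass
class Database:
    entries: dict[str, EntryRecord] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    residue_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_MAP))


def map_residue(three_letter: str, table: dict[str, str] | None = None) -> str:
    """One-letter code for a three-letter residue; unknown codes give 'X'."""
    if not three_letter:
        raise ValueError("empty residue code")
    table = DEFAULT_RESIDUE_MAP if table is None else table
    return table.get(three_letter.strip().upper(), "X")


def _clean_sequence(seq: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise IngestError("empty chain sequence")
    return "".join(ch if ch in SEQUENCE_ALPHABET else "X" for ch in seq)


def build_record(
    entry_id: str,
    organism: str,
    method: str,
    cell: UnitCell,
    space_group: str,
    r_work: float | None,
    r_free: float | None,
    chains: list[tuple[str, str]],
    aliases: dict[str, str] | None = None,
) -> EntryRecord:
    """Validate fields, resolve the space group and precompute the P1 cell."""
    if len(entry_id) < 4:
        raise IngestError(f"entry id {entry_id!r} shorter than 4 characters")
    sg = parse_space_group(space_group, aliases)
    validate_cell(cell)
    return EntryRecord(
        entry_id=entry_id,
        organism=organism,
        method=method,
        cell=cell,
        space_group=sg.canonical_symbol,
        r_work=r_work,
        r_free=r_free,
        p1_cell=reduce_to_p1(cell, sg),
        chains=tuple((cid, _clean_sequence(s)) for cid, s in chains),
        n_ops_conventional=sg.n_ops_conventional,
        n_ops_primitive=sg.n_ops_primitive,
    )


# ---------------------------------------------------------------------------
# ingest

def _first_value(block: cif.Block, tags: list[str]) -> str | None:
    for tag in tags:
        for raw in block.find_values(tag):
            val = cif.as_string(raw).strip()
            if val and val not in ("?", "."):
                return val
    return None


def _optional_float(block: cif.Block, tags: list[str]) -> float | None:
    val = _first_value(block, tags)
    try:
        return float(val) if val is not None else None
    except ValueError:
        return None


def ingest_mmcif_header(
    path: str | Path,
    aliases: dict[str, str] | None = None,
    residue_map: dict[str, str] | None = None,
) -> EntryRecord:
    """Build an :class:`EntryRecord` from an mmCIF header file.

    A missing cell or space group rejects the file; missing organism,
    method or R factors leave those fields empty.
    """
    doc = cif.read(str(path))
    block = doc.sole_block()
    entry_id = (_first_value(block, ["_entry.id"]) or block.name).lower()

    cell_vals = []
    for tag in ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta", "angle_gamma"):
        v = _first_value(block, [f"_cell.{tag}"])
        if v is None:
            raise IngestError(f"{path}: missing cell parameter _cell.{tag}")
        cell_vals.append(float(v))
    cell = UnitCell(*cell_vals)

    sg_symbol = _first_value(
        block,
        ["_symmetry.space_group_name_H-M", "_space_group.name_H-M_alt", "_space_group.name_H-M_full"],
    )
    if sg_symbol is None:
        raise IngestError(f"{path}: missing space group")

    organism = _first_value(
        block,
        [
            "_entity_src_nat.pdbx_organism_scientific",
            "_entity_src_gen.pdbx_gene_src_scientific_name",
            "_pdbx_entity_src_syn.organism_scientific",
        ],
    ) or ""
    method = _first_value(block, ["_exptl.method"]) or ""
    r_work = _optional_float(block, ["_refine.ls_R_factor_R_work", "_refine.ls_R_factor_obs"])
    r_free = _optional_float(block, ["_refine.ls_R_factor_R_free"])

    # sequences: three-letter codes per entity, chain ids per entity
    seq_by_entity: dict[str, list[str]] = {}
    for row in block.find("_entity_poly_seq.", ["entity_id", "mon_id"]):
        seq_by_entity.setdefault(cif.as_string(row[0]), []).append(
            map_residue(cif.as_string(row[1]), residue_map)
        )
    chains: list[tuple[str, str]] = []
    for row in block.find("_entity_poly.", ["entity_id", "pdbx_strand_id"]):
        entity = cif.as_string(row[0])
        seq = "".join(seq_by_entity.get(entity, []))
        if not seq:
            continue
        for chain_id in cif.as_string(row[1]).replace(" ", "").split(","):
            if chain_id:
                chains.append((chain_id, seq))

    return build_record(
        entry_id, organism, method, cell, sg_symbol, r_work, r_free, chains, aliases
    )


def parse_tsv_row(line: str, aliases: dict[str, str] | None = None) -> EntryRecord:
    """One TSV row -> record.  See ``TSV_COLUMNS`` for the layout."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != len(TSV_COLUMNS):
        raise IngestError(f"expected {len(TSV_COLUMNS)} columns, got {len(fields)}")
    row = dict(zip(TSV_COLUMNS, fields))
    try:
        cell = UnitCell(*(float(row[k]) for k in ("a", "b", "c", "alpha", "beta", "gamma")))
    except ValueError as exc:
        raise IngestError(f"non-numeric cell parameter: {exc}") from exc
    chains = []
    if row["chains"]:
        for item in row["chains"].split(";"):
            chain_id, _, seq = item.partition(":")
            if not chain_id or not seq:
                raise IngestError(f"malformed chain field {item!r}")
            chains.append((chain_id, seq))
    return build_record(
        entry_id=row["entry_id"],
        organism=row["organism"],
        method=row["method"],
        cell=cell,
        space_group=row["space_group"],
        r_work=float(row["r_work"]) if row["r_work"] else None,
        r_free=float(row["r_free"]) if row["r_free"] else None,
        chains=chains,
        aliases=aliases,
    )


def ingest_tsv(
    path: str | Path, aliases: dict[str, str] | None = None
) -> list[EntryRecord]:
    """All valid records of a TSV file; malformed rows are skipped and logged.

    A duplicated entry_id keeps the later row (with a warning).
    """
    records: dict[str, EntryRecord] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        try:
            rec = parse_tsv_row(line, aliases)
        except CellMatchError as exc:
            logger.warning("%s:%d: skipped row: %s", path, lineno, exc)
            continue
        if rec.entry_id in records:
            logger.warning("%s:%d: duplicate entry %s, later row wins", path, lineno, rec.entry_id)
        records[rec.entry_id] = rec
    return list(records.values())


# ---------------------------------------------------------------------------
# output and mutation

def entry_fasta(record: EntryRecord) -> str:
    """FASTA text for an entry, one block per chain, 60-column wrapped."""
    if not record.chains:
        raise ValueError(f"entry {record.entry_id} has no chains")
    blocks = []
    for chain_id, seq in record.chains:
        wrapped = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        blocks.append(f">{record.entry_id}_{chain_id} {record.organism}".rstrip() + f"\n{wrapped}\n")
    return "".join(blocks)


def upsert_entry(db: Database, record: EntryRecord) -> None:
    db.entries[record.entry_id] = record


def purge_entry(db: Database, entry_id: str) -> None:
    if db.entries.pop(entry_id, None) is None:
        logger.warning("purge of absent entry %s: no-op", entry_id)


# ---------------------------------------------------------------------------
# persistence

def _cell_list(cell: UnitCell) -> list[float]:
    return list(cell.as_tuple())


def _record_to_json(rec: EntryRecord) -> dict:
    return {
        "entry_id": rec.entry_id,
        "organism": rec.organism,
        "method": rec.method,
        "cell": _cell_list(rec.cell),
        "space_group": rec.space_group,
        "r_work": rec.r_work,
        "r_free": rec.r_free,
        "p1_cell": _cell_list(rec.p1_cell.cell),
        "chains": [[cid, seq] for cid, seq in rec.chains],
        "n_ops_conventional": rec.n_ops_conventional,
        "n_ops_primitive": rec.n_ops_primitive,
    }


def _record_from_json(obj: dict) -> EntryRecord:
    cell = UnitCell(*obj["cell"])
    return EntryRecord(
        entry_id=obj["entry_id"],
        organism=obj["organism"],
        method=obj["method"],
        cell=cell,
        space_group=obj["space_group"],
        r_work=obj["r_work"],
        r_free=obj["r_free"],
        p1_cell=P1Cell(
            cell=UnitCell(*obj["p1_cell"]),
            source_cell=cell,
            source_space_group=obj["space_group"],
        ),
        chains=tuple((cid, seq) for cid, seq in obj["chains"]),
        n_ops_conventional=obj["n_ops_conventional"],
        n_ops_primitive=obj["n_ops_primitive"],
    )


def _dumps(obj: dict) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"))


def _table_checksum(table: dict[str, str]) -> str:
    return hashlib.sha256(_dumps(table).encode()).hexdigest()[:16]


def save(db: Database, path: str | Path) -> None:
    """Write the database as JSON Lines (header line + one entry per line)."""
    header = {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "n_entries": len(db.entries),
        "aliases": db.aliases,
        "residue_map": db.residue_map,
        "alias_checksum": _table_checksum(db.aliases),
        "residue_checksum": _table_checksum(db.residue_map),
    }
    lines = [_dumps(header)]
    for entry_id in sorted(db.entries):
        lines.append(_dumps(_record_to_json(db.entries[entry_id])))
    Path(path).write_text("\n".join(lines) + "\n")


def load(path: str | Path) -> Database:
    """Read a JSON Lines database, verifying format, version and entry count."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DatabaseFormatError(f"{path}: empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise DatabaseFormatError(f"{path}: corrupt header: {exc}") from exc
    if header.get("format") != FORMAT_NAME:
        raise DatabaseFormatError(f"{path}: not a {FORMAT_NAME} file")
    if header.get("version") != FORMAT_VERSION:
        raise DatabaseFormatError(
            f"{path}: version {header.get('version')} != supported {FORMAT_VERSION}"
        )
    if header.get("n_entries") != len(lines) - 1:
        raise DatabaseFormatError(
            f"{path}: truncated or padded: header says {header.get('n_entries')} entries, "
            f"found {len(lines) - 1}"
        )
    db = Database(aliases=dict(header["aliases"]), residue_map=dict(header["residue_map"]))
    for lineno, line in enumerate(lines[1:], 2):
        try:
            rec = _record_from_json(json.loads(line))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise DatabaseFormatError(f"{path}:{lineno}: corrupt entry: {exc}") from exc
        db.entries[rec.entry_id] = rec
    return db
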