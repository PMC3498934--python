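import logging

import numpy as np
import pytest

from cellmatch import database as dbmod
from cellmatch.cell_geometry import UnitCell
from cellmatch.errors import DatabaseFormatError, IngestError
from cellmatch.reduction import reduce_to_p1
from cellmatch.spacegroup import parse_space_group

MMCIF_FIXTURE = """\
data_1ABC
_entry.id 1ABC
_cell.length_a     57.800
_cell.length_b     57.800
_cell.length_c     150.100
_cell.angle_alpha  90.00
_cell.angle_beta   90.00
_cell.angle_gamma  90.00
_symmetry.space_group_name_H-M  'P 41 21 2'
_exptl.method  'X-RAY DIFFRACTION'
_refine.ls_R_factor_R_work 0.185
_refine.ls_R_factor_R_free 0.221
_entity_src_gen.pdbx_gene_src_scientific_name 'Thaumatococcus daniellii'
loop_
_entity_poly.entity_id
_entity_poly.pdbx_strand_id
1 'A,B'
loop_
_entity_poly_seq.entity_id
_entity_poly_seq.num
_entity_poly_seq.mon_id
1 1 MSE
1 2 ALA
1 3 GLY
1 4 ZZZ
1 5 LYS
"""

MMCIF_NO_CELL = """\
data_2XYZ
_entry.id 2XYZ
_symmetry.space_group_name_H-M 'P 1'
"""


def tsv_line(entry_id="abcd", organism="Testus organismus", sg="P 21 21 21",
             cell=(40, 50, 60, 90, 90, 90), chains="A:MKVLA;B:GGHHEE",
             r_work="0.18", r_free="0.22"):
    fields = [entry_id, organism, "X-RAY DIFFRACTION",
              *(str(x) for x in cell), sg, r_work, r_free, chains]
    return "\t".join(fields)


class TestResidueMapping:
    @pytest.mark.parametrize("three,one", [
        ("MSE", "M"), ("ALA", "A"), ("TRP", "W"), ("SEP", "S"),
        ("PTR", "Y"), ("ZZZ", "X"), ("mse", "M"),
    ])
    def test_mapping(self, three, one):
        assert dbmod.map_residue(three) == one

    def test_empty_code_rejected(self):
        with pytest.raises(ValueError):
            dbmod.map_residue("")

    def test_alphabet_closed(self):
        assert set(dbmod.DEFAULT_RESIDUE_MAP.values()) <= set(dbmod.SEQUENCE_ALPHABET)


class TestMmcifIngest:
    def test_header_fields_extracted(self, tmp_path):
        path = tmp_path / "1abc.cif"
        path.write_text(MMCIF_FIXTURE)
        rec = dbmod.ingest_mmcif_header(path)
        assert rec.entry_id == "1abc"
        assert rec.cell == UnitCell(57.8, 57.8, 150.1, 90, 90, 90)
        assert rec.space_group == "P 41 21 2"
        assert rec.n_ops_conventional == 8
        assert rec.organism == "Thaumatococcus daniellii"
        assert rec.r_work == pytest.approx(0.185)
        assert rec.r_free == pytest.approx(0.221)
        # one entity shared by chains A and B; MSE -> M, unknown ZZZ -> X
        assert rec.chains == (("A", "MAGXK"), ("B", "MAGXK"))

    def test_missing_cell_rejected(self, tmp_path):
        path = tmp_path / "2xyz.cif"
        path.write_text(MMCIF_NO_CELL)
        with pytest.raises(IngestError, match="cell"):
            dbmod.ingest_mmcif_header(path)

    def test_p1_cell_precomputed_consistently(self, tmp_path):
        path = tmp_path / "1abc.cif"
        path.write_text(MMCIF_FIXTURE)
        rec = dbmod.ingest_mmcif_header(path)
        expected = reduce_to_p1(rec.cell, parse_space_group(rec.space_group)).cell
        assert np.allclose(rec.p1_cell.cell.as_tuple(), expected.as_tuple(), rtol=1e-12)


class TestTsvIngest:
    def test_three_rows(self, tmp_path):
        path = tmp_path / "in.tsv"
        path.write_text("\n".join([
            tsv_line("aaaa"), tsv_line("bbbb", sg="C2", cell=(30, 40, 50, 90, 100, 90)),
            tsv_line("cccc", chains="A:MKV"),
        ]) + "\n")
        records = dbmod.ingest_tsv(path)
        assert [r.entry_id for r in records] == ["aaaa", "bbbb", "cccc"]
        assert records[1].n_ops_primitive == 2

    def test_bad_rows_skipped_with_reason(self, tmp_path, caplog):
        path = tmp_path / "in.tsv"
        path.write_text("\n".join([
            tsv_line("aaaa"),
            tsv_line("badg", sg="Q999"),      # unknown space group
            tsv_line("badc", cell=(0, 50, 60, 90, 90, 90)),  # degenerate cell
            "too\tfew\tcolumns",
        ]) + "\n")
        with caplog.at_level(logging.WARNING):
            records = dbmod.ingest_tsv(path)
        assert [r.entry_id for r in records] == ["aaaa"]
        assert sum("skipped" in m for m in caplog.messages) == 3

    def test_duplicate_id_later_row_wins(self, tmp_path, caplog):
        path = tmp_path / "in.tsv"
        path.write_text(tsv_line("aaaa") + "\n" +
                        tsv_line("aaaa", cell=(41, 50, 60, 90, 90, 90)) + "\n")
        with caplog.at_level(logging.WARNING):
            records = dbmod.ingest_tsv(path)
        assert len(records) == 1
        assert records[0].cell.a == 41
        assert any("duplicate" in m for m in caplog.messages)

    def test_sequence_alphabet_enforced(self, tmp_path):
        path = tmp_path / "in.tsv"
        path.write_text(tsv_line("aaaa", chains="A:MKB*Z") + "\n")
        (rec,) = dbmod.ingest_tsv(path)
        assert rec.chains == (("A", "MKXXX"),)


class TestFasta:
    def _record(self):
        return dbmod.build_record(
            "abcd", "Testus organismus", "X-RAY DIFFRACTION",
            UnitCell(40, 50, 60, 90, 90, 90), "P212121", None, None,
            [("A", "MKVLA" * 30), ("B", "GG")],
        )

    def test_blocks_headers_and_wrapping(self):
        text = dbmod.entry_fasta(self._record())
        lines = text.splitlines()
        assert lines[0] == ">abcd_A Testus organismus"
        assert all(len(ln) <= 60 for ln in lines)
        assert ">abcd_B Testus organismus" in lines

    def test_roundtrip_through_fasta_parser(self):
        from io import StringIO
        from Bio import SeqIO

        rec = self._record()
        parsed = list(SeqIO.parse(StringIO(dbmod.entry_fasta(rec)), "fasta"))
        assert [(p.id.split("_")[1], str(p.seq)) for p in parsed] == list(rec.chains)

    def test_chainless_record_rejected(self):
        rec = dbmod.build_record("abcd", "", "", UnitCell(40, 50, 60, 90, 90, 90),
                                 "P1", None, None, [])
        with pytest.raises(ValueError):
            dbmod.entry_fasta(rec)


class TestUpsertPurge:
    def test_random_interleaving_matches_dict_oracle(self, rng):
        db = dbmod.Database()
        oracle: dict[str, float] = {}
        ids = [f"ent{i}" for i in range(8)]
        for step in range(200):
            entry_id = ids[int(rng.integers(len(ids)))]
            if rng.random() < 0.6:
                a = float(rng.uniform(30, 80))
                rec = dbmod.build_record(entry_id, "o", "m",
                                         UnitCell(a, 50, 60, 90, 90, 90),
                                         "P1", None, None, [("A", "MK")])
                dbmod.upsert_entry(db, rec)
                oracle[entry_id] = a
            else:
                dbmod.purge_entry(db, entry_id)
                oracle.pop(entry_id, None)
        assert {k: v.cell.a for k, v in db.entries.items()} == oracle

    def test_upsert_recomputes_p1_cell(self):
        db = dbmod.Database()
        r1 = dbmod.build_record("abcd", "o", "m", UnitCell(40, 50, 60, 90, 90, 90),
                                "P1", None, None, [("A", "MK")])
        r2 = dbmod.build_record("abcd", "o", "m", UnitCell(70, 50, 60, 90, 90, 90),
                                "P1", None, None, [("A", "MK")])
        dbmod.upsert_entry(db, r1)
        dbmod.upsert_entry(db, r2)
        assert len(db.entries) == 1
        assert db.entries["abcd"].p1_cell.cell.c == pytest.approx(70)

    def test_purge_absent_is_noop_with_warning(self, caplog):
        db = dbmod.Database()
        with caplog.at_level(logging.WARNING):
            dbmod.purge_entry(db, "nothere")
        assert any("no-op" in m for m in caplog.messages)


class TestPersistence:
    def _db(self):
        db = dbmod.Database(aliases={"H3": "R3:H"})
        for i, sg in enumerate(["P1", "C2", "P41212"]):
            cell = (UnitCell(40 + i, 50, 60, 90, 100, 90) if sg == "C2"
                    else UnitCell(50 + i, 50 + i, 60, 90, 90, 90) if sg == "P41212"
                    else UnitCell(40 + i, 50, 60, 85, 95, 100))
            rec = dbmod.build_record(f"ent{i:04d}", f"org {i}", "X-RAY DIFFRACTION",
                                     cell, sg, 0.2, 0.25, [("A", "MKVL"), ("B", "GHE")],
                                     db.aliases)
            dbmod.upsert_entry(db, rec)
        return db

    def test_roundtrip_field_for_field(self, tmp_path):
        db = self._db()
        path = tmp_path / "db.jsonl"
        dbmod.save(db, path)
        loaded = dbmod.load(path)
        assert loaded.aliases == db.aliases
        assert loaded.residue_map == db.residue_map
        assert set(loaded.entries) == set(db.entries)
        for k in db.entries:
            a, b = db.entries[k], loaded.entries[k]
            assert a.cell == b.cell
            assert a.p1_cell.cell == b.p1_cell.cell
            assert (a.organism, a.method, a.space_group, a.r_work, a.r_free,
                    a.chains, a.n_ops_conventional, a.n_ops_primitive) == (
                   b.organism, b.method, b.space_group, b.r_work, b.r_free,
                   b.chains, b.n_ops_conventional, b.n_ops_primitive)

    def test_save_is_byte_stable(self, tmp_path):
        db = self._db()
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        dbmod.save(db, p1)
        dbmod.save(db, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truncated_file_rejected_atomically(self, tmp_path):
        db = self._db()
        path = tmp_path / "db.jsonl"
        dbmod.save(db, path)
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(DatabaseFormatError, match="truncated"):
            dbmod.load(path)

    def test_wrong_format_or_version_rejected(self, tmp_path):
        path = tmp_path / "x.jsonl"
        path.write_text('{"format":"something-else","version":1}\n')
        with pytest.raises(DatabaseFormatError):
            dbmod.load(path)
        path.write_text('{"format":"cellmatch-db","version":99,"n_entries":0,'
                        '"aliases":{},"residue_map":{}}\n')
        with pytest.raises(DatabaseFormatError, match="version"):
            dbmod.load(path)

    def test_stored_p1_cells_recheck(self, fixture_db):
        db = fixture_db["db"]
        for rec in db.entries.values():
            expected = reduce_to_p1(rec.cell, parse_space_group(rec.space_group)).cell
            assert np.allclose(rec.p1_cell.cell.as_tuple(), expected.as_tuple(),
                               rtol=1e-6, atol=1e-6)
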