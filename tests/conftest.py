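import numpy as np
import pytest

from cellmatch.cell_geometry import UnitCell, validate_cell
from cellmatch.errors import DegenerateCellError


def random_valid_cell(rng: np.random.Generator,
                      length_range=(20.0, 120.0),
                      angle_range=(60.0, 130.0)) -> UnitCell:
    """Draw a generic triclinic cell, resampling until geometrically valid."""
    while True:
        params = [
            *(rng.uniform(*length_range) for _ in range(3)),
            *(rng.uniform(*angle_range) for _ in range(3)),
        ]
        try:
            return validate_cell(UnitCell(*params))
        except DegenerateCellError:
            continue


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fixture_db(tmp_path_factory):
    """A small synthetic database with ground truth, shared across tests."""
    from cellmatch import database as dbmod
    from cellmatch.fixtures import FixtureSpec, build_fixture_db

    root = tmp_path_factory.mktemp("fixture_db")
    spec = FixtureSpec(seed=7, n_background=30, n_planted=2)
    manifest = build_fixture_db(spec, root / "entries.tsv", root / "manifest.json")
    db = dbmod.Database()
    for rec in dbmod.ingest_tsv(root / "entries.tsv"):
        dbmod.upsert_entry(db, rec)
    db_path = root / "db.jsonl"
    dbmod.save(db, db_path)
    return {"spec": spec, "manifest": manifest, "db": db, "db_path": db_path,
            "tsv_path": root / "entries.tsv"}
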