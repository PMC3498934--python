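"""Space-group symbol handling for the 65 Sohncke groups.

Protein crystals are enantiopure, so only the Sohncke space groups (those
containing proper operations only) occur.  Symbols are resolved through the
International Tables data shipped with gemmi: spacing-insensitive
Hermann-Mauguin forms ("P41212" / "P 41 21 2"), rhombohedral setting
suffixes (":R" / ":H") and, first of all, a user-supplied alias table for
nonstandard symbols occasionally deposited in the PDB.

The quantity downstream code needs is the operator count: the number of
symmetry operators of the conventional setting (centering translations
included) and of the primitive setting (conventional count divided by the
centering multiplicity).  Bare rhombohedral symbols like "R3" resolve to
the hexagonal setting (multiplicity 3), matching the IT default.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from pathlib import Path

import gemmi

from .errors import UnknownSpaceGroupError

#: centering letter -> number of lattice points in the conventional cell
CENTERING_MULTIPLICITY = {
    "P": 1,
    "A": 2,
    "B": 2,
    "C": 2,
    "I": 2,
    "F": 4,
    "R_hex": 3,
    "R_rhomb": 1,
}


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Resolved space group: canonical symbol, centering and operator counts."""

    canonical_symbol: str
    centering: str  # key into CENTERING_MULTIPLICITY
    n_ops_conventional: int
    n_ops_primitive: int

    @property
    def multiplicity(self) -> int:
        return CENTERING_MULTIPLICITY[self.centering]


def _sohncke_symbols() -> list[str]:
    seen = []
    for sg in gemmi.spacegroup_table():
        if sg.is_sohncke() and sg.xhm() not in seen:
            seen.append(sg.xhm())
    return seen


def load_alias_table(path: str | Path) -> dict[str, str]:
    """Read a two-column plain-text alias table.

    Each non-empty, non-comment line maps an observed symbol to a canonical
    one; columns are separated by a tab or by ``->``.
    """
    aliases: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "->" in line:
            left, _, right = line.partition("->")
        elif "\t" in line:
            left, _, right = line.partition("\t")
        else:
            raise ValueError(f"{path}:{lineno}: expected 'observed -> canonical' or tab-separated columns")
        aliases[left.strip()] = right.strip()
    return aliases


def _centering_key(sg: gemmi.SpaceGroup) -> str:
    symbol = sg.xhm()
    if symbol.startswith("R"):
        return "R_hex" if sg.ext == "H" else "R_rhomb"
    return sg.centring_type()


def parse_space_group(
    symbol: str | None, aliases: dict[str, str] | None = None
) -> SpaceGroupInfo:
    """Resolve a Hermann-Mauguin symbol to a :class:`SpaceGroupInfo`.

    An absent / empty symbol defaults to P1 (a query without a space group
    is treated as already primitive).  Unknown symbols raise
    :class:`UnknownSpaceGroupError` listing the nearest Sohncke symbols.
    """
    if symbol is None or not symbol.strip():
        symbol = "P1"
    symbol = symbol.strip()
    if aliases:
        symbol = aliases.get(symbol, symbol)
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None or not sg.is_sohncke():
        pool = _sohncke_symbols()
        compact = symbol.replace(" ", "").upper()
        candidates = difflib.get_close_matches(
            compact, [s.replace(" ", "").upper() for s in pool], n=3, cutoff=0.6
        )
        named = [p for p in pool if p.replace(" ", "").upper() in candidates]
        raise UnknownSpaceGroupError(symbol, named)
    centering = _centering_key(sg)
    n_conv = len(sg.operations())
    mult = CENTERING_MULTIPLICITY[centering]
    assert n_conv % mult == 0, (symbol, n_conv, mult)
    return SpaceGroupInfo(
        canonical_symbol=sg.xhm(),
        centering=centering,
        n_ops_conventional=n_conv,
        n_ops_primitive=n_conv // mult,
    )


def symop_count(sg: SpaceGroupInfo) -> tuple[int, int]:
    """(conventional, primitive) operator counts of a resolved group."""
    return (sg.n_ops_conventional, sg.n_ops_primitive)
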