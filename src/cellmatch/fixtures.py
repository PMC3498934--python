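"""Synthetic PDB-like metadata with known ground truth.

Real inputs to this tool are weekly PDB metadata dumps; tests and demos
instead use a generated stand-in with the same shape and a manifest of
what was planted:

* random unit cells drawn per space group with the metric constraints of
  its crystal system enforced (tetragonal cells really have a = b and
  right angles, rhombohedral cells a = b = c, ...), so symbols and cells
  are mutually consistent like genuine depositions;
* *planted match groups*: a base entry plus near-copies whose cells are
  perturbed to sit well inside the default matching cutoff, decoy entries
  perturbed to sit well outside it, and optionally a "coincident" entry —
  an unrelated protein in an almost identical cell, the case the family
  clustering exists to separate;
* sequence families with controlled intra-family identity (mutants of a
  parent with an exact substitution count) against a background of
  unrelated random sequences (~5% pairwise identity).

Everything is drawn from one seeded generator, so a given spec yields
byte-identical TSV and manifest files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .cell_geometry import UnitCell, validate_cell
from .errors import DegenerateCellError
from .reduction import reduce_to_p1
from .spacegroup import parse_space_group
from .superposition import best_cell_rmsd, default_cutoff

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sohncke groups common in protein crystallography, used as the default palette.
DEFAULT_SG_PALETTE = (
    "P 1", "P 1 21 1", "C 1 2 1", "P 21 21 21", "P 41 21 2",
    "P 32 2 1", "I 2 2 2", "P 63", "R 3:H", "I 4",
)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_background: int = 60
    n_planted: int = 3
    n_near_per_planted: int = 5
    n_decoy_per_planted: int = 2
    coincident_per_planted: int = 1
    sg_palette: tuple[str, ...] = DEFAULT_SG_PALETTE
    length_range: tuple[float, float] = (30.0, 150.0)
    sigma_len: float = 0.08  # Å, near-copy jitter
    sigma_ang: float = 0.05  # degrees
    decoy_sigma_len: float = 25.0
    decoy_sigma_ang: float = 8.0
    seq_length: int = 120
    intra_identity: float = 0.95
    max_chains: int = 2


# ---------------------------------------------------------------------------
# cells

def _monoclinic_unique_axis(xhm: str) -> int:
    parts = xhm.split()[1:]
    for i, p in enumerate(parts):
        if p != "1":
            return i
    return 1


def _free_params(sg_symbol: str) -> tuple[list[list[int]], list[int], list[float]]:
    """(length tie-groups, free angle indices, fixed angle values) per system."""
    sg = gemmi.find_spacegroup_by_name(sg_symbol)
    cs = sg.crystal_system_str()
    if cs == "triclinic":
        return [[0], [1], [2]], [0, 1, 2], [90.0, 90.0, 90.0]
    if cs == "monoclinic":
        axis = _monoclinic_unique_axis(sg.xhm())
        return [[0], [1], [2]], [axis], [90.0, 90.0, 90.0]
    if cs == "orthorhombic":
        return [[0], [1], [2]], [], [90.0, 90.0, 90.0]
    if cs == "tetragonal":
        return [[0, 1], [2]], [], [90.0, 90.0, 90.0]
    if cs in ("trigonal", "hexagonal"):
        if sg.ext == "R":
            return [[0, 1, 2]], [-1], [90.0, 90.0, 90.0]  # -1: all three angles tied
        return [[0, 1], [2]], [], [90.0, 90.0, 120.0]
    if cs == "cubic":
        return [[0, 1, 2]], [], [90.0, 90.0, 90.0]
    raise ValueError(f"unhandled crystal system {cs!r} for {sg_symbol}")


def _assemble(lengths: list[float], angles: list[float]) -> UnitCell:
    return validate_cell(UnitCell(*lengths, *angles))


def synth_cell(
    rng: np.random.Generator,
    sg_symbol: str,
    length_range: tuple[float, float] = (30.0, 150.0),
) -> UnitCell:
    """A random valid cell consistent with the space group's metric constraints."""
    ties, free_angles, fixed = _free_params(sg_symbol)
    lo, hi = length_range
    for _ in range(100):
        lengths = [0.0, 0.0, 0.0]
        for group in ties:
            val = float(rng.uniform(lo, hi))
            for i in group:
                lengths[i] = val
        angles = list(fixed)
        if free_angles == [-1]:  # rhombohedral: three equal oblique angles
            val = float(rng.uniform(70.0, 110.0))
            angles = [val, val, val]
        else:
            for i in free_angles:
                angles[i] = float(rng.uniform(80.0, 120.0))
        try:
            return _assemble(lengths, angles)
        except DegenerateCellError:
            continue
    raise RuntimeError(f"could not sample a valid cell for {sg_symbol}")


def perturb_cell(
    cell: UnitCell,
    sigma_len: float,
    sigma_ang: float,
    rng: np.random.Generator | int,
    sg_symbol: str = "P 1",
) -> tuple[UnitCell, dict[str, float]]:
    """Gaussian jitter on the cell's free parameters, resampled until valid.

    Parameters tied by the crystal system (a = b in tetragonal cells, the
    right angles of orthorhombic cells, ...) move together or not at all,
    so the perturbed cell remains consistent with the space group.  Returns
    the new cell and the true perturbation applied, for ground truth.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    ties, free_angles, _ = _free_params(sg_symbol)
    for _ in range(100):
        lengths = list(cell.lengths)
        angles = list(cell.angles)
        deltas: dict[str, float] = {}
        for group in ties:
            d = float(rng.normal(0.0, sigma_len)) if sigma_len > 0 else 0.0
            for i in group:
                lengths[i] = cell.lengths[i] + d
                deltas["abc"[i]] = d
        if free_angles == [-1]:
            d = float(rng.normal(0.0, sigma_ang)) if sigma_ang > 0 else 0.0
            angles = [x + d for x in cell.angles]
            deltas.update({"alpha": d, "beta": d, "gamma": d})
        else:
            for i in free_angles:
                d = float(rng.normal(0.0, sigma_ang)) if sigma_ang > 0 else 0.0
                angles[i] = cell.angles[i] + d
                deltas[("alpha", "beta", "gamma")[i]] = d
        try:
            return _assemble(lengths, angles), deltas
        except DegenerateCellError:
            continue
    raise RuntimeError("perturbation kept producing degenerate cells")


# ---------------------------------------------------------------------------
# sequences

def synth_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def synth_sequence_family(
    n: int, length: int, intra_identity: float, rng: np.random.Generator | int
) -> list[str]:
    """A parent plus n-1 mutants with an exact substitution count each.

    Each mutant differs from the parent at exactly
    ``round((1 - intra_identity) * length)`` distinct positions, every
    substitution to a different letter.
    """
    if not (0.0 < intra_identity <= 1.0):
        raise ValueError(f"intra_identity must be in (0, 1], got {intra_identity}")
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    parent = synth_sequence(rng, length)
    n_sub = round((1.0 - intra_identity) * length)
    out = [parent]
    for _ in range(n - 1):
        positions = rng.choice(length, size=n_sub, replace=False)
        seq = list(parent)
        for pos in positions:
            choices = [aa for aa in AMINO_ACIDS if aa != seq[pos]]
            seq[pos] = choices[int(rng.integers(len(choices)))]
        out.append("".join(seq))
    return out


# ---------------------------------------------------------------------------
# database fixture

@dataclass
class _PendingEntry:
    entry_id: str
    organism: str
    cell: UnitCell
    space_group: str
    chains: list[tuple[str, str]]
    r_work: float
    r_free: float
    role: str  # base | near | decoy | coincident | background
    group: int | None
    proteins: list[str]  # ground-truth protein labels, one per chain


def _reduced(cell: UnitCell, sg_symbol: str) -> UnitCell:
    return reduce_to_p1(cell, parse_space_group(sg_symbol)).cell


def build_fixture_db(
    spec: FixtureSpec,
    tsv_path: str | Path,
    manifest_path: str | Path,
) -> dict:
    """Write the TSV metadata dump plus a ground-truth manifest; return the manifest.

    Near copies are accepted only if their reduced-cell RMSD to the base is
    below half the base query's default cutoff; decoys and background
    entries only if above twice it (above it, for background, against every
    planted base) — so the planted in/out-of-cutoff sets are unambiguous
    by construction.
    """
    rng = np.random.default_rng(spec.seed)
    entries: list[_PendingEntry] = []
    manifest_groups = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"syn{counter:04d}"

    def r_factors() -> tuple[float, float]:
        rw = float(np.round(rng.uniform(0.14, 0.24), 3))
        return rw, float(np.round(rw + rng.uniform(0.02, 0.05), 3))

    def make_chains(seqs: list[str], labels: list[str]) -> tuple[list[tuple[str, str]], list[str]]:
        ids = [chr(ord("A") + i) for i in range(len(seqs))]
        return list(zip(ids, seqs)), labels

    protein_counter = 0

    def new_protein_label() -> str:
        nonlocal protein_counter
        protein_counter += 1
        return f"prot{protein_counter:03d}"

    base_reduced: list[tuple[UnitCell, float]] = []  # (reduced base cell, base cutoff)

    def far_from_other_bases(red: UnitCell, own_group: int | None) -> bool:
        """True if *red* is safely outside every other group's cutoff."""
        return all(
            best_cell_rmsd(other_red, red).rmsd > 2.0 * other_cutoff
            for gi, (other_red, other_cutoff) in enumerate(base_reduced)
            if gi != own_group
        )

    for g in range(spec.n_planted):
        for _ in range(500):
            sg_symbol = spec.sg_palette[int(rng.integers(len(spec.sg_palette)))]
            base_cell = synth_cell(rng, sg_symbol, spec.length_range)
            cutoff = default_cutoff(base_cell)
            base_red = _reduced(base_cell, sg_symbol)
            # well separated from previous groups so planted sets stay disjoint
            if all(
                best_cell_rmsd(other_red, base_red).rmsd > 3.0 * (cutoff + other_cutoff)
                for other_red, other_cutoff in base_reduced
            ):
                break
        else:
            raise RuntimeError("could not place a planted base away from earlier groups")
        base_reduced.append((base_red, cutoff))
        n_chains = int(rng.integers(1, spec.max_chains + 1))
        labels = [new_protein_label() for _ in range(n_chains)]
        n_members = 1 + spec.n_near_per_planted
        seq_families = [
            synth_sequence_family(n_members, spec.seq_length, spec.intra_identity, rng)
            for _ in range(n_chains)
        ]

        def planted_entry(cell: UnitCell, role: str, member_idx: int | None) -> _PendingEntry:
            rw, rf = r_factors()
            if member_idx is None:  # unrelated content
                label = new_protein_label()
                chains, labs = make_chains([synth_sequence(rng, spec.seq_length)], [label])
            else:
                chains, labs = make_chains(
                    [fam[member_idx] for fam in seq_families], list(labels)
                )
            return _PendingEntry(
                entry_id=next_id(), organism=f"Synthetica sp. {labs[0]}",
                cell=cell, space_group=sg_symbol, chains=chains,
                r_work=rw, r_free=rf, role=role, group=g, proteins=labs,
            )

        base_entry = planted_entry(base_cell, "base", 0)
        entries.append(base_entry)
        near_ids, decoy_ids, coincident_ids = [], [], []

        def place_inside(role: str, member_idx: int | None) -> _PendingEntry:
            for _ in range(200):
                cell, _d = perturb_cell(base_cell, spec.sigma_len, spec.sigma_ang, rng, sg_symbol)
                red = _reduced(cell, sg_symbol)
                if best_cell_rmsd(base_red, red).rmsd <= 0.5 * cutoff and far_from_other_bases(red, g):
                    return planted_entry(cell, role, member_idx)
            raise RuntimeError(f"could not place a {role} entry inside the cutoff")

        for i in range(spec.n_near_per_planted):
            e = place_inside("near", 1 + i)
            entries.append(e)
            near_ids.append(e.entry_id)

        for _i in range(spec.n_decoy_per_planted):
            for _ in range(200):
                cell, _d = perturb_cell(
                    base_cell, spec.decoy_sigma_len, spec.decoy_sigma_ang, rng, sg_symbol
                )
                red = _reduced(cell, sg_symbol)
                if best_cell_rmsd(base_red, red).rmsd >= 2.0 * cutoff and far_from_other_bases(red, g):
                    break
            else:
                raise RuntimeError("could not place a decoy outside the cutoff")
            e = planted_entry(cell, "decoy", None)
            entries.append(e)
            decoy_ids.append(e.entry_id)

        for _i in range(spec.coincident_per_planted):
            e = place_inside("coincident", None)
            entries.append(e)
            coincident_ids.append(e.entry_id)

        manifest_groups.append(
            {
                "group": g,
                "base_id": base_entry.entry_id,
                "near_ids": near_ids,
                "decoy_ids": decoy_ids,
                "coincident_ids": coincident_ids,
                "space_group": sg_symbol,
                "base_cell": list(base_cell.as_tuple()),
                "cutoff": cutoff,
            }
        )

    for _ in range(spec.n_background):
        for _ in range(500):
            sg_symbol = spec.sg_palette[int(rng.integers(len(spec.sg_palette)))]
            cell = synth_cell(rng, sg_symbol, spec.length_range)
            if far_from_other_bases(_reduced(cell, sg_symbol), None):
                break
        else:
            raise RuntimeError("could not place a background entry away from planted bases")
        rw, rf = r_factors()
        label = new_protein_label()
        entries.append(
            _PendingEntry(
                entry_id=next_id(), organism=f"Synthetica sp. {label}",
                cell=cell, space_group=sg_symbol,
                chains=[("A", synth_sequence(rng, spec.seq_length))],
                r_work=rw, r_free=rf, role="background", group=None, proteins=[label],
            )
        )

    # write TSV
    lines = []
    for e in entries:
        chains_field = ";".join(f"{cid}:{seq}" for cid, seq in e.chains)
        cell_fields = [repr(x) for x in e.cell.as_tuple()]  # full precision round-trip
        lines.append(
            "\t".join(
                [e.entry_id, e.organism, "X-RAY DIFFRACTION", *cell_fields,
                 e.space_group, f"{e.r_work:.3f}", f"{e.r_free:.3f}", chains_field]
            )
        )
    Path(tsv_path).write_text("\n".join(lines) + "\n")

    manifest = {
        "spec": {
            "seed": spec.seed,
            "n_background": spec.n_background,
            "n_planted": spec.n_planted,
            "n_near_per_planted": spec.n_near_per_planted,
            "n_decoy_per_planted": spec.n_decoy_per_planted,
            "coincident_per_planted": spec.coincident_per_planted,
            "seq_length": spec.seq_length,
            "intra_identity": spec.intra_identity,
        },
        "groups": manifest_groups,
        "entries": {
            e.entry_id: {
                "role": e.role,
                "group": e.group,
                "space_group": e.space_group,
                "proteins": e.proteins,
                "primitive_volume_ratio": 1.0 / parse_space_group(e.space_group).multiplicity,
            }
            for e in entries
        },
    }
    Path(manifest_path).write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")
    return manifest
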