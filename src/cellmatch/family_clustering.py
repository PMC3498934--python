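"""Grouping of cell-match hits into sequence families.

Many PDB entries of the same protein crystallize in the same (or a very
similar) cell, so a cell match often returns dozens of hits that are all
one crystal form.  To report each distinct content once, the hit set's
chain sequences are greedily clustered at a sequence-identity threshold
(90% of the shorter sequence by default), each entry is described by how
many chains of each cluster its primitive P1 cell contains — chains in
the asymmetric unit times the primitive symmetry-operator count — and
entries whose cluster multiplicities match exactly form one family,
represented by the member with the smallest RMSD to the query.

Identity between two sequences is the number of identical positions in
the optimal global alignment (match +1, mismatch 0, affine gaps
open -10 / extend -0.5, used only to shape the alignment) divided by the
shorter sequence length.  Clustering is recomputed per query over the hit
set only; at that scale the exact alignment is fast and fully
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import Align

from .database import EntryRecord
from .superposition import MatchHit

DEFAULT_IDENTITY_THRESHOLD = 0.90

#: slack for comparing an identity fraction against the threshold, so that a
#: pair at exactly the threshold (e.g. 90/100) always co-clusters
_THRESHOLD_FUZZ = 1e-9


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError(f"identity threshold must be in (0, 1], got {self.identity_threshold}")


@dataclass
class SequenceCluster:
    cluster_id: int
    representative: str
    members: list[tuple[str, str]] = field(default_factory=list)  # (entry_id, chain_id)


@dataclass(frozen=True)
class Family:
    family_id: int
    composition: tuple[tuple[int, int], ...]  # sorted (cluster_id, multiplicity)
    members: tuple[MatchHit, ...]
    representative: MatchHit


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(s1: str, s2: str) -> float:
    """Fraction of identical aligned positions over the shorter length."""
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    if s1 == s2:
        return 1.0
    alignment = _ALIGNER.align(s1, s2)[0]
    identities = alignment.counts().identities
    return identities / min(len(s1), len(s2))


def greedy_cluster(
    sequences: Iterable[tuple[tuple[str, str], str]],
    params: ClusteringParams | None = None,
) -> list[SequenceCluster]:
    """CD-HIT-style greedy incremental clustering of labelled sequences.

    Input items are ``((entry_id, chain_id), sequence)``.  Sequences are
    visited longest-first (ties by sequence then label); each one joins the
    first existing cluster whose *representative* it matches at or above
    the identity threshold, otherwise it seeds a new cluster.  The order is
    total, so the partition is deterministic.
    """
    params = params or ClusteringParams()
    items = sorted(sequences, key=lambda it: (-len(it[1]), it[1], it[0]))
    if not items:
        return []
    clusters: list[SequenceCluster] = []
    for label, seq in items:
        for cluster in clusters:
            if pairwise_identity(cluster.representative, seq) >= (
                params.identity_threshold - _THRESHOLD_FUZZ
            ):
                cluster.members.append(label)
                break
        else:
            clusters.append(
                SequenceCluster(cluster_id=len(clusters) + 1, representative=seq, members=[label])
            )
    return clusters


def _membership(clusters: Sequence[SequenceCluster]) -> dict[tuple[str, str], int]:
    return {label: c.cluster_id for c in clusters for label in c.members}


def composition_vector(
    record: EntryRecord, clusters: Sequence[SequenceCluster]
) -> dict[int, int]:
    """Cluster multiplicities of the entry's primitive P1 cell.

    Chain counts in the asymmetric unit are multiplied by the primitive
    symmetry-operator count, since the stored P1 cell is the primitive
    cell whose content is ASU content x primitive operator count.
    """
    member_of = _membership(clusters)
    counts: dict[int, int] = {}
    for chain_id, _ in record.chains:
        try:
            cid = member_of[(record.entry_id, chain_id)]
        except KeyError:
            raise KeyError(
                f"chain {record.entry_id}/{chain_id} was not clustered"
            ) from None
        counts[cid] = counts.get(cid, 0) + 1
    return {cid: n * record.n_ops_primitive for cid, n in counts.items()}


def group_families(
    hits: Sequence[MatchHit],
    params: ClusteringParams | None = None,
) -> tuple[list[Family], list[SequenceCluster]]:
    """Partition hits into families of identical cluster composition.

    Sequence clusters are computed over all chains of all hits; hits with
    equal composition vectors form one family.  Families are sorted by
    their representative's RMSD (the member with the smallest RMSD, ties
    by entry_id) and numbered from 1.
    """
    if not hits:
        return [], []
    labelled = [
        ((hit.entry_id, chain_id), seq)
        for hit in hits
        for chain_id, seq in hit.record.chains
    ]
    clusters = greedy_cluster(labelled, params)
    by_composition: dict[tuple[tuple[int, int], ...], list[MatchHit]] = {}
    for hit in hits:
        key = tuple(sorted(composition_vector(hit.record, clusters).items()))
        by_composition.setdefault(key, []).append(hit)
    families = []
    for key, members in by_composition.items():
        members = sorted(members, key=lambda h: (h.rmsd, h.entry_id))
        families.append((key, members))
    families.sort(key=lambda kv: (kv[1][0].rmsd, kv[1][0].entry_id))
    return (
        [
            Family(
                family_id=i,
                composition=key,
                members=tuple(members),
                representative=members[0],
            )
            for i, (key, members) in enumerate(families, 1)
        ],
        clusters,
    )
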