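"""Independent brute-force oracles used by the test suite.

These deliberately avoid the algorithms used by the package itself:
rotation fitting is done by random search plus simplex refinement (no
SVD), lattice checks by integer enumeration, and alignment identity by a
full dynamic-programming table over the alignment graph (no Biopython).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_min_rmsd(P: np.ndarray, Q: np.ndarray, seed: int = 0,
                         n_coarse: int = 4000) -> float:
    """Minimum RMSD over proper rotations (+ translation) by direct search.

    Coarse stage: RMSD under ``n_coarse`` random rotations after centroid
    removal.  Fine stage: Nelder-Mead refinement in rotation-vector space
    from the best coarse candidates.
    """
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    rots = Rotation.random(n_coarse, random_state=seed)
    mats = rots.as_matrix()  # (n, 3, 3)
    rotated = np.einsum("nij,kj->nki", mats, P0)
    rmsds = np.sqrt(((rotated - Q0) ** 2).sum(axis=(1, 2)) / P0.shape[0])

    def objective(rotvec: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = P0 @ R.T - Q0
        return float(np.sqrt((d * d).sum() / P0.shape[0]))

    best = np.inf
    for idx in np.argsort(rmsds)[:5]:
        res = minimize(objective, rots[int(idx)].as_rotvec(), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(res.fun))
    return best


def shortest_lattice_vector(basis: np.ndarray, reach: int = 3) -> float:
    """Length of the shortest nonzero lattice vector, by integer enumeration."""
    rng = range(-reach, reach + 1)
    combos = np.array([(i, j, k) for i in rng for j in rng for k in rng
                       if (i, j, k) != (0, 0, 0)])
    vecs = combos @ basis
    return float(np.linalg.norm(vecs, axis=1).min())


def alignment_identity_range(s1: str, s2: str, match=1.0, mismatch=0.0,
                             gap_open=-10.0, gap_extend=-0.5):
    """(optimal score, min identities, max identities) over all optimal
    global alignments, by full DP over the affine-gap alignment graph.

    States: 0 = aligned pair, 1 = gap in s2 (s1 residue unmatched),
    2 = gap in s1.  A gap of length k costs gap_open + (k-1)*gap_extend.
    """
    n, m = len(s1), len(s2)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int):
        """Optimal (score, min_id, max_id) aligning s1[:i], s2[:j], last op = state."""
        if i == 0 and j == 0:
            return (0.0, 0, 0) if state == 0 else None
        options = []
        if state == 0 and i > 0 and j > 0:
            step = match if s1[i - 1] == s2[j - 1] else mismatch
            ident = 1 if s1[i - 1] == s2[j - 1] else 0
            for prev in (0, 1, 2):
                r = best(i - 1, j - 1, prev)
                if r is not None:
                    options.append((r[0] + step, r[1] + ident, r[2] + ident))
        elif state == 1 and i > 0:
            for prev, cost in ((0, gap_open), (1, gap_extend), (2, gap_open)):
                r = best(i - 1, j, prev)
                if r is not None:
                    options.append((r[0] + cost, r[1], r[2]))
        elif state == 2 and j > 0:
            for prev, cost in ((0, gap_open), (1, gap_open), (2, gap_extend)):
                r = best(i, j - 1, prev)
                if r is not None:
                    options.append((r[0] + cost, r[1], r[2]))
        if not options:
            return None
        top = max(o[0] for o in options)
        tied = [o for o in options if o[0] >= top - 1e-9]
        return (top, min(o[1] for o in tied), max(o[2] for o in tied))

    finals = [r for r in (best(n, m, s) for s in (0, 1, 2)) if r is not None]
    top = max(r[0] for r in finals)
    tied = [r for r in finals if r[0] >= top - 1e-9]
    return top, min(r[1] for r in tied), max(r[2] for r in tied)
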