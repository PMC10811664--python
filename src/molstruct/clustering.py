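"""k-medoids clustering on the configuration metric and structural-symmetry
analysis of the resulting medoids.

A molecular structure is operationalized as a compact high-probability
region of the rotation-quotient configuration space; k-medoids (PAM) finds
such regions directly from the pairwise RMSD distance matrix, representing
each cluster by the snapshot minimizing the sum of distances to the other
members.

The medoid's molecular-symmetry content is read off by applying every
identical-nuclei label permutation P and measuring d(P . medoid, medoid):
permutations with near-zero distance are *feasible* as structural symmetries
(they can be undone by a rotation).  With g feasible permutations out of
N_perm, the structure exists in N_perm / g distinct permutational *versions*;
g = N_perm means a single version (all permutations feasible, as for an
equilateral triangle of identical nuclei).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .alignment import config_distance
from .system import ParticleSystem, count_label_permutations, nuclear_permutations

__all__ = [
    "ClusterResult",
    "SymmetryReport",
    "k_medoids",
    "suggest_k",
    "symmetry_analysis",
    "default_symmetry_tolerance",
]


@dataclass
class ClusterResult:
    """Labels, medoids and total cost of a k-medoids partition."""

    labels: np.ndarray
    medoid_indices: np.ndarray
    cost: float
    k: int
    seed: int

    def recompute_cost(self, D_square: np.ndarray) -> float:
        return float(
            D_square[np.arange(len(self.labels)), self.medoid_indices[self.labels]].sum()
        )

    def as_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "medoid_indices": self.medoid_indices.tolist(),
            "cost": self.cost,
            "k": self.k,
            "seed": self.seed,
        }


def _as_square(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim == 1:
        return squareform(D)
    if D.ndim == 2:
        if D.shape[0] != D.shape[1]:
            raise ValueError(f"distance matrix not square: {D.shape}")
        return D
    raise ValueError("distance matrix must be condensed (1D) or square (2D)")


def _swap_to_local_optimum(S: np.ndarray, med: np.ndarray,
                           max_iter: int) -> tuple[np.ndarray, float]:
    """Best-improvement swap phase: exchange a medoid for a non-medoid while
    any exchange lowers the cost."""
    n = S.shape[0]
    k = med.size
    for _ in range(max_iter):
        d_med = S[:, med]  # (n, k)
        best_cost = float(d_med.min(axis=1).sum())
        best_swap = None
        for mi in range(k):
            if k == 1:
                d_others = np.full(n, np.inf)
            else:
                d_others = np.delete(d_med, mi, axis=1).min(axis=1)
            cand_costs = np.minimum(d_others[:, None], S).sum(axis=0)
            cand_costs[med] = np.inf
            h = int(np.argmin(cand_costs))
            if cand_costs[h] < best_cost - 1e-12:
                best_cost = float(cand_costs[h])
                best_swap = (mi, h)
        if best_swap is None:
            return med, best_cost
        med = med.copy()
        med[best_swap[0]] = best_swap[1]
    return med, float(S[:, med].min(axis=1).sum())


def k_medoids(D: np.ndarray, k: int, seed: int = 0,
              max_iter: int = 200, n_restarts: int = 10) -> ClusterResult:
    """PAM-style k-medoids on a precomputed distance matrix.

    Greedy BUILD initialization (each new medoid is the point that lowers
    total cost most) followed by best-swap iterations until no single
    medoid/non-medoid exchange lowers the cost.  Because the swap phase is a
    local search, ``n_restarts`` additional swap passes from seeded random
    initial medoid sets guard against local optima; the best-cost solution
    wins (strict improvement only, so the result is deterministic for a
    given seed).  Ties are broken toward the lowest index.
    """
    S = _as_square(D)
    n = S.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k = {k} outside [1, {n}]")

    # BUILD
    medoids = [int(np.argmin(S.sum(axis=0)))]
    d_near = S[:, medoids[0]].copy()
    while len(medoids) < k:
        costs = np.minimum(d_near[:, None], S).sum(axis=0)
        costs[medoids] = np.inf
        c = int(np.argmin(costs))
        medoids.append(c)
        d_near = np.minimum(d_near, S[:, c])

    med, best_cost = _swap_to_local_optimum(S, np.array(medoids), max_iter)
    if k > 1:
        rng = np.random.default_rng(seed)
        for _ in range(n_restarts):
            med_r, cost_r = _swap_to_local_optimum(
                S, rng.choice(n, size=k, replace=False), max_iter
            )
            if cost_r < best_cost - 1e-12:
                med, best_cost = med_r, cost_r

    med = np.sort(med)
    labels = np.argmin(S[:, med], axis=1)
    cost = float(S[np.arange(n), med[labels]].sum())
    return ClusterResult(labels=labels, medoid_indices=med, cost=cost, k=k, seed=seed)


def suggest_k(D: np.ndarray, k_max: int, seed: int = 0,
              threshold: float = 0.25) -> tuple[int, dict[int, float]]:
    """Recommend a cluster count from silhouette scores.

    Runs k-medoids for k = 2..k_max and scores each partition with the mean
    silhouette on the precomputed metric.  The best k is recommended unless
    its silhouette falls below ``threshold``, in which case the data are
    treated as a single structure (k = 1).
    """
    S = _as_square(D)
    n = S.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n <= k_max:
        raise ValueError(f"only {n} points for k_max = {k_max}")
    scores: dict[int, float] = {}
    for k in range(2, k_max + 1):
        res = k_medoids(S, k, seed=seed)
        if len(np.unique(res.labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = float(silhouette_score(S, res.labels, metric="precomputed"))
    best_k = max(scores, key=lambda k: (scores[k], -k))
    if scores[best_k] < threshold:
        return 1, scores
    return best_k, scores


@dataclass
class SymmetryReport:
    """Feasible-permutation analysis of a medoid structure.

    ``distances[q]`` is d(P_q . medoid, medoid) for the q-th identical-nuclei
    permutation; ``feasible[q]`` flags distances below the tolerance.  ``g``
    is the structural-symmetry order and ``versions = N_perm / g`` the number
    of distinct permutational versions of the structure.
    """

    permutations: list = field(repr=False)
    distances: np.ndarray = field(repr=False)
    feasible: np.ndarray = field(repr=False)
    tolerance: float = 0.0
    g: int = 1
    n_perm: int = 1
    versions: float = 1.0
    group_closed: bool = True
    ms_group_label: str | None = None

    def as_dict(self) -> dict:
        return {
            "tolerance_bohr": self.tolerance,
            "n_perm": self.n_perm,
            "g": self.g,
            "versions": self.versions,
            "group_closed": self.group_closed,
            "ms_group_label": self.ms_group_label,
            "permutation_distances_bohr": self.distances.tolist(),
            "feasible": self.feasible.tolist(),
        }


def default_symmetry_tolerance(medoid_distances: np.ndarray) -> float:
    """Default feasibility tolerance: the ensemble's median snapshot-to-medoid
    distance (the vibrational spread sets the natural similarity scale)."""
    return float(np.median(np.asarray(medoid_distances)))


_MS_GROUP_LOOKUP = {
    # (sorted nontrivial nuclear group sizes, g) -> MS group label
    ((3,), 6): "D3h(M)",
    ((3,), 3): "C3v(M)",
    ((2,), 2): "C2v(M)",
    ((2, 2), 4): "C2v(M)x2",
}


def symmetry_analysis(medoid: np.ndarray, system: ParticleSystem,
                      tol: float) -> SymmetryReport:
    """Flag the identical-nuclei permutations that are structural symmetries
    of a medoid configuration.

    A permutation P is feasible when d(P . medoid, medoid) <= tol, i.e. the
    relabeled configuration can be rotated back onto the original.  The
    identity is always feasible.  When the flagged set is closed under
    composition, versions x g = N_perm exactly; a non-closed set or a
    non-integer version count triggers a warning (usually the tolerance sits
    in the middle of the distance spectrum).
    """
    medoid = np.asarray(medoid, dtype=float)
    perms = nuclear_permutations(system)
    n_perm = count_label_permutations(system)
    dists = np.array([
        config_distance(medoid[p], medoid, system) for p in perms
    ])
    feasible = dists <= tol
    feasible[0] = True  # identity, d == 0 by construction
    g = int(feasible.sum())
    versions = n_perm / g
    if abs(versions - round(versions)) > 1e-9:
        warnings.warn(
            f"flagged symmetry order g = {g} does not divide N_perm = {n_perm}; "
            "the tolerance likely cuts through the distance spectrum",
            stacklevel=2,
        )
    else:
        versions = int(round(versions))

    flagged = {tuple(p) for p, f in zip(perms, feasible) if f}
    closed = all(
        tuple(np.asarray(a)[list(b)]) in flagged
        for a in flagged for b in flagged
    )
    if not closed:
        warnings.warn(
            "feasible-permutation set is not closed under composition; "
            "version count is unreliable at this tolerance",
            stacklevel=2,
        )

    sizes = tuple(sorted(
        len(gr) for gr in system.nuclear_groups if len(gr) > 1
    ))
    label = _MS_GROUP_LOOKUP.get((sizes, g)) if closed else None
    return SymmetryReport(
        permutations=perms,
        distances=dists,
        feasible=feasible,
        tolerance=float(tol),
        g=g,
        n_perm=n_perm,
        versions=versions,
        group_closed=closed,
        ms_group_label=label,
    )
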