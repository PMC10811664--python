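"""Rotation-quotient distance between labeled configurations.

The similarity metric between two labeled configurations is the nuclear RMSD
after optimal superposition: both configurations are translated to put their
(mass-weighted) nuclear center of mass at the origin, then the proper
rotation minimizing the nuclear RMSD is found (Kabsch construction: SVD of
the cross-covariance with a determinant sign correction, so space inversion
is excluded and chirality is preserved).  Electrons are carried through the
alignment — they are rotated by the nuclear optimal rotation — but never
enter the metric.

The metric is over *labeled* configurations: there is no minimization over
permutations of identical nuclei.  This is deliberate — distinct
permutational images of a structure must remain distinguishable so that
structural symmetry can be detected as near-zero distance between a
configuration and a *specific* permuted copy.

Centering is mass-weighted while the RMSD sum itself is unweighted over
nuclei; both choices are switchable (``mass_weighted_rmsd``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import ParticleSystem

__all__ = [
    "AlignmentResult",
    "PairCountError",
    "nuclear_com_center",
    "optimal_rotation",
    "config_distance",
    "distance_matrix",
    "distances_to_reference",
]

_DEGENERACY_RTOL = 1e-8


class PairCountError(MemoryError):
    """The requested pairwise distance matrix exceeds the configured guard."""


@dataclass
class AlignmentResult:
    """Optimal proper rotation and the minimized RMSD.

    ``rotation`` maps the moving configuration onto the reference:
    ``moving @ rotation.T ~= reference``.  ``degenerate`` flags an ambiguous
    optimum (collinear or planar-degenerate covariance); the tie is then
    broken deterministically by choosing the smallest-angle rotation about
    the ambiguous axis.
    """

    rotation: np.ndarray
    rmsd: float
    centered: bool = True
    degenerate: bool = False


def nuclear_com_center(positions: np.ndarray, system: ParticleSystem) -> np.ndarray:
    """Translate a configuration so the mass-weighted nuclear centroid is at
    the origin; electrons are translated along."""
    pos = np.asarray(positions, dtype=float)
    nuc = list(system.nuclear_indices)
    w = np.asarray(system.masses)[nuc]
    com = (w[:, None] * pos[nuc]).sum(axis=0) / w.sum()
    return pos - com


def _kabsch_from_cov(H: np.ndarray):
    """Proper rotation maximizing tr(R H) and the corrected singular-value sum.

    H is the 3x3 cross-covariance ``moving.T @ reference``.  Returns
    (R, corrected_trace, degenerate_flag).
    """
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0.0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    corrected = s[0] + s[1] + d * s[2]
    scale = max(s[0], 1.0)
    degenerate = bool(s[1] <= _DEGENERACY_RTOL * scale)
    return R, corrected, degenerate


def _smallest_angle_spin(R: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Compose R with a spin about ``axis`` so the total rotation angle is
    minimal (deterministic tie-break for collinear configurations)."""
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])

    def spin(theta: float) -> np.ndarray:
        return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)

    # trace(spin(theta) @ R) = A cos(theta) + B sin(theta) + C
    f0 = np.trace(R)
    fpi = np.trace(spin(np.pi) @ R)
    fh = np.trace(spin(np.pi / 2) @ R)
    A = (f0 - fpi) / 2.0
    C = (f0 + fpi) / 2.0
    B = fh - C
    theta = float(np.arctan2(B, A))
    return spin(theta) @ R


def optimal_rotation(moving: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> AlignmentResult:
    """Proper rotation minimizing the RMSD between two centered nucleus sets.

    Both inputs are (m, 3) arrays of already-centered nuclear positions.
    The result excludes improper rotations (determinant is +1), so mirror
    images are *not* identified.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"incompatible nucleus arrays {P.shape} vs {Q.shape}")
    m = P.shape[0]
    if weights is None:
        w = np.ones(m)
    else:
        w = np.asarray(weights, dtype=float)
    H = (w[:, None] * P).T @ Q
    R, _corrected, degenerate = _kabsch_from_cov(H)
    if degenerate:
        # collinear reference: optimum unique only up to spin about the line
        _, _, Vt = np.linalg.svd(Q.T @ (w[:, None] * Q))
        R = _smallest_angle_spin(R, Vt[0])
    # residual of the explicitly rotated coordinates: exact at the minimum,
    # free of the cancellation the closed-form trace expression suffers
    resid = P @ R.T - Q
    msd = float((w[:, None] * resid**2).sum() / w.sum())
    return AlignmentResult(
        rotation=R, rmsd=float(np.sqrt(msd)), centered=True, degenerate=degenerate
    )


def config_distance(a: np.ndarray, b: np.ndarray, system: ParticleSystem,
                    mass_weighted_rmsd: bool = False) -> float:
    """Metric d(a, b): nuclear RMSD after center-of-mass superposition and
    optimal proper rotation.  Electrons are ignored entirely.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    N = system.n_particles
    if a.shape != (N, 3) or b.shape != (N, 3):
        raise ValueError(
            f"configurations {a.shape}, {b.shape} do not match system size {N}"
        )
    nuc = list(system.nuclear_indices)
    ca = nuclear_com_center(a, system)[nuc]
    cb = nuclear_com_center(b, system)[nuc]
    w = np.asarray(system.masses)[nuc] if mass_weighted_rmsd else None
    return optimal_rotation(ca, cb, weights=w).rmsd


def _centered_nuclei(configs: np.ndarray, system: ParticleSystem) -> np.ndarray:
    """Stack of mass-weighted-centered nuclear coordinate arrays (M, m, 3)."""
    configs = np.asarray(configs, dtype=float)
    nuc = list(system.nuclear_indices)
    w = np.asarray(system.masses)[nuc]
    X = configs[:, nuc, :]
    com = (w[None, :, None] * X).sum(axis=1) / w.sum()
    return X - com[:, None, :]


def _pair_rmsd_batch(Xi: np.ndarray, Xj: np.ndarray) -> np.ndarray:
    """RMSD after optimal proper rotation for paired stacks (B, m, 3)."""
    m = Xi.shape[1]
    H = np.einsum("bak,bal->bkl", Xi, Xj)
    s = np.linalg.svd(H, compute_uv=False)
    sign = np.sign(np.linalg.det(H))
    sign[sign == 0.0] = 1.0
    corrected = s[:, 0] + s[:, 1] + sign * s[:, 2]
    sq = (Xi**2).sum(axis=(1, 2)) + (Xj**2).sum(axis=(1, 2)) - 2.0 * corrected
    return np.sqrt(np.clip(sq, 0.0, None) / m)


def distance_matrix(configs, system: ParticleSystem,
                    max_pairs: int = 200_000_000,
                    chunk: int = 500_000) -> np.ndarray:
    """All pairwise configuration distances, condensed (scipy convention).

    The number of pairs grows quadratically with the snapshot count; a guard
    rejects requests above ``max_pairs`` so an oversized ensemble fails fast
    instead of exhausting memory.
    """
    X = _centered_nuclei(np.asarray(configs, dtype=float), system)
    M = X.shape[0]
    if M < 2:
        raise ValueError("need at least two configurations")
    n_pairs = M * (M - 1) // 2
    if n_pairs > max_pairs:
        raise PairCountError(
            f"{M} configurations give {n_pairs} pairs, above the guard "
            f"({max_pairs}); thin the ensemble or raise max_pairs"
        )
    iu, ju = np.triu_indices(M, k=1)
    out = np.empty(n_pairs)
    for lo in range(0, n_pairs, chunk):
        hi = min(lo + chunk, n_pairs)
        out[lo:hi] = _pair_rmsd_batch(X[iu[lo:hi]], X[ju[lo:hi]])
    return out


def distances_to_reference(configs, reference: np.ndarray,
                           system: ParticleSystem) -> np.ndarray:
    """Metric distance from every configuration to one reference (vectorized)."""
    X = _centered_nuclei(np.asarray(configs, dtype=float), system)
    ref = _centered_nuclei(np.asarray(reference, dtype=float)[None], system)
    return _pair_rmsd_batch(X, np.broadcast_to(ref, X.shape))
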