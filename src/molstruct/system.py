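"""Particle systems, coordinate conventions and permutation bookkeeping.

A molecule is modelled as a collection of N point particles (nuclei and
electrons) with masses in units of the electron mass, charges in units of e,
and positions in Bohr.  All-particle densities are functions of *internal*
coordinates: the 3(N-1) Cartesian coordinates of particles 2..N relative to
particle 1 (the reference particle, by convention a nucleus).

Identical particles (same mass, charge and kind) are grouped; the number of
label permutations that interchange positions of identical *nuclei*,
``N_perm``, is the product of the factorials of the nuclear group sizes.
Electrons never enter this count: molecular structure is a statement about
nuclear positions only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParticleSystem",
    "CoincidentParticlesError",
    "PermutationOverflowError",
    "count_label_permutations",
    "nuclear_permutations",
    "coulomb_potential",
    "internal_to_lab",
    "lab_to_internal",
]

#: deuteron mass in electron masses (CODATA 2018)
DEUTERON_MASS = 3670.48296788


class CoincidentParticlesError(ZeroDivisionError):
    """Two particles occupy the same point, so the Coulomb energy diverges."""


class PermutationOverflowError(RuntimeError):
    """The identical-nuclei permutation group is too large to enumerate."""


@dataclass(frozen=True)
class ParticleSystem:
    """Masses, charges and kinds of the particles making up a molecule.

    Parameters
    ----------
    masses : array of float
        Per-particle masses in electron masses.
    charges : array of float
        Per-particle charges in units of the elementary charge.
    kinds : sequence of str
        ``"nucleus"`` or ``"electron"`` per particle.
    labels : sequence of str, optional
        Short tags used in file output (element symbols for nuclei, ``"e"``
        for electrons).  Defaults to ``"X"``/``"e"``.
    """

    masses: tuple[float, ...]
    charges: tuple[float, ...]
    kinds: tuple[str, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        masses = tuple(float(m) for m in self.masses)
        charges = tuple(float(q) for q in self.charges)
        kinds = tuple(str(k) for k in self.kinds)
        if not (len(masses) == len(charges) == len(kinds)):
            raise ValueError(
                f"inconsistent lengths: {len(masses)} masses, "
                f"{len(charges)} charges, {len(kinds)} kinds"
            )
        if any(k not in ("nucleus", "electron") for k in kinds):
            raise ValueError("kinds must be 'nucleus' or 'electron'")
        if any(m <= 0 for m in masses):
            raise ValueError("masses must be positive")
        if "nucleus" not in kinds:
            raise ValueError("at least one nucleus required")
        labels = self.labels
        if not labels:
            labels = tuple("e" if k == "electron" else "X" for k in kinds)
        if len(labels) != len(masses):
            raise ValueError("labels length mismatch")
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "charges", charges)
        object.__setattr__(self, "kinds", kinds)
        object.__setattr__(self, "labels", tuple(labels))

    # -- basic counts -----------------------------------------------------
    @property
    def n_particles(self) -> int:
        return len(self.masses)

    @property
    def nuclear_indices(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == "nucleus")

    @property
    def electron_indices(self) -> tuple[int, ...]:
        return tuple(i for i, k in enumerate(self.kinds) if k == "electron")

    @property
    def identical_groups(self) -> tuple[tuple[int, ...], ...]:
        """Partition of particle indices into groups sharing (mass, charge, kind)."""
        keys: dict[tuple[float, float, str], list[int]] = {}
        for i, (m, q, k) in enumerate(zip(self.masses, self.charges, self.kinds)):
            keys.setdefault((m, q, k), []).append(i)
        # deterministic: groups ordered by first member
        groups = sorted(keys.values(), key=lambda g: g[0])
        return tuple(tuple(g) for g in groups)

    @property
    def nuclear_groups(self) -> tuple[tuple[int, ...], ...]:
        return tuple(
            g for g in self.identical_groups if self.kinds[g[0]] == "nucleus"
        )

    def group_label(self, group: tuple[int, ...]) -> str:
        return self.labels[group[0]]

    # -- convenience constructors -----------------------------------------
    @classmethod
    def d3_plus(cls) -> "ParticleSystem":
        """The D3+ molecular ion: three deuterons and two electrons."""
        return cls(
            masses=(DEUTERON_MASS,) * 3 + (1.0, 1.0),
            charges=(1.0, 1.0, 1.0, -1.0, -1.0),
            kinds=("nucleus",) * 3 + ("electron",) * 2,
            labels=("D", "D", "D", "e", "e"),
        )

    @classmethod
    def bare_nuclei(cls, masses, charges, labels=None) -> "ParticleSystem":
        """A system of nuclei only (no electrons), for geometric tests."""
        n = len(masses)
        return cls(
            masses=tuple(masses),
            charges=tuple(charges),
            kinds=("nucleus",) * n,
            labels=tuple(labels) if labels else (),
        )


def count_label_permutations(system: ParticleSystem) -> int:
    """Number of label permutations interchanging positions of identical nuclei.

    The product over identical-nuclei groups of (group size)!.  Electrons are
    excluded: the permutational structure of a molecular structure is defined
    on the nuclei alone.
    """
    n_perm = 1
    for g in system.nuclear_groups:
        n_perm *= math.factorial(len(g))
    return n_perm


def nuclear_permutations(
    system: ParticleSystem, limit: int = 100_000
) -> list[np.ndarray]:
    """Enumerate every particle-index permutation acting within identical
    nuclear groups.

    Returns full-length permutation arrays ``p`` such that the permuted
    configuration places particle ``i`` at the old position of particle
    ``p[i]``.  The identity comes first and the order is deterministic.
    """
    n_perm = count_label_permutations(system)
    if n_perm > limit:
        raise PermutationOverflowError(
            f"N_perm = {n_perm} exceeds enumeration limit {limit}"
        )
    groups = [g for g in system.nuclear_groups if len(g) > 1]
    base = np.arange(system.n_particles)
    perms: list[np.ndarray] = []
    # itertools.permutations yields the identity arrangement first for each
    # group, so the overall identity is the first combined permutation.
    for combo in itertools.product(
        *(itertools.permutations(g) for g in groups)
    ):
        p = base.copy()
        for g, arrangement in zip(groups, combo):
            p[list(g)] = arrangement
        perms.append(p)
    if not perms:
        perms.append(base.copy())
    return perms


def coulomb_potential(system: ParticleSystem, positions: np.ndarray) -> float:
    """Coulomb energy V = sum_{i<j} q_i q_j / r_ij in Hartree.

    ``positions`` is an (N, 3) array in Bohr, laboratory frame.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (system.n_particles, 3):
        raise ValueError(
            f"positions shape {pos.shape} != ({system.n_particles}, 3)"
        )
    q = np.asarray(system.charges)
    iu, ju = np.triu_indices(system.n_particles, k=1)
    r = np.linalg.norm(pos[iu] - pos[ju], axis=1)
    zero = r == 0.0
    if np.any(zero):
        i, j = iu[zero][0], ju[zero][0]
        raise CoincidentParticlesError(
            f"particles {i} and {j} are coincident; Coulomb energy diverges"
        )
    return float(np.sum(q[iu] * q[ju] / r))


def internal_to_lab(x: np.ndarray) -> np.ndarray:
    """Internal coordinates (3(N-1),) -> lab configuration (N, 3).

    The reference particle (index 0) is placed at the origin.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size % 3 != 0:
        raise ValueError(f"internal coordinate length {x.size} not divisible by 3")
    rel = x.reshape(-1, 3)
    return np.vstack([np.zeros((1, 3)), rel])


def lab_to_internal(positions: np.ndarray) -> np.ndarray:
    """Lab configuration (N, 3) -> internal coordinates (3(N-1),).

    Positions of particles 2..N relative to particle 1; invariant under any
    global translation of the input.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
        raise ValueError(f"expected (N, 3) with N >= 2, got {pos.shape}")
    return (pos[1:] - pos[0]).ravel()
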