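"""Vibrationally averaged particle densities in the medoid frame.

Every snapshot of an ensemble is superimposed onto the medoid structure
(nuclear center-of-mass translation + optimal proper rotation of the
nuclei, with electrons co-transformed), after which kernel density
estimates of the pooled particle positions give vibrationally averaged
densities: a 2D map of the nuclear positions in the medoid's best-fit
plane, and a full 3D electron density exportable as a Gaussian cube file.

KDE kernels are isotropic Gaussians with an explicit bandwidth in Bohr
(default: Scott's rule on the pooled positions).  Grids are regular and
axis-aligned; densities are normalized so the grid integral equals the
number of pooled particles per snapshot (nucleus count for the 2D map,
electron count for the 3D density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import _centered_nuclei, nuclear_com_center, optimal_rotation
from .sampler import SampleSet
from .system import ParticleSystem

__all__ = [
    "AlignedEnsemble",
    "DensityGrid",
    "align_ensemble",
    "canonical_medoid_frame",
    "nuclear_kde_2d",
    "electron_kde_3d",
    "scott_bandwidth",
    "write_cube",
    "read_cube",
    "write_grid_2d",
]


@dataclass
class AlignedEnsemble:
    """Snapshots rotated into the medoid frame.

    ``positions`` is (M, N, 3) in Bohr with every snapshot's nuclear
    center of mass at the origin; ``nuclear_rmsd[i]`` is the minimized
    nuclear RMSD of snapshot i to the medoid (identical to the configuration
    metric).
    """

    positions: np.ndarray
    medoid: np.ndarray
    nuclear_rmsd: np.ndarray
    system: ParticleSystem = field(repr=False)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.positions.shape[0]

    def nuclear_positions(self) -> np.ndarray:
        """Pooled aligned nuclear positions, ((M * m), 3)."""
        nuc = list(self.system.nuclear_indices)
        return self.positions[:, nuc, :].reshape(-1, 3)

    def electron_positions(self) -> np.ndarray:
        """Pooled aligned electron positions, ((M * E), 3)."""
        ele = list(self.system.electron_indices)
        return self.positions[:, ele, :].reshape(-1, 3)


def canonical_medoid_frame(medoid: np.ndarray, system: ParticleSystem) -> np.ndarray:
    """Rotate a centered medoid so its best-fit nuclear plane is the x-y plane.

    Principal axes of the nuclear coordinates are mapped to x, y, z in
    decreasing order of extent (a proper rotation), so planar structures lie
    flat and the 2D nuclear map is taken in their plane.
    """
    centered = nuclear_com_center(medoid, system)
    nuc = list(system.nuclear_indices)
    _, _, Vt = np.linalg.svd(centered[nuc], full_matrices=True)
    if np.linalg.det(Vt) < 0:
        Vt[2] *= -1.0
    return centered @ Vt.T


def align_ensemble(samples, medoid: np.ndarray, system: ParticleSystem,
                   medoid_id=None, canonicalize: bool = True) -> AlignedEnsemble:
    """Superimpose every snapshot onto the medoid structure.

    ``samples`` is a :class:`SampleSet` or an (M, N, 3) array of lab
    configurations.  Each snapshot is centered on its nuclear center of
    mass and rotated by the optimal nuclear rotation; electrons ride along.
    """
    if isinstance(samples, SampleSet):
        configs = samples.lab_configs()
    else:
        configs = np.asarray(samples, dtype=float)
    if configs.shape[0] == 0:
        raise ValueError("empty ensemble")
    med = np.asarray(medoid, dtype=float)
    if canonicalize:
        med = canonical_medoid_frame(med, system)
    else:
        med = nuclear_com_center(med, system)
    nuc = list(system.nuclear_indices)
    med_nuc = med[nuc]

    # center all snapshots (electrons translated along)
    w = np.asarray(system.masses)[nuc]
    com = (w[None, :, None] * configs[:, nuc, :]).sum(axis=1) / w.sum()
    centered = configs - com[:, None, :]

    # batched Kabsch rotations onto the medoid nuclei
    H = np.einsum("mak,al->mkl", centered[:, nuc, :], med_nuc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.einsum("mij,mjk->mik", np.transpose(Vt, (0, 2, 1)),
                                        np.transpose(U, (0, 2, 1)))))
    d[d == 0.0] = 1.0
    D = np.zeros_like(H)
    D[:, 0, 0] = 1.0
    D[:, 1, 1] = 1.0
    D[:, 2, 2] = d
    R = np.einsum("mij,mjk,mkl->mil", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    aligned = np.einsum("mij,mnj->mni", R, centered)

    resid = aligned[:, nuc, :] - med_nuc[None]
    rmsd = np.sqrt((resid**2).sum(axis=(1, 2)) / len(nuc))
    return AlignedEnsemble(
        positions=aligned,
        medoid=med,
        nuclear_rmsd=rmsd,
        system=system,
        provenance={"medoid_id": medoid_id, "canonical_frame": canonicalize,
                    "n_snapshots": configs.shape[0]},
    )


@dataclass
class DensityGrid:
    """A regular axis-aligned grid of estimated particle density.

    ``values`` has shape ``shape`` (2D or 3D); ``origin`` is the coordinate
    of the first grid point and ``spacing`` the per-axis step, both in Bohr.
    ``normalization`` is the declared integral of the density (particle
    count); the trapezoidal grid integral matches it to within the grid's
    truncation error.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    normalization: float
    bandwidth: float
    n_samples: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def ndim(self) -> int:
        return self.values.ndim

    def axes(self) -> list[np.ndarray]:
        return [
            self.origin[a] + self.spacing[a] * np.arange(n)
            for a, n in enumerate(self.shape)
        ]

    def integral(self) -> float:
        """Trapezoidal integral of the density over the grid."""
        v = self.values
        for a in reversed(range(v.ndim)):
            v = np.trapezoid(v, dx=self.spacing[a], axis=a)
        return float(v)


def scott_bandwidth(points: np.ndarray) -> float:
    """Scott's rule bandwidth (isotropic, Bohr) for pooled d-dimensional points."""
    pts = np.asarray(points, dtype=float)
    n, d = pts.shape
    sigma = float(pts.std(axis=0, ddof=1).mean())
    return sigma * n ** (-1.0 / (d + 4))


def _grid_axes(points: np.ndarray, bandwidth: float, grid_points, padding: float):
    d = points.shape[1]
    npts = np.broadcast_to(np.asarray(grid_points, dtype=int), (d,))
    lo = points.min(axis=0) - padding * bandwidth
    hi = points.max(axis=0) + padding * bandwidth
    spacing = (hi - lo) / (npts - 1)
    return lo, spacing, npts


def _gaussian_kde_on_grid(points: np.ndarray, bandwidth: float,
                          origin, spacing, shape,
                          chunk: int = 2_000_000) -> np.ndarray:
    """Exact Gaussian-kernel sum evaluated on a regular grid (chunked)."""
    d = points.shape[1]
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(d)]
    mesh = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
    n = points.shape[0]
    norm = 1.0 / (n * (2.0 * np.pi) ** (d / 2.0) * bandwidth**d)
    out = np.zeros(mesh.shape[0])
    # chunk over grid x data so memory stays bounded
    g_chunk = max(1, int(chunk // max(n, 1)))
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    for lo in range(0, mesh.shape[0], g_chunk):
        hi = min(lo + g_chunk, mesh.shape[0])
        diff = mesh[lo:hi, None, :] - points[None, :, :]
        out[lo:hi] = np.exp(-(diff**2).sum(-1) * inv2h2).sum(axis=1)
    return (norm * out).reshape(tuple(shape))


def nuclear_kde_2d(aligned: AlignedEnsemble, plane: tuple[int, int] = (0, 1),
                   bandwidth: float | None = None,
                   grid_points: int = 101, padding: float = 5.0) -> DensityGrid:
    """2D Gaussian KDE of the pooled aligned nuclear positions in a plane.

    ``plane`` selects the two Cartesian axes (default x-y, the medoid's
    best-fit nuclear plane in the canonical frame).  The density integrates
    to the nucleus count.
    """
    a, b = plane
    if a == b or not (0 <= a < 3 and 0 <= b < 3):
        raise ValueError(f"invalid plane {plane}")
    pts = aligned.nuclear_positions()[:, [a, b]]
    if pts.shape[0] == 0:
        raise ValueError("empty ensemble")
    h = scott_bandwidth(pts) if bandwidth is None else float(bandwidth)
    origin, spacing, shape = _grid_axes(pts, h, grid_points, padding)
    values = _gaussian_kde_on_grid(pts, h, origin, spacing, shape)
    m = len(aligned.system.nuclear_indices)
    return DensityGrid(
        origin=origin, spacing=spacing, values=values * m,
        normalization=float(m), bandwidth=h, n_samples=len(aligned),
    )


def electron_kde_3d(aligned: AlignedEnsemble,
                    bandwidth: float | None = None,
                    grid_points: int = 41, padding: float = 5.0) -> DensityGrid:
    """3D Gaussian KDE of the pooled aligned electron positions.

    The density integrates to the electron count, giving a vibrationally
    averaged electron density in the medoid frame.
    """
    pts = aligned.electron_positions()
    if pts.shape[0] == 0:
        raise ValueError("system has no electrons (or empty ensemble)")
    h = scott_bandwidth(pts) if bandwidth is None else float(bandwidth)
    origin, spacing, shape = _grid_axes(pts, h, grid_points, padding)
    values = _gaussian_kde_on_grid(pts, h, origin, spacing, shape)
    n_e = len(aligned.system.electron_indices)
    return DensityGrid(
        origin=origin, spacing=spacing, values=values * n_e,
        normalization=float(n_e), bandwidth=h, n_samples=len(aligned),
    )


# ---------------------------------------------------------------------------
# Gaussian cube export (3D) and delimited text export (2D)
# ---------------------------------------------------------------------------

def write_cube(grid: DensityGrid, system: ParticleSystem, medoid: np.ndarray,
               path) -> None:
    """Write a 3D density grid in Gaussian cube format (Bohr units).

    The medoid nuclei become the atom records (atomic number taken from the
    nuclear charge).  Voxel order follows the cube standard: x outermost,
    z fastest.  Output is byte-stable for fixed inputs.
    """
    if grid.ndim != 3:
        raise ValueError(
            "cube export requires a 3D grid; use write_grid_2d for 2D maps"
        )
    nuc = list(system.nuclear_indices)
    med = np.asarray(medoid, dtype=float)
    lines = [
        "molstruct vibrationally averaged density (Bohr, density per Bohr^3)",
        f"bandwidth_bohr={grid.bandwidth:.6g} snapshots={grid.n_samples} "
        f"normalization={grid.normalization:.6g}",
        f"{len(nuc):5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}{grid.origin[2]:12.6f}",
    ]
    for a in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[a] = grid.spacing[a]
        lines.append(
            f"{grid.shape[a]:5d}{vec[0]:12.6f}{vec[1]:12.6f}{vec[2]:12.6f}"
        )
    for i in nuc:
        z = int(round(system.charges[i]))
        x, y, zc = med[i]
        lines.append(f"{z:5d}{float(system.charges[i]):12.6f}{x:12.6f}{y:12.6f}{zc:12.6f}")
    flat = grid.values.reshape(grid.shape[0], grid.shape[1], grid.shape[2])
    for ix in range(grid.shape[0]):
        for iy in range(grid.shape[1]):
            row = flat[ix, iy]
            for lo in range(0, row.size, 6):
                lines.append("".join(f"{v:13.5E}" for v in row[lo:lo + 6]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cube(path):
    """Parse a Gaussian cube file -> (DensityGrid, atom records).

    Atom records are (atomic_number, charge, position) tuples.  Only
    axis-aligned (diagonal) voxel vectors are supported.
    """
    with open(path) as fh:
        fh.readline()
        meta = fh.readline()
        natoms_line = fh.readline().split()
        natoms = int(natoms_line[0])
        origin = np.array([float(v) for v in natoms_line[1:4]])
        shape = []
        spacing = []
        for a in range(3):
            tok = fh.readline().split()
            shape.append(int(tok[0]))
            vec = np.array([float(v) for v in tok[1:4]])
            if np.count_nonzero(vec) > 1:
                raise ValueError("non-axis-aligned cube voxels not supported")
            spacing.append(vec[a])
        atoms = []
        for _ in range(natoms):
            tok = fh.readline().split()
            atoms.append((int(tok[0]), float(tok[1]),
                          np.array([float(v) for v in tok[2:5]])))
        values = np.array(fh.read().split(), dtype=float).reshape(tuple(shape))
    bandwidth = 0.0
    n_samples = 0
    norm = float("nan")
    for tok in meta.split():
        if tok.startswith("bandwidth_bohr="):
            bandwidth = float(tok.split("=")[1])
        elif tok.startswith("snapshots="):
            n_samples = int(tok.split("=")[1])
        elif tok.startswith("normalization="):
            norm = float(tok.split("=")[1])
    grid = DensityGrid(
        origin=origin, spacing=np.array(spacing), values=values,
        normalization=norm, bandwidth=bandwidth, n_samples=n_samples,
    )
    return grid, atoms


def write_grid_2d(grid: DensityGrid, path) -> None:
    """Write a 2D density map as delimited text with metadata comments."""
    if grid.ndim != 2:
        raise ValueError("write_grid_2d requires a 2D grid")
    header = (
        "molstruct 2D density map (Bohr, density per Bohr^2)\n"
        f"bandwidth_bohr={grid.bandwidth:.6g} snapshots={grid.n_samples} "
        f"normalization={grid.normalization:.6g}\n"
        f"origin={grid.origin[0]:.6g},{grid.origin[1]:.6g} "
        f"spacing={grid.spacing[0]:.6g},{grid.spacing[1]:.6g} "
        f"shape={grid.shape[0]}x{grid.shape[1]}"
    )
    np.savetxt(path, grid.values, header=header, fmt="%.8e")
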