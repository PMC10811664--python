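"""Ensemble alignment, kernel density estimates and cube export."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from molstruct import (
    ParticleSystem,
    align_ensemble,
    distances_to_reference,
    electron_kde_3d,
    equilateral_model,
    nuclear_kde_2d,
    read_cube,
    sample_direct,
    write_cube,
)
from molstruct.density import DensityGrid, write_grid_2d


@pytest.fixture(scope="module")
def aligned_triangle(triangle_model, triangle_samples):
    configs = triangle_samples.lab_configs()
    sys_ = triangle_model.system
    d_all = distances_to_reference(configs, configs[0], sys_)
    medoid = configs[int(np.argmin(d_all))]
    return align_ensemble(triangle_samples, medoid, sys_)


class TestAlignEnsemble:
    def test_rotated_copies_collapse_onto_medoid(self, d3_system, rng):
        medoid = rng.normal(size=(5, 3))
        Rs = Rotation.random(30, rng=rng).as_matrix()
        ensemble = np.einsum("rij,nj->rni", Rs, medoid)
        aligned = align_ensemble(ensemble, medoid, d3_system, canonicalize=False)
        assert np.allclose(aligned.nuclear_rmsd, 0.0, atol=1e-8)
        assert np.allclose(
            aligned.positions - aligned.positions[0], 0.0, atol=1e-8
        )

    def test_rmsd_matches_metric_recomputation(self, aligned_triangle,
                                               triangle_samples, d3_system):
        configs = triangle_samples.lab_configs()
        recomputed = distances_to_reference(configs, aligned_triangle.medoid, d3_system)
        assert np.allclose(aligned_triangle.nuclear_rmsd, recomputed, atol=1e-7)

    def test_nuclear_centroid_at_origin(self, aligned_triangle, d3_system):
        w = np.asarray(d3_system.masses)[:3]
        com = (
            w[None, :, None] * aligned_triangle.positions[:, :3]
        ).sum(axis=1) / w.sum()
        assert np.abs(com).max() < 1e-8

    def test_planted_fluctuation_width_recovered(self, aligned_triangle,
                                                 triangle_model):
        """The planted vibrational width survives the pipeline: each side
        length of the aligned triangles fluctuates with standard deviation
        sigma_nuc * sqrt(2) (difference of two independent isotropic
        displacements projected on the bond), within 10%."""
        sigma = triangle_model.sigma_nuc
        nuc = aligned_triangle.positions[:, :3]
        for i, j in ((0, 1), (0, 2), (1, 2)):
            side = np.linalg.norm(nuc[:, i] - nuc[:, j], axis=1)
            assert side.std(ddof=1) == pytest.approx(
                sigma * np.sqrt(2.0), rel=0.10
            )


class TestNuclearKDE2D:
    def test_sharp_peaks_for_identical_snapshots(self, d3_system):
        model = equilateral_model(side=1.65, sigma_nuc=1e-9)
        ss = sample_direct(model, 50, seed=1)
        configs = ss.lab_configs()
        aligned = align_ensemble(ss, configs[0], d3_system)
        grid = nuclear_kde_2d(aligned, bandwidth=0.05, grid_points=81)
        # peaks at the three vertex projections
        med2 = aligned.medoid[:3, :2]
        axes = grid.axes()
        for v in med2:
            ia = np.argmin(np.abs(axes[0] - v[0]))
            ib = np.argmin(np.abs(axes[1] - v[1]))
            assert grid.values[ia, ib] > 0.5 * grid.values.max()

    def test_integral_equals_nucleus_count(self, aligned_triangle):
        grid = nuclear_kde_2d(aligned_triangle, grid_points=81)
        assert grid.integral() == pytest.approx(3.0, rel=0.01)

    def test_peak_width_is_gaussian_convolution(self, d3_system, rng):
        """Vertex peak FWHM = 2.355 * sqrt(sigma^2 + bandwidth^2) (Gaussian
        convolution identity), measured via local second moments on an
        ensemble with pure vertex noise (no rotations, so the planted width
        enters the KDE unmodified)."""
        sigma, h, n = 0.06, 0.05, 4000
        tri = equilateral_model(side=2.2).conformers[0]
        pos = np.zeros((n, 5, 3))
        pos[:, :3] = tri[None] + sigma * rng.normal(size=(n, 3, 3))
        medoid = np.zeros((5, 3))
        medoid[:3] = tri
        from molstruct.density import AlignedEnsemble
        aligned = AlignedEnsemble(
            positions=pos, medoid=medoid, nuclear_rmsd=np.zeros(n),
            system=d3_system,
        )
        grid = nuclear_kde_2d(aligned, bandwidth=h, grid_points=161)
        X, Y = np.meshgrid(*grid.axes(), indexing="ij")
        v = tri[0, :2]
        win = (np.abs(X - v[0]) < 0.5) & (np.abs(Y - v[1]) < 0.5)
        w = np.where(win, grid.values, 0.0)
        w_sum = w.sum()
        mx, my = (w * X).sum() / w_sum, (w * Y).sum() / w_sum
        var = ((w * ((X - mx) ** 2 + (Y - my) ** 2)).sum() / w_sum) / 2.0
        fwhm = 2.355 * np.sqrt(var)
        expected = 2.355 * np.sqrt(sigma**2 + h**2)
        assert fwhm == pytest.approx(expected, rel=0.10)


class TestElectronKDE3D:
    def test_integral_equals_electron_count(self, aligned_triangle):
        grid = electron_kde_3d(aligned_triangle, grid_points=31)
        assert grid.integral() == pytest.approx(2.0, rel=0.01)

    def test_planted_gaussian_recovered(self, rng):
        """KDE of an isotropic Gaussian electron cloud matches the analytic
        convolution N(0, (sigma^2 + h^2) I): sup error < 5% of the peak."""
        sigma, h, n = 0.8, 0.4, 40_000
        sys_ = ParticleSystem(
            masses=(1836.0, 1.0), charges=(1.0, -1.0),
            kinds=("nucleus", "electron"),
        )
        pos = np.zeros((n, 2, 3))
        pos[:, 1] = sigma * rng.normal(size=(n, 3))
        aligned = align_ensemble(pos, np.array([[0.0, 0, 0], [0, 0, 1.0]]),
                                 sys_, canonicalize=False)
        grid = electron_kde_3d(aligned, bandwidth=h, grid_points=25, padding=4.0)
        s2 = sigma**2 + h**2
        X, Y, Z = np.meshgrid(*grid.axes(), indexing="ij")
        analytic = (2 * np.pi * s2) ** -1.5 * np.exp(
            -(X**2 + Y**2 + Z**2) / (2 * s2)
        )
        err = np.abs(grid.values - analytic).max() / analytic.max()
        assert err < 0.05

    def test_threefold_symmetry_of_electron_density(self, aligned_triangle):
        """The generator is D3h-symmetric, so the aligned electron density at
        120-degree-rotated point triples must agree within Monte-Carlo error."""
        pts = aligned_triangle.electron_positions()
        h = 0.3
        probe = np.array([0.9, 0.0, 0.2])
        R120 = Rotation.from_euler("z", 120, degrees=True).as_matrix()
        vals, errs = [], []
        n_snap = len(aligned_triangle)
        for p in (probe, R120 @ probe, R120 @ R120 @ probe):
            contrib = np.exp(
                -((pts - p) ** 2).sum(axis=1) / (2 * h**2)
            ) / (2 * np.pi * h**2) ** 1.5
            per_snap = contrib.reshape(n_snap, -1).sum(axis=1)
            vals.append(per_snap.mean())
            errs.append(per_snap.std(ddof=1) / np.sqrt(n_snap))
        vals, errs = np.array(vals), np.array(errs)
        spread = np.abs(vals - vals.mean())
        assert np.all(spread <= 3.0 * np.sqrt(errs**2 + errs.mean() ** 2))


class TestCubeFormat:
    def test_round_trip_and_header(self, tmp_path, aligned_triangle, d3_system):
        grid = electron_kde_3d(aligned_triangle, grid_points=13)
        path = tmp_path / "density.cube"
        write_cube(grid, d3_system, aligned_triangle.medoid, path)
        back, atoms = read_cube(path)
        assert len(atoms) == 3  # nucleus count
        assert np.allclose(back.values, grid.values, rtol=1e-4)
        assert np.allclose(back.origin, grid.origin, atol=1e-6)
        assert np.allclose(back.spacing, grid.spacing, atol=1e-6)

    def test_independent_parser_recovers_axes(self, tmp_path, aligned_triangle,
                                              d3_system):
        """Cross-parse with a minimal independent cube reader written against
        the format description (not the package parser)."""
        grid = electron_kde_3d(aligned_triangle, grid_points=9)
        path = tmp_path / "density.cube"
        write_cube(grid, d3_system, aligned_triangle.medoid, path)
        lines = path.read_text().splitlines()
        natoms = int(lines[2].split()[0])
        origin = [float(v) for v in lines[2].split()[1:4]]
        counts, vecs = [], []
        for ln in lines[3:6]:
            tok = ln.split()
            counts.append(int(tok[0]))
            vecs.append([float(v) for v in tok[1:4]])
        values = [float(v) for ln in lines[6 + natoms:] for v in ln.split()]
        assert natoms == 3
        assert counts == [9, 9, 9]
        assert np.allclose(origin, grid.origin, atol=1e-6)
        assert np.allclose(np.diag(vecs), grid.spacing, atol=1e-6)
        assert len(values) == 9**3
        # cube ordering: z fastest, x slowest
        assert values[1] == pytest.approx(grid.values[0, 0, 1], rel=1e-4)
        assert values[9] == pytest.approx(grid.values[0, 1, 0], rel=1e-4)

    def test_2d_grid_rejected(self, tmp_path, aligned_triangle, d3_system):
        grid2 = nuclear_kde_2d(aligned_triangle, grid_points=21)
        with pytest.raises(ValueError, match="2D"):
            write_cube(grid2, d3_system, aligned_triangle.medoid,
                       tmp_path / "bad.cube")
        write_grid_2d(grid2, tmp_path / "map.txt")  # 2D text export works
        assert (tmp_path / "map.txt").exists()

    def test_byte_stability(self, tmp_path, aligned_triangle, d3_system):
        grid = electron_kde_3d(aligned_triangle, grid_points=7)
        p1, p2 = tmp_path / "a.cube", tmp_path / "b.cube"
        write_cube(grid, d3_system, aligned_triangle.medoid, p1)
        write_cube(grid, d3_system, aligned_triangle.medoid, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_normalization_invariant_many_grids(aligned_triangle):
    """Grids extending >= 5 bandwidths beyond the data keep the declared
    integral within 1%."""
    for gp in (25, 33):
        g = electron_kde_3d(aligned_triangle, grid_points=gp, padding=5.0)
        assert g.integral() == pytest.approx(g.normalization, rel=0.01)
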