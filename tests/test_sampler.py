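"""Metropolis chain behaviour, step-size tuning and expectation estimates."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from molstruct import (
    ParticleSystem,
    SamplerConfig,
    SampleSet,
    estimate_expectations,
    run_chain,
    tune_step_sizes,
)
from molstruct.sampler import ChainAbortError, ZeroDensityStartError


@pytest.fixture(scope="module")
def three_body():
    """One nucleus + two electrons: 6 internal coordinates, single kind moving
    per block is 'electron' only for coords... both particles are electrons."""
    return ParticleSystem(
        masses=(1836.0, 1.0, 1.0),
        charges=(1.0, -1.0, -1.0),
        kinds=("nucleus", "electron", "electron"),
    )


def std_normal_6d(x):
    return -0.5 * float(np.dot(x, x))


class TestChain:
    def test_standard_normal_moments(self, three_body):
        cfg = SamplerConfig(
            total_steps=100_000, burn_in_steps=10_000, thinning=2,
            step_size_electron=1.0, step_size_nucleus=1.0, seed=17,
        )
        ss = run_chain(std_normal_6d, three_body, cfg, start=np.full(6, 0.5))
        assert ss.coords.shape[1] == 6
        mean = ss.coords.mean(axis=0)
        var = ss.coords.var(axis=0)
        assert np.all(np.abs(mean) < 0.05)
        assert np.all(np.abs(var - 1.0) < 0.05)

    def test_vanishing_step_freezes_chain(self, three_body):
        cfg = SamplerConfig(
            total_steps=2_000, burn_in_steps=100, thinning=10,
            step_size_electron=1e-14, step_size_nucleus=1e-14,
            tune=False, seed=3,
        )
        start = np.arange(6, dtype=float)
        ss = run_chain(std_normal_6d, three_body, cfg, start=start)
        assert ss.acceptance_fraction == 1.0
        assert np.allclose(ss.coords, start, atol=1e-10)

    def test_same_seed_bit_identical(self, three_body):
        cfg = SamplerConfig(total_steps=5_000, burn_in_steps=500, thinning=5, seed=42)
        a = run_chain(std_normal_6d, three_body, cfg, start=np.zeros(6) + 0.1)
        b = run_chain(std_normal_6d, three_body, cfg, start=np.zeros(6) + 0.1)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.log_density, b.log_density)
        assert a.acceptance_fraction == b.acceptance_fraction

    def test_zero_density_start_rejected(self, three_body):
        cfg = SamplerConfig(total_steps=100, burn_in_steps=10)

        def oracle(x):
            return -np.inf

        with pytest.raises(ZeroDensityStartError):
            run_chain(oracle, three_body, cfg, start=np.zeros(6))

    def test_nan_oracle_aborts_with_step_index(self, three_body):
        calls = {"n": 0}

        def oracle(x):
            calls["n"] += 1
            return float("nan") if calls["n"] > 50 else -0.5 * float(np.dot(x, x))

        cfg = SamplerConfig(total_steps=1_000, burn_in_steps=100, seed=1)
        with pytest.raises(ChainAbortError, match="step"):
            run_chain(oracle, three_body, cfg, start=np.zeros(6) + 0.1)

    def test_detailed_balance_double_well(self):
        """Histogram of thinned samples from a 1D double-well marginal matches
        the normalized density (chi-square p > 0.01)."""
        sys_ = ParticleSystem(
            masses=(1836.0, 1.0), charges=(1.0, -1.0),
            kinds=("nucleus", "electron"),
        )

        def log_rho(x):
            # double well in x, standard normal in y, z
            return -((x[0] ** 2 - 1.5) ** 2) - 0.5 * (x[1] ** 2 + x[2] ** 2)

        cfg = SamplerConfig(
            total_steps=220_000, burn_in_steps=20_000, thinning=20,
            step_size_electron=0.8, step_size_nucleus=0.8, seed=8,
        )
        ss = run_chain(log_rho, sys_, cfg, start=np.array([1.2, 0.0, 0.0]))
        xs = ss.coords[:, 0]
        edges = np.linspace(-2.8, 2.8, 15)
        obs, _ = np.histogram(xs, bins=edges)
        norm = quad(lambda t: np.exp(-((t**2 - 1.5) ** 2)), -np.inf, np.inf)[0]
        probs = np.array([
            quad(lambda t: np.exp(-((t**2 - 1.5) ** 2)) / norm, a, b)[0]
            for a, b in zip(edges[:-1], edges[1:])
        ])
        inside = xs[(xs > edges[0]) & (xs < edges[-1])]
        exp_counts = probs / probs.sum() * len(inside)
        keep = exp_counts > 5
        _, p = chisquare(obs[keep], exp_counts[keep] * obs[keep].sum() / exp_counts[keep].sum())
        assert p > 0.01


class TestTuning:
    def test_oversized_step_shrinks_monotonically(self, three_body):
        cfg = SamplerConfig(
            total_steps=60_000, burn_in_steps=50_000, thinning=10,
            step_size_electron=50.0, step_size_nucleus=50.0,
            tuning_window=500, seed=5,
        )
        ss = run_chain(std_normal_6d, three_body, cfg, np.zeros(6) + 0.1)
        log = ss.provenance["tuning_log"]
        electron_steps = [s for (_, kind, s) in log if kind == "electron"]
        assert electron_steps and electron_steps[-1] < 50.0
        assert all(b < a for a, b in zip(electron_steps, electron_steps[1:]))
        lo, hi = cfg.target_acceptance
        assert lo <= ss.acceptance_fraction <= hi

    def test_step_in_window_unchanged(self, three_body):
        """Tuning is idempotent: restarting it from its own converged step
        size leaves the step size unchanged."""
        cfg = SamplerConfig(
            total_steps=50_001, burn_in_steps=50_000, thinning=1,
            step_size_electron=50.0, step_size_nucleus=50.0,
            tuning_window=2_000, seed=6,
        )
        sizes = tune_step_sizes(std_normal_6d, three_body, cfg, np.zeros(6) + 0.1)
        cfg2 = SamplerConfig(
            total_steps=20_001, burn_in_steps=20_000, thinning=1,
            step_size_electron=sizes["electron"],
            step_size_nucleus=sizes["electron"],
            tuning_window=2_000, seed=60,
        )
        sizes2 = tune_step_sizes(std_normal_6d, three_body, cfg2, np.zeros(6) + 0.1)
        assert sizes2["electron"] == sizes["electron"]

    def test_adaptation_confined_to_burn_in(self, three_body):
        cfg = SamplerConfig(
            total_steps=30_000, burn_in_steps=5_000, thinning=10,
            step_size_electron=30.0, step_size_nucleus=30.0,
            tuning_window=500, seed=9,
        )
        ss = run_chain(std_normal_6d, three_body, cfg, np.zeros(6) + 0.1)
        assert all(step < cfg.burn_in_steps for step, _, _ in ss.provenance["tuning_log"])


class TestExpectations:
    def test_single_snapshot_two_particles(self):
        sys_ = ParticleSystem(
            masses=(1836.0, 1.0), charges=(1.0, -1.0),
            kinds=("nucleus", "electron"),
        )
        ss = SampleSet(
            coords=np.array([[3.0, 0.0, 0.0]]),
            log_density=np.zeros(1), acceptance_fraction=1.0,
        )
        rep = estimate_expectations(ss, sys_)
        mean, se = rep.distances["X-e"]
        assert mean == pytest.approx(3.0)
        assert se == 0.0

    def test_maxwell_mean_distance(self, rng):
        """|r| of an isotropic 3D Gaussian pair displacement follows a Maxwell
        distribution with mean sigma * sqrt(8/pi)."""
        sigma = 0.7
        n = 40_000
        coords = sigma * rng.normal(size=(n, 3))
        sys_ = ParticleSystem(
            masses=(1836.0, 1.0), charges=(1.0, -1.0),
            kinds=("nucleus", "electron"),
        )
        ss = SampleSet(coords=coords, log_density=np.zeros(n), acceptance_fraction=1.0)
        rep = estimate_expectations(ss, sys_)
        mean, se = rep.distances["X-e"]
        expected = sigma * np.sqrt(8.0 / np.pi)
        assert mean == pytest.approx(expected, abs=4 * max(se, 1e-4))

    def test_virial_identity_exact(self, triangle_samples, d3_system):
        rep = estimate_expectations(triangle_samples, d3_system)
        assert rep.total_energy[0] == rep.potential_energy[0] / 2.0
        assert rep.total_energy[1] == rep.potential_energy[1] / 2.0

    def test_empty_sample_set_rejected(self, d3_system):
        ss = SampleSet(coords=np.empty((0, 12)), log_density=np.empty(0),
                       acceptance_fraction=1.0)
        with pytest.raises(ValueError, match="empty"):
            estimate_expectations(ss, d3_system)
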