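"""Metropolis random-walk sampling of all-particle densities.

The sampler draws from any log-density oracle over internal coordinates with
a Gaussian random-walk proposal.  Nuclei and electrons get separate step
sizes (nuclei are thousands of times heavier and move on a much smaller
scale); each step updates the coordinates of one particle kind, cycling
deterministically through the kinds, which keeps per-kind acceptance rates
well defined.  During burn-in the step sizes are adapted multiplicatively in
windows until the acceptance rate enters a target window; they are frozen at
the burn-in boundary so the recorded chain is a valid Markov chain.

Expectation values (mean interparticle distances per particle-class pair and
the mean Coulomb energy) are estimated from the thinned sample with block
averaging for error bars.  For a purely Coulombic eigenstate the virial
theorem gives the total energy as half the mean potential energy,
E_tot = <V>/2, which is how the total energy is reported.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .system import ParticleSystem, CoincidentParticlesError

__all__ = [
    "SamplerConfig",
    "SampleSet",
    "ExpectationReport",
    "ZeroDensityStartError",
    "ChainAbortError",
    "run_chain",
    "tune_step_sizes",
    "estimate_expectations",
]


class ZeroDensityStartError(ValueError):
    """The chain was started at a point of zero probability density."""


class ChainAbortError(RuntimeError):
    """The oracle returned a non-finite (NaN) value mid-chain."""


@dataclass
class SamplerConfig:
    """Random-walk Metropolis settings.

    Step sizes are in Bohr.  Defaults mirror a long production run: 3 million
    steps, 1e5 burn-in, thinning 100.
    """

    total_steps: int = 3_000_000
    burn_in_steps: int = 100_000
    thinning: int = 100
    step_size_nucleus: float = 0.1
    step_size_electron: float = 0.5
    target_acceptance: tuple[float, float] = (0.2, 0.5)
    tuning_window: int = 1_000
    max_tuning_rounds: int = 50
    tune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.total_steps > self.burn_in_steps >= 0):
            raise ValueError("require total_steps > burn_in_steps >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.step_size_nucleus <= 0 or self.step_size_electron <= 0:
            raise ValueError("step sizes must be positive")


@dataclass
class SampleSet:
    """Thinned MCMC snapshots in internal coordinates with provenance."""

    coords: np.ndarray          # (M, 3(N-1))
    log_density: np.ndarray     # (M,)
    acceptance_fraction: float
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def lab_configs(self) -> np.ndarray:
        """Snapshots as (M, N, 3) lab configurations, reference particle at origin."""
        M = self.coords.shape[0]
        rel = self.coords.reshape(M, -1, 3)
        return np.concatenate([np.zeros((M, 1, 3)), rel], axis=1)

    def subset(self, indices) -> "SampleSet":
        idx = np.asarray(indices)
        prov = dict(self.provenance)
        prov["subset_of"] = prov.get("oracle", "unknown")
        return SampleSet(
            coords=self.coords[idx],
            log_density=self.log_density[idx],
            acceptance_fraction=self.acceptance_fraction,
            provenance=prov,
        )


@dataclass
class ExpectationReport:
    """Sample means of the observables characterizing the sampled state.

    ``distances`` maps a particle-class pair tag (e.g. ``"D-D"``) to a
    (mean, standard error) tuple in Bohr.  Energies are in Hartree; the total
    energy is obtained from the virial theorem for Coulomb systems,
    E_tot = <V>/2, so ``total_energy == potential_energy / 2`` holds exactly.
    """

    distances: dict[str, tuple[float, float]]
    potential_energy: tuple[float, float]
    total_energy: tuple[float, float]
    n_samples: int
    n_blocks: int

    def as_dict(self) -> dict:
        return {
            "distances_bohr": {k: list(v) for k, v in self.distances.items()},
            "potential_energy_hartree": list(self.potential_energy),
            "total_energy_hartree": list(self.total_energy),
            "n_samples": self.n_samples,
            "n_blocks": self.n_blocks,
        }


def _coord_kind_masks(system: ParticleSystem) -> dict[str, np.ndarray]:
    """Boolean masks over the 3(N-1) internal coordinates, one per kind present."""
    kinds = system.kinds[1:]  # particles 2..N own the internal coordinates
    masks: dict[str, np.ndarray] = {}
    for kind in ("nucleus", "electron"):
        m = np.repeat([k == kind for k in kinds], 3)
        if m.any():
            masks[kind] = m
    return masks


def _run_engine(log_density, system, config, start, stop_at_burn_in=False):
    rng = np.random.default_rng(config.seed)
    x = np.asarray(start, dtype=float).copy().ravel()
    n_coords = 3 * (system.n_particles - 1)
    if x.size != n_coords:
        raise ValueError(f"start has {x.size} coordinates, expected {n_coords}")
    lp = float(log_density(x))
    if not np.isfinite(lp):
        raise ZeroDensityStartError(
            f"log-density at start is {lp}; the chain must start at rho > 0"
        )
    masks = _coord_kind_masks(system)
    kinds = list(masks)
    sigma = {
        "nucleus": config.step_size_nucleus,
        "electron": config.step_size_electron,
    }
    lo, hi = config.target_acceptance
    win_prop = {k: 0 for k in kinds}
    win_acc = {k: 0 for k in kinds}
    rounds = {k: 0 for k in kinds}
    tuned = {k: False for k in kinds}
    tuning_log: list[tuple[int, str, float]] = []

    n_record = 0
    if not stop_at_burn_in:
        post = config.total_steps - config.burn_in_steps
        n_record = post // config.thinning
    coords_out = np.empty((n_record, n_coords))
    logdens_out = np.empty(n_record)
    rec = 0
    post_prop = 0
    post_acc = 0

    total = config.burn_in_steps if stop_at_burn_in else config.total_steps
    for step in range(total):
        kind = kinds[step % len(kinds)]
        mask = masks[kind]
        prop = x.copy()
        prop[mask] += sigma[kind] * rng.standard_normal(int(mask.sum()))
        lp_prop = float(log_density(prop))
        if np.isnan(lp_prop):
            raise ChainAbortError(f"oracle returned NaN at step {step}")
        accept = np.log(rng.random()) < lp_prop - lp
        if accept:
            x, lp = prop, lp_prop
        in_burn_in = step < config.burn_in_steps
        if in_burn_in and config.tune:
            win_prop[kind] += 1
            win_acc[kind] += int(accept)
            if win_prop[kind] >= config.tuning_window and not tuned[kind]:
                rate = win_acc[kind] / win_prop[kind]
                if rate < lo:
                    sigma[kind] *= 0.8
                    tuning_log.append((step, kind, sigma[kind]))
                elif rate > hi:
                    sigma[kind] *= 1.25
                    tuning_log.append((step, kind, sigma[kind]))
                else:
                    tuned[kind] = True
                win_prop[kind] = 0
                win_acc[kind] = 0
                rounds[kind] += 1
                if rounds[kind] >= config.max_tuning_rounds and not tuned[kind]:
                    warnings.warn(
                        f"step-size tuning for {kind} did not reach the "
                        f"target acceptance window ({lo}, {hi}) after "
                        f"{rounds[kind]} rounds; keeping {sigma[kind]:.4g}",
                        stacklevel=3,
                    )
                    tuned[kind] = True
        if not in_burn_in:
            post_prop += 1
            post_acc += int(accept)
            if (step - config.burn_in_steps + 1) % config.thinning == 0 and rec < n_record:
                coords_out[rec] = x
                logdens_out[rec] = lp
                rec += 1
    acc_frac = post_acc / post_prop if post_prop else float("nan")
    return (
        coords_out[:rec],
        logdens_out[:rec],
        acc_frac,
        {k: sigma[k] for k in kinds},
        tuning_log,
    )


def run_chain(log_density, system: ParticleSystem, config: SamplerConfig,
              start: np.ndarray) -> SampleSet:
    """Run a random-walk Metropolis chain and return the thinned sample.

    ``log_density`` is a callable over internal coordinates returning
    log rho (may be -inf, never NaN).  Identical seeds produce identical
    output.
    """
    coords, logdens, acc, sigma, tlog = _run_engine(
        log_density, system, config, start
    )
    oracle_id = getattr(log_density, "identifier", getattr(log_density, "__name__", "oracle"))
    return SampleSet(
        coords=coords,
        log_density=logdens,
        acceptance_fraction=acc,
        provenance={
            "seed": config.seed,
            "total_steps": config.total_steps,
            "burn_in_steps": config.burn_in_steps,
            "thinning": config.thinning,
            "oracle": oracle_id,
            "final_step_sizes": sigma,
            "tuning_log": tlog,
        },
    )


def tune_step_sizes(log_density, system: ParticleSystem, config: SamplerConfig,
                    start: np.ndarray) -> dict[str, float]:
    """Run the burn-in adaptation only; return the frozen per-kind step sizes."""
    if config.burn_in_steps <= 0:
        raise ValueError("tuning requires burn_in_steps > 0")
    *_, sigma, _tlog = _run_engine(
        log_density, system, config, start, stop_at_burn_in=True
    )
    return sigma


# ---------------------------------------------------------------------------
# expectation values
# ---------------------------------------------------------------------------

def _group_tags(system: ParticleSystem) -> list[str]:
    """Unique short tag per identical group (disambiguated on label clashes)."""
    groups = system.identical_groups
    tags = [system.group_label(g) for g in groups]
    seen: dict[str, int] = {}
    out = []
    for t in tags:
        if tags.count(t) > 1:
            seen[t] = seen.get(t, 0) + 1
            out.append(f"{t}{seen[t]}")
        else:
            out.append(t)
    return out


def _block_se(series: np.ndarray, n_blocks: int) -> float:
    nb = min(n_blocks, len(series))
    if nb < 2:
        return 0.0
    means = np.array([b.mean() for b in np.array_split(series, nb)])
    return float(means.std(ddof=1) / np.sqrt(nb))


def estimate_expectations(samples: SampleSet, system: ParticleSystem,
                          n_blocks: int = 50) -> ExpectationReport:
    """Mean interparticle distances, potential energy and virial total energy.

    Distance means for a class pair average over every particle pair in that
    class pair and every snapshot; standard errors come from block averaging
    over ``n_blocks`` contiguous blocks of the chain.
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    lab = samples.lab_configs()  # (M, N, 3)
    N = system.n_particles
    iu, ju = np.triu_indices(N, k=1)
    r = np.linalg.norm(lab[:, iu] - lab[:, ju], axis=2)  # (M, P)
    if np.any(r == 0.0):
        m, p = np.argwhere(r == 0.0)[0]
        raise CoincidentParticlesError(
            f"snapshot {m}: particles {iu[p]} and {ju[p]} coincide"
        )
    q = np.asarray(system.charges)
    V = (q[iu] * q[ju] / r).sum(axis=1)  # (M,)
    v_mean = float(V.mean())
    v_se = _block_se(V, n_blocks)

    groups = system.identical_groups
    tags = _group_tags(system)
    membership = np.empty(N, dtype=int)
    for gi, g in enumerate(groups):
        membership[list(g)] = gi
    pair_group = (membership[iu], membership[ju])
    distances: dict[str, tuple[float, float]] = {}
    for a, b in itertools.combinations_with_replacement(range(len(groups)), 2):
        mask = ((pair_group[0] == a) & (pair_group[1] == b)) | (
            (pair_group[0] == b) & (pair_group[1] == a)
        )
        if not mask.any():
            continue  # same-group pair needs >= 2 members
        series = r[:, mask].mean(axis=1)
        distances[f"{tags[a]}-{tags[b]}"] = (
            float(series.mean()), _block_se(series, n_blocks)
        )
    return ExpectationReport(
        distances=distances,
        potential_energy=(v_mean, v_se),
        total_energy=(v_mean / 2.0, v_se / 2.0),
        n_samples=len(samples),
        n_blocks=min(n_blocks, len(samples)),
    )
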