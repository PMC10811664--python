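"""End-to-end pipeline: sample -> expectations -> cluster -> symmetry -> densities.

A run is described by a versioned plain-text (YAML) configuration and is
fully reproducible from the configuration plus its seeds.  Each stage
persists its artifact in the run directory and later stages consume the
persisted artifacts, so stages can be re-run individually (the CLI exposes
them as subcommands):

    samples.h5        thinned MCMC snapshots with provenance
    expectations.json mean distances, potential and virial total energy
    distances.h5      condensed RMSD matrix of the clustering subset
    cluster.json      k-medoids labels, medoids, cost
    medoid_<i>.xyz    medoid structures (Bohr)
    symmetry.json     feasible permutations, g, versions per medoid
    nuclear_kde_2d.txt  2D nuclear density map in the medoid plane
    electron_density.cube  3D electron density (when electrons are present)
    summary.txt       human-readable digest

Defaults mirror a production-quality run (3e6 steps, thinning 100, 30000
clustering subset, k = 1); small studies override them in the config.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import alignment, clustering, density, io, sampler, synthetic, wavefunction
from .system import ParticleSystem

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "load_config"]

logger = logging.getLogger("molstruct.pipeline")

CONFIG_VERSION = 1


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained in the run dir."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Validated pipeline settings with explicit defaults.

    ``input_kind`` is ``"synthetic"`` (with ``synthetic_model`` holding a
    model spec dict) or ``"wavefunction"`` (with ``wavefunction_path``).
    """

    input_kind: str
    output_dir: str
    synthetic_model: dict | None = None
    wavefunction_path: str | None = None
    sampler: dict = field(default_factory=dict)
    clustering: dict = field(default_factory=dict)
    symmetry: dict = field(default_factory=dict)
    kde: dict = field(default_factory=dict)
    seed: int = 1
    version: int = CONFIG_VERSION

    def __post_init__(self) -> None:
        if self.version != CONFIG_VERSION:
            raise ValueError(f"unsupported config version {self.version}")
        if self.input_kind == "synthetic":
            if not self.synthetic_model:
                raise ValueError("synthetic input requires a 'synthetic_model' spec")
        elif self.input_kind == "wavefunction":
            if not self.wavefunction_path:
                raise ValueError("wavefunction input requires 'wavefunction_path'")
        else:
            raise ValueError(
                f"input_kind must be 'synthetic' or 'wavefunction', "
                f"got {self.input_kind!r}"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        inp = d.get("input", {})
        return cls(
            input_kind=inp.get("kind", ""),
            synthetic_model=inp.get("model"),
            wavefunction_path=inp.get("path"),
            output_dir=d.get("output_dir", "molstruct_run"),
            sampler=d.get("sampler", {}),
            clustering=d.get("clustering", {}),
            symmetry=d.get("symmetry", {}),
            kde=d.get("kde", {}),
            seed=int(d.get("seed", 1)),
            version=int(d.get("version", CONFIG_VERSION)),
        )

    def to_dict(self) -> dict:
        inp: dict = {"kind": self.input_kind}
        if self.synthetic_model is not None:
            inp["model"] = self.synthetic_model
        if self.wavefunction_path is not None:
            inp["path"] = self.wavefunction_path
        return {
            "version": self.version,
            "seed": self.seed,
            "input": inp,
            "output_dir": self.output_dir,
            "sampler": self.sampler,
            "clustering": self.clustering,
            "symmetry": self.symmetry,
            "kde": self.kde,
        }


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _resolve_input(config: RunConfig):
    """(system, log-density oracle, default start) from the configured input."""
    if config.input_kind == "synthetic":
        model = synthetic.model_from_dict(config.synthetic_model)
        oracle = synthetic.make_density(model)
        system = model.system
        start = _default_start_synthetic(model)
    else:
        model = wavefunction.read_wavefunction(config.wavefunction_path)
        oracle = wavefunction.make_log_density(model)
        system = model.system
        start = _default_start_generic(system)
    return system, oracle, start


def _default_start_synthetic(model) -> np.ndarray:
    """Deterministic asymmetric start: stretched first conformer, electrons
    offset from distinct nuclei."""
    sys_ = model.system
    lab = np.zeros((sys_.n_particles, 3))
    nuc_idx = list(sys_.nuclear_indices)
    conf = model.conformers[0]
    stretch = 1.0 + 0.15 * np.arange(len(nuc_idx))
    lab[nuc_idx] = conf * stretch[:, None]
    for j, e in enumerate(sys_.electron_indices):
        site = nuc_idx[j % len(nuc_idx)]
        lab[e] = lab[site] + 0.3 * np.array([1.0, 0.5, -0.25]) * (j + 1)
    return (lab[1:] - lab[0]).ravel()


def _default_start_generic(system: ParticleSystem) -> np.ndarray:
    n = 3 * (system.n_particles - 1)
    return 0.1 * (1.0 + np.arange(n, dtype=float))


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage name must propagate
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s: done in %.2f s", name, time.perf_counter() - t0)
            return out
        wrapped.__name__ = fn.__name__
        return wrapped
    return deco


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}, which is produced by the "
            f"'{produced_by}' stage; run that stage first"
        )
    return path


@_stage("sample")
def stage_sample(config: RunConfig, out: Path):
    system, oracle, default_start = _resolve_input(config)
    s = dict(config.sampler)
    start = np.asarray(s.pop("start", default_start), dtype=float)
    cfg = sampler.SamplerConfig(
        total_steps=int(s.get("total_steps", 3_000_000)),
        burn_in_steps=int(s.get("burn_in_steps", 100_000)),
        thinning=int(s.get("thinning", 100)),
        step_size_nucleus=float(s.get("step_size_nucleus", 0.1)),
        step_size_electron=float(s.get("step_size_electron", 0.5)),
        seed=int(s.get("seed", config.seed)),
    )
    samples = sampler.run_chain(oracle, system, cfg, start)
    io.save_sample_set(samples, out / "samples.h5")
    logger.info(
        "sampled %d snapshots, acceptance %.3f", len(samples),
        samples.acceptance_fraction,
    )
    return samples


@_stage("expectations")
def stage_expectations(config: RunConfig, out: Path):
    system, _, _ = _resolve_input(config)
    samples = io.load_sample_set(_require(out / "samples.h5", "expectations", "sample"))
    report = sampler.estimate_expectations(samples, system)
    (out / "expectations.json").write_text(json.dumps(report.as_dict(), indent=2))
    return report


@_stage("cluster")
def stage_cluster(config: RunConfig, out: Path):
    system, _, _ = _resolve_input(config)
    samples = io.load_sample_set(_require(out / "samples.h5", "cluster", "sample"))
    c = dict(config.clustering)
    subset = int(c.get("subset", 30_000))
    idx = np.arange(len(samples))
    if len(samples) > subset:
        stride = len(samples) // subset
        idx = idx[::stride][:subset]
    configs = samples.lab_configs()[idx]
    D = alignment.distance_matrix(
        configs, system, max_pairs=int(c.get("max_pairs", 200_000_000))
    )
    io.save_distance_matrix(D, idx, out / "distances.h5")
    k_setting = c.get("k", 1)
    seed = int(c.get("seed", config.seed))
    scores = None
    if k_setting == "auto":
        k, scores = clustering.suggest_k(D, int(c.get("k_max", 5)), seed=seed)
    else:
        k = int(k_setting)
    result = clustering.k_medoids(D, k, seed=seed)
    payload = result.as_dict()
    payload["subset_indices"] = idx.tolist()
    if scores is not None:
        payload["silhouette_scores"] = {str(kk): v for kk, v in scores.items()}
    (out / "cluster.json").write_text(json.dumps(payload, indent=2))
    for ci, mi in enumerate(result.medoid_indices):
        io.write_xyz(
            out / f"medoid_{ci}.xyz", configs[mi], system,
            log_density=[samples.log_density[idx[mi]]],
            comment=f"medoid of cluster {ci}",
        )
    return result


@_stage("symmetry")
def stage_symmetry(config: RunConfig, out: Path):
    system, _, _ = _resolve_input(config)
    samples = io.load_sample_set(_require(out / "samples.h5", "symmetry", "sample"))
    cluster_payload = json.loads(
        _require(out / "cluster.json", "symmetry", "cluster").read_text()
    )
    idx = np.array(cluster_payload["subset_indices"])
    labels = np.array(cluster_payload["labels"])
    medoids = np.array(cluster_payload["medoid_indices"])
    configs = samples.lab_configs()[idx]
    tol_setting = config.symmetry.get("tolerance", "auto")
    reports = []
    for ci, mi in enumerate(medoids):
        members = configs[labels == ci]
        medoid = configs[mi]
        dists = alignment.distances_to_reference(members, medoid, system)
        tol = (
            clustering.default_symmetry_tolerance(dists)
            if tol_setting == "auto" else float(tol_setting)
        )
        rep = clustering.symmetry_analysis(medoid, system, tol)
        payload = rep.as_dict()
        payload["cluster"] = ci
        reports.append(payload)
    (out / "symmetry.json").write_text(json.dumps(reports, indent=2))
    return reports


@_stage("density")
def stage_density(config: RunConfig, out: Path):
    system, _, _ = _resolve_input(config)
    samples = io.load_sample_set(_require(out / "samples.h5", "density", "sample"))
    medoid_path = _require(out / "medoid_0.xyz", "density", "cluster")
    medoid, _, _ = io.read_xyz(medoid_path)
    aligned = density.align_ensemble(samples, medoid[0], system, medoid_id="medoid_0")
    kcfg = dict(config.kde)
    bw = kcfg.get("bandwidth", "auto")
    bw = None if bw == "auto" else float(bw)
    grid2d = density.nuclear_kde_2d(
        aligned, bandwidth=bw, grid_points=int(kcfg.get("nuclear_grid_points", 101))
    )
    density.write_grid_2d(grid2d, out / "nuclear_kde_2d.txt")
    grids = {"nuclear_2d": grid2d}
    if system.electron_indices:
        grid3d = density.electron_kde_3d(
            aligned, bandwidth=bw,
            grid_points=int(kcfg.get("electron_grid_points", 41)),
        )
        density.write_cube(grid3d, system, aligned.medoid, out / "electron_density.cube")
        grids["electron_3d"] = grid3d
    return grids


def _write_summary(config: RunConfig, out: Path) -> None:
    lines = ["molstruct pipeline summary", "=" * 26, ""]
    exp = json.loads((out / "expectations.json").read_text())
    lines.append("Expectation values (atomic units):")
    for tag, (mean, se) in exp["distances_bohr"].items():
        lines.append(f"  <r_{tag}> = {mean:.4f} +/- {se:.4f} Bohr")
    v, vse = exp["potential_energy_hartree"]
    e, ese = exp["total_energy_hartree"]
    lines.append(f"  <V>     = {v:.4f} +/- {vse:.4f} Hartree")
    lines.append(f"  E_tot   = {e:.4f} +/- {ese:.4f} Hartree (virial: <V>/2)")
    cl = json.loads((out / "cluster.json").read_text())
    lines.append("")
    lines.append(
        f"Clustering: k = {cl['k']}, cost = {cl['cost']:.3f}, "
        f"medoids = {cl['medoid_indices']}"
    )
    sym = json.loads((out / "symmetry.json").read_text())
    for rep in sym:
        lines.append(
            f"Cluster {rep['cluster']}: {rep['g']} of {rep['n_perm']} "
            f"permutations feasible -> {rep['versions']} version(s)"
            + (f", MS group {rep['ms_group_label']}" if rep["ms_group_label"] else "")
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    stage_sample(config, out)
    stage_expectations(config, out)
    stage_cluster(config, out)
    stage_symmetry(config, out)
    stage_density(config, out)
    _write_summary(config, out)
    logger.info("pipeline finished: %s", out)
    return out
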