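"""File I/O: XYZ snapshots, HDF5 sample sets and distance matrices.

The XYZ dialect used here is plain XYZ with two conventions stated in the
comment line: coordinates are in **Bohr** (not Angstrom), and the per-frame
log-density may be recorded as ``logrho=<value>``.  The element-symbol
column carries the particle label ("D", "H", ... for nuclei, "e" for
electrons).
"""

from __future__ import annotations

import json

import numpy as np

from .sampler import SampleSet
from .system import ParticleSystem

__all__ = [
    "write_xyz",
    "read_xyz",
    "save_sample_set",
    "load_sample_set",
    "save_distance_matrix",
    "load_distance_matrix",
]


def write_xyz(path, configs, system: ParticleSystem, log_density=None,
              comment: str = "") -> None:
    """Write one or more lab configurations as (multi-frame) XYZ, Bohr units."""
    configs = np.asarray(configs, dtype=float)
    if configs.ndim == 2:
        configs = configs[None]
    M = configs.shape[0]
    if log_density is not None:
        log_density = np.asarray(log_density, dtype=float).ravel()
        if log_density.size != M:
            raise ValueError("one log-density per frame required")
    with open(path, "w") as fh:
        for f in range(M):
            fh.write(f"{system.n_particles}\n")
            parts = ["units=Bohr"]
            if log_density is not None:
                parts.append(f"logrho={float(log_density[f])!r}")
            if comment:
                parts.append(comment)
            fh.write(" ".join(parts) + "\n")
            for lab, (x, y, z) in zip(system.labels, configs[f]):
                fh.write(f"{lab} {float(x)!r} {float(y)!r} {float(z)!r}\n")


def read_xyz(path):
    """Read (multi-frame) XYZ -> (configs (M, N, 3), labels, log_densities).

    ``log_densities`` entries are NaN for frames without a ``logrho=`` tag.
    """
    frames = []
    logrho = []
    labels = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline()
            lr = float("nan")
            for tok in comment.split():
                if tok.startswith("logrho="):
                    lr = float(tok.split("=", 1)[1])
            rows = []
            labs = []
            for _ in range(n):
                tok = fh.readline().split()
                labs.append(tok[0])
                rows.append([float(v) for v in tok[1:4]])
            frames.append(rows)
            logrho.append(lr)
            if labels is None:
                labels = labs
    return np.array(frames), labels, np.array(logrho)


def save_sample_set(samples: SampleSet, path) -> None:
    """Persist a sample set to HDF5 with its provenance attributes."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("coords", data=samples.coords)
        fh.create_dataset("log_density", data=samples.log_density)
        fh.attrs["acceptance_fraction"] = samples.acceptance_fraction
        fh.attrs["provenance"] = json.dumps(samples.provenance, default=str)
        fh.attrs["units"] = "Bohr (coords), log of unnormalized density"


def load_sample_set(path) -> SampleSet:
    import h5py

    with h5py.File(path, "r") as fh:
        return SampleSet(
            coords=fh["coords"][()],
            log_density=fh["log_density"][()],
            acceptance_fraction=float(fh.attrs["acceptance_fraction"]),
            provenance=json.loads(fh.attrs["provenance"]),
        )


def save_distance_matrix(condensed: np.ndarray, snapshot_indices, path) -> None:
    """Persist a condensed distance matrix plus the snapshot index map."""
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("condensed", data=np.asarray(condensed))
        fh.create_dataset("snapshot_indices", data=np.asarray(snapshot_indices))
        fh.attrs["units"] = "Bohr (RMSD after alignment)"


def load_distance_matrix(path):
    import h5py

    with h5py.File(path, "r") as fh:
        return fh["condensed"][()], fh["snapshot_indices"][()]
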