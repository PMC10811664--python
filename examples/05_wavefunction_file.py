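"""Evaluate an explicitly-correlated-Gaussian wave function from a file.

Writes a tiny hand-made ECG parameter file (one Gaussian term over the
internal coordinates of a three-particle system), reads it back, evaluates
Psi and log rho = 2 log|Psi|, and samples rho by MCMC to check a closed-form
Gaussian moment.
"""

from pathlib import Path

import numpy as np

import molstruct as ms
from molstruct.wavefunction import make_log_density

system = ms.ParticleSystem(
    masses=(1836.0, 1.0, 1.0), charges=(1.0, -1.0, -1.0),
    kinds=("nucleus", "electron", "electron"),
)
model = ms.ECGModel(
    system=system,
    cholesky_factors=np.eye(2)[None],   # A = I: Psi(x) = exp(-|x|^2)
    coefficients=np.array([1.0]),
)

path = Path("scratch")
path.mkdir(exist_ok=True)
wf = path / "toy.ecg"
ms.write_wavefunction(model, wf)
model = ms.read_wavefunction(wf)

x = np.zeros(6)
print(f"Psi(0)      = {ms.evaluate_psi(model, x):.6f}  (exact: 1)")
x[0] = 1.0
print(f"Psi(|x|=1)  = {ms.evaluate_psi(model, x):.6f}  (exact: e^-1 = 0.367879)")
print(f"log rho     = {ms.log_density(model, x):.6f}  (exact: -2)")

cfg = ms.SamplerConfig(total_steps=60_000, burn_in_steps=5_000, thinning=5,
                       step_size_electron=0.5, step_size_nucleus=0.5, seed=5)
samples = ms.run_chain(make_log_density(model), system, cfg, 0.1 * np.ones(6))
msr = (samples.coords**2).sum(axis=1).mean()
print(f"MCMC <|x|^2> = {msr:.3f}  (closed form for rho = e^(-2|x|^2): 1.5)")
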