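"""Structural symmetry: feasible permutations and versions of a structure.

For each identical-nuclei label permutation P the analysis measures
d(P . structure, structure); permutations undone by a rotation (distance ~ 0)
are feasible.  With g feasible permutations out of N_perm the structure has
N_perm / g permutational versions.  An equilateral triangle of identical
nuclei has g = 6 (one version, MS group D3h(M)); a scalene one g = 1; a bent
symmetric two-proton molecule g = 2 (the swap is a 180-degree rotation).
"""

import numpy as np

import molstruct as ms


def triangle(sides):
    a, b, c = sides
    x = (a**2 + b**2 - c**2) / (2 * a)
    return np.array([[0.0, 0, 0], [a, 0, 0], [x, np.sqrt(b**2 - x**2), 0.0]])


d3 = ms.ParticleSystem.d3_plus()
for name, sides in (("equilateral", (1.69, 1.69, 1.69)),
                    ("scalene", (1.0, 1.4, 1.9))):
    config = np.vstack([triangle(sides), np.zeros((2, 3))])
    rep = ms.symmetry_analysis(config, d3, tol=0.1)
    print(f"{name:12s}: g = {rep.g} of N_perm = {rep.n_perm}, "
          f"versions = {rep.versions}, MS group = {rep.ms_group_label}")

water = ms.ParticleSystem(
    masses=(29156.95, 1836.15, 1836.15, 1.0),
    charges=(8.0, 1.0, 1.0, -1.0),
    kinds=("nucleus", "nucleus", "nucleus", "electron"),
    labels=("O", "H", "H", "e"),
)
bent = np.array([[0.0, 0, 0], [1.43, 1.11, 0], [-1.43, 1.11, 0], [0, 0.5, 0.0]])
rep = ms.symmetry_analysis(bent, water, tol=0.1)
print(f"{'water-like':12s}: g = {rep.g} of N_perm = {rep.n_perm}, "
      f"versions = {rep.versions}, MS group = {rep.ms_group_label}")
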