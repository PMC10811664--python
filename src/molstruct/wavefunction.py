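"""All-particle wave functions built from explicitly correlated Gaussians.

The ansatz is a linear combination of K basis terms

    phi_k(x) = exp(-x^T (A_k  (x)  I_3) x),      A_k = L_k L_k^T,

over the 3n internal coordinates x of an (n+1)-particle molecule, acted on by
a permutational symmetry projector

    Psi(x) = sum_s w_s sum_k c_k phi_k(T_s x),

where each T_s is an n x n linear transform on internal coordinates (applied
identically to the three Cartesian components) and w_s a signed weight.  Spin
is integrated out: the projector carries the net *spatial* symmetrization
weights, so no spin coordinates are ever sampled.

Exponent matrices are stored through their Cholesky factors L_k (lower
triangular, positive diagonal) so positive definiteness is structural.
Amplitudes are evaluated with a signed log-sum-exp over basis and projector
terms to stay finite at large |x|.

The probability density sampled downstream is rho(x) = |Psi(x)|^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .system import ParticleSystem

__all__ = [
    "ECGModel",
    "WavefunctionFormatError",
    "read_wavefunction",
    "write_wavefunction",
    "evaluate_psi",
    "log_density",
    "read_atom_mol_nonbo",
]

FORMAT_VERSION = 1


class WavefunctionFormatError(ValueError):
    """A wave-function parameter file failed validation."""


@dataclass
class ECGModel:
    """Explicitly-correlated-Gaussian expansion of an all-particle wave function.

    Attributes
    ----------
    system : ParticleSystem
        The particle content (masses/charges/kinds).
    cholesky_factors : (K, n, n) array
        Lower-triangular factors L_k with positive diagonal; the exponent
        matrix of term k is ``A_k = L_k @ L_k.T``.
    coefficients : (K,) array
        Linear expansion coefficients c_k.
    projector_transforms : (S, n, n) array
        Linear transforms T_s on internal coordinates.
    projector_weights : (S,) array
        Signed weights w_s; the identity transform must be present.
    reference_particle : int
        Index of the particle at the origin of the internal frame (recorded
        from the parameter file; a nucleus by convention).
    """

    system: ParticleSystem
    cholesky_factors: np.ndarray
    coefficients: np.ndarray
    projector_transforms: np.ndarray = field(default=None)  # type: ignore[assignment]
    projector_weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    reference_particle: int = 0

    def __post_init__(self) -> None:
        n = self.system.n_particles - 1
        L = np.asarray(self.cholesky_factors, dtype=float)
        if L.ndim != 3 or L.shape[1:] != (n, n):
            raise WavefunctionFormatError(
                f"cholesky_factors shape {L.shape} incompatible with n = {n}"
            )
        K = L.shape[0]
        c = np.asarray(self.coefficients, dtype=float).ravel()
        if c.size != K:
            raise WavefunctionFormatError(
                f"{c.size} coefficients for {K} basis terms"
            )
        tri = np.triu_indices(n, k=1)
        if np.any(L[:, tri[0], tri[1]] != 0.0):
            raise WavefunctionFormatError("cholesky factors must be lower triangular")
        if np.any(np.diagonal(L, axis1=1, axis2=2) <= 0.0):
            bad = int(np.where(np.diagonal(L, axis1=1, axis2=2) <= 0.0)[0][0])
            raise WavefunctionFormatError(
                f"term {bad}: non-positive Cholesky diagonal — exponent matrix "
                "not positive definite"
            )
        if self.projector_transforms is None:
            self.projector_transforms = np.eye(n)[None]
        if self.projector_weights is None:
            self.projector_weights = np.ones(self.projector_transforms.shape[0])
        T = np.asarray(self.projector_transforms, dtype=float)
        w = np.asarray(self.projector_weights, dtype=float).ravel()
        if T.ndim != 3 or T.shape[1:] != (n, n) or T.shape[0] != w.size:
            raise WavefunctionFormatError("projector shape mismatch")
        if not any(np.allclose(Ts, np.eye(n)) for Ts in T):
            raise WavefunctionFormatError("projector must contain the identity")
        self.cholesky_factors = L
        self.coefficients = c
        self.projector_transforms = T
        self.projector_weights = w

    @property
    def basis_size(self) -> int:
        return self.cholesky_factors.shape[0]

    @property
    def n_pseudo(self) -> int:
        """n = N - 1, the number of internal-coordinate particles."""
        return self.cholesky_factors.shape[1]

    def exponent_matrices(self) -> np.ndarray:
        """The (K, n, n) positive-definite exponent matrices A_k."""
        L = self.cholesky_factors
        return np.einsum("kij,klj->kil", L, L)


def _signed_log_terms(model: ECGModel, x: np.ndarray):
    """log|c_k w_s| and sign for every (s, k) term plus the Gaussian exponents.

    Returns (log_mag, sign) arrays of shape (S*K,) for a single point x.
    """
    n = model.n_pseudo
    X = np.asarray(x, dtype=float).reshape(n, 3)
    A = model.exponent_matrices()  # (K, n, n)
    T = model.projector_transforms  # (S, n, n)
    Y = np.einsum("sij,jd->sid", T, X)  # transformed coordinates
    # quadratic forms q[s, k] = tr(Y_s^T A_k Y_s)
    q = np.einsum("sid,kij,sjd->sk", Y, A, Y)
    cw = model.projector_weights[:, None] * model.coefficients[None, :]
    with np.errstate(divide="ignore"):
        log_mag = np.log(np.abs(cw)) - q
    return log_mag.ravel(), np.sign(cw).ravel()


def evaluate_psi(model: ECGModel, x: np.ndarray) -> float:
    """Wave-function amplitude Psi(x) at internal coordinates x."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != 3 * model.n_pseudo:
        raise ValueError(f"expected {3 * model.n_pseudo} coordinates, got {x.size}")
    log_mag, sign = _signed_log_terms(model, x)
    log_abs, s = logsumexp(log_mag, b=sign, return_sign=True)
    if np.isneginf(log_abs):
        return 0.0
    return float(s * np.exp(log_abs))


def log_density(model: ECGModel, x: np.ndarray) -> float:
    """log rho(x) = 2 log|Psi(x)|; -inf at nodes, never NaN."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != 3 * model.n_pseudo:
        raise ValueError(f"expected {3 * model.n_pseudo} coordinates, got {x.size}")
    log_mag, sign = _signed_log_terms(model, x)
    log_abs, _ = logsumexp(log_mag, b=sign, return_sign=True)
    return float(2.0 * log_abs)


def make_log_density(model: ECGModel):
    """A log-density oracle ``f(x) -> log rho(x)`` closing over the model."""

    def _oracle(x: np.ndarray) -> float:
        return log_density(model, x)

    _oracle.identifier = f"ecg(K={model.basis_size}, n={model.n_pseudo})"
    return _oracle


# ---------------------------------------------------------------------------
# native parameter-file format (versioned plain text)
# ---------------------------------------------------------------------------

def write_wavefunction(model: ECGModel, path) -> None:
    """Write the model in the native versioned plain-text format.

    Header: version, particle table (mass, charge, kind, label), reference
    particle, basis size; body: projector terms (weight + row-major T) and
    basis terms (coefficient + row-major lower-triangle of L).  All lengths
    in Bohr^-2 (exponents) and atomic units.
    """
    n = model.n_pseudo
    sys_ = model.system
    lines = [
        f"# molstruct ECG wave function, atomic units (Bohr, Hartree, m_e)",
        f"version {FORMAT_VERSION}",
        f"particles {sys_.n_particles}",
        "masses " + " ".join(repr(float(m)) for m in sys_.masses),
        "charges " + " ".join(repr(float(q)) for q in sys_.charges),
        "kinds " + " ".join(sys_.kinds),
        "labels " + " ".join(sys_.labels),
        f"reference_particle {model.reference_particle}",
        f"basis_size {model.basis_size}",
        f"projector_size {model.projector_weights.size}",
    ]
    for w, T in zip(model.projector_weights, model.projector_transforms):
        lines.append("projector " + repr(float(w)) + " " + " ".join(repr(float(v)) for v in T.ravel()))
    il, jl = np.tril_indices(n)
    for c, L in zip(model.coefficients, model.cholesky_factors):
        lines.append("term " + repr(float(c)) + " " + " ".join(repr(float(v)) for v in L[il, jl]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_wavefunction(path) -> ECGModel:
    """Read a native-format parameter file into an :class:`ECGModel`.

    Raises :class:`WavefunctionFormatError` with a distinct diagnostic for a
    malformed file, a non-positive-definite exponent factor, or a basis-count
    mismatch.
    """
    fields: dict[str, list[str]] = {}
    projectors: list[list[str]] = []
    terms: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, *rest = line.split()
            if key == "projector":
                projectors.append(rest)
            elif key == "term":
                terms.append(rest)
            else:
                fields[key] = rest
    try:
        version = int(fields["version"][0])
        n_part = int(fields["particles"][0])
        masses = [float(v) for v in fields["masses"]]
        charges = [float(v) for v in fields["charges"]]
        kinds = fields["kinds"]
        labels = fields.get("labels", [])
        ref = int(fields["reference_particle"][0])
        basis_size = int(fields["basis_size"][0])
    except (KeyError, ValueError, IndexError) as exc:
        raise WavefunctionFormatError(f"malformed parameter file: {exc!r}") from exc
    if version != FORMAT_VERSION:
        raise WavefunctionFormatError(f"unsupported format version {version}")
    system = ParticleSystem(
        masses=tuple(masses), charges=tuple(charges), kinds=tuple(kinds),
        labels=tuple(labels),
    )
    if system.n_particles != n_part:
        raise WavefunctionFormatError("particle count does not match particle table")
    n = n_part - 1
    if len(terms) != basis_size:
        raise WavefunctionFormatError(
            f"basis_size {basis_size} but {len(terms)} term lines"
        )
    il, jl = np.tril_indices(n)
    L = np.zeros((basis_size, n, n))
    c = np.zeros(basis_size)
    for k, tok in enumerate(terms):
        vals = [float(v) for v in tok]
        if len(vals) != 1 + il.size:
            raise WavefunctionFormatError(
                f"term {k}: expected coefficient + {il.size} factor entries, "
                f"got {len(vals)}"
            )
        c[k] = vals[0]
        L[k, il, jl] = vals[1:]
    T = np.zeros((max(len(projectors), 1), n, n))
    w = np.ones(max(len(projectors), 1))
    if projectors:
        for s, tok in enumerate(projectors):
            vals = [float(v) for v in tok]
            if len(vals) != 1 + n * n:
                raise WavefunctionFormatError(
                    f"projector {s}: expected weight + {n * n} matrix entries"
                )
            w[s] = vals[0]
            T[s] = np.array(vals[1:]).reshape(n, n)
    else:
        T[0] = np.eye(n)
    return ECGModel(
        system=system, cholesky_factors=L, coefficients=c,
        projector_transforms=T, projector_weights=w, reference_particle=ref,
    )


def read_atom_mol_nonbo(path) -> ECGModel:
    """Converter stub for ATOM-MOL-nonBO parameter dumps.

    The deposited D3+ wave function is distributed as a dump of the
    ATOM-MOL-nonBO program.  Converting it requires that program's dump
    layout (ordering of exponent entries and the symmetry-projector
    conventions of its ECG ansatz), which this package does not reimplement.
    Convert such dumps to the native format documented in
    :func:`write_wavefunction` and load them with :func:`read_wavefunction`.
    """
    raise NotImplementedError(
        "ATOM-MOL-nonBO dump conversion is a documented extension point; "
        "convert to the native format and use read_wavefunction()"
    )
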