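"""Adjacency-matrix samplers for the nine DCDFM edge-weight families.

Each family draws the upper triangle of ``A`` independently with
``E[A_ij] = Omega_ij`` (the uniform family is the one exception, see
below) and mirrors it to the lower triangle so symmetry is exact:

========== =======================================================
family      law for A_ij given Omega_ij
========== =======================================================
bernoulli   Bernoulli(Omega)
binomial    Binomial(m, Omega/m)
poisson     Poisson(Omega)
geometric   support {1,2,...}, success probability 1/Omega
exponential rate 1/Omega (mean Omega)
normal      Normal(Omega, sigma2)
laplace     Laplace, mean Omega, variance sigma2 (scale sigma/sqrt 2)
uniform     Uniform(0, Omega)   -- NOTE: mean is Omega/2, not Omega
signed      +1 w.p. (1+Omega)/2, -1 otherwise
========== =======================================================

The uniform law is sampled exactly as written even though its mean is
Omega/2; callers relying on E[A] = Omega should treat the uniform family
as "expectation Omega/2" (see docs/methods.md).

Diagonal entries are 0 by default (no self-loops); ``include_diagonal``
samples them from the same law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import ModelSpec, SpecValidationError, build_omega, validate_spec

__all__ = ["WeightedNetwork", "sample_adjacency", "theta_from_rho"]


@dataclass
class WeightedNetwork:
    """A symmetric weighted network: dense adjacency plus provenance.

    ``node_ids`` maps internal 0-based indices to external identifiers
    (defaults to 1-based integers); ``meta`` records family, seed, etc.
    """

    A: np.ndarray
    node_ids: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError(f"adjacency must be square, got shape {self.A.shape}")
        if not np.all(np.isfinite(self.A)):
            raise ValueError("adjacency contains non-finite entries")
        if not self.node_ids:
            self.node_ids = list(range(1, self.A.shape[0] + 1))

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def is_symmetric(self, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.A, self.A.T, atol=atol, rtol=0.0))


def as_adjacency(net) -> np.ndarray:
    """Accept a WeightedNetwork or a bare array; return the dense matrix."""
    A = net.A if isinstance(net, WeightedNetwork) else np.asarray(net, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    return A


def theta_from_rho(
    n: int,
    rho: float,
    mode: str = "uniform_scaled",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw the heterogeneity vector from the sparsity parameter rho.

    ``uniform_scaled``: theta_i = U_i * rho with U_i ~ Uniform(0,1) i.i.d.
    (the default convention for the simulation studies); ``constant``:
    theta_i = rho for all i; ``constant_sqrt``: theta_i = sqrt(rho), the
    distribution-free-model convention in which rho is the network
    sparsity, Omega = rho * Z P Z' (used by the geometric and
    signed-network studies).
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    if mode == "constant":
        return np.full(n, float(rho))
    if mode == "constant_sqrt":
        return np.full(n, float(np.sqrt(rho)))
    if mode == "uniform_scaled":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return rng.uniform(0.0, 1.0, size=n) * rho
    raise ValueError(f"unknown theta mode {mode!r}")


def _draw(family: str, omega: np.ndarray, rng: np.random.Generator,
          m: int | None, sigma2: float | None, clip: bool) -> np.ndarray:
    size = omega.shape
    if family == "bernoulli":
        p = np.clip(omega, 0.0, 1.0) if clip else omega
        return (rng.random(size) < p).astype(np.float64)
    if family == "binomial":
        p = omega / m
        if clip:
            p = np.clip(p, 0.0, 1.0)
        return rng.binomial(m, p, size=size).astype(np.float64)
    if family == "poisson":
        return rng.poisson(omega, size=size).astype(np.float64)
    if family == "geometric":
        return rng.geometric(1.0 / omega, size=size).astype(np.float64)
    if family == "exponential":
        return rng.exponential(scale=omega, size=size)
    if family == "normal":
        return rng.normal(loc=omega, scale=np.sqrt(sigma2), size=size)
    if family == "laplace":
        # scale b with variance 2 b^2 = sigma2
        return rng.laplace(loc=omega, scale=np.sqrt(sigma2 / 2.0), size=size)
    if family == "uniform":
        return rng.uniform(0.0, 1.0, size=size) * omega
    if family == "signed":
        p_plus = (1.0 + omega) / 2.0
        if clip:
            p_plus = np.clip(p_plus, 0.0, 1.0)
        return np.where(rng.random(size) < p_plus, 1.0, -1.0)
    raise ValueError(f"unknown family {family!r}")


def sample_adjacency(
    spec: ModelSpec,
    seed: int | np.random.Generator | None = None,
    *,
    validate: bool = True,
    clip: bool = False,
    include_diagonal: bool = False,
) -> WeightedNetwork:
    """Sample one symmetric adjacency matrix from a DCDFM spec.

    The strict upper triangle is drawn once per pair and mirrored, so the
    output is exactly symmetric for every family and seed, and identical
    (spec, seed) pairs give bit-identical matrices.

    Parameters
    ----------
    clip : bool
        Clip Bernoulli/Binomial/signed success probabilities into [0, 1]
        instead of rejecting specs whose Omega strays out of range
        (the simulation harness enables this; see docs/methods.md).
    include_diagonal : bool
        Sample A_ii from the same law; default leaves the diagonal 0.
    """
    if validate:
        report = validate_spec(spec, clip_probabilities=clip)
        report.raise_if_invalid()
    omega = build_omega(spec, validate=False)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    iu, ju = np.triu_indices(spec.n, k=0 if include_diagonal else 1)
    vals = _draw(spec.family, omega[iu, ju], rng, spec.m, spec.sigma2, clip)
    if not np.all(np.isfinite(vals)):
        raise FloatingPointError(f"{spec.family} sampler produced non-finite weights")

    A = np.zeros((spec.n, spec.n))
    A[iu, ju] = vals
    A[ju, iu] = vals
    return WeightedNetwork(
        A=A,
        meta={"family": spec.family, "n": spec.n, "K": spec.K},
    )
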