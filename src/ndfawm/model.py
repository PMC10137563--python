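"""Degree-corrected distribution-free model (DCDFM) parameter objects.

The DCDFM generates a symmetric weighted adjacency matrix ``A`` whose
entries are independent draws from an arbitrary distribution family ``F``
with expectation

    E[A_ij] = Omega_ij = theta_i * theta_j * P[l_i, l_j],

where ``l`` assigns each of the ``n`` nodes to one of ``K`` communities,
``theta`` is a vector of positive per-node heterogeneity factors (producing
degree variation within communities), and ``P`` is a symmetric full-rank
K x K connectivity matrix with entries in [-1, 1] and maximum absolute
entry 1.  Depending on ``F``, edge weights may be binary, counts, real or
signed; which signs ``P`` may carry is family-specific and enforced by
:func:`validate_spec`.

Special cases: constant ``theta`` gives the distribution-free model (DFM);
Bernoulli ``F`` with nonnegative ``P`` gives the DCSBM; both restrictions
together give the classical SBM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

FAMILIES = (
    "bernoulli",
    "binomial",
    "poisson",
    "geometric",
    "exponential",
    "normal",
    "laplace",
    "uniform",
    "signed",
)

# Families whose draws are Bernoulli/Binomial trials: their success
# probabilities are the only place where an out-of-range Omega can be
# salvaged by clipping rather than rejected outright.
_PROB_FAMILIES = ("bernoulli", "binomial", "signed")


class InvalidLabelsError(ValueError):
    """A label vector contains entries outside {1..K}."""


class SpecValidationError(ValueError):
    """A ModelSpec violates a structural or family-specific constraint."""

    def __init__(self, report: "ValidationReport"):
        self.report = report
        super().__init__("; ".join(f.message for f in report.errors))


@dataclass(frozen=True)
class Finding:
    """One validation finding: a machine-readable code plus a message."""

    code: str
    message: str


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_invalid(self) -> None:
        if self.errors:
            raise SpecValidationError(self)


@dataclass
class ModelSpec:
    """Parameter bundle for one DCDFM network.

    Parameters
    ----------
    n : int
        Number of nodes.
    K : int
        Number of communities (1 <= K <= n).
    labels : (n,) int array
        Community assignment, entries in {1..K}.
    theta : (n,) float array
        Positive node heterogeneity factors.
    P : (K, K) float array
        Symmetric connectivity matrix, rank K, entries in [-1, 1],
        max |P| = 1 by convention (theta absorbs the overall scale).
    family : str
        One of :data:`FAMILIES`.
    m : int, optional
        Trial count, Binomial family only.
    sigma2 : float, optional
        Variance, Normal and Laplace families only.
    """

    n: int
    K: int
    labels: np.ndarray
    theta: np.ndarray
    P: np.ndarray
    family: str
    m: int | None = None
    sigma2: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        self.P = np.atleast_2d(np.asarray(self.P, dtype=np.float64))

    @property
    def Z(self) -> np.ndarray:
        """Membership matrix, derived from labels on demand."""
        return build_membership(self.labels, self.K)

    @property
    def Theta(self) -> np.ndarray:
        """Diagonal heterogeneity matrix, derived from theta on demand."""
        return np.diag(self.theta)

    # -- flat-config serialization -------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n": int(self.n),
            "K": int(self.K),
            "labels": [int(x) for x in self.labels],
            "theta": [float(x) for x in self.theta],
            "P": [float(x) for x in self.P.ravel()],
            "family": self.family,
        }
        if self.m is not None:
            d["m"] = int(self.m)
        if self.sigma2 is not None:
            d["sigma2"] = float(self.sigma2)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        K = int(d["K"])
        return cls(
            n=int(d["n"]),
            K=K,
            labels=np.asarray(d["labels"], dtype=np.int64),
            theta=np.asarray(d["theta"], dtype=np.float64),
            P=np.asarray(d["P"], dtype=np.float64).reshape(K, K),
            family=str(d["family"]),
            m=int(d["m"]) if "m" in d and d["m"] is not None else None,
            sigma2=float(d["sigma2"]) if "sigma2" in d and d["sigma2"] is not None else None,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_membership(labels: Iterable[int], K: int) -> np.ndarray:
    """Build the n x K binary membership matrix Z from a label vector.

    ``Z[i, k-1] = 1`` iff node ``i`` belongs to community ``k``; each row
    has exactly one 1 and column ``k-1`` sums to the size of community k.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.ndim != 1:
        raise InvalidLabelsError("labels must be a 1-D vector")
    if labels.size and (labels.min() < 1 or labels.max() > K):
        bad = labels[(labels < 1) | (labels > K)][0]
        raise InvalidLabelsError(f"label {bad} outside {{1..{K}}}")
    Z = np.zeros((labels.size, K), dtype=np.int8)
    Z[np.arange(labels.size), labels - 1] = 1
    return Z


def build_omega(spec: ModelSpec, *, validate: bool = True) -> np.ndarray:
    """Expectation matrix Omega = Theta Z P Z' Theta.

    Computed entrywise as ``Omega_ij = theta_i theta_j P[l_i, l_j]``,
    which is algebraically identical to the matrix product but O(n^2)
    instead of O(n^2 K).  Exactly symmetric by construction.
    """
    if validate:
        validate_spec(spec, structural_only=True).raise_if_invalid()
    block = spec.P[np.ix_(spec.labels - 1, spec.labels - 1)]
    # outer(theta, theta) is bitwise symmetric, so Omega is exactly so
    return np.outer(spec.theta, spec.theta) * block


def _rank(P: np.ndarray, rtol: float = 1e-10) -> int:
    s = np.linalg.svd(P, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def validate_spec(
    spec: ModelSpec,
    *,
    strict_max_abs: bool = False,
    structural_only: bool = False,
    clip_probabilities: bool = False,
) -> ValidationReport:
    """Check a ModelSpec against structural and family-specific rules.

    Structural rules: shapes consistent; labels cover {1..K}; theta > 0;
    P symmetric with rank K and entries in [-1, 1].  max|P| = 1 is a
    warning unless ``strict_max_abs`` (the convention only fixes the
    scale split between P and theta).

    Family rules (entrywise on the off-diagonal of Omega):

    - bernoulli: P >= 0 and Omega in [0, 1]
    - binomial:  P >= 0 and Omega/m in [0, 1]
    - poisson:   Omega >= 0
    - geometric: P > 0 and Omega >= 1 (success probability 1/Omega in (0,1])
    - exponential: P > 0 (rate 1/Omega must be positive)
    - normal/laplace: none (any real mean is valid)
    - uniform:   P >= 0
    - signed:    |Omega| <= 1 (so (1 +/- Omega)/2 are probabilities)

    With ``clip_probabilities`` the Bernoulli/Binomial/signed probability
    range findings are downgraded to warnings, matching a sampler that
    clips success probabilities into [0, 1].
    """
    rep = ValidationReport()
    err = lambda code, msg: rep.errors.append(Finding(code, msg))
    warn = lambda code, msg: rep.warnings.append(Finding(code, msg))

    if spec.family not in FAMILIES:
        err("family", f"unknown family {spec.family!r}")
        return rep
    if spec.n < 1 or spec.K < 1 or spec.K > spec.n:
        err("shape", f"need 1 <= K <= n, got n={spec.n}, K={spec.K}")
    if spec.labels.shape != (spec.n,):
        err("shape", f"labels shape {spec.labels.shape} != ({spec.n},)")
    if spec.theta.shape != (spec.n,):
        err("shape", f"theta shape {spec.theta.shape} != ({spec.n},)")
    if spec.P.shape != (spec.K, spec.K):
        err("shape", f"P shape {spec.P.shape} != ({spec.K}, {spec.K})")
    if rep.errors:
        return rep

    if spec.labels.min() < 1 or spec.labels.max() > spec.K:
        err("labels-range", "labels contain entries outside {1..K}")
    elif np.unique(spec.labels).size < spec.K:
        missing = set(range(1, spec.K + 1)) - set(np.unique(spec.labels).tolist())
        err("labels-empty-community", f"communities {sorted(missing)} are empty")
    if np.any(spec.theta <= 0):
        i = int(np.argmax(spec.theta <= 0))
        err("theta-positive", f"theta[{i}] = {spec.theta[i]} is not positive")
    if not np.allclose(spec.P, spec.P.T, atol=1e-12):
        err("P-symmetric", "P is not symmetric")
    if np.any(np.abs(spec.P) > 1 + 1e-12):
        err("P-range", f"|P| entries exceed 1 (max {np.abs(spec.P).max():.6g})")
    r = _rank(spec.P)
    if r < spec.K:
        err("P-rank", f"P has numerical rank {r} < K = {spec.K}")
    maxabs = np.abs(spec.P).max()
    if not np.isclose(maxabs, 1.0, atol=1e-12):
        f = Finding("P-maxabs", f"max |P| = {maxabs:.6g}, convention is 1")
        (rep.errors if strict_max_abs else rep.warnings).append(f)

    if rep.errors or structural_only:
        return rep

    # family-specific sign / range rules on P and the off-diagonal Omega
    fam = spec.family
    omega = build_omega(spec, validate=False)
    off = ~np.eye(spec.n, dtype=bool)
    om = omega[off]

    def prob_finding(code: str, msg: str) -> None:
        if clip_probabilities and fam in _PROB_FAMILIES:
            warn(code, msg + " (clipped at sampling time)")
        else:
            err(code, msg)

    if fam in ("bernoulli", "binomial", "uniform") and np.any(spec.P < 0):
        err("P-sign", f"{fam}: all elements of P must be non-negative")
    if fam in ("geometric", "exponential") and np.any(spec.P <= 0):
        err("P-sign", f"{fam}: all elements of P must be positive")

    if fam == "bernoulli":
        if om.size and (om.min() < 0 or om.max() > 1):
            prob_finding("prob-range", f"bernoulli: Omega in [0,1] required, range [{om.min():.4g}, {om.max():.4g}]")
    elif fam == "binomial":
        if spec.m is None or spec.m < 1:
            err("aux-m", "binomial family requires a positive integer m")
        elif om.size and (om.min() < 0 or om.max() > spec.m):
            prob_finding("prob-range", f"binomial: Omega/m in [0,1] required, Omega range [{om.min():.4g}, {om.max():.4g}], m={spec.m}")
    elif fam == "poisson":
        if om.size and om.min() < 0:
            err("omega-range", f"poisson: Omega >= 0 required, min {om.min():.4g}")
    elif fam == "geometric":
        if om.size and om.min() < 1:
            err("omega-range", f"geometric: Omega >= 1 required (success prob 1/Omega in (0,1]), min {om.min():.4g}")
    elif fam in ("normal", "laplace"):
        if spec.sigma2 is None or spec.sigma2 <= 0:
            err("aux-sigma2", f"{fam} family requires positive sigma2")
    elif fam == "signed":
        if om.size and np.abs(om).max() > 1:
            prob_finding("prob-range", f"signed: |Omega| <= 1 required, max {np.abs(om).max():.4g}")
    return rep
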