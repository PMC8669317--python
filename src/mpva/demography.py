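"""Single-population stage-structured demography.

The core of the model is a 3x3 female-only (single-sex) projection matrix with
stages (sub-adult, breeding adult, non-breeding adult) under a pre-breeding
census: the youngest tracked class are birds approaching age 1 that already
survived their first winter.

    A = [[ s1*(1-g),  (e/2)*h*f*s0,  0        ],
         [ s1*g,      s2*b,          s3*b     ],
         [ 0,         s2*(1-b),      s3*(1-b) ]]

where ``g`` is the sub-adult-to-adult growth transition for a fixed stage
duration of ``T`` years,

    g = ((s1/lam)^T - (s1/lam)^(T-1)) / ((s1/lam)^T - 1),

and ``lam`` is the dominant eigenvalue of A itself, so (g, lam) must be solved
as a fixed point.  Density dependence acts on fledging success through a
theta-logistic divisor that halves f exactly at N = K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VitalRates",
    "ProjectionMatrix",
    "DensityDependence",
    "growth_fraction",
    "build_matrix",
    "stable_stage_distribution",
    "density_dependent_fledging",
    "InvalidParameterError",
    "ConvergenceError",
    "DegenerateMatrixError",
]

STAGE_NAMES = ("sub-adult", "breeding adult", "non-breeding adult")


class InvalidParameterError(ValueError):
    """A vital rate or model parameter is outside its admissible domain."""


class ConvergenceError(RuntimeError):
    """The lambda-g fixed-point iteration failed to converge."""

    def __init__(self, msg: str, last_lambdas: tuple[float, float] | None = None):
        super().__init__(msg)
        self.last_lambdas = last_lambdas


class DegenerateMatrixError(ValueError):
    """Dominant eigenvalue is complex or not unique within tolerance."""


@dataclass(frozen=True)
class VitalRates:
    """Demographic parameter set for one population.

    Attributes
    ----------
    s0 : first-winter (fledgling) survival probability
    s1 : sub-adult annual survival probability
    s2 : breeding-adult annual survival probability
    s3 : non-breeding-adult annual survival probability
    b  : adult annual breeding probability
    e  : mean eggs per breeding pair (typically 1-3)
    h  : hatching success probability
    f  : baseline fledging probability
    afr : age of first reproduction in years (integer >= 1)
    """

    s0: float
    s1: float
    s2: float
    s3: float
    b: float
    e: float
    h: float
    f: float
    afr: int

    def __post_init__(self) -> None:
        for name in ("s0", "s1", "s2", "s3", "b", "h", "f"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise InvalidParameterError(f"{name}={v!r} must lie in [0, 1]")
        if not (self.e > 0):
            raise InvalidParameterError(f"e={self.e!r} must be positive")
        if int(self.afr) != self.afr or self.afr < 1:
            raise InvalidParameterError(f"afr={self.afr!r} must be an integer >= 1")

    def with_rates(self, **kwargs: float) -> "VitalRates":
        """Return a copy with some rates replaced."""
        return replace(self, **kwargs)

    def stage_duration(self, recruitment_offset: int = 1) -> int:
        """Sub-adult stage duration T = AFR - recruitment_offset, floored at 1.

        The default offset of 1 reflects the pre-breeding census: recruitment
        to the sub-adult class happens at age 1 and first breeding at AFR.
        """
        return max(1, int(self.afr) - recruitment_offset)


@dataclass(frozen=True)
class DensityDependence:
    """Theta-logistic reduction of fledging success near carrying capacity.

    ``theta`` controls abruptness (values of 5-10 leave fledging essentially
    untouched below ~2/3 of K); ``K`` is the female carrying capacity.
    """

    theta: float = 7.5
    K: float = 1.0

    def __post_init__(self) -> None:
        if not (self.theta > 0):
            raise InvalidParameterError(f"theta={self.theta!r} must be > 0")
        if not (self.K > 0):
            raise InvalidParameterError(f"K={self.K!r} must be > 0")


@dataclass
class ProjectionMatrix:
    """A converged stage projection matrix with its growth diagnostics."""

    entries: np.ndarray
    lam: float
    g: float
    stage_names: tuple[str, str, str] = field(default=STAGE_NAMES)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (3, 3):
            raise InvalidParameterError("projection matrix must be 3x3")
        if (self.entries < 0).any():
            raise InvalidParameterError("projection matrix entries must be >= 0")

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.entries, dtype=dtype)


def growth_fraction(s1: float, lam: float, T: int) -> float:
    """Probability a surviving sub-adult graduates to the adult stage.

    Uses the fixed-stage-duration formula
    ``g = (r^T - r^(T-1)) / (r^T - 1)`` with ``r = s1/lam``, which equals the
    proportion of the within-stage stable age distribution sitting in the final
    year of the stage.  At r -> 1 the analytic limit 1/T is returned.
    """
    if not (s1 > 0) or not (lam > 0):
        raise InvalidParameterError(f"s1={s1!r} and lam={lam!r} must be positive")
    if int(T) != T or T < 1:
        raise InvalidParameterError(f"T={T!r} must be an integer >= 1")
    T = int(T)
    if T == 1:
        return 1.0
    r = s1 / lam
    # Near r=1 both numerator and denominator vanish; switch to the limit.
    if abs(r - 1.0) < 1e-9:
        return 1.0 / T
    g = (r**T - r ** (T - 1)) / (r**T - 1.0)
    return min(1.0, max(0.0, g))


def _matrix_entries(v: VitalRates, g: float) -> np.ndarray:
    fec = (v.e / 2.0) * v.h * v.f * v.s0
    return np.array(
        [
            [v.s1 * (1.0 - g), fec, 0.0],
            [v.s1 * g, v.s2 * v.b, v.s3 * v.b],
            [0.0, v.s2 * (1.0 - v.b), v.s3 * (1.0 - v.b)],
        ]
    )


def _dominant_eigenvalue(entries: np.ndarray) -> float:
    ev = np.linalg.eigvals(entries)
    return float(np.max(ev.real))


def build_matrix(
    v: VitalRates,
    tol: float = 1e-6,
    max_iter: int = 500,
    lam0: float = 1.0,
    recruitment_offset: int = 1,
) -> ProjectionMatrix:
    """Build the stage projection matrix, solving (lambda, g) by fixed point.

    Starting from ``lam0`` the iteration alternates computing g from the
    current lambda and lambda as the dominant eigenvalue of the resulting
    matrix, until successive lambdas differ by less than ``tol``.  ``tol`` may
    be relaxed to 1e-2 to match a 2-decimal stabilization rule.
    """
    T = v.stage_duration(recruitment_offset)
    lam = float(lam0)
    if v.s1 == 0.0:
        # No sub-adult survival: g is irrelevant, matrix is immediate.
        entries = _matrix_entries(v, 0.0)
        return ProjectionMatrix(entries, _dominant_eigenvalue(entries), 0.0)
    prev = math.inf
    for _ in range(max_iter):
        g = growth_fraction(v.s1, lam, T)
        entries = _matrix_entries(v, g)
        new_lam = _dominant_eigenvalue(entries)
        if new_lam <= 0:
            # Non-growing degenerate chain (e.g. all adults die, no breeding).
            return ProjectionMatrix(entries, new_lam, g)
        prev, lam = lam, new_lam
        if abs(lam - prev) < tol:
            return ProjectionMatrix(entries, lam, g)
    raise ConvergenceError(
        f"lambda-g fixed point did not converge within {max_iter} iterations; "
        f"last two lambda values: {prev:.8f}, {lam:.8f}",
        last_lambdas=(prev, lam),
    )


def stable_stage_distribution(A: ProjectionMatrix | np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Stable stage distribution: dominant right eigenvector, summing to 1."""
    entries = np.asarray(A, dtype=float)
    vals, vecs = np.linalg.eig(entries)
    order = np.argsort(-vals.real)
    i = order[0]
    lam = vals[i]
    if abs(lam.imag) > tol * max(1.0, abs(lam.real)):
        raise DegenerateMatrixError(f"dominant eigenvalue {lam} is complex")
    others = vals[order[1:]]
    if others.size and np.any(np.abs(others - lam) < tol * max(1.0, abs(lam))):
        raise DegenerateMatrixError("dominant eigenvalue is not unique within tolerance")
    w = vecs[:, i].real
    w = np.where(np.abs(w) < tol, 0.0, w)
    if w.sum() < 0:
        w = -w
    if (w < 0).any():
        raise DegenerateMatrixError("dominant eigenvector has mixed signs")
    return w / w.sum()


def density_dependent_fledging(f: float, N: float, dd: DensityDependence) -> float:
    """Fledging success reduced by crowding: ``f / (1 + (N/K)^theta)``.

    Strictly decreasing in N; exactly f/2 at N = K; essentially f for
    N below ~2/3 K when theta is in the 5-10 range.
    """
    if N < 0:
        raise InvalidParameterError(f"N={N!r} must be >= 0")
    return f / (1.0 + (N / dd.K) ** dd.theta)
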