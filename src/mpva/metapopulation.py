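"""Multi-colony assembly: block demography plus stage-specific dispersal.

Colony projection matrices A_i are stacked block-diagonally into C (3k x 3k,
island-major).  Emigration probabilities per stage form a diagonal matrix D,
and an inter-colony connectivity matrix IP routes emigrants among destinations
with probabilities decaying exponentially in great-circle distance.  The
metapopulation matrix is

    M = (IP kron D) @ C + C

whose diagonal blocks are (I - D) A_i (stayers) and whose off-diagonal block
(j, i) is p_{i,j} D A_i (movers from i that settle at j).  The -1 diagonal of
IP makes the subtraction of emigrants fall out of the Kronecker product, and
guarantees exact conservation: dispersal redistributes individuals without
creating or destroying them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mpva.demography import InvalidParameterError, ProjectionMatrix

__all__ = [
    "DispersalSpec",
    "ColonyGeometry",
    "build_connectivity",
    "assemble",
    "project",
    "block_diagonal",
    "great_circle_distances",
    "NoDestinationError",
]

EARTH_RADIUS_KM = 6371.0


class NoDestinationError(ValueError):
    """Connectivity requested for fewer than two colonies."""


@dataclass(frozen=True)
class DispersalSpec:
    """Per-stage emigration probabilities and mean dispersal distance (km)."""

    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0
    delta: float = 100.0

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name}={v!r} must lie in [0, 1]")
        if not (self.delta > 0):
            raise InvalidParameterError(f"delta={self.delta!r} must be > 0")

    def as_matrix(self) -> np.ndarray:
        return np.diag([self.d1, self.d2, self.d3])


@dataclass(frozen=True)
class ColonyGeometry:
    """Pairwise great-circle distances (km) between k colonies."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidParameterError("distance matrix must be square")
        if (d < 0).any():
            raise InvalidParameterError("distances must be non-negative")
        if not np.allclose(d, d.T, atol=1e-8):
            raise InvalidParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise InvalidParameterError("distance matrix diagonal must be zero")
        object.__setattr__(self, "distances", d)

    @property
    def k(self) -> int:
        return self.distances.shape[0]

    @classmethod
    def from_coordinates(cls, lon: np.ndarray, lat: np.ndarray) -> "ColonyGeometry":
        """Build from lon/lat in degrees via great-circle (haversine) distance."""
        return cls(great_circle_distances(np.asarray(lon, float), np.asarray(lat, float)))


def great_circle_distances(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Haversine distances in km between all pairs of (lon, lat) points."""
    lon_r = np.radians(lon)[:, None]
    lat_r = np.radians(lat)[:, None]
    dlon = lon_r - lon_r.T
    dlat = lat_r - lat_r.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat_r) * np.cos(lat_r.T) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return d


def build_connectivity(geom: ColonyGeometry, delta: float) -> np.ndarray:
    """Inter-colony connectivity matrix IP.

    Off-diagonal entry (j, i) is the probability that an emigrant leaving
    colony i settles at colony j, proportional to exp(-d_ij / delta) and
    normalized so each column's off-diagonal entries sum to 1.  The diagonal
    is fixed at -1 so that (IP kron D) C + C subtracts emigrants in place.
    """
    if geom.k < 2:
        raise NoDestinationError("connectivity needs at least 2 colonies; use the k=1 bypass")
    if not (delta > 0):
        raise InvalidParameterError(f"delta={delta!r} must be > 0")
    d = geom.distances
    w = np.exp(-d / delta)
    np.fill_diagonal(w, 0.0)
    colsum = w.sum(axis=0)
    if (colsum <= 0).any():
        raise InvalidParameterError("a colony has no reachable destination")
    ip = w / colsum  # column-normalized: IP[j, i] = p_{i -> j}
    np.fill_diagonal(ip, -1.0)
    return ip


def block_diagonal(mats: list[ProjectionMatrix | np.ndarray]) -> np.ndarray:
    """Stack per-colony 3x3 projection matrices into C (island-major)."""
    k = len(mats)
    C = np.zeros((3 * k, 3 * k))
    for i, A in enumerate(mats):
        C[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] = np.asarray(A, dtype=float)
    return C


def assemble(C: np.ndarray, D: DispersalSpec | np.ndarray, IP: np.ndarray) -> np.ndarray:
    """Metapopulation matrix M = (IP kron D) @ C + C."""
    C = np.asarray(C, dtype=float)
    Dm = D.as_matrix() if isinstance(D, DispersalSpec) else np.asarray(D, dtype=float)
    IP = np.asarray(IP, dtype=float)
    k = IP.shape[0]
    if C.shape != (3 * k, 3 * k):
        raise InvalidParameterError(
            f"C has shape {C.shape}, expected {(3 * k, 3 * k)} for k={k} colonies"
        )
    if Dm.shape != (3, 3):
        raise InvalidParameterError("D must be 3x3")
    M = np.kron(IP, Dm) @ C + C
    # Clamp the tiny negatives from floating cancellation of stayer terms.
    M[(M < 0) & (M > -1e-12)] = 0.0
    if (M < 0).any():
        raise InvalidParameterError("assembled metapopulation matrix has negative entries")
    return M


def project(M: np.ndarray, n: np.ndarray) -> np.ndarray:
    """One annual step of the metapopulation: n_{t+1} = M n_t."""
    n = np.asarray(n, dtype=float)
    if (n < 0).any():
        raise InvalidParameterError("abundances must be non-negative")
    M = np.asarray(M, dtype=float)
    if M.shape[1] != n.shape[0]:
        raise InvalidParameterError(f"shape mismatch: M {M.shape} vs n {n.shape}")
    return M @ n
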