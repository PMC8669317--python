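"""Invasive-species impacts as proportional hazards on vital rates.

Each invasive taxon on an island is classified into one of five categories
(bird, carnivore, herbivore, omnivore, rat) and contributes a hazard ratio
Delta > 1 on egg/chick mortality, keyed by the seabird's nesting type crossed
with the invasive category.  The per-island cumulative log hazard on fledging
is

    gamma_f = [sum_x log(Delta_x)] * (1/X)^phi * (1/Area)^psi

where X is the number of invasives present (phi in [0,1] interpolates between
purely additive mortality at phi=0 and purely compensatory at phi=1) and Area
in km^2 discounts per-capita impacts on larger islands (psi >= 0).  Adult
hazards use the same form with per-member log(Omega_x) =
zeta_x * beta1 * log(Delta_x) / (1/AdSz + 1)^beta2, where zeta_x switches off
categories that pose no risk to adults and AdSz is adult body mass in kg.
Hazards transform survival-type rates through the proportional-hazards
identity S' = S^exp(gamma).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mpva.demography import InvalidParameterError

__all__ = [
    "INVASIVE_CATEGORIES",
    "NESTING_TYPES",
    "DEFAULT_ZETA",
    "InvasiveAssemblage",
    "HazardParameters",
    "chick_log_hazard",
    "adult_log_hazard_single",
    "adult_cumulative_hazard",
    "apply_hazards",
    "sample_delta",
]

INVASIVE_CATEGORIES = ("bird", "carnivore", "herbivore", "omnivore", "rat")
NESTING_TYPES = ("arboreal", "burrow", "cliff", "crevice", "crevice/burrow", "surface")

# Which categories threaten adult birds (not just eggs/chicks).
DEFAULT_ZETA = {"herbivore": 0, "bird": 0, "carnivore": 1, "omnivore": 1, "rat": 1}

# Floor on island area to keep (1/Area)^psi bounded on islets.
MIN_ISLAND_AREA_KM2 = 0.01


@dataclass(frozen=True)
class InvasiveAssemblage:
    """The invasive species present on one island.

    ``members`` is a list of (category, zeta) pairs where zeta in {0, 1}
    switches adult risk; pass zeta=None to use the category default.
    """

    members: tuple[tuple[str, int], ...]
    island_area: float

    def __init__(
        self,
        members: list[tuple[str, int | None]] | list[str],
        island_area: float,
    ):
        if island_area <= 0:
            raise InvalidParameterError(f"island_area={island_area!r} must be > 0")
        norm: list[tuple[str, int]] = []
        for m in members:
            if isinstance(m, str):
                cat, zeta = m, None
            else:
                cat, zeta = m
            if cat not in INVASIVE_CATEGORIES:
                raise InvalidParameterError(
                    f"unknown invasive category {cat!r}; valid: {INVASIVE_CATEGORIES}"
                )
            if zeta is None:
                zeta = DEFAULT_ZETA[cat]
            if zeta not in (0, 1):
                raise InvalidParameterError(f"zeta={zeta!r} must be 0 or 1")
            norm.append((cat, int(zeta)))
        object.__setattr__(self, "members", tuple(norm))
        object.__setattr__(self, "island_area", float(island_area))

    @property
    def Xi(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HazardParameters:
    """Hazard-function parameters shared across islands for one species.

    ``delta`` maps (nesting_type, invasive_category) -> hazard ratio >= 1 on
    chick mortality; ``nesting_type`` selects the row used for this species.
    ``delta_bar``/``sigma_delta`` are the hierarchical hyper-parameters from
    which unobserved Delta entries may be drawn (truncated at 1).
    """

    delta: dict[tuple[str, str], float]
    nesting_type: str = "surface"
    phi: float = 0.5
    psi: float = 0.0
    beta1: float = 0.5
    beta2: float = 1.0
    adult_size: float = 1.0
    delta_bar: float = 1.2
    sigma_delta: float = 0.2
    zeta_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nesting_type not in NESTING_TYPES:
            raise InvalidParameterError(
                f"unknown nesting type {self.nesting_type!r}; valid: {NESTING_TYPES}"
            )
        if not (0.0 <= self.phi <= 1.0):
            raise InvalidParameterError(f"phi={self.phi!r} must lie in [0, 1]")
        if self.psi < 0:
            raise InvalidParameterError(f"psi={self.psi!r} must be >= 0")
        if self.adult_size <= 0:
            raise InvalidParameterError(f"adult_size={self.adult_size!r} must be > 0")
        if self.sigma_delta <= 0:
            raise InvalidParameterError(f"sigma_delta={self.sigma_delta!r} must be > 0")
        for key, d in self.delta.items():
            if d <= 0:
                raise InvalidParameterError(f"delta{key!r}={d!r} must be > 0")

    def delta_for(self, category: str) -> float:
        return self.delta[(self.nesting_type, category)]


def sample_delta(
    rng: np.random.Generator,
    delta_bar: float,
    sigma_delta: float,
    size: int | tuple[int, ...] = 1,
    log_scale: bool = False,
) -> np.ndarray:
    """Draw hazard ratios from the hierarchical distribution N(delta_bar, sigma).

    Draws below 1 are truncated to 1 (an invasive never helps seabirds).
    ``log_scale=True`` places the normal on log(Delta) instead.
    """
    z = rng.normal(delta_bar, sigma_delta, size=size)
    if log_scale:
        z = np.exp(z)
    return np.maximum(z, 1.0)


def _area_factor(area: float, psi: float) -> float:
    return (1.0 / max(area, MIN_ISLAND_AREA_KM2)) ** psi


def chick_log_hazard(assemblage: InvasiveAssemblage, params: HazardParameters) -> float:
    """Cumulative log hazard ratio gamma_f on egg/chick (fledging) mortality."""
    if assemblage.Xi == 0:
        return 0.0
    total = 0.0
    for cat, _zeta in assemblage.members:
        d = params.delta_for(cat)
        if d < 1.0:
            raise InvalidParameterError(f"delta for {cat!r} is {d} < 1; hazards must not help")
        total += math.log(d)
    return total * (1.0 / assemblage.Xi) ** params.phi * _area_factor(
        assemblage.island_area, params.psi
    )


def adult_log_hazard_single(
    delta_x: float, zeta: int, adult_size: float, beta1: float, beta2: float
) -> float:
    """Per-member adult log hazard: zeta * beta1 * log(Delta) / (1/AdSz + 1)^beta2."""
    if delta_x <= 0:
        raise InvalidParameterError(f"delta_x={delta_x!r} must be > 0")
    if adult_size <= 0:
        raise InvalidParameterError(f"adult_size={adult_size!r} must be > 0")
    return zeta * beta1 * math.log(delta_x) / (1.0 / adult_size + 1.0) ** beta2


def adult_cumulative_hazard(assemblage: InvasiveAssemblage, params: HazardParameters) -> float:
    """Cumulative log hazard gamma_s on adult survival.

    Same sum-then-scale structure as ``chick_log_hazard`` with per-member
    log(Omega_x) in place of log(Delta_x); the compensation exponent phi and
    island-size exponent psi are shared with the chick hazard.
    """
    if assemblage.Xi == 0:
        return 0.0
    total = 0.0
    for cat, zeta in assemblage.members:
        zeta = params.zeta_overrides.get(cat, zeta)
        total += adult_log_hazard_single(
            params.delta_for(cat), zeta, params.adult_size, params.beta1, params.beta2
        )
    return total * (1.0 / assemblage.Xi) ** params.phi * _area_factor(
        assemblage.island_area, params.psi
    )


def apply_hazards(
    f: float, s2: float, gamma_f: float, gamma_s: float
) -> tuple[float, float]:
    """Apply cumulative log hazards to fledging and adult survival.

    Proportional-hazards survival identity: S' = S^exp(gamma), i.e. the
    cumulative mortality hazard -log(S) scales by the hazard ratio exp(gamma).
    """
    if gamma_f < 0 or gamma_s < 0:
        raise InvalidParameterError("cumulative log hazards must be >= 0")
    f2 = 0.0 if f == 0.0 else f ** math.exp(gamma_f)
    s2p = 0.0 if s2 == 0.0 else s2 ** math.exp(gamma_s)
    return f2, s2p
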