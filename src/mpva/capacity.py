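"""Carrying capacity estimation and allocation among colonies.

Range-wide female carrying capacity is approximated as K = AoO* x eta, where
AoO* scales the IUCN Area-of-Occupancy by a fitted proportion of area actually
usable for nesting (a logit-linear model in log body size with family
offsets) and eta is maximum nest density (one nest per female).  Total K is
then partitioned among occupied islands with a logit-linear allocation model
in island area, number of islands, and relative area share, subject to the
constraint that each island's K is at least twice its current abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mpva.demography import InvalidParameterError

__all__ = [
    "AllocationModel",
    "AoOProportionModel",
    "CapacityEstimate",
    "scale_aoo",
    "species_K",
    "allocate",
    "partition_K",
    "fit_allocation_model",
    "fit_aoo_model",
    "InfeasibleCapacityWarning",
]


class InfeasibleCapacityWarning(UserWarning):
    """Total K could not accommodate every island's 2x-abundance floor."""


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return np.log(p / (1.0 - p))


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class AllocationModel:
    """Logit-linear model of the proportional allocation of abundance.

    Linear predictor per island i (NI islands, areas in km^2):

        b0 + b_logarea*log(A_i) + b_ni*NI + b_share*(A_i / sum A)
           + b_logarea_ni*log(A_i)*NI + b_ni_share*NI*(A_i / sum A)
           + family offset

    passed through the inverse logit and renormalized to sum to 1.
    """

    intercept: float = 0.0
    b_logarea: float = 0.0
    b_ni: float = 0.0
    b_share: float = 0.0
    b_logarea_ni: float = 0.0
    b_ni_share: float = 0.0
    family_effects: dict[str, float] = field(default_factory=dict)

    def linear_predictor(self, areas: np.ndarray, family: str | None = None) -> np.ndarray:
        areas = np.asarray(areas, dtype=float)
        if (areas <= 0).any():
            raise InvalidParameterError("island areas must be positive")
        ni = areas.size
        share = areas / areas.sum()
        la = np.log(areas)
        eta = (
            self.intercept
            + self.b_logarea * la
            + self.b_ni * ni
            + self.b_share * share
            + self.b_logarea_ni * la * ni
            + self.b_ni_share * ni * share
        )
        if family is not None:
            eta = eta + self.family_effects.get(family, 0.0)
        return eta


@dataclass(frozen=True)
class AoOProportionModel:
    """Logit-linear model of the proportion of AoO usable for nesting."""

    intercept: float
    b_log_body_size: float = 0.0
    family_effects: dict[str, float] = field(default_factory=dict)
    has_global_intercept: bool = True

    def predict_proportion(self, body_size: float, family: str | None = None) -> float:
        if body_size <= 0:
            raise InvalidParameterError(f"body_size={body_size!r} must be > 0")
        if family is not None and family not in self.family_effects:
            if not self.has_global_intercept:
                raise InvalidParameterError(
                    f"family {family!r} unknown to the model and no global intercept available"
                )
        eta = self.intercept + self.b_log_body_size * np.log(body_size)
        if family is not None:
            eta += self.family_effects.get(family, 0.0)
        p = float(_inv_logit(np.asarray(eta)))
        return min(1.0, max(p, 1e-12))


@dataclass(frozen=True)
class CapacityEstimate:
    """Range-wide and per-island female carrying capacities."""

    K_total: float
    K_i: np.ndarray
    AoO_star: float
    eta: float


def scale_aoo(
    aoo: float, body_size: float, family: str | None, model: AoOProportionModel
) -> float:
    """Suitable nesting area AoO* = AoO x predicted usable proportion."""
    if aoo <= 0:
        raise InvalidParameterError(f"AoO={aoo!r} must be > 0")
    return aoo * model.predict_proportion(body_size, family)


def species_K(aoo_star: float, eta: float) -> float:
    """Range-wide female K = suitable nesting area x nest density.

    One nest corresponds to one breeding female, so the product is already on
    the female scale.  A zero AoO* propagates to K=0 with a warning.
    """
    if aoo_star < 0 or eta <= 0:
        raise InvalidParameterError("AoO* must be >= 0 and eta > 0")
    if aoo_star == 0:
        warnings.warn("AoO* is zero; carrying capacity degenerate at 0", InfeasibleCapacityWarning)
    return aoo_star * eta


def allocate(
    areas: np.ndarray, model: AllocationModel, family: str | None = None
) -> np.ndarray:
    """Proportional allocation of range-wide abundance among islands (sums to 1)."""
    areas = np.asarray(areas, dtype=float)
    if areas.size < 1:
        raise InvalidParameterError("need at least one island")
    if areas.size == 1:
        return np.array([1.0])
    p = _inv_logit(model.linear_predictor(areas, family))
    return p / p.sum()


def partition_K(
    K_total: float,
    proportions: np.ndarray,
    current_abundances: np.ndarray,
    max_rounds: int = 100,
) -> np.ndarray:
    """Split K_total by proportion, honouring per-island floors of 2x abundance.

    Water-filling: islands whose proportional share falls below the floor are
    pinned at it and the remainder is re-split among the rest, iterating until
    stable.  If the floors alone exceed K_total the floors are returned and
    the effective total rises, with a warning.
    """
    proportions = np.asarray(proportions, dtype=float)
    current = np.asarray(current_abundances, dtype=float)
    if proportions.shape != current.shape:
        raise InvalidParameterError("proportions and abundances must have equal length")
    floors = 2.0 * current
    if floors.sum() >= K_total:
        warnings.warn(
            f"2x-abundance floors (sum {floors.sum():.1f}) exceed K_total={K_total:.1f}; "
            "raising total to the floors",
            InfeasibleCapacityWarning,
        )
        return floors.copy()
    K = K_total * proportions / proportions.sum()
    pinned = np.zeros(K.shape, dtype=bool)
    for _ in range(max_rounds):
        below = (K < floors) & ~pinned
        if not below.any():
            break
        pinned |= below
        K[pinned] = floors[pinned]
        free = ~pinned
        remaining = K_total - floors[pinned].sum()
        K[free] = remaining * proportions[free] / proportions[free].sum()
    return K


def fit_aoo_model(table: pd.DataFrame, ridge: float = 0.0) -> AoOProportionModel:
    """Fit the usable-AoO proportion model from (proportion, body_size_kg, family).

    OLS on the logit of the observed proportion with log body size and family
    dummy offsets (ridge-penalized when ``ridge`` > 0, approximating a random
    effect).
    """
    y = _logit(table["proportion"].to_numpy(float))
    x = np.log(table["body_size_kg"].to_numpy(float))
    fams = sorted(table["family"].unique())
    X = [np.ones_like(x), x]
    for fam in fams[1:]:
        X.append((table["family"] == fam).to_numpy(float))
    X = np.column_stack(X)
    if ridge > 0:
        model = sm.OLS(y, X).fit_regularized(alpha=ridge, L1_wt=0.0)
    else:
        model = sm.OLS(y, X).fit()
    params = np.asarray(model.params)
    effects = {fams[0]: 0.0}
    effects.update({fam: float(c) for fam, c in zip(fams[1:], params[2:])})
    return AoOProportionModel(
        intercept=float(params[0]), b_log_body_size=float(params[1]), family_effects=effects
    )


def fit_allocation_model(table: pd.DataFrame, ridge: float = 0.0) -> AllocationModel:
    """Fit the allocation model from a colony table.

    Expects columns (species, area_km2, ni, share) where ``share`` is the
    observed fraction of the species' abundance on that island; fits OLS on
    logit(share) with the standard covariate set.  Family offsets, if a
    ``family`` column is present, are ridge-penalized fixed effects.
    """
    areas = table["area_km2"].to_numpy(float)
    ni = table["ni"].to_numpy(float)
    share_area = table.groupby("species")["area_km2"].transform(lambda a: a / a.sum())
    share_area = share_area.to_numpy(float)
    y = _logit(table["share"].to_numpy(float))
    la = np.log(areas)
    cols = [np.ones_like(la), la, ni, share_area, la * ni, ni * share_area]
    fams: list[str] = []
    if "family" in table.columns:
        fams = sorted(table["family"].unique())
        for fam in fams[1:]:
            cols.append((table["family"] == fam).to_numpy(float))
    X = np.column_stack(cols)
    if ridge > 0 or fams:
        model = sm.OLS(y, X).fit_regularized(alpha=max(ridge, 1e-6), L1_wt=0.0)
    else:
        model = sm.OLS(y, X).fit()
    p = np.asarray(model.params)
    effects = {}
    if fams:
        effects = {fams[0]: 0.0}
        effects.update({fam: float(c) for fam, c in zip(fams[1:], p[6:])})
    return AllocationModel(
        intercept=float(p[0]),
        b_logarea=float(p[1]),
        b_ni=float(p[2]),
        b_share=float(p[3]),
        b_logarea_ni=float(p[4]),
        b_ni_share=float(p[5]),
        family_effects=effects,
    )
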