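"""Weighted literature priors for vital rates.

Published estimates for a parameter are pooled across the focal species'
taxonomic family, replicated by relatedness (20x same species, 5x same genus,
1x same family), and a parametric distribution is fitted to the expanded
sample by maximum likelihood:

* rate parameters (s0..s3, b, h, f, d1..d3) -> normal on the logit scale;
* integer parameters (e, AFR)               -> Poisson (AFR shifted by 1 so
  the support starts at 1);
* positive continuous (dispersal distance delta, nest density eta)
                                            -> log-normal.

Data-rich taxa thus get sharp priors and data-poor taxa diffuse ones, from
the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mpva.demography import InvalidParameterError

__all__ = [
    "RATE_PARAMETERS",
    "COUNT_PARAMETERS",
    "POSITIVE_PARAMETERS",
    "LiteratureRecord",
    "PriorDistribution",
    "DataDeficientError",
    "weight_records",
    "fit_prior",
    "sample_prior",
    "fit_all_priors",
    "records_from_frame",
]

RATE_PARAMETERS = frozenset({"s0", "s1", "s2", "s3", "b", "h", "f", "d1", "d2", "d3"})
COUNT_PARAMETERS = frozenset({"e", "AFR"})
POSITIVE_PARAMETERS = frozenset({"delta", "eta"})

RATE_CLIP = (0.001, 0.999)  # before logit; 0/1 observations are clipped in
MIN_LOGIT_SIGMA = 0.05  # floor so degenerate samples still give a proper prior

# Replication factors by taxonomic relatedness to the focal species.
WEIGHTS = {"species": 20, "genus": 5, "family": 1}


class DataDeficientError(ValueError):
    """No in-family literature records for a parameter."""


@dataclass(frozen=True)
class LiteratureRecord:
    """One published estimate of one vital-rate parameter."""

    parameter: str
    value: float
    se: float | None = None
    species: str = ""
    genus: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        p, v = self.parameter, self.value
        if p in RATE_PARAMETERS and not (0.0 < v < 1.0):
            raise InvalidParameterError(f"{p}={v!r} must lie in (0, 1)")
        if p in COUNT_PARAMETERS and v <= 0:
            raise InvalidParameterError(f"{p}={v!r} must be positive")
        if p in POSITIVE_PARAMETERS and v <= 0:
            raise InvalidParameterError(f"{p}={v!r} must be positive")
        if p not in RATE_PARAMETERS | COUNT_PARAMETERS | POSITIVE_PARAMETERS:
            raise InvalidParameterError(f"unknown parameter {p!r}")


@dataclass(frozen=True)
class PriorDistribution:
    """A fitted prior: logit-normal, shifted Poisson, or log-normal."""

    family: str  # "logit-normal" | "poisson" | "log-normal"
    loc: float  # mean of logit/log values, or Poisson rate
    scale: float  # SD on the transformed scale (0 for poisson)
    n_effective: int
    parameter: str = ""
    shift: int = 0  # support offset for shifted Poisson (AFR uses 1)

    def mean(self) -> float:
        """Mean on the natural scale (logit-normal mean by quadrature)."""
        if self.family == "poisson":
            return self.loc + self.shift
        if self.family == "log-normal":
            return math.exp(self.loc + self.scale**2 / 2.0)
        x, w = np.polynomial.hermite_e.hermegauss(41)
        vals = 1.0 / (1.0 + np.exp(-(self.loc + self.scale * x)))
        return float((w * vals).sum() / w.sum())


def weight_records(
    records: Iterable[LiteratureRecord],
    focal: tuple[str, str, str],
) -> list[LiteratureRecord]:
    """Filter to the focal family and replicate by taxonomic relatedness.

    Records from the focal species are replicated 20x, same genus (different
    species) 5x, same family (different genus) 1x; other families are dropped.
    """
    sp, genus, family = focal
    expanded: list[LiteratureRecord] = []
    for r in records:
        if r.family != family:
            continue
        if r.species == sp:
            reps = WEIGHTS["species"]
        elif r.genus == genus:
            reps = WEIGHTS["genus"]
        else:
            reps = WEIGHTS["family"]
        expanded.extend([r] * reps)
    if not expanded:
        raise DataDeficientError(
            f"no literature records within family {family!r}; supply family-level defaults"
        )
    return expanded


def fit_prior(values: Sequence[float], parameter: str) -> PriorDistribution:
    """MLE fit of the parameter's prior family to an expanded value sample."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 1:
        raise DataDeficientError(f"no values to fit for {parameter!r}")
    n = int(vals.size)
    if parameter in RATE_PARAMETERS:
        clipped = np.clip(vals, *RATE_CLIP)
        rejected = np.sum((vals <= 0) | (vals >= 1))
        if rejected:
            raise InvalidParameterError(
                f"{int(rejected)} value(s) outside (0,1) for rate parameter {parameter!r}"
            )
        z = np.log(clipped / (1.0 - clipped))
        sigma = float(z.std(ddof=0))  # normal MLE uses 1/n
        return PriorDistribution(
            "logit-normal", float(z.mean()), max(sigma, MIN_LOGIT_SIGMA), n, parameter
        )
    if parameter in COUNT_PARAMETERS:
        shift = 1 if parameter == "AFR" else 0
        shifted = vals - shift
        if (shifted < 0).any():
            raise InvalidParameterError(f"{parameter!r} values below support after shift")
        return PriorDistribution("poisson", float(shifted.mean()), 0.0, n, parameter, shift)
    if parameter in POSITIVE_PARAMETERS:
        if (vals <= 0).any():
            raise InvalidParameterError(f"{parameter!r} values must be positive")
        z = np.log(vals)
        sigma = float(z.std(ddof=0))
        return PriorDistribution(
            "log-normal", float(z.mean()), max(sigma, MIN_LOGIT_SIGMA), n, parameter
        )
    raise InvalidParameterError(f"unknown parameter {parameter!r}")


def sample_prior(
    dist: PriorDistribution, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Seeded draws on the natural scale (rates in (0,1); counts >= shift)."""
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if dist.family == "logit-normal":
        z = rng.normal(dist.loc, dist.scale, size=n)
        return 1.0 / (1.0 + np.exp(-z))
    if dist.family == "poisson":
        return rng.poisson(dist.loc, size=n) + dist.shift
    if dist.family == "log-normal":
        return np.exp(rng.normal(dist.loc, dist.scale, size=n))
    raise InvalidParameterError(f"unknown prior family {dist.family!r}")


def records_from_frame(frame: pd.DataFrame) -> list[LiteratureRecord]:
    """Parse a literature table (parameter, value, se, species, genus, family)."""
    out = []
    for row in frame.itertuples(index=False):
        se = getattr(row, "se", None)
        se = None if se is None or (isinstance(se, float) and math.isnan(se)) else float(se)
        out.append(
            LiteratureRecord(
                parameter=str(row.parameter),
                value=float(row.value),
                se=se,
                species=str(row.species),
                genus=str(row.genus),
                family=str(row.family),
            )
        )
    return out


def fit_all_priors(
    records: Iterable[LiteratureRecord],
    focal: tuple[str, str, str],
) -> dict[str, PriorDistribution]:
    """Weight, pool, and fit priors for every parameter present in ``records``."""
    expanded = weight_records(records, focal)
    by_param: dict[str, list[float]] = {}
    for r in expanded:
        by_param.setdefault(r.parameter, []).append(r.value)
    return {p: fit_prior(vals, p) for p, vals in by_param.items()}
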