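"""Stochastic forward projection and quasi-extinction risk.

Two nested replication loops drive the risk assessment: an outer loop draws
one joint parameter vector per replicate from the posterior (parameter
uncertainty), and an inner loop runs repeated 100-year simulations under that
vector (environmental and demographic stochasticity).  Each year the model

1. applies invasive hazards per the active scenario,
2. applies density-dependent fledging per colony,
3. perturbs vital rates with spatially and temporally autocorrelated
   logit-scale environmental deviates,
4. rebuilds per-colony matrices and the dispersal-linked metapopulation
   matrix, and projects one step,
5. below a colony abundance threshold, replaces expected survival with beta
   draws of variance p(1-p)/n (demographic stochasticity).

Trajectories that drop below the quasi-extinction threshold (QE) are
absorbed at zero.  The per-outer-replicate outputs are a point estimate of
projected abundance (terminal-year median over inner runs) and the
quasi-extinction probability (fraction of inner runs ever below QE);
summaries report the median, standard error and inter-quartile range across
outer replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.stats import beta as beta_dist

from mpva.demography import (
    DensityDependence,
    InvalidParameterError,
    VitalRates,
    build_matrix,
    density_dependent_fledging,
    stable_stage_distribution,
)
from mpva.hazards import (
    INVASIVE_CATEGORIES,
    HazardParameters,
    InvasiveAssemblage,
    adult_cumulative_hazard,
    apply_hazards,
    chick_log_hazard,
    sample_delta,
)
from mpva.metapopulation import (
    ColonyGeometry,
    DispersalSpec,
    assemble,
    block_diagonal,
    build_connectivity,
)

__all__ = [
    "StochasticityConfig",
    "Scenario",
    "IslandColony",
    "SpeciesConfig",
    "SimulationParams",
    "SimulationResult",
    "spatial_correlation",
    "generate_env_deviates",
    "demographic_survival_draw",
    "initialize",
    "run_inner",
    "run_full",
    "compute_qep",
    "select_qe_threshold",
]

# Vital-rate slots perturbed by environmental stochasticity; fledging gets its
# larger default SD, everything else the common smaller one.
PERTURBED_RATES = ("s0", "s1", "s2", "s3", "b", "h", "f")


@dataclass(frozen=True)
class StochasticityConfig:
    """Environmental/demographic stochasticity settings.

    ``sigma_f`` is the logit-scale SD of annual deviations in fledging
    success (default 1.0); ``sigma_other`` applies to every other perturbed
    rate (default 0.5).  Deviations are perfectly correlated across rates
    within a colony-year, share lag-1 temporal autocorrelation
    ``temporal_r`` (default 0.67), and are spatially correlated so colonies
    100 km apart have R=0.9 and 1000 km apart R=0.5.  Demographic
    stochasticity (beta survival draws) switches on below
    ``demographic_threshold`` females at a colony.
    """

    sigma_f: float = 1.0
    sigma_other: float = 0.5
    temporal_r: float = 0.67
    anchor_near: tuple[float, float] = (100.0, 0.9)
    anchor_far: tuple[float, float] = (1000.0, 0.5)
    demographic_threshold: float = 100.0
    qe_absorbing: bool = True

    def __post_init__(self) -> None:
        if self.sigma_f < 0 or self.sigma_other < 0:
            raise InvalidParameterError("sigma values must be >= 0")
        if not (-1.0 < self.temporal_r < 1.0):
            raise InvalidParameterError("temporal_r must lie in (-1, 1)")
        if self.demographic_threshold < 0:
            raise InvalidParameterError("demographic_threshold must be >= 0")

    def sigma_for(self, rate: str) -> float:
        return self.sigma_f if rate == "f" else self.sigma_other


@dataclass(frozen=True)
class Scenario:
    """A management scenario.

    kinds: "default", "invasive_removal" (clear ``islands`` of invasives from
    ``start_year``), "at_sea_mitigation" (log-hazard reduction
    ``at_sea_offset`` on sub-adult and adult survival), "reintroduction" /
    "translocation" (activate colony ``target_island`` at ``start_year`` with
    ``founders`` females per stage and carrying capacity ``target_K``;
    translocation removes the founders proportionally from source colonies).
    """

    kind: str = "default"
    islands: tuple[str, ...] = ()
    start_year: int = 0
    at_sea_offset: float = 0.0
    target_island: str | None = None
    founders: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_K: float = 0.0

    def __post_init__(self) -> None:
        kinds = ("default", "invasive_removal", "at_sea_mitigation", "reintroduction", "translocation")
        if self.kind not in kinds:
            raise InvalidParameterError(f"unknown scenario kind {self.kind!r}; valid: {kinds}")
        if self.kind == "at_sea_mitigation" and self.at_sea_offset < 0:
            raise InvalidParameterError("at_sea_offset must be >= 0")
        if self.kind in ("reintroduction", "translocation") and self.target_island is None:
            raise InvalidParameterError(f"{self.kind} requires target_island")


@dataclass(frozen=True)
class IslandColony:
    """One breeding island: area, capacity, invasives, starting abundance."""

    island_id: str
    area_km2: float
    K: float
    assemblage: InvasiveAssemblage
    init_females: float | None = None  # total females (all stages)
    init_pairs: float | None = None  # breeding pairs (= breeding females)
    active: bool = True  # False for potential (re)introduction sites

    def __post_init__(self) -> None:
        if self.area_km2 <= 0:
            raise InvalidParameterError("area_km2 must be > 0")
        if self.K < 0:
            raise InvalidParameterError("K must be >= 0")


@dataclass(frozen=True)
class SpeciesConfig:
    """Species-level structure shared across posterior draws."""

    islands: tuple[IslandColony, ...]
    geometry: ColonyGeometry
    dispersal: DispersalSpec
    nesting_type: str = "surface"
    adult_size: float = 1.0
    afr: int = 4
    theta: float = 7.5
    qe_override: float | None = None

    def __post_init__(self) -> None:
        if self.geometry.k != len(self.islands):
            raise InvalidParameterError("geometry size must match number of islands")


@dataclass(frozen=True)
class SimulationParams:
    """One joint parameter vector for the inner loop."""

    vitals: VitalRates
    hazard_params: HazardParameters | None
    config: SpeciesConfig


@dataclass
class SimulationResult:
    """Outer-loop distributions of projected abundance and QE probability."""

    n_proj: np.ndarray  # (NS1,) terminal-abundance point estimates
    qep: np.ndarray  # (NS1,) quasi-extinction probabilities
    qe_threshold: float
    summaries: dict[str, float]
    sample_trajectories: np.ndarray | None = None  # (n, years+1) total females


# ----------------------------------------------------------------------
# Stochasticity machinery


def spatial_correlation(
    distances: np.ndarray,
    anchor_near: tuple[float, float] = (100.0, 0.9),
    anchor_far: tuple[float, float] = (1000.0, 0.5),
) -> np.ndarray:
    """Cross-colony correlation of annual deviates.

    Stretched-exponential decay R(d) = exp(-(d/rho)^c) with (c, rho) solved
    so both anchors hold exactly; projected to the nearest PSD matrix if the
    geometry demands it.
    """
    d_near, r_near = anchor_near
    d_far, r_far = anchor_far
    c = math.log(math.log(r_far) / math.log(r_near)) / math.log(d_far / d_near)
    rho = d_near / (-math.log(r_near)) ** (1.0 / c)
    d = np.asarray(distances, dtype=float)
    R = np.exp(-((d / rho) ** c))
    np.fill_diagonal(R, 1.0)
    vals = np.linalg.eigvalsh(R)
    if vals.min() < -1e-10:
        w, V = np.linalg.eigh(R)
        R = (V * np.clip(w, 0.0, None)) @ V.T
        sd = np.sqrt(np.diag(R))
        R = R / np.outer(sd, sd)
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise InvalidParameterError("spatial correlation matrix not PSD after projection")
    return R


def _correlation_factor(R: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(R)
        return V * np.sqrt(np.clip(w, 0.0, None))


def generate_env_deviates(
    n_years: int,
    k: int,
    cfg: StochasticityConfig,
    distances: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
    burn: int = 50,
) -> np.ndarray:
    """Standardized environmental deviate field of shape (n_years, k).

    Unit marginal SD, lag-1 autocorrelation ``cfg.temporal_r``, cross-colony
    correlation from ``spatial_correlation``.  Spatially correlated
    innovations are drawn first, each colony's series is then passed through
    the AR(1) filter, and the output is rescaled to unit marginal variance
    (a burn-in prefix removes the filter transient).  Rate-specific deviates
    are this field scaled by sigma_for(rate), making deviations perfectly
    correlated across rates within a colony-year.
    """
    if n_years < 1:
        raise InvalidParameterError("n_years must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if k > 1 and distances is not None:
        L = _correlation_factor(spatial_correlation(distances, cfg.anchor_near, cfg.anchor_far))
    else:
        L = np.eye(k)
    eps = rng.standard_normal((n_years + burn, k)) @ L.T
    r = cfg.temporal_r
    x = lfilter([1.0], [1.0, -r], eps, axis=0)[burn:]
    return x * math.sqrt(1.0 - r * r)


def demographic_survival_draw(
    p: float,
    n: int,
    seed: int | np.random.Generator = 0,
    u: float | None = None,
) -> float:
    """Beta draw of a realized survival rate at a small colony.

    Mean p, variance p(1-p)/n via method-of-moments shapes a = p(n-1),
    b = (1-p)(n-1).  At n=1 the beta variance cannot reach p(1-p), so a
    Bernoulli-consistent draw (0 or 1 with probability p) is returned.
    ``u`` supplies an externally drawn uniform quantile so that common
    random numbers can be shared across scenarios.
    """
    if not (0.0 < p < 1.0):
        return float(min(1.0, max(0.0, p)))
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if u is None:
        u = float(rng.random())
    if n == 1:
        return 1.0 if u < p else 0.0
    a = p * (n - 1)
    b = (1.0 - p) * (n - 1)
    return float(beta_dist.ppf(u, a, b))


# ----------------------------------------------------------------------
# Initialization


def initialize(
    islands: tuple[IslandColony, ...] | list[IslandColony],
    vitals: VitalRates,
    allocation: np.ndarray | None = None,
    species_total: float | None = None,
) -> np.ndarray:
    """Initial stacked stage vector (females) from abundance information.

    Per-island totals are halved (females) and spread by the stable stage
    distribution; per-island breeding-pair counts set the breeding-adult
    stage directly with the other stages scaled by SSD ratios; a species
    total is halved then partitioned by ``allocation`` proportions and spread
    by SSD.  Inactive islands start at zero.
    """
    A = build_matrix(vitals)
    ssd = stable_stage_distribution(A)
    k = len(islands)
    n0 = np.zeros(3 * k)
    if species_total is not None:
        if allocation is None:
            raise InvalidParameterError("species_total requires allocation proportions")
        females = np.asarray(allocation, float) * (species_total / 2.0)
        for i, isl in enumerate(islands):
            if isl.active:
                n0[3 * i : 3 * i + 3] = females[i] * ssd
        return n0
    for i, isl in enumerate(islands):
        if not isl.active:
            continue
        if isl.init_pairs is not None:
            if ssd[1] <= 0:
                raise InvalidParameterError("SSD has no breeding adults; cannot scale pairs")
            n0[3 * i : 3 * i + 3] = isl.init_pairs * ssd / ssd[1]
        elif isl.init_females is not None:
            n0[3 * i : 3 * i + 3] = (isl.init_females / 2.0) * ssd
        else:
            raise InvalidParameterError(f"island {isl.island_id!r} has no abundance information")
    return n0


def select_qe_threshold(initial_pairs: float) -> float:
    """QE = 50 females above 200 initial breeding pairs, 10 females otherwise."""
    return 50.0 if initial_pairs > 200 else 10.0


# ----------------------------------------------------------------------
# Inner loop


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


def _inv_logit(z: float) -> float:
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


def _perturb(rate: float, sigma: float, eps: float) -> float:
    if sigma == 0.0 or eps == 0.0 or rate <= 0.0 or rate >= 1.0:
        return rate
    return _inv_logit(_logit(rate) + sigma * eps)


def run_inner(
    params: SimulationParams,
    init_vector: np.ndarray,
    scenario: Scenario = Scenario(),
    years: int = 100,
    cfg: StochasticityConfig = StochasticityConfig(),
    seed: int | np.random.Generator = 0,
    qe_threshold: float = 0.0,
) -> np.ndarray:
    """Simulate one stochastic trajectory; returns (years+1, k, 3) females."""
    sc = params.config
    islands = sc.islands
    k = len(islands)
    n = np.asarray(init_vector, dtype=float).copy()
    if n.shape != (3 * k,):
        raise InvalidParameterError(f"init_vector must have length {3 * k}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    active = np.array([isl.active for isl in islands], dtype=bool)
    K = np.array([isl.K for isl in islands], dtype=float)
    assemblages: list[InvasiveAssemblage] = [isl.assemblage for isl in islands]
    idx_by_id = {isl.island_id: i for i, isl in enumerate(islands)}

    eps = generate_env_deviates(years, k, cfg, sc.geometry.distances, rng)
    # Pre-drawn uniforms keep demographic draws aligned across scenarios
    # under common random numbers: (year, island, stage incl. fledgling).
    demo_u = rng.random((years, k, 4))

    traj = np.zeros((years + 1, k, 3))
    traj[0] = n.reshape(k, 3)
    v0 = params.vitals
    hp = params.hazard_params
    dd_theta = sc.theta
    lam_warm = [1.0 for _ in range(k)]
    extinct = False

    for t in range(years):
        if extinct:
            break
        # Scenario events.
        if scenario.kind in ("reintroduction", "translocation") and t == scenario.start_year:
            j = idx_by_id[scenario.target_island]
            active[j] = True
            K[j] = scenario.target_K if scenario.target_K > 0 else K[j]
            founders = np.asarray(scenario.founders, float)
            if scenario.kind == "translocation":
                total = n.sum()
                if total > 0:
                    take = min(founders.sum(), total)
                    n -= n * (take / total)
            n[3 * j : 3 * j + 3] += founders

        mats = []
        for i, isl in enumerate(islands):
            if not active[i]:
                mats.append(np.zeros((3, 3)))
                continue
            asm = assemblages[i]
            if (
                scenario.kind == "invasive_removal"
                and t >= scenario.start_year
                and (not scenario.islands or isl.island_id in scenario.islands)
            ):
                asm = InvasiveAssemblage([], isl.area_km2)
            Ni = n[3 * i : 3 * i + 3].sum()
            # Density-dependent fledging before hazards and noise.
            f_i = density_dependent_fledging(
                v0.f, Ni, DensityDependence(theta=dd_theta, K=max(K[i], 1e-9))
            ) if K[i] > 0 else v0.f
            e_t = eps[t, i]
            s = {
                name: _perturb(getattr(v0, name), cfg.sigma_for(name), e_t)
                for name in ("s0", "s1", "s2", "s3", "b", "h")
            }
            f_i = _perturb(f_i, cfg.sigma_for("f"), e_t)
            if scenario.kind == "at_sea_mitigation" and t >= scenario.start_year:
                boost = math.exp(-scenario.at_sea_offset)
                for name in ("s1", "s2", "s3"):
                    s[name] = s[name] ** boost
            if hp is not None and asm.Xi > 0:
                gf = chick_log_hazard(asm, hp)
                gs = adult_cumulative_hazard(asm, hp)
                f_i, s["s2"] = apply_hazards(f_i, s["s2"], gf, gs)
            # Demographic stochasticity below the colony threshold.
            if 0 < Ni < cfg.demographic_threshold:
                stage_n = n[3 * i : 3 * i + 3]
                chicks = stage_n[1] * v0.b * (v0.e / 2.0) * v0.h * v0.f
                pool = (chicks, stage_n[0], stage_n[1], stage_n[2])
                for j, name in enumerate(("s0", "s1", "s2", "s3")):
                    m = max(1, int(round(pool[j])))
                    if 0.0 < s[name] < 1.0:
                        s[name] = demographic_survival_draw(s[name], m, rng, u=demo_u[t, i, j])
            vit = v0.with_rates(f=f_i, **s)
            try:
                A = build_matrix(vit, lam0=lam_warm[i])
                lam_warm[i] = max(A.lam, 0.1)
            except Exception as err:  # pragma: no cover - diagnostic path
                raise RuntimeError(f"matrix build failed at year {t}, island {i}: {err}")
            mats.append(np.asarray(A))

        C = block_diagonal(mats)
        n_active = int(active.sum())
        if n_active >= 2 and (sc.dispersal.d1 or sc.dispersal.d2 or sc.dispersal.d3):
            act = np.where(active)[0]
            sub_geom = ColonyGeometry(sc.geometry.distances[np.ix_(act, act)])
            ip = build_connectivity(sub_geom, sc.dispersal.delta)
            rows = np.concatenate([np.arange(3 * a, 3 * a + 3) for a in act])
            C_sub = C[np.ix_(rows, rows)]
            M_sub = assemble(C_sub, sc.dispersal, ip)
            n_sub = n[rows]
            n_new = n.copy()
            n_new[rows] = M_sub @ n_sub
            n = n_new
        else:
            n = C @ n
        if not np.isfinite(n).all():
            raise OverflowError(f"numeric overflow in projection at year {t}")
        total = n.sum()
        if cfg.qe_absorbing and qe_threshold > 0 and total < qe_threshold:
            n[:] = 0.0
            extinct = True
        traj[t + 1] = n.reshape(k, 3)
    return traj


# ----------------------------------------------------------------------
# Outer loop


def params_from_draw(
    row, config: SpeciesConfig, rng: np.random.Generator | None = None
) -> SimulationParams:
    """Build a SimulationParams from one posterior draw (a mapping of names).

    Expects vital-rate columns s0..s3, b, e, h, f (AFR optional) and, when
    hazards are in play, phi/psi/beta1/beta2 plus delta_<category> columns;
    categories present on islands but absent from the draw are imputed from
    the hierarchical hyper-parameters (delta_bar, sigma_delta).
    """
    vit = VitalRates(
        s0=float(row["s0"]), s1=float(row["s1"]), s2=float(row["s2"]), s3=float(row["s3"]),
        b=float(row["b"]), e=float(row["e"]), h=float(row["h"]), f=float(row["f"]),
        afr=int(row["AFR"]) if "AFR" in row else config.afr,
    )
    needed = sorted({cat for isl in config.islands for cat, _ in isl.assemblage.members})
    hp = None
    if needed and "phi" in row:
        rng = rng or np.random.default_rng(0)
        delta = {}
        for cat in INVASIVE_CATEGORIES:
            col = f"delta_{cat}"
            if col in row:
                delta[(config.nesting_type, cat)] = float(row[col])
            elif cat in needed:
                delta[(config.nesting_type, cat)] = float(
                    sample_delta(rng, float(row["delta_bar"]), float(row["sigma_delta"]))[0]
                )
        hp = HazardParameters(
            delta=delta,
            nesting_type=config.nesting_type,
            phi=float(row["phi"]),
            psi=float(row["psi"]),
            beta1=float(row["beta1"]),
            beta2=float(row["beta2"]),
            adult_size=config.adult_size,
            delta_bar=float(row.get("delta_bar", 1.2)),
            sigma_delta=float(row.get("sigma_delta", 0.2)),
        )
    return SimulationParams(vitals=vit, hazard_params=hp, config=config)


def compute_qep(trajectories: np.ndarray, qe: float) -> float:
    """Fraction of runs whose total female abundance ever drops below QE.

    ``trajectories`` is (n_runs, years+1) of metapopulation totals; the
    initial year counts (a population already below QE is quasi-extinct)."""
    totals = np.asarray(trajectories, dtype=float)
    if totals.ndim != 2:
        raise InvalidParameterError("trajectories must be (n_runs, years+1)")
    return float((totals.min(axis=1) < qe).mean())


def run_full(
    posteriors,
    species_config: SpeciesConfig,
    scenario: Scenario = Scenario(),
    ns1: int = 100,
    ns2: int = 100,
    years: int = 100,
    cfg: StochasticityConfig = StochasticityConfig(),
    seed: int = 0,
    keep_trajectories: int = 0,
) -> SimulationResult:
    """Full two-loop risk projection.

    ``posteriors`` is a PosteriorDraws or a DataFrame of joint samples.  Each
    outer replicate draws one parameter row, initializes the metapopulation,
    and runs ``ns2`` inner stochastic simulations; the inner distribution
    gives that replicate's N_proj (terminal-year median) and QEP.  Random
    streams are derived so that two scenarios run with the same master seed
    share environmental and demographic randomness replicate for replicate.
    """
    samples = posteriors.samples if hasattr(posteriors, "samples") else posteriors
    if len(samples) == 0:
        raise InvalidParameterError("posterior sample set is empty")
    master = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(master.spawn(1)[0])
    n_proj = np.zeros(ns1)
    qep = np.zeros(ns1)
    kept = []
    qe_used = species_config.qe_override or 0.0
    for o in range(ns1):
        row = samples.iloc[int(draw_rng.integers(len(samples)))]
        params = params_from_draw(row, species_config, draw_rng)
        init = initialize(species_config.islands, params.vitals)
        pairs = init.reshape(-1, 3)[:, 1].sum()
        qe = species_config.qe_override or select_qe_threshold(pairs)
        qe_used = qe
        totals = np.zeros((ns2, years + 1))
        finals = np.zeros(ns2)
        # Seeds keyed by (outer, inner) position only, for common random numbers.
        inner_ss = np.random.SeedSequence((seed, o)).spawn(ns2)
        for r in range(ns2):
            traj = run_inner(
                params, init, scenario, years, cfg,
                np.random.default_rng(inner_ss[r]), qe_threshold=qe,
            )
            tot = traj.sum(axis=(1, 2))
            totals[r] = tot
            finals[r] = tot[-1]
            if len(kept) < keep_trajectories:
                kept.append(tot)
        n_proj[o] = float(np.median(finals))
        qep[o] = compute_qep(totals, qe)
    summaries = {
        "n_proj_median": float(np.median(n_proj)),
        "n_proj_se": float(n_proj.std(ddof=1) / math.sqrt(ns1)) if ns1 > 1 else 0.0,
        "n_proj_iqr_low": float(np.percentile(n_proj, 25)),
        "n_proj_iqr_high": float(np.percentile(n_proj, 75)),
        "qep_median": float(np.median(qep)),
        "qep_se": float(qep.std(ddof=1) / math.sqrt(ns1)) if ns1 > 1 else 0.0,
        "qep_iqr_low": float(np.percentile(qep, 25)),
        "qep_iqr_high": float(np.percentile(qep, 75)),
    }
    return SimulationResult(
        n_proj=n_proj,
        qep=qep,
        qe_threshold=qe_used,
        summaries=summaries,
        sample_trajectories=np.array(kept) if kept else None,
    )
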