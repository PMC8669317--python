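# Methods

`mpva` projects the abundance of island-breeding seabird metapopulations and
estimates quasi-extinction risk under management scenarios. This note
documents the model, the fitting machinery, the synthetic-data generator used
for calibration, and the numerical and design choices a maintainer should
know about.

## Demographic core

Females are tracked in three stages — sub-adult, breeding adult, non-breeding
adult — under a pre-breeding census (the youngest tracked class has already
survived its first winter). The annual projection matrix is

```
A = [ s1(1-g)   (e/2)·h·f·s0   0        ]
    [ s1·g      s2·b           s3·b     ]
    [ 0         s2(1-b)        s3(1-b)  ]
```

with survival probabilities `s0..s3` (first winter, sub-adult, breeding
adult, non-breeding adult), breeding probability `b`, eggs per pair `e`
(halved for the female-only model), hatching success `h`, and fledging
success `f`. The fecundity element deliberately excludes `b`, matching the
matrix as specified; the sensitivity of results to that reading is small
because `b` still gates the flow between adult stages.

The growth transition `g` collapses a fixed-duration sub-adult stage of
`T = AFR - 1` years (recruitment at age 1, first breeding at the age of
first reproduction; the offset is configurable via
`VitalRates.stage_duration`). `g` uses the standard fixed-stage-duration
form `g = (r^T - r^{T-1}) / (r^T - 1)` with `r = s1/λ`, which requires λ —
itself the dominant eigenvalue of `A` — so (λ, g) is solved by fixed-point
iteration. We iterate to `|Δλ| < 1e-6` (maximum 500 iterations) for
reproducibility; the looser 2-decimal rule is available through the `tol`
argument. The fixed point agrees with an age-classified expansion of the
sub-adult stage to ~1e-8, which the test suite checks against an independent
Leslie-matrix oracle, and is insensitive to the starting λ (checked from
0.5, 1.0, 1.5). At `r → 1` the analytic limit `g = 1/T` is used; the
crossover is continuous to 1e-5.

Density dependence acts on fledging only (the vital rate with low
elasticity, where regulation is typically observed in colonial seabirds):
`f_dd = f / (1 + (N/K)^θ)`. The shape exponent θ defaults to 7.5, the
midpoint of the sensible 5–10 range; any θ in that range leaves fledging
essentially untouched below ~2/3 of K and halves it exactly at `N = K`.

## Metapopulation assembly

Per-colony matrices stack block-diagonally into `C` (island-major). A
diagonal matrix `D` holds per-stage emigration probabilities `d1..d3`, and a
connectivity matrix `IP` routes emigrants: off-diagonal entries decay
exponentially with great-circle distance (mean dispersal distance δ),
rescaled so each column's off-diagonal entries sum to 1, with the diagonal
fixed at −1. The metapopulation matrix is `M = (IP ⊗ D)·C + C`, whose
diagonal blocks are `(I−D)·A_i` (stayers) and whose (j,i) block is
`p_ij·D·A_i` (movers). The −1 diagonal makes emigrant subtraction fall out
of the Kronecker product, so column sums of `M` equal those of `C` exactly:
dispersal redistributes individuals without creating or destroying them
(asserted to 1e-10 on random systems). Dispersal applies to post-demography
abundances (survive/transition, then move), and dispersers incur no extra
mortality. A single colony bypasses connectivity entirely (`M := C`).

## Invasive-species hazards

Invasive taxa are classified into five categories (bird, carnivore,
herbivore, omnivore, rat); hazard ratios `Δ_x > 1` on egg/chick mortality
are keyed by seabird nesting type × invasive category rather than by species
pair, keeping the parameter count manageable. The cumulative log hazard on
fledging at island i is

```
γ_f = [Σ_x log Δ_x] · (1/X_i)^φ · (1/Area_i)^ψ
```

where `X_i` counts the invasives present. φ ∈ [0,1] interpolates between
purely additive mortality (φ=0, hazards sum) and purely compensatory (φ=1,
two identical invasives no worse than one); ψ ≥ 0 dilutes per-capita impacts
on larger islands (area in km², floored at 0.01 km² so islets cannot amplify
the hazard without bound). Adult-survival hazards use the same sum-then-scale
structure (with the same φ and ψ) over per-member terms
`log Ω_x = ζ_x·β1·log(Δ_x)/(1/AdSz + 1)^β2`, where the binary switch ζ_x
defaults to 0 for herbivores and birds and 1 for carnivores, omnivores and
rats (overridable per species), and AdSz is adult body mass in kg — larger
birds are less exposed for β2 > 0.

Hazards transform survival-type rates through the proportional-hazards
identity `S' = S^{exp(γ)}`, i.e. the cumulative mortality hazard `-log S`
scales by the hazard ratio. This is the only reading under which
independent hazards are additive in log form, and it keeps `S'` in (0,1]
for any γ ≥ 0.

Hierarchically, `Δ_x ~ N(Δ̄, σ_Δ)` truncated at 1 — an invasive species is
never allowed to *reduce* chick mortality. A log-scale variant of the
hierarchy is available behind a flag.

## Literature priors

Published vital-rate estimates are pooled within the focal species' family
and replicated by relatedness — 20× same species, 5× same genus, 1× same
family — before a maximum-likelihood fit of the prior: normal on the logit
scale for rates (values clipped to [0.001, 0.999] first), Poisson for the
integer parameters (`AFR` is fitted on `AFR − 1` so the support respects
`AFR ≥ 1`), log-normal for dispersal distance and nest density. A floor of
0.05 on the transformed-scale SD keeps degenerate samples proper. Reported
standard errors are carried but unused by default (the fit is to point
estimates); a precision-weighted variant exists as a clearly flagged
extension. Data-rich species get sharp priors and data-poor species diffuse
ones from the same machinery; a family with zero records raises a
data-deficient error rather than guessing.

## Carrying capacity

Range-wide female K multiplies suitable nesting area by maximum nest
density: `K = AoO* × η`, with `AoO*` scaling the Area of Occupancy by a
fitted usable proportion (logit-linear in log body mass with family
offsets). Total K is split among islands by a logit-linear allocation model
(log area, number of islands, relative area share, and their interactions;
family offsets as ridge-penalized fixed effects — full mixed-model machinery
would be out of proportion to the role this sub-model plays). Each island's
K is floored at twice its current abundance; the floor is enforced by
water-filling (pin violators, re-split the remainder, repeat), and if the
floors alone exceed total K the floors win and the total is raised with a
warning.

## Bayesian fitting

Two fitting problems share one sampler.

**State-space fit of invasive impacts.** Observed survey counts `O_{i,t}`
at islands with differing invasive assemblages (including eradication
events) are Poisson around a latent female total `N_{i,t}` that follows the
deterministic hazard-adjusted stage projection — density dependence and
dispersal are excluded here, and there is no process noise in the latent
dynamics. Fitted parameters: the baseline vitals (literature priors; the
Poisson prior on `e` is evaluated through its continuous gamma-function
extension; `AFR` is held fixed at the prior's rounded mean because integer
moves destabilize the adaptive proposal), the hazard shapes φ, ψ, β1, β2,
the `Δ_x` set with hyper-parameters `(Δ̄, σ_Δ)`, and each island's initial
abundance.

Priors for the hazard block are weakly informative rather than nominally
flat: `φ ~ U(0,1)`, `ψ ~ half-N(0,2)`, `β1, β2 ~ N(0,2)`,
`log(Δ̄−1) ~ N(0,1.5)`, `σ_Δ ~ half-N(0,1)`, and log-uniform initial
abundances on `[1, 10·max(O)]`. Two of these deserve comment. First, the
hyper-mean Δ̄ is constrained above the truncation point of the Δ_x
hierarchy: if Δ̄ is allowed to wander below 1 on a very diffuse scale, the
induced prior on Δ_x piles up against the boundary (its density falls about
threefold across (1,2)) and systematically attenuates the hazard estimate —
a bias we verified by prior-only simulation and by comparing the profile
likelihood (which peaks at the generating value on synthetic data) with the
distorted marginal posterior. Second, scales of ~2 on exponent-type
parameters still cover any biologically plausible value (an area exponent or
adult-scaling factor beyond ±3 is absurd) without the sampling pathologies
of SD-10 normals.

The sampler is a blocked adaptive Metropolis-within-Gibbs: two random-walk
blocks on transformed scales (vital rates; hazard parameters), each with
Haario-style covariance adaptation toward an acceptance rate of 0.234,
diminishing adaptation continuing after burn-in, and a 5% mixture of wide
proposals at the initial per-parameter scales to escape ridge collapse —
the fecundity product `s0·h·f·e` and the β1–Δ trade-off (chick versus adult
attribution of the same decline) are genuine ridges at this data size.
Initial abundances are Gibbs-sampled exactly: the latent trajectory is
linear in `N_{i,1}`, so its full conditional under the flat-on-log prior is
`Gamma(Σ_t O_t, Σ_t c_t)` with `c_t` the unit-abundance trajectory. The
default configuration is 4 chains × 2000 burn-in + 2000 saved samples
(a full-scale 20 × 5000 + 10000 configuration is one call away);
convergence is summarized by split-R-hat with a 1.1 threshold — exceeding
it warns and flags the draws rather than discarding them, since several
hazard-shape parameters are honestly weakly identified and prior-dominated.

**Trend update.** IUCN-style categorical trends become 100 pseudo-observed
annual growth rates via a fixed weight table over λ ∈ {0.90, …, 1.10}
(weights per status sum to 100; modal λ of 1.02, 1.00, 0.98 for Increasing /
Stable / Decreasing, and a near-flat Unknown column). Pseudo-observations
are modeled as log-normal around the deterministic λ̂ implied by a candidate
vital-rate vector (hazards applied first when the island carries invasives),
with the spread σ_λ fitted jointly (half-N(0,1) prior). Invasive-hazard
parameters are held fixed at their state-space draws rather than
re-estimated — one joint draw per outer simulation replicate carries their
uncertainty forward. 5000 samples are saved by default.

## Stochastic projection

The risk engine runs two nested loops: NS1 = 100 outer replicates each draw
one joint parameter vector from the posterior; NS2 = 100 inner replicates
run the 100-year simulation under that vector. Each simulated year applies,
in order: scenario events → density-dependent fledging (per colony, using
current abundance) → environmental perturbation → at-sea mitigation →
invasive hazards → demographic stochasticity → matrix rebuild and
projection through the dispersal-linked metapopulation matrix.

*Environmental stochasticity* adds zero-centered normal deviates to the
logit of every rate (log scale for `e`), perfectly correlated across rates
within a colony-year but scaled per rate: SD 1.0 for fledging, 0.5 for all
others. Deviates carry lag-1 temporal autocorrelation R = 0.67 and spatial
correlation decaying as a stretched exponential `exp(-(d/ρ)^c)` with (c, ρ)
solved so that colonies 100 km apart have R = 0.9 and 1000 km apart R = 0.5
exactly. Construction order matters for the marginal variance: spatially
correlated innovations (Cholesky factor) are passed through the AR(1)
filter per colony, then rescaled to unit marginal SD, with a 50-year
transient discarded. Monte-Carlo checks at 1e5 samples reproduce all three
anchors within ±0.02.

*Demographic stochasticity* engages when a colony's female total drops
below 100: realized survival is drawn from a Beta with mean `p` and
variance `p(1-p)/n` (method-of-moments shapes; `n` = individuals in the
stage, with the first-winter class sized by expected fledglings). At
`n = 1` the Beta degenerates, so a Bernoulli draw is used. Draws consume
pre-generated uniforms indexed by (year, island, stage) so that scenarios
compared under one master seed share their randomness; recruitment noise
below the threshold exists as an optional extension, off by default.

*Quasi-extinction* uses QE = 50 females for species starting above 200
breeding pairs and 10 females otherwise. Crossing QE is absorbing (a
non-absorbing variant is a flag). Per outer replicate, QEP is the fraction
of inner runs ever below QE and N_proj is the median terminal-year total
(the point-estimate convention; terminal-year was chosen over a horizon
average and is documented here because either reading is defensible).
Summaries report the median, standard error and inter-quartile range of
both across outer replicates.

*Scenarios*: `default` (current threats); `invasive_removal` (listed
islands cleared from a start year); `at_sea_mitigation` (a log-hazard
offset removed from sub-adult and adult survival — the scenario is named
but not parameterized in any source, so this interpretation is ours);
`reintroduction` / `translocation` (a target colony activates at a start
year with specified founders and K, entering the connectivity matrix from
that year; translocation additionally removes the founders proportionally
from existing colonies).

## Synthetic worlds

The `fixtures` module generates every input the toolkit reads — colony
tables with coordinates and areas, literature records, invasive
assemblages, survey counts, trend labels — from a small archipelago with
known parameters, bit-reproducibly per seed. Counts come from the same
generating process the state-space fit assumes (deterministic
hazard-adjusted projection, Poisson observation), which is what makes
parameter recovery a meaningful calibration: the default removal experiment
(two rat-invaded islands eradicated at year 10 of 30, one clean control,
~300 females per island) yields 95% credible intervals that covered the
generating hazard ratio Δ = 1.3 in 20 of 20 seeded replicates when we ran
the calibration experiment in the test suite. Literature records scatter
around the true rates with logit-normal noise (SD 0.3, a typical
between-study spread); record counts per taxonomic level are configurable
to emulate data-rich (5/10/20) versus data-poor (0/1/5) species. Trend
labels derive from the true deterministic λ with thresholds at 1.01/0.99.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: observation error beyond Poisson counting
(real surveys have detection biases and variance inflation), process noise
in the latent dynamics during fitting, model misspecification (the fit and
the generator share one functional form), immigration from outside the
modeled metapopulation, and catastrophes. Recovery results certify internal
consistency of the machinery, not field performance.

## Default problem sizes

The shipped tests and the acceptance script run deliberately compact
configurations chosen to exercise every code path at meaningful
Monte-Carlo precision: 3-island worlds with 30-year series for inference,
20 recovery replicates, NS1 = 20 × NS2 = 50 for scenario contrasts, and
1e5-sample stochasticity calibrations. The full-scale settings (100 × 100
simulation loops, 20-chain MCMC) are plain configuration changes.

## Known limitations

- Single-sex, three-stage structure: no senescence, no two-sex dynamics,
  no age-classified refinement.
- The state-space fit treats latent abundance as continuous and
  deterministic given parameters; environmental noise enters only the
  forward simulations.
- The hazard model shares φ and ψ between chick and adult channels, and β1
  is only weakly identified without strong between-island contrast in
  assemblages — expect prior-dominated posteriors there.
- The allocation GLMM is approximated by penalized logit-linear regression;
  shares are renormalized post hoc rather than modeled multinomially.
- Dispersal is distance-only: no density dependence, directionality, or
  natal philopatry beyond stage-specific rates.
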