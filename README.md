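# mpva — metapopulation viability analysis for island-breeding seabirds

Invasive mammals and birds on breeding islands are the dominant tractable
threat to the world's rarest seabirds, and the case for any given
eradication, translocation, or bycatch-mitigation project is ultimately a
claim about extinction risk. `mpva` is a toolkit for making that claim
quantitatively and *consistently across species*: a stage-structured,
multi-colony population projection model with Bayesian parameterization
designed to work even for data-poor taxa, producing comparable
quasi-extinction probabilities under alternative management scenarios. It is
aimed at conservation scientists and resource managers prioritizing island
restoration portfolios.

## The model

Females are tracked in three stages (sub-adult, breeding adult,
non-breeding adult) under a pre-breeding census. Colony *i* projects
annually by

```
        [ s1(1−g)   (e/2)·h·f·s0   0       ]
A_i  =  [ s1·g      s2·b           s3·b    ]
        [ 0         s2(1−b)        s3(1−b) ]
```

with the sub-adult graduation probability `g` solved jointly with the
dominant eigenvalue λ for a fixed stage duration of `AFR − 1` years.
Colonies stack block-diagonally into `C` and are linked by stage-specific
dispersal through `M = (IP ⊗ D)·C + C`, where `D` holds emigration
probabilities and the connectivity matrix `IP` routes emigrants by
exponential decay in great-circle distance. Fledging success is
density-regulated, `f_dd = f / (1 + (N/K)^θ)` — untouched at low density,
halved exactly at carrying capacity.

Invasive species impose proportional hazards on chick and adult mortality:
per island, `γ_f = [Σ log Δ_x] · (1/X)^φ · (1/Area)^ψ` with hazard ratios
`Δ_x` per nesting-type × invasive-category, a compensation exponent φ
(additive mortality at 0, compensatory at 1), and an island-size discount ψ;
survival transforms as `S' = S^exp(γ)`. The hazard parameters are estimated
by a Bayesian state-space fit (adaptive Metropolis-within-Gibbs, Poisson
observation of latent deterministic dynamics) to survey counts at invaded
islands and islands where invasives were removed. Baseline vital rates get
taxonomically weighted literature priors (records replicated 20×/5×/1× for
same species/genus/family), optionally updated against IUCN-style
categorical trend labels via 100 pseudo-observed growth rates. Carrying
capacity comes from nest density × scaled area of occupancy, allocated
among islands by a fitted logit-linear model and floored at 2× current
abundance.

Risk projections run two nested loops — outer replicates draw joint
parameter vectors (parameter uncertainty), inner replicates simulate 100
years with spatiotemporally autocorrelated environmental noise and
below-threshold demographic stochasticity — and report the median, SE and
IQR of projected abundance and quasi-extinction probability (QEP: the
fraction of runs dropping below 50 females, or 10 for very small
populations).

## Worked example

Everything runs from synthetic data with known ground truth — no downloads.
Generate an archipelago where two rat-invaded islands were cleared at year
10, fit the invasive-hazard model to its survey counts, and compare
scenarios:

```bash
mpva make-fixtures --out world/ --seed 7 --islands 3 --removal-year 10 --years 30
mpva fit-invasive --world world/ --out fit/ --seed 1
mpva compare-scenarios --posterior fit/posterior_samples.csv --world world/ \
    --ns1 20 --ns2 50 --seed 1 --out comparison/
```

The same analysis through the library:

```python
from mpva.fixtures import make_removal_experiment
from mpva.priors import fit_all_priors
from mpva.inference import fit_state_space, MCMCConfig

world = make_removal_experiment(seed=3)
priors = fit_all_priors(world.records,
                        (world.spec.species, world.spec.genus, world.spec.family))
post = fit_state_space(world.series, world.species_meta, priors,
                       MCMCConfig(), seed=1)
lo, mid, hi = post.samples["delta_rat"].quantile([0.025, 0.5, 0.975])
print(f"rat hazard ratio: {mid:.2f}  (95% CI {lo:.2f}-{hi:.2f})")
```

which prints

```
rat hazard ratio: 1.24  (95% CI 1.07-1.63)
```

— the posterior for the chick-mortality hazard ratio of rats in this world,
whose generating value is 1.30: the presence of rats raised egg/chick
mortality hazard by ~30%, and the fit recovers that from count trends alone.
A scenario comparison on a declining two-island system
(`tests/test_acceptance.py` runs exactly this) gives a median QEP of 0.56
under current threats versus 0.40 after eradication, with the reduction
holding replicate-for-replicate under shared random numbers.

## Layout

| module | role |
|---|---|
| `mpva.demography` | stage matrix, λ–g fixed point, density dependence |
| `mpva.metapopulation` | connectivity, Kronecker assembly, projection |
| `mpva.hazards` | invasive proportional hazards on vital rates |
| `mpva.priors` | weighted literature priors (logit-normal / Poisson / log-normal) |
| `mpva.capacity` | K from nest density × usable area; island allocation |
| `mpva.inference` | state-space MCMC; trend-label posterior updates |
| `mpva.simulation` | stochastic two-loop projection, scenarios, QEP |
| `mpva.fixtures` | seeded synthetic worlds with ground truth |
| `mpva.cli` | `mpva` command-line entry points |

See `docs/methods.md` for the full model description, prior choices,
numerical details, and known limitations.
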