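# movesynd

Movement-syndrome analysis for radio-telemetry studies of animals in
heterogeneous landscapes: a diffusion movement model with habitat-specific
rates and preferences, a filtering likelihood for receiver detection
histories, hierarchical Bayesian estimation across individuals,
posterior-predictive validation with sixteen movement statistics, and
PCA / k-means detection of behavioural syndromes.

The package is built for the kind of dataset produced by a grid of coded
radio receivers ("dataloggers") tracking a population of tagged animals —
the motivating case is a population of small frugivorous bats in a
forest / matrix / open-area mosaic — and ships a synthetic-data generator
that emulates such a campaign end to end, so the whole pipeline is testable
with known ground truth.

## The model

Each individual i carries seven parameters on transformed scales,

    Θᵢ = ( log Dᵢ¹, log Dᵢ², log Dᵢ³, log kᵢ², log kᵢ³, log mᵢ, logit qᵢ )

with D^h the diffusion rate (m²/day) in habitat h ∈ {forest, matrix,
open}, k^h the habitat preference (equilibrium density relative to forest,
k¹ ≡ 1), m the mortality / battery-death rate (1/day) and q the per-slot
detection probability inside a receiver's detection area.  The location
density follows a diffusion whose transformed variable u = p/k is
continuous across habitat edges, so the stationary density satisfies
p ∝ k^h.  The PDE is discretized with lumped-mass P1 finite elements on a
triangulated landscape; the resulting generator is a continuous-time
Markov chain on mesh vertices, which both the likelihood (via its exact
exponential kernel) and the track simulator share — simulator and
likelihood agree exactly by construction.

Across individuals, vec(Θ) ~ N(vec(Tζ), Σ ⊗ I): a trait matrix T
(intercept, sex, centred log weight), trait effects ζ (3 × 7) and a
between-individual covariance Σ (7 × 7), estimated by adaptive
Metropolis-within-Gibbs with conjugate draws for ζ and Σ.  Model fit is
checked by simulating replicate datasets from the posterior and comparing
sixteen movement statistics (habitat use, fruit availability at used
receivers, movement distances, receiver fidelity, detectability); the
per-individual residuals of these statistics plus the posterior-mean
parameters form a 23-variable matrix whose PCA / k-means clustering (k by
the Average Silhouette Method) yields the movement syndromes.

See `docs/methods.md` for the full model description, numerical choices
and limitations.

## Worked example

The `movesynd` CLI chains five stages — `simulate`, `fit`, `validate`,
`syndromes`, `report` — over a run directory.  The bundled desk-scale
design (15 individuals tracked for 10 days on a 2 × 2 km synthetic mosaic
with 12 receivers, chains 2 × (2,000 + 8,000)):

```bash
movesynd simulate --config config.yaml --out run/
movesynd fit      --config config.yaml --out run/
movesynd validate --config config.yaml --out run/
movesynd syndromes --config config.yaml --out run/
movesynd report   --config config.yaml --out run/
```

with `config.yaml`:

```yaml
seed: 3
study: {extent: 2000.0, cell: 250.0, mesh_max_area: 31250.0,
        n_loggers: 12, detect_radius: 130.0,
        n_individuals: 15, n_male: 11, horizon_days: 10.0}
mcmc_n_adapt: 2000
mcmc_n_iter: 8000
mcmc_n_chains: 2
mcmc_thin: 8
n_rep: 200
k_min: 2
k_max: 6
```

`fit` writes the population-level posterior summary
(`run/fit/posterior_summary.csv`), which for this run reads:

```
parameter,mean,q0.025,q0.975
k1,1,1,1
k2,28.575,9.67258e-06,157.78
k3,27276.7,3.21918,261130
D1,1.96796e+06,0.108528,4.1061e+06
D2,1.74793e+06,0.120603,1.51413e+06
D3,1.27753e+07,81847.7,1.20876e+08
m,0.0559759,0.00632519,0.14077
q,0.985511,0.876022,0.999994
```

Read it honestly: at this design, transmitter batteries die after about a
week, each animal contributes only a handful of detection slots, and the
population-level movement parameters are barely identified — the
diffusion and preference intervals span orders of magnitude (their means
are inflated accordingly, being means of the exponential of a very wide
log-scale posterior).  What the data do pin down are the observation-side
parameters: detection inside a receiver's area is near-certain
(q ≈ 0.99, interval 0.88–1.00) and batteries fail at ≈ 0.06/day, an
~18-day life.  The forest preference k¹ is 1.00 with a degenerate
interval by construction — it is the normalization reference, not an
estimate.  The accompanying posterior-predictive check
(`validate/predictive_check.csv`) shows all 16 observed population-mean
movement statistics inside their central 95 % replicate bands, i.e. the
fitted model reproduces the data it was given even where individual
parameters stay uncertain; the test suite additionally demonstrates that
with informative histories (long-lived transmitters, ~100 detections per
individual) the posterior means do recover the individual parameter
ranking.  `syndromes` writes the residual matrix, silhouette profile,
cluster assignments and a PC1/PC2 biplot, and `report` a single Markdown
summary.  (All numbers above are from the actual run with seed 3; your
values will match exactly under the same config and seed.)

The same functionality is available as a library
(`movesynd.make_dataset`, `movesynd.run_mcmc`,
`movesynd.posterior_predictive`, `movesynd.detect_syndromes`, ...).

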