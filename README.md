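# popmix

Deconvolution of bulk expression time courses into sub-population fractions
and profiles, built around the convex-analysis-of-mixtures (CAM) geometry.

## The problem

A differentiating cell culture — the motivating case is MDI-induced 3T3-L1
pre-adipocytes profiled over roughly 0–240 hours — is a mixture of
non-identical cells. Bulk RNA-Seq or microarray profiling averages over that
mixture, so each gene's signal is a composite of its expression in two or
more latent sub-populations whose proportions change over time. `popmix`
takes a genes × samples expression matrix and estimates, without any
single-cell reference:

- **K latent sub-populations** and their **marker genes** (genes expressed
  near-exclusively in one population),
- the **mixing fractions** `A` (samples × K, rows on the probability
  simplex) at every time point,
- the **population-specific expression profiles** `S` (genes × K,
  non-negative),

under the linear mixing model `X ≈ S·Aᵀ`. Around this core it provides the
supporting analyses such a study needs: sample ordination with classical
MDS, marker-resampling stability checks, population-specific differential
expression under treatments (PSEA-style reference regression),
Kolmogorov–Smirnov comparisons of fold-change distributions, gene-set
over-representation, a cell-cycle signature index, and a two-population
growth model

    dP1/dt = -r·P1,   dP2/dt = r·P2,   dN/dt = (P2 - P1)·r

that explains how a small responsive population can overtake a confluent
culture: `N` dips and recovers at `t* = ln(P1₀/P2₀)/r`.

The geometric idea: scale every expressed gene's vector to unit sum across
samples. Mixed genes land inside a K-corner simplex; exclusive markers land
at its corners, which correspond to the pure populations. `popmix` locates
the corners (k-means + exhaustive convex-hull scoring), keeps the genes at
the extremities, validates them by one-vs-everyone (OVE) fold-change with a
bootstrap lower confidence bound, estimates fractions from the markers by
standardized averaging, and recovers profiles per gene by non-negative
least squares.

A first-class synthetic-data module generates ground-truth mixtures with
the structure of the motivating study (dominant progenitor pool collapsing
from 95% to under 40%, a responder rising above 60%, a minor transient
population, planted exclusive markers, multiplicative log-normal noise), so
every stage is testable against a known truth.

## Worked example

```python
from popmix import synthetic_data, cam_deconv, validation

truth = synthetic_data.make_truth(seed=7)                # 2000 genes, K=3
sim = synthetic_data.simulate_mixture(truth, seed=8)     # 10 times x 3 reps
res = cam_deconv.deconvolve(sim.expression, k=3, seed=9)

print(res.markers.counts())
print(res.fractions.values.groupby(sim.expression.samples["time_h"]).mean().round(3))
```

prints the identified marker counts

```
{'P1': 40, 'P2': 40, 'P3': 39}
```

(39 of the 40 planted P3 markers pass the expression floor; no shared gene
is selected) and the estimated mixing fractions, e.g. at 0 / 72 / 240 h:

```
P1: 0.839  0.505  0.345
P2: 0.042  0.255  0.625
P3: 0.119  0.241  0.029
```

— the progenitor pool P1 dominates the uninduced culture and falls below
40%, the responder P2 ends above 60%, and the minor population P3 rises
transiently before fading, mirroring the planted course. Against the known
truth the fractions have a mean absolute error of 0.0026
(`validation.fraction_mae` after Hungarian matching), and resampling random
35-marker subsets 100 times (`validation.resample_markers`) leaves the
estimates essentially unchanged: median coefficient of variation 0.65%,
maximum absolute bias 0.0003.

For the dynamics model, `dynamics.solve_rate(0.95, 0.05, 48.0)` returns
`r = 0.061342` per hour — the rate at which a 5% responsive population
restores the total size of a confluent culture within two days, with the
minimum at 24 h.

The same stages are available from a shell:

```
popmix simulate --out-dir sim --seed 7
popmix deconvolve --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --k 3 --out-dir out
popmix run --config config.yaml          # the full pipeline + manifest
```

## Layout

| module | contents |
| --- | --- |
| `popmix.core_io` | `ExpressionMatrix`, TSV/GMT readers and writers, probe collapsing, log-CPM, quantile normalization, batch adjustment |
| `popmix.synthetic_data` | ground-truth generator, fraction schedules, mixture and treatment simulation |
| `popmix.cam_deconv` | simplex projection, corner search, OVE fold-change, marker selection, fraction and profile estimation, `deconvolve` |
| `popmix.exploration` | sample distances, classical MDS with goodness-of-fit, stage distance tests |
| `popmix.validation` | marker-resampling stability (CV/bias), profile correlation, population matching |
| `popmix.popde` | mixture DE, PSEA reference regression, KS comparisons, BH FDR, response correlations |
| `popmix.dynamics` | two-population ODE model: analytic/RK4 trajectories, recovery time, rate solving |
| `popmix.signatures` | cell-cycle index, enrichment score, hypergeometric over-representation |
| `popmix.pipeline_cli` | `popmix` console script and the `run` orchestrator |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
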