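# Methods

## Mixing model and assumptions

All deconvolution algebra operates on the linear expression scale under

    X[g, s] = Σ_p S[g, p] · A[s, p],      A[s, ·] on the probability simplex,

with `X` the observed genes × samples matrix, `S ≥ 0` the population
profiles and `A` the mixing fractions. Inputs on a log2 scale are inverted
with `2^x − 1` before any mixing algebra. The model assumes (i) expression
adds linearly across cell populations, (ii) each population's profile is
constant over the course (composition, not regulation, drives the change —
treatment contrasts relax this via explicit interaction terms), and
(iii) each population owns at least a handful of exclusively expressed
marker genes. Assumption (iii) is what makes the problem well posed: after
scaling each gene's vector to unit sum across samples, mixed genes lie in
the convex hull of K corner points and exclusive markers sit at the
corners.

## Pipeline

1. **Simplex projection** (`project_simplex`). Genes whose maximum linear
   expression is below a floor are dropped; the default floor is the 20th
   percentile of per-gene maxima. Remaining gene vectors are scaled to unit
   sum.
2. **Corner search** (`find_corners`). The scaled vectors are clustered
   with k-means (`n_clusters = 20`, fixed seed, 10 restarts; an empty
   cluster triggers one re-seeded retry). Every K-subset of cluster centres
   is scored by the total squared residual of projecting *all* centres onto
   the convex hull of the subset (simplex-constrained least squares via
   NNLS with a heavily weighted sum-to-one row, ρ = 1e4); the minimizing
   subset is the corner set. Exhaustive scoring is tractable because
   C(20, K) is small.
3. **Extremity candidates** (`corner_candidates`). Each kept gene's vector
   is decomposed as a convex combination of the K corner centres; genes
   whose dominant corner weight is ≥ 0.75 are marker candidates for that
   corner. Interior genes — whose weights simply mirror the average mixing
   fractions — are excluded. The 0.75 default assumes no population
   averages more than three quarters of the mixture across the sampled
   course; on the reference simulation planted markers score ≥ 0.81 and
   shared genes ≤ 0.65. This geometric pre-filter matters statistically:
   the fold-change/CI criterion below controls only its nominal per-gene
   error rate (a one-sided 5% test), which on a genome-wide candidate set
   would admit a few percent of interior genes as spurious markers and
   dilute the fraction estimates.
4. **Marker statistics** (`ove_fold_change`, `select_markers`). The
   one-vs-everyone fold-change is
   `OVE[g, p] = (S[g, p] + c) / (max_{q≠p} S[g, q] + c)` with pseudocount
   `c = 1e-8` guarding exclusive markers. Profiles are estimated on the
   full data and on 100 bootstrap datasets (samples resampled with
   replacement, re-using the matching fraction rows; rank-deficient draws
   are redrawn). A candidate becomes a marker of its argmax population when
   the full-data OVE exceeds 1 and the 5th percentile of the bootstrap
   log-OVE is positive (percentile interval at level 0.95). A basic
   (reverse-percentile) interval was evaluated and discarded: the bootstrap
   distribution of log-OVE is strongly left-skewed, which makes the basic
   lower bound reject true markers.
5. **Fractions by standardized averaging** (`estimate_fractions`). Each
   marker gene's linear expression vector is scaled to unit sum across
   samples — the standardization that makes markers of different magnitudes
   comparable — and the scaled vectors are averaged within each population.
   Because the per-gene scaling leaves each population's signal known only
   up to a column scale, the scales are resolved by NNLS against the
   simplex constraint (`min_{c≥0} ‖R·c − 1‖`); for exclusive markers of a
   noiseless mixture this recovers the true fractions exactly. Each
   sample's K signals are finally normalized to sum to one. Marker symbols
   are matched case-insensitively so marker sets transfer across species
   conventions; missing markers warn, a fully missing population errors.
6. **Profiles by NNLS** (`estimate_profiles`). Per gene,
   `min_{s≥0} ‖X[g, ·] − A·s‖²`. Implementation detail: the unconstrained
   least-squares solution is computed for all genes in one batch and only
   rows with negative coefficients are re-solved with NNLS.
7. **Supervised mode**. `deconvolve(em, markers=...)` skips stages 1–4 and
   drives fraction and profile estimation from a precomputed marker set —
   how markers learned on one dataset (e.g. the mouse course) are applied
   to another (e.g. human arrays).

Populations are relabelled `P1..PK` for reporting: `P1` dominates the
earliest time point, `P2` is the largest remaining population at the final
time point. `K` is always user-fixed (default 3); `elbow_report` prints the
reconstruction error `‖X − S·Aᵀ‖_F / ‖X‖_F` over a range of K but never
auto-selects. At the reference noise level the elbow is operationalized as
shape, not an absolute bound: the relative error drop from K=2 to 3 exceeds
three times the drop from 3 to 4, because the fourth component still
absorbs noise worth ~1.6% relative error.

## Synthetic ground truth

`synthetic_data` emulates the structure the analysis assumes, not raw
sequencing: expression starts at the gene level.

- **Profiles**: shared genes draw a common log-normal baseline
  (`lognormal(4, 1)`, median ≈ 55) times mild per-population loadings
  (`exp(N(0, 0.05))`, ≤ ~10% between-population differences), so shared
  genes are genuinely non-markers under the fold-change criterion. Each
  population gets 40 planted markers, exclusively expressed at
  `lognormal(5.5, 0.4)` (≈ 4–5× baseline) — bright by design, because a
  marker whose mixture signal falls below the expression floor is
  undetectable by construction.
- **Fractions**: logistic interpolation from (0.95, 0.03, 0.02) to
  (0.35, 0.62, 0.03) with midpoint 72 h and steepness 0.05/h. The default
  schedule adds a transient Gaussian bump to P3 (height 0.3 before
  renormalization, centre 60 h, width 60 h; peak share ≈ 24%, final ≈ 3%):
  both minor groups respond initially but only P2 keeps growing. The
  transient is also an identifiability requirement — with a single shared
  logistic every fraction column is affine in one scalar, `A` has rank 2
  and the profiles are unidentifiable; the bump's breadth and height were
  chosen from the noise-amplification factors `diag((AᵀA)^{-1})^{1/2}` so
  the minor population's profile standard error stays within a small factor
  of the major populations'.
- **Noise**: multiplicative log-normal, `X ← X·exp(ε)`, `ε ~ N(0, 0.1²)`
  i.i.d. per entry, keeping the mixing model exact in expectation on the
  linear scale. Optional per-batch multiplicative gene offsets emulate
  location batch effects (matching what `batch_adjust` removes).
  Count-level negative-binomial simulation is out of scope.
- **Treatments**: `apply_treatment_effect` multiplies one population's
  profile at chosen genes by `2^lfc`; `simulate_two_groups` emits a
  control/treated pair differing only in that population.

Defaults (2000 genes, K = 3, 40 markers/population, 10 time points × 3
replicates, noise sd 0.1) are the reference conditions for the test-suite
and the acceptance script; they were sized to run in seconds on one CPU.
What passing on these mixtures does **not** show: robustness to count
noise, to profile drift over time, to unequal library sizes, or to
populations lacking exclusive markers.

## Supporting analyses

- **Ordination**: Euclidean distances over genes on the transformed scale;
  classical (Torgerson) MDS with goodness-of-fit = (sum of k largest
  eigenvalues) / (sum of |eigenvalues|) — negative eigenvalues contribute
  magnitude to the denominator. Stage comparisons use a Welch t-test of
  within-stage vs between-stage pairwise distances, treating pairs as
  independent observations (a deliberate simplification; distances sharing
  a sample are correlated). Sign convention: t > 0 means within-stage
  distances exceed between-stage ones.
- **Stability** (`resample_markers`): per (sample, population), CV and bias
  of fraction estimates across random marker subsets of fixed size; CV is
  reported as a percentage and summarized by the median, bias by the
  maximum absolute value. The reference experiment uses subsets of 35
  markers and 100 iterations; with near-perfect marker recovery the
  "smallest population" rule would equal the full set and the experiment
  would be vacuous.
- **Profile correlation**: Spearman on shared genes (≥ 10 required),
  p-values via the t-approximation throughout — with at least 10 points an
  exact permutation null (10! orderings) buys nothing and costs minutes.
- **Mixture DE**: per-gene OLS on a group indicator — the pooled-variance
  two-sample t-test — with BH FDR. No empirical-Bayes variance moderation:
  at a handful of replicates the unmoderated test is noisier for weakly
  expressed genes than a moderated one would be.
- **PSEA**: per population p, reference signal = mean of that population's
  unit-mean-scaled markers; per gene,
  `y = α + β·ref_p + γ·(ref_p × treated)`, with the t-test on γ as the
  population-specific effect and `log2((β+γ)/β)` as its fold-change
  (flagged undefined unless both β and β+γ are positive). One model per
  population ("one-to-one" comparisons) rather than a joint all-population
  model with stepwise selection: simpler, and identifiable at desk-scale
  sample sizes. Discrimination between populations relies on fraction
  variation across samples; with compositions frozen (single time point per
  group) the per-population interactions become collinear.
- **KS comparisons**: directional `D⁺ = sup(F_x − F_y)`,
  `D⁻ = sup(F_y − F_x)`; two-sided p from the asymptotic two-sample
  distribution, one-sided tails `exp(−2·(nm/(n+m))·D²)`.
- **Signatures**: cell-cycle index = per-sample mean z-score of the
  eight-gene signature (Mki67, Rb1, Hist1h2ae, Ccnb1, Cbx3, Gapdh, Ccnb2,
  E2f1); zero-variance genes contribute 0, missing genes are reported. The
  enrichment score is the classic unweighted running sum (+1/m per hit,
  −1/(N−m) per miss, signed max deviation), which equals the signed
  sup-difference between the hit- and non-hit-position ECDFs exactly (the
  one-sample-vs-uniform reading is only asymptotic); its p-value comes from
  random same-size hit sets with the add-one correction. ORA uses the
  upper-tail hypergeometric `P(X ≥ k)` with BH FDR and a reporting flag at
  overlap ≥ 3 and FDR < 0.2; nothing is dropped.
- **Dynamics**: hours everywhere; "two days" = 48 h. The narrative form of
  the model is internally inconsistent about P2's growth term; the
  equations (`dP2/dt = r·P2`) are taken as authoritative, and the
  `(P2 − P1)·r` expression is the derivative of N, not its size. RK4 is
  provided as an independent numerical check of the closed forms.

## Degenerate inputs and numerical choices

Ties in probe collapsing break by lexicographic probe id. Quantile
normalization assigns tied ranks the interpolated mean profile; it is
idempotent on tie-free data. Batch adjustment is per-gene location/scale
standardization to the pooled within-batch SD (zero-variance genes and
zero-SD batches pass through location-only); ComBat-style shrinkage is out
of scope and unnecessary for the location/scale effects the generator
injects. Zero marker signal across all populations sets a sample's
fractions to uniform with a warning. `t = 0, p = 1` for exactly equal
zero-variance groups. All stochastic steps take explicit seeds; pipeline
outputs are byte-identical across runs with the same config, and the `run`
subcommand writes a manifest with sha256 checksums of every artifact.

## Known limitations

Fraction estimates are relative (composition), never absolute cell counts.
Populations without exclusive markers violate the corner assumption and
will be merged or misassigned. The corner search scores cluster centres,
not raw genes, so fewer than ~K·2 well-populated extremity clusters can
hide a corner. The extremity dominance threshold (0.75) fails if one
population averages above it across the whole course. Bootstrap CIs are
percentile-based with 100 draws — lower bounds are coarse (resolution
~1/100 quantile). PSEA assumes the reference signals are measured without
error; marker noise attenuates γ. The two-population model ignores P3 and
any density dependence beyond the fixed symmetric rate.
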