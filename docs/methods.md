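# Methods

## The experiment in one paragraph

`bioscen` runs a climate-change impact experiment on a synthetic world: fit
several species distribution models (SDMs) per species under current climate,
project them onto a factorial set of future climates (GCM x RCP x period)
under two dispersal assumptions, summarize the projections as sensitivity
metrics, and partition the deviance of each metric into the contributions of
the SDM, GCM and RCP choices. Because the world and the species are
simulated, the variance structure that the partition engine should recover is
known exactly, which is what the package's tests exploit.

## Synthetic world

**Grid.** A planar equal-area lattice of square cells (default 100 km).
Distances are Euclidean between cell centres, in km, with no wrap-around;
"area" is a cell count throughout. This keeps every geometric operation
(buffers, discs, masks) exactly testable against brute-force distance
computations; great-circle geometry is a real-data concern that the synthetic
world deliberately avoids.

**Baseline climate.** Four bioclimatic variables: annual mean temperature
(°C), annual temperature range (°C), annual precipitation sum (mm) and
precipitation seasonality (CV of monthly sums, %). Each is a planar gradient
(temperature varies along rows, precipitation along columns, with a 10%
cross-axis tilt so no variable is constant along either axis) plus spatially
autocorrelated Gaussian noise, generated by smoothing white noise with a
Gaussian kernel of standard deviation `corr_length` cells and rescaling to a
per-variable noise sd (defaults: 1.5 °C, 2 °C, 180 mm, 9%). Non-negative
variables are clipped at zero. With the noise sd forced to zero each layer is
an exact plane, which several tests use as a degenerate-limit check.

**Scenario ensemble.** Future layers are produced by the delta method:
additive deltas for the temperature-like variables, multiplicative for the
precipitation-like ones. For scenario (GCM g, RCP r, period p):

```
temperature:    x + rank(r) * step * scale(p) + d_g + noise
precipitation:  x * (1 + rank(r) * step * scale(p)) * (1 + d_g) * (1 + noise)
```

`rank(r)` is the RCP's 1-based position in the severity ordering
(RCP2.6 < RCP4.5 < RCP6.0 < RCP8.5), so emission severity is monotone by
construction. `d_g` is the GCM's idiosyncratic deviation field, drawn once
per GCM from the master seed and reused across RCPs and periods, so "GCM" is
a coherent factor level. It is built as `gcm_sd * (z_g + s_g(x))` with
`z_g ~ N(0,1)` a spatial-mean offset and `s_g` a smooth zero-mean unit-sd
field; the between-GCM variance of the spatial-mean delta therefore equals
`gcm_sd²` exactly, which a Monte-Carlo test verifies. Default effect sizes
(0.8 °C of warming per RCP rank, −2.5% precipitation per rank, GCM sd 0.5 °C,
period scaling 1.0 / 1.6 for 2041–2060 / 2061–2080, small scenario noise) are
of CMIP5-like magnitude relative to the baseline gradients; they are the
knobs that set the ground-truth variance shares in recovery experiments.

The default scenario design mirrors the study layout this pipeline is built
for: five GCMs x four RCPs restricted to a fixed 14-combo subset (every GCM
under RCP4.5 and RCP8.5, two GCMs each under RCP2.6 and RCP6.0), two future
periods. Which 14 combos form the subset is configurable; only the count and
the coverage of all factor levels matter to the unbalanced-design handling.

**Virtual species.** Each species has an independent 4-D Gaussian niche:
suitability is `∏_v exp(−(x_v − μ_v)² / (2 σ_v²))`. The optimum is the
(jittered) climate of a randomly chosen anchor cell — guaranteeing the niche
is realized on the grid — and the breadths are drawn as 0.4–1.2 times each
variable's spatial sd. The true range is the set of cells above the
suitability quantile that realizes a target prevalence drawn uniformly from a
configurable interval. Species that cannot reach the 20-presence-cell
retention filter are re-drawn and eventually dropped with a warning. No
niche covariance terms are used: independence keeps the true suitability
surface available in closed form for recovery tests.

**Regions.** IPBES-style sub-regions are emulated by contiguous rectangular
blocks tiling the grid, with the row/column band factorization chosen to keep
blocks as square as possible and band sizes differing by at most one cell.

## SDM ensemble

**Training data.** All range cells are presences. Pseudo-absences are drawn
uniformly without replacement from the taxon-specific geographic buffer
around the range (amphibian 2000 km, mammal 3000 km, bird 4000 km by
default — the same distances later used as dispersal limits), excluding the
range itself; sampling absences globally would inflate apparent accuracy.
The default absence count is `min(10 x presences, all buffer cells)`,
bounding class imbalance. One absence sample is drawn per species; the
70/30 calibration/evaluation split is re-drawn for each of the four
cross-validation repetitions.

**Algorithms.** Four families, deliberately modest and fixed:

| family | implementation | key settings |
|---|---|---|
| GLM | logistic regression on linear + quadratic terms | L2, max_iter 2000 |
| GAM | additive cubic-spline basis (5 knots/variable) + logistic link | L2 |
| BRT | gradient-boosted trees | 150 trees, lr 0.05, depth 3, subsample 0.8 |
| RF | random forest | 200 trees, min leaf 2 |

**Scoring and binarization.** Continuous predictions on the 30% hold-out are
scored with the true skill statistic, `TSS = sensitivity + specificity − 1`.
The binarization cutoff is the TSS-maximizing threshold over the hold-out's
unique scores and their midpoints, ties broken towards the smallest cutoff
(constant scores fall back to 0.5 with a warning). The cutoff is stored per
fitted model and reused for every projection. Models are retained only if
their hold-out TSS reaches the policy threshold (0.4, 0.6 or 0.7); raising
the threshold can only shrink the retained set, a monotonicity the tests
assert. Note one numerical consequence of maximizing TSS over cutoffs: on
skill-free data the score is biased slightly above zero, with the bias
shrinking as the evaluation split grows.

**Projection.** Every retained model is projected onto the current layers and
every scenario's layers, inside the species' limited-dispersal domain; cells
outside the domain are missing. Single-class splits are refused with a
re-split suggestion; fits that fail outright are flagged non-converged and
excluded, leaving an unbalanced design the partition engine must (and does)
tolerate.

## Dispersal assumptions

`no_dispersal`: the current range, exactly. `limited_dispersal`: all cells
whose centre lies within the taxon's buffer distance of any range-cell
centre (inclusive boundary, with a 1e−9 relative tolerance against float
rounding of exact lattice distances). The no-dispersal mask is a subset of
every limited-dispersal mask, and masks grow monotonically with distance.

## Sensitivity metrics

Per (species, algorithm, repetition, GCM, RCP, period):

- `CCS = (future − current) / current` over suitable-cell counts, both maps
  restricted to the limited-dispersal domain; undefined (NaN) when no cell is
  currently suitable.
- `LCS = |suitable now ∧ unsuitable in future| / |suitable now|`, evaluated
  within the current range (the no-dispersal domain), using the
  model-predicted currently-suitable cells as denominator, since the metric
  contrasts two projections of the same fitted model. Restricting the future
  map to the currently suitable area makes `CCS = −LCS` exactly, an identity
  the tests check.

Per pixel (per taxon, stacking the per-species maps of one design cell):
`Δα = 100 (αf − αc)/αc` where current richness is positive;
`%loss = 100 · lost/αc` under no dispersal; `βt = (lost + gained)/(αc +
gained)` under limited dispersal, in [0, 1]. Per region:
`Δβs = 100 (βf − βc)/βc` with Whittaker's multiplicative `β = γ/ᾱ` (γ =
regional richness, ᾱ = mean per-cell richness). The alternative literal
reading — percent change in γ, divided by ᾱ — is available via
`semantics="literal"`; the two disagree whenever ᾱ changes while γ does not,
and the Whittaker reading is the default because "change in spatial turnover"
names a β-diversity quantity. Undefined values (zero denominators) propagate
as NaN and are dropped from partitions with logged counts.

Range-size stratification uses equal-width bins on log10(range size),
right-closed with the lowest edge included, so every species is assigned.

## Deviance partitioning

"Deviance" is Gaussian deviance — sums of squares of the (centred) response.
The nested scheme `SDM / GCM:RCP` is expanded as three cumulative
least-squares models:

1. intercept + SDM
2. … + SDM:GCM (GCM within SDM)
3. … + SDM:RCP (RCP within SDM)

Each term's deviance is the drop in residual sum of squares when it is
added; the remainder after step 3 is residual. The within-SDM GCM:RCP
interaction is pooled into the residual by default and can be split out with
`include_interaction=True`; cross-validation repetitions are replicates, not
a factor (an optional blocking column lets one verify that they explain a
negligible share — under 1% on exchangeable replicates). The full-factorial
variant replaces steps 2–3 with crossed main effects `+ GCM`, `+ RCP`.
Computationally each cumulative design matrix (one-hot factor encodings;
rank deficiency is irrelevant) is reduced to an orthonormal basis by SVD, so
a per-pixel sweep reuses `RSS = yᵀy − ‖Qᵀy‖²` per basis. The engine's sums
of squares agree with statsmodels' sequential (type-I) ANOVA to machine
precision on balanced and unbalanced designs, and with a direct group-means
decomposition on balanced ones — both are test oracles, never the
implementation.

Conservation (`ΣSS + residual = total`) holds to 1e−8 relative tolerance by
telescoping. Relative influence is always emitted in both conventions —
share of explained deviance and share of total — to avoid ambiguity.
Degenerate inputs are flagged rather than imputed: constant responses give
zero total deviance and NaN shares; single-level factors contribute zero;
missing responses are dropped with logged counts.

**Calibration experiments** (`bioscen.experiments`). The recovery study
plants additive factor effects standardized to an exact 9:4:1 variance ratio
on a balanced 4 x 5 x 4 design with 4 replicates; the recovered shares of
explained deviance settle at the df-weighted ratio
`80·3·9 : 64·4·4 : 80·3·1` ≈ 63.1 : 29.9 : 7.0 percent, within a few points
of the naive 9/14 : 4/14 : 1/14. The null study checks that with a pure-noise
response each component's share of total deviance equals its
degrees-of-freedom fraction. The planted-mechanism study generates projection
maps directly — algorithms agreeing inside the current range but diverging
strongly in the novel-climate expansion zone, loss inside the range scaling
with RCP rank — and confirms the direction the full pipeline exhibits: SDM
dominates the CCS partition, RCP dominates the LCS partition.

## Pipeline and problem sizes

The seven stages (simulate, fit, project, mask, metrics, partition, report)
read and write a single output directory; every stage seed derives
deterministically from the master seed, so re-running a stage with unchanged
inputs reproduces its outputs byte for byte, and a JSON manifest records
per-stage outputs and counts. Gridded state is persisted as `.npz`, fitted
models via joblib, all tables as CSV written at full float precision (note
that pandas' default CSV float parser is not round-trip exact; comparisons
against parsed floats use tolerances).

The shipped demo configuration — 20 species on a 15 x 20 grid, 2 GCMs x
2 RCPs x 1 period, 320 fitted models, 1280 future projections — was chosen as
the smallest world on which every stage (including per-pixel partitions and
the three-threshold comparison) is exercised with non-trivial unbalancedness;
it completes in about a minute on one CPU. A `paper_scale` config with the
full 14-combo x 2-period design on a 30 x 40 grid is included for longer
runs. The projection-count arithmetic (4 x 4 x 14 x 2 = 448 per species) is
exposed as a closed form and checked against actual counts in the manifest.

## What the synthetic world does and does not show

Virtual species have smooth, independent Gaussian responses realized exactly
on the training climate, so hold-out TSS is high (≈0.96 in the demo) and
nearly all models pass even the 0.7 threshold; real range data carry
observation error, non-climatic range limits and niche truncation, so real
TSS distributions are lower and retention bites harder. The demo world's
partition shares are properties of its configured effect sizes, not
predictions about real taxa: what the package demonstrates quantitatively is
that the machinery recovers planted variance structure and mechanism
directions. Also out of scope by design: real-data ingestion (range
polygons, climatologies, downscaling), spherical geometry, dispersal kernels
or time-stepped spread, ensemble weighting/averaging of continuous scores,
random-effects (REML) variance components and significance tests on the
partition.
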