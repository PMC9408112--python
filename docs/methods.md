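# Methods

## Scope and data model

The package analyzes a complete long-format panel: m regions × T years ×
14 indicators split into a supply subsystem (X₁–X₁₀) and a demand subsystem
(Y₁–Y₄). Completeness is enforced before any computation — the entropy and
coupling formulas assume a full region × year grid, and a missing cell is
reported by key rather than imputed. Values are nonnegative levels (persons,
beds, m², yuan); interpolation and missing-data handling are deliberately
out of scope.

## Standardization

Min–max standardization is applied per indicator, across regions, **within
each year**. The alternative (pooling the decade before scaling) changes
what a weight of "1" means: per-year scaling makes each year's weights and
scores a cross-sectional ranking, which is what yearly weight trajectories
and per-year Moran's I require. A `scope="pooled"` flag provides the pooled
variant for sensitivity analysis.

A degenerate indicator (identical across all regions in a year) is set to
0.5 everywhere and flagged. This choice is self-consistent: uniform values
give uniform proportions, hence maximal entropy and a difference coefficient
of zero, so the indicator's weight is exactly zero — it carries no
cross-sectional information and silently drops out rather than raising an
error mid-pipeline. Zero proportions (which min–max scaling necessarily
produces) use the continuity limit 0·ln 0 = 0.

## Entropy weights

Proportions are taken over regions within an indicator. Weights are computed
separately per year and per subsystem, so the 10 supply weights and 4 demand
weights each sum to 1 every year. Degenerate indicators get weight exactly 0
(set directly, not left to ~1e-16 float residue). The tested invariants:
weights sum to one, are invariant to region permutation, equivariant to
indicator permutation, and agree with a literal loop transcription of the
formulas to 1e-12.

## Coupling coordination

C = 2√(T₁T₂)/(T₁+T₂) with C = 0 when both scores vanish; D = C·(αT₁+βT₂)
with α = 0.4, β = 0.6 (demand weighted more heavily, the stated expert
judgment). D is implemented **without** the square root used in much of the
coupling-coordination literature because that is the printed form of the
model; `sqrt_variant=True` supplies D = √(C·(αT₁+βT₂)) for comparison.
Subsystem scores are weighted averages of values in [0, 1] and may exceed
1.0 by one part in 10¹⁶; scores are clipped at the boundary after a
tolerance check rather than propagating rounding spill into a domain error.

Classification bins are half-open [a, a+0.1) with the top bin closed at 1.0,
and the three coordination categories follow the 0.4 / 0.6 thresholds
(poor / medium / excellent). The published classification table's row layout
is ambiguous about which levels sit in which category; the prose thresholds
are taken as authoritative, which places "Primary balance" (0.6–0.7) in
excellent coordination.

### Reference-table arithmetic

The printed per-region coordination tables (2010–2019 observed, 2020–2024
forecast) ship as package data. `fixture_check()` recomputes every row's
period mean and compares it to the printed "average" at the table's
4-decimal precision, i.e. |mean − printed| ≤ 5×10⁻⁵: two rows
(means 0.42795 and 0.33125) fall exactly on the rounding boundary, where the
published tables rounded half-up while IEEE rounding is half-even, so
agreement-to-printed-precision is the faithful comparison. The underlying
yearbook inputs are not public, so the headline D values themselves are
arithmetic fixtures, not recomputation targets.

## Spatial autocorrelation

Global Moran's I uses the classical form I = [z'Wz / ΣW] · [n / z'z] with
binary contiguity weights by default — the statistic normalizes by the total
weight itself, so row standardization (available as an option) is not
required. The packaged China adjacency is queen contiguity among the 31
mainland units, hand-encoded from standard province borders, plus a
Hainan–Guangdong bridge so no region is an island; it is one conventional
choice among several, and Moran values computed with it are comparison
values, not reproductions (the original analysis never states its weight
matrix, and its printed Moran sequence repeats cyclically across years,
which is internally inconsistent). Inference is a one-sided permutation test,
p = (1 + #{I_perm ≥ I_obs})/(n_perm + 1); only the cross-product term varies
under permutation, so each draw costs one matrix–vector product. Under an
unstructured null the test's empirical size at the 5% level is checked to
lie in [0.02, 0.08].

## Synthetic panels

The generator produces, for region p, year t, indicator j,

    log Z = log scale_j + s_p + λ_j·(u_p or v_p) + (t−t₀)·log(1+g) + ε

with s_p ~ N(0, σ_region²) a shared region-size effect, (u_p, v_p) standard
bivariate normal with correlation ρ (the supply–demand coupling knob),
loadings λ_j ~ U(0.4, 0.9), growth g, and lognormal noise ε with coefficient
of variation c (mean 1 on the level scale). Defaults: m = 31 regions,
2010–2019, σ_region = 0.6 (order-of-magnitude size spread between provinces),
g = 0.08/year (the rapid build-out of care capacity over the decade),
c = 0.15, ρ = 0.6. All indicators are multiplicative-lognormal because the
real quantities are nonnegative counts and amounts.

What the generator emulates: scale heterogeneity, common growth, tunable
supply–demand coupling, per-indicator magnitudes. What it does not: spatial
structure (regions are exchangeable — which is exactly what the Moran null
tests need), demand-side demographic dynamics, policy shocks, or calibration
to actual yearbook magnitudes. Passing recovery tests therefore show the
pipeline detects latent coupling and holds its error rates under this model,
not that the published substantive findings are correct.

Tested recovery properties: the median coupling degree C rises strictly in
ρ ∈ {0, 0.45, 0.9} (100 replicates per level, common seeds; observed medians
≈ 0.90 → 0.94 → 0.99 at the 4-year panel size used in the suite), and
latent corr(u, v) converges to ρ as m grows. Replicated statistical checks
in the suite use 31-region, 4-year panels — the smallest panel the generator
accepts — to keep hundreds of full pipeline runs cheap; single-run
integration tests use the full 31 × 10 × 14 default.

## Forecasting

Each (region, indicator) series is forecast independently in sliding-window
form: windows of `lag` consecutive values predict the next value, and
multi-step forecasts recurse on their own outputs. Series are min–max scaled
to [0, 1] before training and inverse-scaled and clipped at 0 after; a
constant series bypasses the network and forecasts the constant exactly.

The network is one hidden layer of 8 tanh units fit by full-batch L-BFGS
from 5 seeded initializations, keeping the lowest training loss. With ten
yearly observations and lag 3 there are seven training windows, so anything
larger would be unidentifiable; deterministic quasi-Newton training rather
than stochastic descent makes runs bit-reproducible given the seed, which
the test suite requires. Per-series seeds are spawned from the master seed,
so forecasts are independent of panel iteration order. Accuracy expectations
are deliberately modest and tested as such: exact on constants, within 10%
one step ahead on a noiseless linear trend, and never worse than the
persistence (last value) forecast on noiseless linear and exponential
trends. No train/validation split, early stopping, or prediction intervals:
with n = 7 windows none is meaningful.

## Pipeline and reproducibility

`run_pipeline` chains every stage, writes all artifacts as full-precision
CSV (4-decimal display rounding is an option on exports mirroring published
table layouts), and emits a manifest with SHA-256 hashes of every output;
re-running with the same configuration and seed reproduces the hashes
byte-for-byte. Validation failures (α + β ≠ 1, malformed panels) are raised
before any computation, and CLI exit codes distinguish validation (1) from
runtime (2) errors.

## Known limitations

- The entropy-weight and min–max machinery is cross-sectional; nothing
  links a region's weight trajectory across years.
- Queen contiguity and the binary scheme are assumptions; Moran's I values
  depend materially on them, which is why reference-table Moran values are
  reported but not asserted.
- The forecaster is a small autoregressive smoother in practice; with seven
  training windows it cannot represent regime changes and long-horizon
  recursive forecasts flatten toward the recent level.
- Synthetic recovery results are conditional on the lognormal latent-factor
  generative model described above.
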