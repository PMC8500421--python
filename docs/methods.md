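# Methods

## Setting and wealth accounting

The unit of analysis is a location-season: a sub-location of a pastoral
region observed in one of two herding seasons per year (LRLD, the long
rain/long dry season, March–September; SRSD, the short rain/short dry
season, October–February). A stylized household holds `k₁` TLU of
livestock (default 1, valued at $1000/TLU) and loses a fraction `M` of it
to seasonal mortality; natural herd growth is deliberately ignored, so
uninsured next-season wealth is `k₁(1 − M)`.

All internal accounting is in fractions of one insured unit's value;
currency enters only as a final display scale. CRRA utility is
homothetic — `U(a·k) = a^(1−ρ)U(k)` — so certainty equivalents scale
linearly in the currency factor and RIB is exactly scale-free. This also
keeps the risk-neutral fair-pricing identity (IB = 0 when `ρ = 0`,
`m = 0`) exact to machine rounding instead of accumulating error at
$1000 magnitudes.

## Contracts and pricing

The livestock contract pays `max(0, M − t)·k₁` with trigger `t = 0.23` by
default; an index contract substitutes the model prediction `M̂` for `M`
in the same schedule. A crop variant pays `q·max(0, t_y·μ_loc − ŷ)` on
predicted yield shortfall relative to the location's long-term mean.

Pricing is either *empirical* (the simple mean of backcast payouts over
all location-seasons in the data — one pooled contract, not
location-differentiated) or *binned* (probability-weighted over a
discrete mortality-outcome distribution). The two agree whenever the
empirical sample realizes the binned distribution. The premium is
`AFP·(1 + m)` with default markup `m = 0.25`, charged every season
including payout seasons.

## Welfare engine

Preferences are CRRA with `ρ = 2` by default (a moderately risk-averse
smallholder; the sensitivity sweep covers 0–3, with `ρ = 1` handled by
the log-utility branch and `CE = exp(EU)`). Expected utility is the
equal-weight average over location-seasons unless an explicit weight
vector (e.g. insured-population shares) is supplied.

RIB is the ratio of certainty-equivalent benefits, defined only where the
perfect contract is itself beneficial (`ÎB_P > 0`). At `ρ = 0` with fair
pricing the perfect contract's benefit is identically zero and with a
markup it is negative, so the ρ-sweep reports RIB as NaN at such grid
points while keeping the IB values; the programmatic `rib()` operation
raises instead, and `evaluate_contract(strict_rib=False)` selects the
NaN behaviour.

The Taylor decomposition evaluates the shadow value `λ = k^(−ρ)` at the
**no-insurance** wealth of each state — the state the household is in
absent the transfer — with an `insured` option for sensitivity. The
decomposition error is second order in the transfer size: halving payouts
and premium roughly quarters the absolute gap to the exact IB.

Degenerate wealth: total loss (`M = 1`) plus a premium makes insured
wealth non-positive, where CRRA utility with `ρ ≥ 1` is undefined. The
default is a hard error naming the offending state; a configurable
`wealth_floor` (e.g. 1% of initial wealth) clips instead, and is the
documented deviation to use for sweeps over harsh scenarios.

Payout-error classes measure the shortfall `s = I_perfect − I_index` in
fractions of the **insured value** (not of the owed indemnity — the
latter is available by changing the thresholds' denominator upstream):
TN when neither contract pays, FP when the index overpays, and false
negatives split at 10% and 30% shortfall (both thresholds configurable);
exact payment with a payout due counts as a small FN, making the
partition exhaustive and exclusive.

## Index preparation

Raw seasonal index means are standardized per location:
`z = (x − μ_loc)/σ_loc`, with the sample (n−1) standard deviation —
conventional for anomaly indices computed from short per-location
series. `μ_loc` and `σ_loc` pool both seasons across all years in the
input table by default (the per-location interpretation of the anomaly);
a season-stratified option groups by (location, season-of-year) instead.
The statistics window is whatever the table spans and is recorded in the
output. Log transformation (for rainfall-like skewed quantities) happens
before standardization, and non-positive values are an error naming the
offending record, since NDVI can legitimately be ≤ 0 over non-vegetated
surfaces and silently log-transforming it would corrupt the index.

## Loss models

For fixed breakpoint ψ the segmented model is exact OLS on
`{1, z, (z − ψ)·1[z > ψ]}`; ψ itself is found by profiling the SSE over
every observed z value that leaves at least 3 observations per segment
(identifiability of two slopes), then refining the best candidate by
golden-section search between its grid neighbours, ties breaking toward
the smallest ψ. Grid-plus-refinement is deterministic and directly
checkable against an exhaustive-grid oracle, which the test suite does.

Quantile regression is solved as an exact linear program (HiGHS):
minimize `τ·Σu⁺ + (1−τ)·Σu⁻` subject to `u⁺ − u⁻ = M − β₀ − β₁z`. This
attains the global pinball-loss optimum deterministically, with no
iteration-budget failure mode, and satisfies the standard residual
balance condition (the fraction of observations under the fitted line is
within 2/n of τ). Default quantile: the 77th percentile.

The truncated fits (`lm0`, `lm5`) are OLS on the subset below their z
cutoff and extrapolate that line over the full range at prediction time;
predictions of every model are clipped to [0, 1] *only* at prediction
time, never during fitting. Payouts are insensitive to the extrapolation
choice because extrapolated predictions above the cutoff sit below the
trigger. R² for all models is reported on the full evaluation sample by
default (so all model kinds share one axis); subset-only scores are
available by passing the subset.

## Sweeps and cross-validation

The sweep evaluates every (index, model) combination on one panel and
reports R², RMSE, RIB, pricing and error-class counts side by side;
failures of individual combinations are recorded per row. Rows are
canonically ordered, so the result is independent of input row order.

Cross-validation partitions records randomly into k = 5 seeded folds by
default (whole-location blocking is available as the spatially defensible
alternative), refits per training split, and pools out-of-fold
predictions into one series covering each record exactly once; R² and
RIB are computed once on the pooled series, giving a single welfare
number comparable to the in-sample one. The index premium is priced in
one pass over the pooled out-of-fold payouts by default; per-fold pricing
from each training split (each record carrying its own fold's premium) is
available via `price_on="train_folds"`. Per-fold R² is undefined (NaN)
for singleton or constant test folds, as in leave-one-out.

## Synthetic scenarios

`gen_mortality_index` emulates the structure of a pastoral livestock
panel: 15 locations × 2 seasons × 8 years (240 records). A latent
standard-normal forage score `z` drives mean mortality through a hinge:
base 0.10, slope −0.25 per z-unit below the breakpoint ψ\* = −1, flat
above. Additive truncated-normal noise (sd 0.05; optionally reallocated
toward high- or low-mortality states at fixed average variance) and
index-independent disease shocks (probability 0.03, magnitude uniform
0.2–0.4) complete the mortality series, clipped to [0, 1]. These defaults
put overall mean mortality near 0.13 with rare losses above 0.6. The raw
index column is a per-location affine transform of `z` with NDVI-like
levels, so the standard z-scoring pipeline approximately recovers the
latent score; `z_latent` is also emitted for direct use.

`gen_matched_r2_pair` builds the canonical counter-example to R²-based
index selection: one shared mortality series (linear in the latent score,
so there is no hinge asymmetry to confound the comparison) and two index
columns with the *same total* prediction-error variance, one concentrating
its entire error budget in payout-relevant high-mortality seasons
(producing severe false negatives) and one in low-mortality seasons.
Noise draws are rescaled within each group to hit the variance budget
exactly and re-drawn until the two segmented-model R² values agree within
0.03. Welfare metrics systematically prefer the second index although R²
cannot separate them.

`gen_outcome_distribution` provides a stylized 25-state mortality risk
distribution on [0, 0.65]: exponentially decaying probabilities (gamma
shape 1) with mean 0.13, discretized by bin mass and renormalized. The
exponential tail makes the perfect contract's fair price about 2% of
insured value (≈ $21 per $1000-TLU) at the 23% trigger.

What the generators do **not** emulate: spatial autocorrelation between
sub-locations, sensor noise or cloud-masking artefacts, household-level
heterogeneity beneath the location-season average, and any beta-like
mortality error structure — the truncated-normal noise is a stand-in.
Tests passing on these scenarios therefore certify the *accounting and
inference machinery* (identities, invariances, oracle agreement,
directional findings), not predictive performance on any real survey.

## Problem sizes and numerical choices

Unit and property tests run on panels of 240–360 records; oracle
comparisons use exhaustive enumeration at small n (two-point vertex
search for quantile fits at n ≤ 50, full breakpoint grids at n ≤ 360)
and Monte-Carlo checks use 20–50 replicate seeds. Tolerances: exact
identities (perfect-contract RIB, scale invariance, risk-neutral
neutrality) are asserted at 1e-10 to 1e-12; oracle agreement for the LP
quantile fit at 1e-8; stochastic directional properties as frequency
bounds over seeds. All randomness flows through
`numpy.random.default_rng` seeded per scenario; identical seeds yield
bitwise-identical datasets and results.

## Known limitations

- The five loss models are single-regressor; multi-index or spline models
  are out of scope.
- One pooled contract is priced for all locations;
  location-differentiated premia and reinsurance layering are not
  modelled.
- The welfare framework is expected-utility only; probability-weighting
  alternatives (CPT/RDU) are intentionally excluded as normative bases.
- Satellite data acquisition, masking and pixel aggregation are upstream
  of this package: inputs are already-aggregated location-season means.
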