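# Methods

## Model

A reaction scheme is a single unbranched cycle of N ∈ {2, 3, 4} enzyme
states with 2N strictly positive first-order rate constants, odd-indexed
forward (counterclockwise, state 1 = free enzyme) and even-indexed reverse.
Substrate and product concentrations are folded into the two binding
constants (k₁ = k₁*·[S], k₂ₙ = k₂ₙ*·[P]) and held fixed — the chemiostatic
steady state.  Multi-cycle mechanisms, two-force (free-energy-transducing)
cycles and relaxation time courses are out of scope.

All quantities follow Hill's steady-state diagram formalism.  For each cycle
size the directional sums Σᵢ (spanning trees of the cycle graph rooted at
state i, edges directed toward the root) give

- stationary probabilities pᵢ = Σᵢ / ΣⱼΣⱼ,
- one-way fluxes J⁺ = Πk_odd / D and J⁻ = Πk_even / D with D = ΣⱼΣⱼ,
- net flux J = J⁺ − J⁻,
- force X/RT = ln K with K = Πk_odd / Πk_even = ΠKᵢ,
- dissipation φ/RT = J · X/RT ≥ 0 (second law; zero exactly at detailed
  balance).

The four-state denominator is the King–Altman sum of sixteen directed-tree
terms; each Σᵢ was cross-validated term by term against an exact-arithmetic
master-equation solve, which is also the oracle in the test suite.

Forward performance parameters use the standard closed forms: k_cat = k₃
(two states), k₃k₅/(k₃+k₄+k₅) (three states), and for four states the
saturating-substrate, zero-product-rebinding limit
k₃k₅k₇/(k₃k₅+k₃k₆+k₃k₇+k₄k₆+k₄k₇+k₅k₇), equivalent to the step-equilibrium
form with K₂ = k₃/k₄, K₃ = k₅/k₆.  Catalytic efficiency is
k_cat/K_m = Πk_odd/([S]·Σ₁) for every size; K_m is their quotient.  These
closed forms are tested against the saturation limit of the cycle flux.

Thermodynamic outputs are reduced by RT (dimensionless force, φ/RT in s⁻¹);
absolute dissipation in J mol⁻¹ s⁻¹ requires an explicit temperature
(`dissipation_absolute`).  State entropy is Shannon entropy in nats,
matching the natural-log force convention.

## Numerical choices

- **Stationary distributions** are computed by GTH (Grassmann–Taksar–Heyman)
  elimination of the rate matrix.  GTH performs the stationary linear solve
  using only additions and multiplications of non-negative rates, so the
  probabilities remain componentwise accurate even when constants span eight
  decades; an SVD null-space solve loses roughly one digit per decade of
  conditioning and cannot meet the 10⁻⁸ oracle-equivalence contract.
- **Irreversible steps.**  A zero reverse constant makes the force infinite;
  the constructor rejects zeros and the table loader substitutes a
  configurable floor (default 10⁻⁸ s⁻¹, the order used for effectively
  irreversible steps in the curated data), logging every substitution.
- **Haldane check** compares the equilibrium constant from the second-order
  rate-constant products with the [P] root of the flux numerator (found by
  bracketed root-finding in log [P]); consistent schemes agree to ~10⁻¹⁵ and
  anything above 10⁻⁹ marks an inconsistent record.
- **Ranking ties** in summary tables break lexicographically by label.
- **p-values** below 5·10⁻⁴ display as "< 0.001" in human-readable output
  but stay exact in machine output.

## Noise protocols

The per-step multiplier is g = √(−2 ln s₁)·cos(2π s₂) + 1 with s₁, s₂
uniform on (0, 1), so g − 1 is standard normal.  Rate constants must stay
positive, so only g > 0 is consumed: a non-positive draw repeats the
previous accepted row, and the first row (which has no predecessor) is
redrawn.  The RNG is numpy's seeded default generator; only the
distribution, not any particular stream, is contractual.

**Forward variations** must apply identical noise to every forward constant
*and* keep every Kᵢ fixed; jointly these force the reverse constants to
scale by the same g, which is how the transform is implemented.  All
homogeneous-degree-one outputs (k_cat, k_cat/K_m, J, φ/RT) scale exactly by
g and the invariant columns (K_m, Kᵢ, X/RT, probabilities, entropy) are
constant along a trace, so the efficiency-versus-dissipation regression has
R² = 1 to machine precision — the protocol's defining signature.  Over
30 000 steps the largest accepted factor is ≈ 5 (the expected maximum of
that many N(1, 1) draws), bounding the attainable amplification.

**Trade-off variations** apply K₁ → g·K₁ and K_last → K_last/g with one
shared g per step (the compensatory pair; independent factors are not used).
Default mode `"rates"` perturbs the association and release *rates*
(k₁ → g·k₁, k₂ₙ₋₁ → k₂ₙ₋₁/g); mode `"reverse"` adjusts the two reverse
constants instead and is kept for sensitivity analysis.  Both leave the
total force exactly fixed.  Since the flux numerator is invariant under mode
"rates", φ(g) = const/D(g) with D(g) containing both g and 1/g terms, an
interior maximum in g always exists.

**Maximal-dissipation search.**  The deterministic oracle scans g
log-spaced over 10⁻³..10³ (601 nodes) and refines with bounded
golden-section minimisation to 10⁻⁶ relative in g.  The stochastic search
splits its step budget (default 30 000) into recentring rounds of 1000
Box–Muller proposals around the current best composed factor: each proposal
is a single noise multiplier, but recentring lets the walk reach optima far
from g = 1, which a single shifted-Gaussian draw (support ≈ (0, 6)) cannot.
g = 1 is always a candidate, so φ_max ≥ φ(g = 1).  An optimum on the scan
boundary is flagged with a warning — the standard remedy is to raise the
substrate concentration and re-run — never silently returned.  Eff/Tur
classification uses a strict inequality (optimal efficiency > observed ⇒
Eff; a fold of exactly 1 is Tur); the expected k_cat implication (Eff ⇒
lower optimal k_cat) is checked and violations warn rather than fail.

## Scaling statistics

Power laws φ/RT = α·xᵝ are fit by OLS of log₁₀ y on log₁₀ x (base 10
throughout), with t-based 95% CI and two-sided slope p-value.  Bootstrap
sensitivity resamples *cases* (pairs) with replacement — 2000 resamples by
default — redrawing the rare degenerate resample with zero x-spread, and
summarises the exponent by mean, SD and percentile CI.  The
generalist-versus-specialized comparison uses the Mann–Whitney U test:
exact null distribution when both groups have ≤ 12 observations without
ties, normal approximation with tie correction otherwise.  The published
comparison does not state sidedness or method, so the report computes all
four configurations and records which reproduces the published p ≈ 0.008
(the one-sided, generalists-lower test; two-sided gives ≈ 0.014–0.016).

## Synthetic data generator

Scheme sampling draws forward and reverse constants log-uniformly over
10⁻²..10⁶ s⁻¹, a target force uniformly in 1..23 RT, then rescales the
product-binding constant to hit the target exactly — so every sample is
forward-driven, inside the force window, and Haldane-consistent by
construction.  [S] is log-uniform over 10⁻⁶..10⁻² M with [P] = [S]/10 (the
"ten-fold lower product" heuristic; overridable, as real records range from
25-fold higher to 1000-fold lower).  A retry budget of 100 keeps generation
deterministic and bounded; sampling is bit-reproducible under a fixed seed.
The generator reproduces the *ranges* of the curated data, not its joint
structure: real reactions correlate force, flux and cycle size through
shared chemistry, while sampled constants are independent.  Passing
property tests on synthetic schemes therefore establishes the correctness
and internal consistency of the formalism and the protocols, not any
empirical claim about real enzymes.

Power-law ensembles are y = α·xᵝ·exp(ε) with ε ~ N(0, sd²) i.i.d. (default
β = 0.73, sd = 0.5, n = 58, matching the scale of the real regression);
parameter-recovery and CI-coverage experiments in the test suite use 200 to
500 replicate ensembles of this size, chosen so the whole suite completes
in a few seconds.

## Dataset fixture

The packaged tables transcribe the published 58-reaction summary (observed
values and trade-off optima), validated on load by SHA-256 checksum and by
the dataset invariants: ranks 1..58 in non-increasing dissipation, exactly
8 generalist flags, 24 Eff / 34 Tur from the efficiency folds, and the
product identity φ/RT = J·X/RT within 1% or the printed-digit rounding
bound for every row except rank 1 (CAII, a documented discrepancy shipped
as printed and excluded from the check).  Transcription anomalies,
including the corrected AR flux, are documented in
`src/dissipath/data/TRANSCRIPTION.md`.

## Known limitations

- Only uni-uni single-cycle mechanisms; reactions with two products are
  treated with the same cycle formalism, as in the source data.
- The fixture carries the printed (rounded) table values, not the
  full-precision appendix constants, so reproduced regression coefficients
  carry a ±0.01 transcription tolerance.
- The stochastic search is a heuristic; agreement with the grid oracle is
  verified statistically (1% over ≥ 100 sampled schemes), not proven.
- No heteroskedasticity-robust errors or alternative power-law estimators;
  the contract is the log-log OLS analysis itself.
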