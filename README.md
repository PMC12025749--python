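# dissipath

Steady-state kinetics, thermodynamics and scaling-law statistics for
reversible enzyme catalytic cycles.

Enzymes that convert a substrate S to a product P through a cycle of 2, 3 or
4 conformational states (E → ES → [EZ → EP] → E), with [S] and [P] held
fixed by continuous exchange, operate in a genuine non-equilibrium steady
state.  When every microscopic rate constant is known — binding steps folded
into first-order constants, k₁ = k₁*·[S] and k₂ₙ = k₂ₙ*·[P] — the cycle's
net flux J, thermodynamic force X = RT·ln K and dissipation function
φ = J·X follow in closed form from Hill's diagram method, alongside the
familiar performance parameters k_cat and k_cat/K_m.  `dissipath` computes
all of these, ships a curated 58-reaction summary dataset spanning eight
decades of dissipation, and implements the analyses built on top of it:

- **Scaling laws.**  Across the 58 reactions, dissipation scales almost
  linearly with the turnover number (φ/RT ≈ 1.4·k_cat^0.96) and sublinearly
  with catalytic efficiency (φ/RT ≈ 0.015·(k_cat/K_m)^0.73), fit by OLS on
  log₁₀-transformed data with case-resampling bootstrap sensitivity and a
  Mann–Whitney comparison of generalist versus specialized enzymes.
- **Noise protocols.**  *Forward variations* multiply all rate constants by
  a positive Box–Muller factor g = √(−2 ln s₁)·cos(2π s₂) + 1 per step,
  preserving every step equilibrium constant, so efficiency climbs exactly
  linearly with dissipation.  *Trade-off variations* perturb only the
  substrate-association and product-release steps compensatorily
  (K₁ → g·K₁, K_last → K_last/g) at fixed total force, and a maximal-entropy-
  production search over g classifies each reaction as **Eff** (the optimum
  improves efficiency) or **Tur** (it improves turnover).
- **Synthetic data.**  A seeded sampler produces physically consistent
  random schemes (Haldane-consistent, forces in 1–23 RT, rate constants over
  eight decades) and noisy power-law ensembles for parameter-recovery
  experiments.

## Worked example

```python
from dissipath import ReactionScheme, performance, steady_state, find_max_dissipation

scheme = ReactionScheme(
    n_states=3,
    k=(320.0, 40.0, 95.0, 12.0, 130.0, 6.5),   # k1..k6, s^-1 (k1, k6 folded)
    substrate_conc=2e-4, product_conc=2e-5,
)
p, sol = performance(scheme), steady_state(scheme)
res = find_max_dissipation(scheme, method="grid")
```

prints (via the obvious format calls):

```text
kcat        = 52.11 1/s
Km          = 4.755e-05 M
kcat/Km     = 1.096e+06 1/(M s)
J           = 41.64 1/s
X/RT        = 7.144
phi/RT      = 297.5 1/s
p           = (0.1901, 0.48, 0.3298)
g_opt       = 0.7159  phi_max/RT = 306.4 1/s  (observed 297.5)
class       = Tur
```

The enzyme turns over 52 substrate molecules per second at saturation but
completes only 42 net cycles per second against the 7.1 RT driving force,
dissipating 297 RT per enzyme per second.  The trade-off search finds the
maximal-dissipation steady state at g ≈ 0.72 (slower substrate capture,
faster product release); because that optimum improves the turnover number
rather than the efficiency, the reaction is classified Tur.

The same pipeline is scriptable from the shell:

```sh
dissipath data show --table 1               # the packaged 58-reaction table
dissipath synth schemes --n 58 --states 3 --seed 1 -o schemes.csv
dissipath compute --input schemes.csv -o summary.csv
dissipath simulate tradeoff --input schemes.csv --steps 5000 --seed 7 --out trace.tsv
dissipath regress --x efficiency --boot 2000 --seed 11
dissipath report --strict                   # full reproduction report
```

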