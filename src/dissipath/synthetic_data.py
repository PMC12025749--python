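"""Generators for physically consistent random schemes and power-law ensembles.

The scheme sampler stands in for per-enzyme microscopic rate-constant
datasets: it draws first-order constants over the broad range such datasets
span (eight decades by default) and then pins the cycle force X/RT inside a
target window by rescaling the product-binding constant, so every sample is a
valid forward-driven non-equilibrium steady state.  The power-law ensemble
generator produces (x, y) pairs from y = alpha * x**beta * exp(eps) with
log-normal noise, the data-generating model behind the dissipation-efficiency
scaling regression, for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cycle_models import ReactionScheme

__all__ = [
    "SchemeSamplerConfig",
    "PowerLawEnsembleConfig",
    "sample_scheme",
    "sample_schemes",
    "generate_power_law_ensemble",
]


@dataclass(frozen=True)
class SchemeSamplerConfig:
    """Sampling ranges for random reaction schemes.

    Defaults emulate the conditions of the curated 58-reaction dataset:
    first-order constants log-uniform over 1e-2..1e6 s^-1, forces X/RT in
    (1, 23), substrate concentrations log-uniform over 1e-6..1e-2 M with the
    product held at one tenth of the substrate.
    """

    n_states: int = 3
    log10_rate_range: tuple[float, float] = (-2.0, 6.0)
    force_window: tuple[float, float] = (1.0, 23.0)
    log10_substrate_range: tuple[float, float] = (-6.0, -2.0)
    product_ratio: float = 0.1
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_states not in (2, 3, 4):
            raise ValueError("n_states must be 2, 3 or 4")
        lo, hi = self.force_window
        if not (0 < lo < hi):
            raise ValueError("force window must be positive and non-degenerate")
        for rng_ in (self.log10_rate_range, self.log10_substrate_range):
            if not rng_[0] < rng_[1]:
                raise ValueError("ranges must be non-degenerate")
        if not self.product_ratio > 0:
            raise ValueError("product_ratio must be positive")


@dataclass(frozen=True)
class PowerLawEnsembleConfig:
    """Parameters of a synthetic y = alpha * x**beta ensemble."""

    alpha: float = 0.015
    beta: float = 0.73
    n: int = 58
    noise_sd: float = 0.5  # sd of the log-residual (natural log)
    log10_x_range: tuple[float, float] = (-4.0, 8.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 points")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def _sample_one(config: SchemeSamplerConfig, rng: np.random.Generator, index: int):
    lo, hi = config.log10_rate_range
    n = config.n_states
    for _ in range(config.max_retries):
        fwd = 10.0 ** rng.uniform(lo, hi, n)
        rev = 10.0 ** rng.uniform(lo, hi, n)
        target = rng.uniform(*config.force_window)
        current = math.log(np.prod(fwd) / np.prod(rev))
        # rescale the product-binding (last reverse) constant to hit the force
        rev[-1] *= math.exp(current - target)
        if not 10.0 ** (lo - 4) <= rev[-1] <= 10.0 ** (hi + 4):
            continue
        s_conc = 10.0 ** rng.uniform(*config.log10_substrate_range)
        p_conc = s_conc * config.product_ratio
        k = tuple(float(v) for pair in zip(fwd, rev) for v in pair)
        return ReactionScheme(
            n_states=n,
            k=k,
            substrate_conc=s_conc,
            product_conc=p_conc,
            k1_second_order=k[0] / s_conc,
            k_rev_bind_second_order=k[-1] / p_conc,
            label=f"synthetic-{n}state-{config.seed}-{index}",
        )
    raise RuntimeError(
        f"could not sample a scheme in the force window {config.force_window} "
        f"after {config.max_retries} retries (rate range {config.log10_rate_range})"
    )


def sample_scheme(config: SchemeSamplerConfig) -> ReactionScheme:
    """Draw one scheme; deterministic in ``config.seed``.

    Forward constants are sampled log-uniformly, a target X/RT is drawn in
    the force window, and the product-binding constant is rescaled to hit it
    exactly, so X/RT lies in the window and J > 0 by construction.
    """
    return _sample_one(config, np.random.default_rng(config.seed), 0)


def sample_schemes(config: SchemeSamplerConfig, n: int) -> list[ReactionScheme]:
    """Draw ``n`` schemes from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    return [_sample_one(config, rng, i) for i in range(n)]


def generate_power_law_ensemble(
    config: PowerLawEnsembleConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) with y = alpha * x**beta * exp(eps), eps ~ N(0, sd^2)."""
    rng = np.random.default_rng(config.seed)
    x = 10.0 ** rng.uniform(*config.log10_x_range, config.n)
    eps = rng.normal(0.0, config.noise_sd, config.n) if config.noise_sd > 0 else 0.0
    y = config.alpha * x**config.beta * np.exp(eps)
    return x, y
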