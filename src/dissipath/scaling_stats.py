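"""Power-law regression, bootstrap sensitivity and non-parametric comparison.

The scaling analysis fits phi/RT = alpha * (k_cat/K_m)**beta (or the k_cat
analogue) by ordinary least squares on log10-transformed data, quantifies the
stability of the exponent by case-resampling bootstrap, and compares the
dissipation of generalist versus specialized enzymes with a Mann-Whitney U
test.  Log base 10 is used throughout, matching the conventional log-log
presentation of scaling laws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PowerLawFit",
    "BootstrapSummary",
    "loglog_power_fit",
    "bootstrap_exponent",
    "mann_whitney_u",
    "format_p_value",
]


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log10 y = log_alpha + beta * log10 x."""

    log_alpha: float  # intercept, log10 scale
    beta: float  # exponent (slope)
    r_squared: float
    beta_ci95: tuple[float, float]  # t-based 95% CI on the slope
    slope_p: float  # two-sided p-value for the zero-slope null
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")
        lo, hi = self.beta_ci95
        if not lo <= self.beta <= hi:
            raise ValueError("CI must contain the point estimate")
        if self.n < 3:
            raise ValueError("need at least 3 points")


@dataclass(frozen=True)
class BootstrapSummary:
    """Case-resampling bootstrap of the power-law exponent."""

    mean_beta: float
    sd_beta: float
    ci95: tuple[float, float]  # percentile interval
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        if self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 must be ordered")


def _validated_logs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    bad = np.flatnonzero(~((x > 0) & (y > 0) & np.isfinite(x) & np.isfinite(y)))
    if bad.size:
        raise ValueError(
            f"x and y must be positive and finite; offending indices: {bad.tolist()}"
        )
    return np.log10(x), np.log10(y)


def loglog_power_fit(x, y) -> PowerLawFit:
    """Fit y = alpha * x**beta by OLS on log10-transformed data."""
    lx, ly = _validated_logs(x, y)
    model = sm.OLS(ly, sm.add_constant(lx)).fit()
    ci = model.conf_int(alpha=0.05)
    return PowerLawFit(
        log_alpha=float(model.params[0]),
        beta=float(model.params[1]),
        r_squared=float(model.rsquared),
        beta_ci95=(float(ci[1, 0]), float(ci[1, 1])),
        slope_p=float(model.pvalues[1]),
        n=len(lx),
    )


def bootstrap_exponent(x, y, n_boot: int = 2000, seed: int = 0) -> BootstrapSummary:
    """Case-resampling (pairs) bootstrap of the log-log slope.

    Degenerate resamples in which all x values coincide (slope undefined)
    are redrawn.
    """
    lx, ly = _validated_logs(x, y)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    n = len(lx)
    betas = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            sx = lx[idx]
            if np.ptp(sx) > 0:
                break
        sy = ly[idx]
        sxm, sym = sx - sx.mean(), sy - sy.mean()
        betas[b] = (sxm @ sym) / (sxm @ sxm)
    lo, hi = np.percentile(betas, [2.5, 97.5])
    return BootstrapSummary(
        mean_beta=float(betas.mean()),
        sd_beta=float(betas.std(ddof=1)),
        ci95=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
    )


_EXACT_LIMIT = 12  # enumeration is cheap up to this group size


def mann_whitney_u(
    a,
    b,
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U statistic (for sample a) and p-value.

    ``method="auto"`` uses the exact null distribution when both groups have
    at most 12 observations and there are no ties, and the normal
    approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
        method = (
            "exact"
            if (a.size <= _EXACT_LIMIT and b.size <= _EXACT_LIMIT and no_ties)
            else "asymptotic"
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def format_p_value(p: float, threshold: float = 5e-4) -> str:
    """Human-readable p-value: values below the threshold print as "< 0.001"."""
    return "< 0.001" if p < threshold else f"{p:.3g}"
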