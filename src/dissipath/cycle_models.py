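"""Closed-form steady-state kinetics and thermodynamics of reversible catalytic cycles.

A single enzyme cycling through N conformational states (N = 2, 3, 4) with
fixed substrate and product concentrations (chemiostatic conditions) is a
genuine non-equilibrium steady state.  With every transition folded into a
first-order rate constant (binding steps multiplied by [S] or [P]), the net
cycle flux J, the thermodynamic force X = RT ln K over the cycle, and the
dissipation function phi = J*X follow from T. L. Hill's diagram method.  This
module provides the closed-form flux/force expressions per cycle size, the
forward Michaelis-Menten performance parameters k_cat and k_cat/K_m, the
stationary state probabilities, and a Haldane consistency check.

All thermodynamic outputs are reduced by RT: ``force_rt`` is dimensionless
and ``dissipation_rt`` carries units of s^-1.  Absolute dissipation in
J mol^-1 s^-1 is available through :func:`dissipation_absolute`.

Rate-constant ordering follows the cycle convention: state 1 is the free
enzyme E, cycling counterclockwise, odd-indexed constants k1, k3, ... are
forward and even-indexed k2, k4, ... reverse, so a scheme with N states
carries 2N first-order constants.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GAS_CONSTANT",
    "SchemeError",
    "ReactionScheme",
    "PerformanceParams",
    "SteadyStateSolution",
    "catalytic_constant",
    "catalytic_efficiency",
    "michaelis_constant",
    "performance",
    "steady_state",
    "haldane_check",
    "master_equation_probabilities",
    "rate_matrix",
    "dissipation_absolute",
    "net_flux",
    "one_way_fluxes",
    "state_probabilities_diagram",
    "catalytic_constant_k",
    "catalytic_efficiency_k",
    "read_schemes_csv",
    "write_schemes_csv",
]

logger = logging.getLogger(__name__)

#: molar gas constant, J mol^-1 K^-1
GAS_CONSTANT = 8.31446261815324

_SUPPORTED_STATES = (2, 3, 4)
_SECOND_ORDER_RTOL = 1e-9


class SchemeError(ValueError):
    """Raised for invalid or inconsistent reaction schemes."""


# ---------------------------------------------------------------------------
# directional-diagram index tables (0-based into the length-2N constant vector)
#
# _SIGMA[n][i] lists the spanning-tree products rooted at state i+1; the
# stationary probability of state i is Sigma_i / sum(Sigma).  The shared
# denominator of the net flux is the same sum.
# ---------------------------------------------------------------------------
_SIGMA = {
    2: (
        ((1,), (2,)),
        ((0,), (3,)),
    ),
    3: (
        ((2, 4), (1, 4), (1, 3)),
        ((3, 5), (0, 4), (0, 3)),
        ((2, 5), (1, 5), (0, 2)),
    ),
    4: (
        ((2, 4, 6), (1, 4, 6), (1, 3, 6), (1, 3, 5)),
        ((3, 5, 7), (0, 4, 6), (0, 3, 6), (0, 3, 5)),
        ((2, 5, 7), (1, 5, 7), (0, 2, 6), (0, 2, 5)),
        ((1, 3, 7), (0, 2, 4), (2, 4, 7), (1, 4, 7)),
    ),
}


def _as_k_array(k: Sequence[float] | np.ndarray, n_states: int) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if k.shape[-1] != 2 * n_states:
        raise SchemeError(
            f"expected {2 * n_states} rate constants for a {n_states}-state cycle, "
            f"got {k.shape[-1]}"
        )
    return k


def _sigma_weights(n_states: int, k: np.ndarray) -> np.ndarray:
    """Directional-diagram sums Sigma_i, shape (..., n_states)."""
    groups = _SIGMA[n_states]
    cols = []
    for terms in groups:
        total = sum(np.prod(k[..., list(idx)], axis=-1) for idx in terms)
        cols.append(total)
    return np.stack(cols, axis=-1)


def net_flux(n_states: int, k: Sequence[float] | np.ndarray) -> np.ndarray | float:
    """Net steady-state cycle flux J = (prod forward - prod reverse)/D, s^-1.

    Vectorised over leading axes of ``k`` (shape ``(..., 2N)``).
    """
    k = _as_k_array(k, n_states)
    num = np.prod(k[..., 0::2], axis=-1) - np.prod(k[..., 1::2], axis=-1)
    den = _sigma_weights(n_states, k).sum(axis=-1)
    return num / den


def one_way_fluxes(
    n_states: int, k: Sequence[float] | np.ndarray
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """One-way cycle fluxes (J+, J-) sharing the net-flux denominator."""
    k = _as_k_array(k, n_states)
    den = _sigma_weights(n_states, k).sum(axis=-1)
    return np.prod(k[..., 0::2], axis=-1) / den, np.prod(k[..., 1::2], axis=-1) / den


def state_probabilities_diagram(
    n_states: int, k: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Stationary probabilities from the directional diagrams (vectorised)."""
    sig = _sigma_weights(n_states, _as_k_array(k, n_states))
    return sig / sig.sum(axis=-1, keepdims=True)


def catalytic_constant_k(n_states: int, k: Sequence[float] | np.ndarray):
    """Forward turnover number k_cat from the raw constant vector (vectorised).

    Two states: k_cat = k3.  Three states: k_cat = k3 k5/(k3+k4+k5).  Four
    states: the saturating-substrate limit of the cycle flux at [P] = 0,
    k_cat = k3 k5 k7 / (k3k5 + k3k6 + k3k7 + k4k6 + k4k7 + k5k7), which is the
    step-equilibrium form with K2 = k3/k4 and K3 = k5/k6.
    """
    k = _as_k_array(k, n_states)
    if n_states == 2:
        return k[..., 2] + 0.0
    if n_states == 3:
        return k[..., 2] * k[..., 4] / (k[..., 2] + k[..., 3] + k[..., 4])
    k3, k4, k5, k6, k7 = (k[..., i] for i in range(2, 7))
    den = k3 * k5 + k3 * k6 + k3 * k7 + k4 * k6 + k4 * k7 + k5 * k7
    return k3 * k5 * k7 / den


def catalytic_efficiency_k(
    n_states: int, k: Sequence[float] | np.ndarray, substrate_conc
):
    """k_cat/K_m in M^-1 s^-1 from the raw constant vector (vectorised).

    Equals (prod forward k) / ([S] * Sigma_1) for every supported cycle size,
    with Sigma_1 the directional sum rooted at the free enzyme.
    """
    k = _as_k_array(k, n_states)
    groups = _SIGMA[n_states][0]
    sigma1 = sum(np.prod(k[..., list(idx)], axis=-1) for idx in groups)
    return np.prod(k[..., 0::2], axis=-1) / (np.asarray(substrate_conc) * sigma1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionScheme:
    """An N-state reversible catalytic cycle with concentrations folded in.

    Parameters
    ----------
    n_states
        Number of enzyme conformational states, 2, 3 or 4.
    k
        The 2N first-order rate constants in s^-1, ordered
        (k1, k2, ..., k_{2N}); odd positions forward, even reverse.  The
        substrate-binding constant k1 and the product-binding constant
        k_{2N} already include the respective concentration.
    substrate_conc, product_conc
        Molar concentrations held fixed by the chemiostat.
    k1_second_order, k_rev_bind_second_order
        Optional second-order binding constants (M^-1 s^-1); when given they
        must reproduce k1/[S] and k_{2N}/[P] to 1e-9 relative.
    """

    n_states: int
    k: tuple[float, ...]
    substrate_conc: float
    product_conc: float
    k1_second_order: float | None = None
    k_rev_bind_second_order: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_states not in _SUPPORTED_STATES:
            raise SchemeError(
                f"unsupported cycle size n_states={self.n_states}; "
                f"supported sizes are {_SUPPORTED_STATES}"
            )
        k = tuple(float(x) for x in self.k)
        if len(k) != 2 * self.n_states:
            raise SchemeError(
                f"need {2 * self.n_states} rate constants, got {len(k)}"
            )
        if not all(math.isfinite(x) for x in k):
            raise SchemeError("rate constants must be finite")
        if any(x <= 0 for x in k):
            raise SchemeError(
                "all rate constants must be strictly positive; replace an "
                "irreversible (zero) step with a small positive floor first"
            )
        if not (self.substrate_conc > 0 and math.isfinite(self.substrate_conc)):
            raise SchemeError("substrate_conc must be positive and finite")
        if not (self.product_conc > 0 and math.isfinite(self.product_conc)):
            raise SchemeError("product_conc must be positive and finite")
        object.__setattr__(self, "k", k)
        for name, value, first_order, conc in (
            ("k1_second_order", self.k1_second_order, k[0], self.substrate_conc),
            (
                "k_rev_bind_second_order",
                self.k_rev_bind_second_order,
                k[-1],
                self.product_conc,
            ),
        ):
            if value is None:
                continue
            implied = first_order / conc
            if abs(value - implied) > _SECOND_ORDER_RTOL * abs(implied):
                raise SchemeError(
                    f"{name}={value!r} inconsistent with first-order constant "
                    f"{first_order!r} at concentration {conc!r} "
                    f"(implied {implied!r})"
                )

    # -- derived views ----------------------------------------------------

    @property
    def forward(self) -> tuple[float, ...]:
        """Forward constants (k1, k3, ...)."""
        return self.k[0::2]

    @property
    def reverse(self) -> tuple[float, ...]:
        """Reverse constants (k2, k4, ...)."""
        return self.k[1::2]

    @property
    def step_equilibrium_constants(self) -> tuple[float, ...]:
        """K_i = k_{2i-1}/k_{2i} for each of the N steps."""
        return tuple(f / b for f, b in zip(self.forward, self.reverse))

    @property
    def equilibrium_constant(self) -> float:
        """Cycle equilibrium constant K = prod forward / prod reverse."""
        return math.prod(self.forward) / math.prod(self.reverse)

    def with_k(self, k: Iterable[float], label: str | None = None) -> "ReactionScheme":
        """Copy with new first-order constants; second-order constants are
        re-derived from the (unchanged) concentrations."""
        k = tuple(float(x) for x in k)
        return replace(
            self,
            k=k,
            k1_second_order=(
                None if self.k1_second_order is None else k[0] / self.substrate_conc
            ),
            k_rev_bind_second_order=(
                None
                if self.k_rev_bind_second_order is None
                else k[-1] / self.product_conc
            ),
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class PerformanceParams:
    """Forward-direction Michaelis-Menten performance parameters."""

    kcat: float  # s^-1
    km: float  # M
    efficiency: float  # M^-1 s^-1

    def __post_init__(self) -> None:
        if not (self.kcat > 0 and self.km > 0 and self.efficiency > 0):
            raise SchemeError("performance parameters must be positive")
        if abs(self.efficiency - self.kcat / self.km) > 1e-12 * self.efficiency:
            raise SchemeError("efficiency must equal kcat/km")


@dataclass(frozen=True)
class SteadyStateSolution:
    """Thermodynamic summary of one cycle's non-equilibrium steady state.

    ``dissipation_rt`` is phi/RT in s^-1; phi = T*P, so the entropy
    production rate P is recoverable by multiplying by R (per mole) and
    dividing by nothing further -- all outputs here are reduced by RT.
    """

    flux: float  # net cycle flux J, s^-1
    force_rt: float  # X/RT, dimensionless
    dissipation_rt: float  # phi/RT = J * X/RT, s^-1
    flux_forward: float  # J+, s^-1
    flux_backward: float  # J-, s^-1
    probabilities: tuple[float, ...]
    shannon_entropy: float  # nats
    equilibrium_constant: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def catalytic_constant(scheme: ReactionScheme) -> float:
    """Turnover number k_cat (s^-1) for the forward direction."""
    return float(catalytic_constant_k(scheme.n_states, scheme.k))


def catalytic_efficiency(scheme: ReactionScheme) -> float:
    """Catalytic efficiency k_cat/K_m (M^-1 s^-1) for the forward direction."""
    if not scheme.substrate_conc > 0:
        raise SchemeError("substrate concentration must be positive")
    return float(
        catalytic_efficiency_k(scheme.n_states, scheme.k, scheme.substrate_conc)
    )


def michaelis_constant(scheme: ReactionScheme) -> float:
    """Forward Michaelis constant K_m = k_cat / (k_cat/K_m), in M."""
    return catalytic_constant(scheme) / catalytic_efficiency(scheme)


def performance(scheme: ReactionScheme) -> PerformanceParams:
    kcat = catalytic_constant(scheme)
    eff = catalytic_efficiency(scheme)
    return PerformanceParams(kcat=kcat, km=kcat / eff, efficiency=eff)


def rate_matrix(scheme: ReactionScheme) -> np.ndarray:
    """Master-equation generator W with W[j, i] the rate from state i to j."""
    n = scheme.n_states
    W = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        W[j, i] += scheme.k[2 * i]  # forward step i+1
        W[i, j] += scheme.k[2 * i + 1]  # its reverse
    W -= np.diag(W.sum(axis=0))
    return W


def master_equation_probabilities(scheme: ReactionScheme) -> np.ndarray:
    """Stationary distribution of the cycle's master equation.

    The stationary linear system is solved by GTH (Grassmann-Taksar-Heyman)
    elimination, which only ever adds and multiplies non-negative rates, so
    the probabilities stay componentwise accurate even when the rate
    constants span many orders of magnitude (a plain SVD null-space solve
    loses digits proportionally to the condition number).
    """
    n = scheme.n_states
    # Q[i, j]: transition rate from state i to state j
    Q = np.zeros((n, n))
    for i in range(n):
        j = (i + 1) % n
        Q[i, j] += scheme.k[2 * i]
        Q[j, i] += scheme.k[2 * i + 1]
    s = np.zeros(n)
    for m in range(n - 1, 0, -1):
        s[m] = Q[m, :m].sum()
        for i in range(m):
            Q[i, :m] += Q[i, m] * Q[m, :m] / s[m]
            Q[i, i] = 0.0
    p = np.zeros(n)
    p[0] = 1.0
    for m in range(1, n):
        p[m] = (p[:m] * Q[:m, m]).sum() / s[m]
    return p / p.sum()


def steady_state(scheme: ReactionScheme) -> SteadyStateSolution:
    """Solve the cycle's non-equilibrium steady state.

    J, J+ and J- come from the closed-form diagram expressions; the state
    probabilities from the stationary linear system of the rate matrix
    (GTH elimination); X/RT = ln K; phi/RT = J * X/RT.
    """
    n, k = scheme.n_states, np.asarray(scheme.k)
    jf, jb = one_way_fluxes(n, k)
    flux = float(jf - jb)
    K = scheme.equilibrium_constant
    force_rt = math.log(K)
    p = master_equation_probabilities(scheme)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = float(-np.sum(np.where(p > 0, p * np.log(np.clip(p, 1e-300, None)), 0.0)))
    return SteadyStateSolution(
        flux=flux,
        force_rt=force_rt,
        dissipation_rt=flux * force_rt,
        flux_forward=float(jf),
        flux_backward=float(jb),
        probabilities=tuple(float(x) for x in p),
        shannon_entropy=ent,
        equilibrium_constant=K,
    )


def dissipation_absolute(solution: SteadyStateSolution, temperature: float) -> float:
    """Absolute dissipation phi in J mol^-1 s^-1 at the given temperature (K)."""
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return solution.dissipation_rt * GAS_CONSTANT * temperature


def haldane_check(scheme: ReactionScheme) -> float:
    """Relative mismatch between the two routes to the equilibrium constant.

    Route one uses the rate-constant products through the stored (or implied)
    second-order binding constants.  Route two varies [P] numerically until
    the flux numerator vanishes (the J = 0 requirement) and reads off
    [P]_eq/[S].  Consistent schemes return ~1e-16; anything above 1e-9 marks
    an inconsistency between the folded first-order constants and the
    concentrations.
    """
    k1_so = (
        scheme.k1_second_order
        if scheme.k1_second_order is not None
        else scheme.k[0] / scheme.substrate_conc
    )
    krev_so = (
        scheme.k_rev_bind_second_order
        if scheme.k_rev_bind_second_order is not None
        else scheme.k[-1] / scheme.product_conc
    )
    fwd, rev = scheme.forward, scheme.reverse
    k_rates = (k1_so * math.prod(fwd[1:])) / (krev_so * math.prod(rev[:-1]))

    log_prod_fwd = sum(math.log(x) for x in fwd)
    log_rev_rest = sum(math.log(x) for x in rev[:-1])

    def log_numerator(log_p: float) -> float:
        # log(prod fwd) - log(prod rev) with the binding step at product conc p
        return log_prod_fwd - (log_rev_rest + math.log(krev_so) + log_p)

    center = log_prod_fwd - log_rev_rest - math.log(krev_so)
    log_p_eq = brentq(log_numerator, center - 60, center + 60, xtol=1e-14)
    k_root = math.exp(log_p_eq) / scheme.substrate_conc
    return abs(k_rates - k_root) / k_rates


# ---------------------------------------------------------------------------
# rate-constant table IO
# ---------------------------------------------------------------------------

_CSV_FIELDS = [
    "label",
    "n_states",
    "k1",
    "k2",
    "k3",
    "k4",
    "k5",
    "k6",
    "k7",
    "k8",
    "S_molar",
    "P_molar",
    "k1_second_order",
    "k_rev_second_order",
]


def read_schemes_csv(
    path: str | Path,
    *,
    reverse_floor: float = 1e-8,
    delimiter: str | None = None,
    on_error: str = "raise",
) -> list[ReactionScheme]:
    """Load rate-constant records from a CSV/TSV file.

    Header columns: label, n_states, k1..k8 (trailing columns empty for
    smaller cycles), S_molar, P_molar and optional second-order constants.
    A reverse constant recorded as zero (an effectively irreversible step,
    which would make the force infinite) is replaced by ``reverse_floor``
    (default 1e-8 s^-1) and the substitution is logged.  With
    ``on_error="skip"`` malformed rows are dropped with a logged diagnostic
    instead of aborting the load.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    schemes: list[ReactionScheme] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = {"label", "n_states", "k1", "k2", "S_molar", "P_molar"} - set(
            reader.fieldnames or []
        )
        if missing:
            raise SchemeError(f"missing required columns: {sorted(missing)}")
        for line_no, row in enumerate(reader, start=2):
            try:
                schemes.append(_parse_scheme_row(row, line_no, reverse_floor))
            except (SchemeError, ValueError) as exc:
                if on_error == "raise":
                    raise
                logger.warning("skipping line %d: %s", line_no, exc)
    return schemes


def _parse_scheme_row(row: dict, line_no: int, reverse_floor: float) -> ReactionScheme:
    n = int(row["n_states"])
    if n not in _SUPPORTED_STATES:
        raise SchemeError(f"line {line_no}: unsupported n_states={n}")
    k = []
    for i in range(1, 2 * n + 1):
        cell = (row.get(f"k{i}") or "").strip()
        if not cell:
            raise SchemeError(f"line {line_no}: missing k{i}")
        value = float(cell)
        if value == 0.0 and i % 2 == 0:
            logger.warning(
                "line %d (%s): reverse constant k%d = 0 replaced by floor %.3g s^-1",
                line_no,
                row["label"],
                i,
                reverse_floor,
            )
            value = reverse_floor
        k.append(value)
    k1_so = (row.get("k1_second_order") or "").strip()
    krev_so = (row.get("k_rev_second_order") or "").strip()
    return ReactionScheme(
        n_states=n,
        k=tuple(k),
        substrate_conc=float(row["S_molar"]),
        product_conc=float(row["P_molar"]),
        k1_second_order=float(k1_so) if k1_so else None,
        k_rev_bind_second_order=float(krev_so) if krev_so else None,
        label=row["label"],
    )


def write_schemes_csv(
    schemes: Iterable[ReactionScheme], path: str | Path, *, delimiter: str | None = None
) -> None:
    """Write schemes in the canonical rate-constant table layout."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS, delimiter=delimiter)
        writer.writeheader()
        for s in schemes:
            row = {
                "label": s.label,
                "n_states": s.n_states,
                "S_molar": repr(s.substrate_conc),
                "P_molar": repr(s.product_conc),
                "k1_second_order": (
                    "" if s.k1_second_order is None else repr(s.k1_second_order)
                ),
                "k_rev_second_order": (
                    ""
                    if s.k_rev_bind_second_order is None
                    else repr(s.k_rev_bind_second_order)
                ),
            }
            for i, value in enumerate(s.k, start=1):
                row[f"k{i}"] = repr(value)
            for i in range(2 * s.n_states + 1, 9):
                row[f"k{i}"] = ""
            writer.writerow(row)
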