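"""Packaged 58-reaction summary dataset: loaders, ranking and census helpers.

The fixture transcribes the published table of catalytic efficiency
(k_cat/K_m), turnover number (k_cat), net flux J, reduced force X/RT and
reduced dissipation phi/RT for 58 enzyme-catalyzed reactions ordered from the
most to the least dissipative, together with the trade-off-variation optima
(fold changes at maximal dissipation).  See ``data/TRANSCRIPTION.md`` for
provenance and the two documented anomalies (CAII rank 1, AR rank 28).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "FixtureError",
    "ReactionRecord",
    "load_table",
    "load_fixture",
    "kcat_flux_ratio",
    "generalist_partition_counts",
    "dissipation_identity_error",
    "printed_rounding_bound",
    "classify_from_fold",
    "export_records",
    "GENERALIST_CODES",
    "IDENTITY_EXEMPT_CODES",
]

#: sha256 of the packaged fixture files; a mismatch means the transcription
#: was altered and the loader refuses to continue.
_CHECKSUMS = {
    "table1.csv": "d74d463a30c3e2d63d2c178dc2b6250ec94f765d6bb49293e6c605fd7070967b",
    "table2.csv": "fd12e7eab50ecb757e2ab1fe9d892919de383e30f20da79b04046934b368aaef",
}

GENERALIST_CODES = frozenset(
    {"GPI", "TIProRC", "TIProR", "KYNase_93D9", "TM0831", "FAProR", "GI", "GI3"}
)

#: rank-1 CAII prints a dissipation that is not the J*X product (documented
#: transcription anomaly); it is exempt from the product-identity check.
IDENTITY_EXEMPT_CODES = frozenset({"CAII"})

N_REACTIONS = 58


class FixtureError(RuntimeError):
    """Raised when the packaged fixture fails validation."""


@dataclass(frozen=True)
class ReactionRecord:
    """One reaction of the summary dataset (merged observed + optimum rows)."""

    rank: int
    code: str
    efficiency: float  # k_cat/K_m, M^-1 s^-1
    kcat: float  # s^-1
    flux: float  # net flux J, s^-1
    force_rt: float  # X/RT
    dissipation_rt: float  # phi/RT, s^-1
    generalist: bool
    eff_fold: float  # optimal k_cat/K_m over observed
    kcat_fold: float  # optimal k_cat over observed
    opt_flux: float  # s^-1
    opt_force_rt: float
    opt_dissipation_rt: float  # phi_max/RT, s^-1
    boundary_case: bool  # maximum reached only after raising [ligand]
    class_label: str  # "Eff" or "Tur"


def _read_packaged(name: str) -> bytes:
    data = resources.files("dissipath.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureError(
            f"checksum mismatch for packaged fixture {name}: {digest}"
        )
    return data


def load_table(table: int) -> pd.DataFrame:
    """Return the raw transcription of table 1 or 2 as a DataFrame."""
    if table not in (1, 2):
        raise ValueError("table must be 1 or 2")
    import io

    return pd.read_csv(io.BytesIO(_read_packaged(f"table{table}.csv")))


def classify_from_fold(eff_fold: float) -> str:
    """Eff if the trade-off optimum improves efficiency (fold > 1, strict)."""
    return "Eff" if eff_fold > 1 else "Tur"


def load_fixture() -> list[ReactionRecord]:
    """Load and validate the 58 merged reaction records.

    Enforces the dataset invariants: ranks are a permutation of 1..58,
    dissipation is non-increasing in rank, exactly 8 generalists, and the
    Eff/Tur classification from the efficiency fold yields 24/34.
    """
    t1, t2 = load_table(1), load_table(2)
    merged = t1.merge(t2, on=["rank", "code"], validate="one_to_one")
    if len(merged) != N_REACTIONS:
        raise FixtureError(f"expected {N_REACTIONS} merged rows, got {len(merged)}")
    if sorted(merged["rank"]) != list(range(1, N_REACTIONS + 1)):
        raise FixtureError("ranks are not a permutation of 1..58")
    merged = merged.sort_values("rank", kind="stable").reset_index(drop=True)
    if not merged["dissipation_rt"].is_monotonic_decreasing:
        raise FixtureError("dissipation must be non-increasing in rank")
    gen = set(merged.loc[merged["generalist"] == 1, "code"])
    if gen != set(GENERALIST_CODES):
        raise FixtureError(f"generalist flags {sorted(gen)} do not match expectation")

    records = [
        ReactionRecord(
            rank=int(r.rank),
            code=str(r.code),
            efficiency=float(r.efficiency),
            kcat=float(r.kcat),
            flux=float(r.flux),
            force_rt=float(r.force_rt),
            dissipation_rt=float(r.dissipation_rt),
            generalist=bool(r.generalist),
            eff_fold=float(r.eff_fold),
            kcat_fold=float(r.kcat_fold),
            opt_flux=float(r.opt_flux),
            opt_force_rt=float(r.opt_force_rt),
            opt_dissipation_rt=float(r.opt_dissipation_rt),
            boundary_case=bool(r.boundary_case),
            class_label=classify_from_fold(float(r.eff_fold)),
        )
        for r in merged.itertuples()
    ]
    n_eff = sum(1 for r in records if r.class_label == "Eff")
    if (n_eff, N_REACTIONS - n_eff) != (24, 34):
        raise FixtureError(f"Eff/Tur census is ({n_eff}, {N_REACTIONS - n_eff})")
    return records


def kcat_flux_ratio(record: ReactionRecord) -> float:
    """k_cat / J; the turnover number always exceeds the net flux forward."""
    if not record.flux > 0:
        raise ValueError(f"{record.code}: flux must be positive")
    return record.kcat / record.flux


def generalist_partition_counts(
    records: list[ReactionRecord], split_rank: int
) -> tuple[int, int]:
    """Generalist counts above and below a rank split of the dissipation order.

    ``records`` must be sorted by dissipation descending (the fixture order);
    returns (count in ranks 1..split_rank, count in split_rank+1..58).
    """
    if not 1 <= split_rank <= N_REACTIONS - 1:
        raise ValueError("split_rank must lie in 1..57")
    diss = [r.dissipation_rt for r in records]
    if any(a < b for a, b in zip(diss, diss[1:])):
        raise ValueError("records must be sorted by dissipation descending")
    top = sum(1 for r in records[:split_rank] if r.generalist)
    bottom = sum(1 for r in records[split_rank:] if r.generalist)
    return top, bottom


def printed_rounding_bound(record: ReactionRecord) -> float:
    """Half-ULP error bound on |phi - J*X| implied by the printed precision.

    Each printed column is accurate to half its last printed digit; the bound
    propagates those three half-ULPs through the product identity.
    """

    def half_ulp(x: float) -> float:
        s = f"{x:.10g}"
        if "e" in s or "E" in s:
            mant, exp = s.split("e")
            dec = len(mant.split(".")[1]) if "." in mant else 0
            return 0.5 * 10.0 ** (int(exp) - dec)
        dec = len(s.split(".")[1]) if "." in s else 0
        return 0.5 * 10.0 ** (-dec)

    return (
        half_ulp(record.dissipation_rt)
        + half_ulp(record.flux) * record.force_rt
        + half_ulp(record.force_rt) * record.flux
    )


def dissipation_identity_error(record: ReactionRecord) -> float:
    """Relative error |phi_printed - J*X| / (J*X) of the product identity."""
    product = record.flux * record.force_rt
    return abs(record.dissipation_rt - product) / product


def export_records(
    records: list[ReactionRecord], path: str | Path, fmt: str | None = None
) -> None:
    """Export merged records to CSV/TSV/JSON (format inferred from suffix)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    frame = pd.DataFrame([asdict(r) for r in records])
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        path.write_text(json.dumps([asdict(r) for r in records], indent=1))
    else:
        raise ValueError(f"unsupported export format: {fmt}")
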