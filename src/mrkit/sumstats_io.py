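"""Reading, validating and writing GWAS summary-statistics tables.

Tables are tab-separated with a header row.  Column names follow the
GWAS-SSF field semantics by default (``rsid``, ``effect_allele``,
``other_allele``, ``effect_allele_frequency``, ``beta``, ``standard_error``,
``p_value``, ``n``); a user-supplied ``column_map`` accommodates other
dialects.  Internally every table is a :class:`pandas.DataFrame` with the
canonical columns ``variant_id, effect_allele, other_allele, eaf, beta, se,
pvalue, n``.

Variant identity is rsID only: the instruments are independent sentinel
variants named by rsID, so chromosomal coordinates are never consulted.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("mrkit")

CANONICAL_COLUMNS = [
    "variant_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Default file-column -> canonical-field mapping (GWAS-SSF names plus the
#: canonical names themselves, so our own output is always readable).
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "rsid": "variant_id",
    "variant_id": "variant_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "effect_allele_frequency": "eaf",
    "eaf": "eaf",
    "beta": "beta",
    "standard_error": "se",
    "se": "se",
    "p_value": "pvalue",
    "pvalue": "pvalue",
    "n": "n",
}

MANDATORY_FIELDS = ["variant_id", "effect_allele", "other_allele", "beta", "se", "pvalue"]

_ALLELE_RE = re.compile(r"^[ACGT]+$")

#: Tolerance (in log10 units) for the warning that a reported p-value is
#: inconsistent with the two-sided normal p implied by beta/se.
PVALUE_LOG10_TOL = 0.5


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's summary statistics for one trait.

    ``beta`` is the per-effect-allele association: SD units for a
    continuous exposure, log-odds for a binary outcome.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside [0, 1]")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue outside (0, 1]")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele identical")
        for a in (self.effect_allele, self.other_allele):
            if not _ALLELE_RE.match(a):
                raise ValueError(f"{self.variant_id}: invalid allele {a!r}")


@dataclass(frozen=True)
class InstrumentSet:
    """The instrumental variables selected for one exposure."""

    exposure_name: str
    variants: tuple[VariantAssociation, ...]
    significance_threshold: float
    unit: str = "SD"

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_ids in instrument set")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


@dataclass
class ProxyMap:
    """Sentinel rsID -> candidate (proxy rsID, r²) substitutions.

    Entries with r² below ``min_r2`` may be stored (a warning is emitted at
    construction) but are never used at that threshold by
    :func:`apply_proxies`.
    """

    entries: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    min_r2: float = 0.8

    def __post_init__(self) -> None:
        n_low = sum(
            1 for cands in self.entries.values() for _, r2 in cands if r2 < self.min_r2
        )
        if n_low:
            logger.warning(
                "ProxyMap holds %d entr%s below r2 = %g; they will not be used at that threshold",
                n_low,
                "y" if n_low == 1 else "ies",
                self.min_r2,
            )

    def candidates(self, sentinel: str) -> list[tuple[str, float]]:
        return self.entries.get(sentinel, [])


# ---------------------------------------------------------------------------
# reading / validation


def _rename(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    present = {src: dst for src, dst in cmap.items() if src in df.columns}
    df = df.rename(columns=present)
    missing = [f for f in MANDATORY_FIELDS if f not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    for opt in ("eaf", "n"):
        if opt not in df.columns:
            df[opt] = np.nan
    return df[CANONICAL_COLUMNS]


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Drop rows violating the per-variant invariants, logging the count.

    Also warns (never fails) when a reported p-value disagrees with the
    two-sided normal p implied by |beta/se| by more than
    ``PVALUE_LOG10_TOL`` orders of magnitude.
    """
    n_in = len(df)
    alleles_ok = df["effect_allele"].astype(str).str.match(_ALLELE_RE) & df[
        "other_allele"
    ].astype(str).str.match(_ALLELE_RE)
    ok = (
        df["se"].gt(0)
        & df["pvalue"].gt(0)
        & df["pvalue"].le(1)
        & (df["eaf"].isna() | (df["eaf"].ge(0) & df["eaf"].le(1)))
        & df["beta"].notna()
        & (df["effect_allele"].astype(str) != df["other_allele"].astype(str))
        & alleles_ok
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.warning("validate_table: dropped %d of %d rows failing invariants", dropped, n_in)
    out = df.loc[ok].reset_index(drop=True)

    with np.errstate(divide="ignore"):
        z = np.abs(out["beta"].to_numpy() / out["se"].to_numpy())
        implied = 2.0 * stats.norm.sf(z)
        lo = np.log10(np.maximum(implied, 5e-324))
        lp = np.log10(out["pvalue"].to_numpy())
    n_incons = int(np.sum(np.abs(lo - lp) > PVALUE_LOG10_TOL))
    if n_incons:
        logger.warning(
            "validate_table: %d row(s) have p-values inconsistent with beta/se "
            "beyond %.1f log10 units",
            n_incons,
            PVALUE_LOG10_TOL,
        )
    return out


def read_sumstats(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a tab-separated summary-statistics file into the canonical table.

    Rows failing the invariants are dropped with a logged count; an empty
    result is fatal.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, float_precision="round_trip")
    df = _rename(df, column_map)
    df["variant_id"] = df["variant_id"].astype(str)
    out = validate_table(df)
    if len(out) == 0:
        raise ValueError(f"{path}: no valid rows after validation")
    return out


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical table as TSV.

    Floats are written with repr-level precision (``%.17g``) so that a
    write/read round trip reproduces betas and SEs bit-identically.
    """
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_proxy_table(path, min_r2: float = 0.8) -> ProxyMap:
    """Read a 3-column TSV (sentinel, proxy, r2) into a :class:`ProxyMap`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    df.columns = [c.lower() for c in df.columns]
    entries: dict[str, list[tuple[str, float]]] = {}
    for sent, prox, r2 in df.itertuples(index=False):
        entries.setdefault(str(sent), []).append((str(prox), float(r2)))
    return ProxyMap(entries=entries, min_r2=min_r2)


def write_proxy_table(proxies: ProxyMap, path) -> None:
    rows = [
        {"sentinel": s, "proxy": p, "r2": r2}
        for s, cands in proxies.entries.items()
        for p, r2 in cands
    ]
    pd.DataFrame(rows, columns=["sentinel", "proxy", "r2"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# record <-> frame conversion


def records_from_frame(df: pd.DataFrame) -> list[VariantAssociation]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            VariantAssociation(
                variant_id=str(row.variant_id),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(row.pvalue),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                n=None if pd.isna(row.n) else float(row.n),
            )
        )
    return recs


def frame_from_records(records: Iterable[VariantAssociation]) -> pd.DataFrame:
    rows = [
        {
            "variant_id": v.variant_id,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "eaf": np.nan if v.eaf is None else v.eaf,
            "beta": v.beta,
            "se": v.se,
            "pvalue": v.pvalue,
            "n": np.nan if v.n is None else v.n,
        }
        for v in records
    ]
    return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# instrument selection and proxy substitution


def select_instruments(
    exposure_table: pd.DataFrame,
    p_threshold: float,
    exposure_name: str = "exposure",
    unit: str = "SD",
) -> InstrumentSet:
    """Keep the variants reaching genome-wide significance on the exposure.

    Instrument selection uses a strict ``pvalue < p_threshold`` cut except
    at ``p_threshold = 1.0``, where every valid variant is retained.
    """
    if p_threshold >= 1.0:
        kept = exposure_table
    else:
        kept = exposure_table.loc[exposure_table["pvalue"] < p_threshold]
    if len(kept) == 0:
        raise ValueError(
            f"no variants pass the significance threshold p < {p_threshold:g} "
            f"for exposure {exposure_name!r}"
        )
    logger.info(
        "select_instruments(%s): %d of %d variants pass p < %g",
        exposure_name,
        len(kept),
        len(exposure_table),
        p_threshold,
    )
    return InstrumentSet(
        exposure_name=exposure_name,
        variants=tuple(records_from_frame(kept)),
        significance_threshold=p_threshold,
        unit=unit,
    )


def apply_proxies(
    instruments: InstrumentSet,
    outcome_table: pd.DataFrame,
    proxies: ProxyMap | None = None,
    r2_min: float = 0.8,
) -> tuple[InstrumentSet, list[str], list[str]]:
    """Substitute LD proxies for instruments missing from the outcome table.

    A sentinel absent from the outcome table is replaced by the candidate
    proxy with the highest r² at or above ``r2_min`` that is itself present
    in the outcome table; with no such candidate the sentinel is dropped.
    The substituted record keeps the sentinel's exposure statistics but takes
    the proxy rsID, so downstream joins against the outcome table succeed.

    Returns ``(retained_set, dropped_ids, substituted_ids)`` with
    ``len(in) == len(out) + len(dropped)``.
    """
    if not (0.0 < r2_min <= 1.0):
        raise ValueError("r2_min must lie in (0, 1]")
    out_ids = set(outcome_table["variant_id"].astype(str))
    retained: list[VariantAssociation] = []
    dropped: list[str] = []
    substituted: list[str] = []
    for v in instruments.variants:
        if v.variant_id in out_ids:
            retained.append(v)
            continue
        cands = [
            (p, r2)
            for p, r2 in (proxies.candidates(v.variant_id) if proxies else [])
            if r2 >= r2_min and p in out_ids and p not in {r.variant_id for r in retained}
        ]
        if cands:
            best = max(cands, key=lambda pr: (pr[1], pr[0]))
            retained.append(replace(v, variant_id=best[0]))
            substituted.append(v.variant_id)
            logger.info(
                "apply_proxies: %s -> proxy %s (r2 = %g)", v.variant_id, best[0], best[1]
            )
        else:
            dropped.append(v.variant_id)
            logger.info("apply_proxies: %s dropped (no proxy with r2 >= %g)", v.variant_id, r2_min)
    logger.info(
        "apply_proxies(%s): %d in = %d retained (%d via proxy) + %d dropped",
        instruments.exposure_name,
        len(instruments),
        len(retained),
        len(substituted),
        len(dropped),
    )
    new_set = InstrumentSet(
        exposure_name=instruments.exposure_name,
        variants=tuple(retained),
        significance_threshold=instruments.significance_threshold,
        unit=instruments.unit,
    )
    return new_set, dropped, substituted
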