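"""Align outcome summary statistics to the exposure's effect allele.

Every estimator consumes pairs (γ̂_j, σ_Xj, Γ̂_j, σ_Yj): the variant's effect
on the exposure (per SD) and on the outcome (log-odds), both expressed for
the same effect allele.  Because the two GWAS may report a variant with
effect/other alleles in either order or on opposite strands, the outcome
record must first be reconciled with the exposure record.

Palindromic variants (A/T or C/G) cannot be strand-resolved from allele
labels alone.  The default policy infers the orientation from the effect
allele frequencies when both are far from 0.5 (outside 0.5 ± ``eaf_window``)
and drops the variant otherwise; ``keep`` trusts labels as reported and
``drop`` always discards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import pandas as pd

from .sumstats_io import InstrumentSet, VariantAssociation

logger = logging.getLogger("mrkit")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PalindromicPolicy = Literal["drop", "infer_by_eaf", "keep"]

#: EAF must be outside [0.5 - window, 0.5 + window] on BOTH traits for a
#: palindromic variant's strand to be inferred from frequency.
DEFAULT_EAF_WINDOW = 0.08


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in allele)


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G variants look identical on both strands."""
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Aligned per-variant effect pair; ``action`` audits the transformation.

    Numeric transformations by action: ``unchanged`` and ``allele_swapped``
    (strand complement, same orientation) leave the outcome beta as
    reported; ``sign_flipped`` negates it and complements the outcome EAF;
    ``palindromic_resolved`` applies whichever of those the frequency rule
    selected (recorded sign is auditable from gamma/Gamma and the inputs).
    """

    variant_id: str
    gamma: float       # exposure beta, per SD
    sigma_x: float     # exposure SE
    Gamma: float       # outcome beta, log-odds
    sigma_y: float     # outcome SE
    action: str

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError(f"{self.variant_id}: standard errors must be > 0")


@dataclass(frozen=True)
class DroppedVariant:
    variant_id: str
    reason: str


@dataclass(frozen=True)
class HarmonizedSet:
    exposure_name: str
    outcome_name: str
    instruments: tuple[HarmonizedInstrument, ...]
    dropped: tuple[DroppedVariant, ...] = ()

    def __post_init__(self) -> None:
        ids = [i.variant_id for i in self.instruments]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant_ids in harmonized set")

    def __len__(self) -> int:
        return len(self.instruments)

    def subset(self, keep_ids) -> "HarmonizedSet":
        keep = set(keep_ids)
        return replace(
            self,
            instruments=tuple(i for i in self.instruments if i.variant_id in keep),
        )

    def without(self, drop_ids, reason: str = "removed") -> "HarmonizedSet":
        drop = set(drop_ids)
        return HarmonizedSet(
            exposure_name=self.exposure_name,
            outcome_name=self.outcome_name,
            instruments=tuple(i for i in self.instruments if i.variant_id not in drop),
            dropped=self.dropped
            + tuple(DroppedVariant(v, reason) for v in sorted(drop)),
        )


def harmonize_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindromic_policy: PalindromicPolicy = "infer_by_eaf",
    eaf_window: float = DEFAULT_EAF_WINDOW,
) -> HarmonizedInstrument | DroppedVariant:
    """Harmonize one variant's outcome record onto the exposure's alleles."""
    if exposure.variant_id != outcome.variant_id:
        raise ValueError("harmonize_pair requires matching variant_ids")
    vid = exposure.variant_id
    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele

    def _result(Gamma: float, action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            variant_id=vid,
            gamma=exposure.beta,
            sigma_x=exposure.se,
            Gamma=Gamma,
            sigma_y=outcome.se,
            action=action,
        )

    if is_palindromic(e_ea, e_oa):
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return DroppedVariant(vid, "allele_mismatch")
        # label-align first (swap is indistinguishable from strand flip here,
        # so labels only fix which number we start from)
        if o_ea == e_ea:
            beta_aligned, eaf_aligned = outcome.beta, outcome.eaf
        else:
            beta_aligned = -outcome.beta
            eaf_aligned = None if outcome.eaf is None else 1.0 - outcome.eaf
        if palindromic_policy == "drop":
            return DroppedVariant(vid, "palindromic_dropped")
        if palindromic_policy == "keep":
            return _result(beta_aligned, "palindromic_resolved")
        # infer_by_eaf
        lo, hi = 0.5 - eaf_window, 0.5 + eaf_window
        if (
            exposure.eaf is None
            or eaf_aligned is None
            or lo <= exposure.eaf <= hi
            or lo <= eaf_aligned <= hi
        ):
            return DroppedVariant(vid, "palindromic_dropped")
        if (exposure.eaf < 0.5) == (eaf_aligned < 0.5):
            return _result(beta_aligned, "palindromic_resolved")
        # frequencies disagree: outcome reported the opposite strand's allele
        return _result(-beta_aligned, "palindromic_resolved")

    if (o_ea, o_oa) == (e_ea, e_oa):
        return _result(outcome.beta, "unchanged")
    if (o_ea, o_oa) == (e_oa, e_ea):
        return _result(-outcome.beta, "sign_flipped")
    c_ea, c_oa = _complement(o_ea), _complement(o_oa)
    if (c_ea, c_oa) == (e_ea, e_oa):
        return _result(outcome.beta, "allele_swapped")
    if (c_ea, c_oa) == (e_oa, e_ea):
        return _result(-outcome.beta, "sign_flipped")
    return DroppedVariant(vid, "allele_mismatch")


def harmonize_set(
    instruments: InstrumentSet,
    outcome_table: pd.DataFrame,
    outcome_name: str = "outcome",
    palindromic_policy: PalindromicPolicy = "infer_by_eaf",
    eaf_window: float = DEFAULT_EAF_WINDOW,
) -> HarmonizedSet:
    """Harmonize every instrument against the outcome table.

    Instruments absent from the outcome table are dropped with reason
    ``missing_in_outcome`` (run :func:`mrkit.sumstats_io.apply_proxies`
    first to rescue them via LD proxies).
    """
    from .sumstats_io import records_from_frame

    by_id = {
        r.variant_id: r
        for r in records_from_frame(
            outcome_table.loc[
                outcome_table["variant_id"].astype(str).isin(instruments.variant_ids)
            ]
        )
    }
    kept: list[HarmonizedInstrument] = []
    dropped: list[DroppedVariant] = []
    for v in instruments.variants:
        out = by_id.get(v.variant_id)
        if out is None:
            dropped.append(DroppedVariant(v.variant_id, "missing_in_outcome"))
            continue
        res = harmonize_pair(v, out, palindromic_policy, eaf_window)
        if isinstance(res, DroppedVariant):
            dropped.append(res)
        else:
            kept.append(res)
    logger.info(
        "harmonize_set(%s ~ %s): %d in = %d harmonized + %d dropped",
        instruments.exposure_name,
        outcome_name,
        len(instruments),
        len(kept),
        len(dropped),
    )
    return HarmonizedSet(
        exposure_name=instruments.exposure_name,
        outcome_name=outcome_name,
        instruments=tuple(kept),
        dropped=tuple(dropped),
    )


def orient_positive(hset: HarmonizedSet) -> HarmonizedSet:
    """Recode instruments so every γ̂_j ≥ 0 (flip both signs where needed).

    MR-Egger's intercept depends on instrument orientation; the convention
    is to point every instrument at the exposure-increasing allele before
    the regression.  Ratio-based estimators are orientation-invariant and
    do not need this.
    """
    flipped = tuple(
        i if i.gamma >= 0 else replace(i, gamma=-i.gamma, Gamma=-i.Gamma)
        for i in hset.instruments
    )
    return replace(hset, instruments=flipped)


# ---------------------------------------------------------------------------
# harmonized-table I/O (TSV columns: variant_id, gamma, sigma_x, Gamma,
# sigma_y, action)

HARMONIZED_COLUMNS = ["variant_id", "gamma", "sigma_x", "Gamma", "sigma_y", "action"]


def write_harmonized(hset: HarmonizedSet, path) -> None:
    rows = [
        {
            "variant_id": i.variant_id,
            "gamma": i.gamma,
            "sigma_x": i.sigma_x,
            "Gamma": i.Gamma,
            "sigma_y": i.sigma_y,
            "action": i.action,
        }
        for i in hset.instruments
    ]
    pd.DataFrame(rows, columns=HARMONIZED_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_harmonized(
    path, exposure_name: str = "exposure", outcome_name: str = "outcome"
) -> HarmonizedSet:
    df = pd.read_csv(
        path, sep="\t", dtype={"variant_id": str}, float_precision="round_trip"
    )
    instruments = tuple(
        HarmonizedInstrument(
            variant_id=str(r.variant_id),
            gamma=float(r.gamma),
            sigma_x=float(r.sigma_x),
            Gamma=float(r.Gamma),
            sigma_y=float(r.sigma_y),
            action=str(r.action),
        )
        for r in df.itertuples(index=False)
    )
    return HarmonizedSet(
        exposure_name=exposure_name, outcome_name=outcome_name, instruments=instruments
    )
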