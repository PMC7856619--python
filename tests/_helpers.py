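"""Shared constructors for test instrument sets."""

from __future__ import annotations

import numpy as np

from mrkit.harmonize import HarmonizedInstrument, HarmonizedSet
from mrkit.simulate import SimulatedStudy


def hset_from_arrays(
    gamma,
    sigma_x,
    Gamma,
    sigma_y,
    ids=None,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    gamma = np.asarray(gamma, dtype=float)
    sigma_x = np.broadcast_to(np.asarray(sigma_x, dtype=float), gamma.shape)
    Gamma = np.asarray(Gamma, dtype=float)
    sigma_y = np.broadcast_to(np.asarray(sigma_y, dtype=float), gamma.shape)
    if ids is None:
        ids = [f"rs{i + 1:07d}" for i in range(len(gamma))]
    instruments = tuple(
        HarmonizedInstrument(
            variant_id=str(v),
            gamma=float(g),
            sigma_x=float(sx),
            Gamma=float(G),
            sigma_y=float(sy),
            action="unchanged",
        )
        for v, g, sx, G, sy in zip(ids, gamma, sigma_x, Gamma, sigma_y)
    )
    return HarmonizedSet(
        exposure_name=exposure_name, outcome_name=outcome_name, instruments=instruments
    )


def hset_from_study(study: SimulatedStudy) -> HarmonizedSet:
    """Pair the simulated tables directly (their alleles are identical by
    construction, so harmonization is the identity)."""
    e, o = study.exposure, study.outcome
    return hset_from_arrays(
        e["beta"].to_numpy(),
        e["se"].to_numpy(),
        o["beta"].to_numpy(),
        o["se"].to_numpy(),
        ids=e["variant_id"].tolist(),
    )
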