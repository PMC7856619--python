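"""End-to-end analysis over exposure/outcome pairs.

For each pair the pipeline runs the sequence: read and validate the two
tables → select genome-wide significant instruments → substitute LD
proxies for instruments missing from the outcome → harmonize alleles →
IVW main analysis → leave-one-out influence analysis → if any variant is
flagged, remove the flagged variants and re-run the whole estimator and
diagnostic suite exactly once → sensitivity estimators (MR-Egger,
weighted median, weighted mode) → heterogeneity and Egger-intercept
tests → funnel data.  Benjamini–Hochberg q-values are computed across the
plan's primary (all-variant) IVW tests only; sensitivity estimates are
reported unadjusted.

Output formatting mirrors the conventional report layout: ORs and CIs to
two decimals, p-values in scientific notation below 1e-3, full-precision
log-scale columns alongside.  Runs are deterministic given the plan seed:
re-running an identical plan reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics as diag
from . import estimators as est
from .harmonize import HarmonizedSet, harmonize_set
from .sumstats_io import apply_proxies, read_proxy_table, read_sumstats, select_instruments

logger = logging.getLogger("mrkit")

DEFAULT_OPTIONS = {
    "p_threshold": 5e-8,
    "r2_min": 0.8,
    "palindromic_policy": "infer_by_eaf",
    "eaf_window": 0.08,
    "n_boot": 1000,
    "phi": 1.0,
    "flag_rule": 1.0,
    "ivw_model": "multiplicative_random",
}


@dataclass(frozen=True)
class PairSpec:
    name: str
    exposure: str
    outcome: str
    proxies: str | None = None
    p_threshold: float | None = None  # overrides the plan-level option


@dataclass(frozen=True)
class AnalysisPlan:
    pairs: tuple[PairSpec, ...]
    seed: int
    output_dir: str
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("analysis plan contains no exposure/outcome pairs")
        names = [p.name for p in self.pairs]
        if len(names) != len(set(names)):
            raise ValueError("pair names must be unique")

    def resolved_options(self) -> dict:
        return {**DEFAULT_OPTIONS, **self.options}


@dataclass
class PairResult:
    name: str
    estimates: pd.DataFrame
    heterogeneity: pd.DataFrame
    intercepts: pd.DataFrame
    loo: pd.DataFrame
    funnel: pd.DataFrame
    accounting: dict
    flagged: tuple[str, ...]


@dataclass
class AnalysisReport:
    pairs: dict[str, PairResult]
    fdr: pd.DataFrame
    provenance: dict
    failures: dict[str, str]


def load_plan(path) -> AnalysisPlan:
    """Load a YAML analysis plan.

    Structure::

        seed: 1
        output_dir: results/
        options: {n_boot: 1000, flag_rule: 1.0}
        pairs:
          - name: bmi_severe
            exposure: bmi.exposure.tsv
            outcome: severe.outcome.tsv
            proxies: proxies.tsv      # optional
            p_threshold: 1.0e-8       # optional override
    """
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent

    def _resolve(p):
        return str(p) if p is None or Path(p).is_absolute() else str(base / p)

    pairs = tuple(
        PairSpec(
            name=d["name"],
            exposure=_resolve(d["exposure"]),
            outcome=_resolve(d["outcome"]),
            proxies=_resolve(d["proxies"]) if d.get("proxies") else None,
            p_threshold=d.get("p_threshold"),
        )
        for d in raw.get("pairs", [])
    )
    if "seed" not in raw:
        raise ValueError("plan must set an explicit seed (bootstrap methods require it)")
    plan = AnalysisPlan(
        pairs=pairs,
        seed=int(raw["seed"]),
        output_dir=_resolve(raw.get("output_dir", "mr_results")),
        options=raw.get("options", {}),
    )
    for p in plan.pairs:
        for f in (p.exposure, p.outcome, p.proxies):
            if f is not None and not Path(f).exists():
                raise FileNotFoundError(f"plan references missing file: {f}")
    return plan


# ---------------------------------------------------------------------------
# formatting helpers (Table-style: OR/CI 2 d.p., P scientific below 1e-3)


def format_p(p: float) -> str:
    # two decimals down to 0.01, scientific below (the conventional table style)
    return f"{p:.1e}" if p < 0.01 else f"{p:.2f}"


def _est_row(e: est.MREstimate, subset: str) -> dict:
    return {
        "method": e.method,
        "subset": subset,
        "n_variants": e.n_variants,
        "OR": f"{e.odds_ratio:.2f}",
        "ci_low": f"{e.or_ci_low:.2f}",
        "ci_high": f"{e.or_ci_high:.2f}",
        "P": format_p(e.pvalue),
        "log_beta": f"{e.beta:.10g}",
        "log_se": f"{e.se:.10g}",
        "log_ci_low": f"{e.ci_low:.10g}",
        "log_ci_high": f"{e.ci_high:.10g}",
        "pvalue": f"{e.pvalue:.10g}",
    }


def _het_row(h: diag.HeterogeneityResult, subset: str) -> dict:
    return {
        "subset": subset,
        "method": "Inverse variance weighted" if h.method == "IVW" else "MR-Egger",
        "Q": f"{h.Q:.3f}",
        "df": h.df,
        "P": format_p(h.pvalue),
    }


def _pair_seed(plan_seed: int, pair_name: str) -> int:
    return int(
        np.random.SeedSequence([plan_seed, zlib.crc32(pair_name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def _analyse_instruments(
    hset: HarmonizedSet, subset: str, opts: dict, seed: int
) -> tuple[list[dict], list[dict], list[dict], est.MREstimate]:
    """All four estimators + heterogeneity + intercept rows for one subset."""
    ivw_fit = est.ivw(hset, model=opts["ivw_model"])
    egger_fit = est.egger(hset)
    med = est.weighted_median(hset, n_boot=opts["n_boot"], seed=seed)
    mode = est.weighted_mode(hset, phi=opts["phi"], n_boot=opts["n_boot"], seed=seed + 1)
    est_rows = [_est_row(e, subset) for e in (ivw_fit, egger_fit, med, mode)]
    het_rows = [
        _het_row(diag.cochran_q(hset, ivw_fit.beta), subset),
        _het_row(diag.rucker_q(hset, egger_fit), subset),
    ]
    it = diag.intercept_test(egger_fit)
    int_rows = [
        {
            "subset": subset,
            "intercept": f"{it.intercept:.3f}",
            "se": f"{it.se:.3f}",
            "P": format_p(it.pvalue),
        }
    ]
    return est_rows, het_rows, int_rows, ivw_fit


def _run_pair(pair: PairSpec, opts: dict, seed: int) -> PairResult:
    p_thr = pair.p_threshold if pair.p_threshold is not None else opts["p_threshold"]
    exposure = read_sumstats(pair.exposure)
    outcome = read_sumstats(pair.outcome)
    iset = select_instruments(exposure, p_thr, exposure_name=pair.name)
    n_selected = len(iset)
    proxy_dropped: list[str] = []
    substituted: list[str] = []
    if pair.proxies:
        proxies = read_proxy_table(pair.proxies, min_r2=opts["r2_min"])
        iset, proxy_dropped, substituted = apply_proxies(
            iset, outcome, proxies, r2_min=opts["r2_min"]
        )
    hset = harmonize_set(
        iset,
        outcome,
        outcome_name=pair.name,
        palindromic_policy=opts["palindromic_policy"],
        eaf_window=opts["eaf_window"],
    )
    n_harmonized = len(hset)

    est_rows, het_rows, int_rows, ivw_all = _analyse_instruments(
        hset, "all_variants", opts, seed
    )

    loo = diag.leave_one_out(hset, est.ivw, model=opts["ivw_model"])
    flags = diag.flag_outliers(loo, rule=opts["flag_rule"])
    loo_frames = [loo.table.assign(subset="all_variants")]
    if flags.flagged:
        # single removal-and-refit pass, never iterated
        hset2 = hset.without(flags.flagged, reason="outlier_removed")
        subset2 = "outliers_removed"
        r2 = _analyse_instruments(hset2, subset2, opts, seed)
        est_rows += r2[0]
        het_rows += r2[1]
        int_rows += r2[2]
        loo2 = diag.leave_one_out(hset2, est.ivw, model=opts["ivw_model"])
        loo_frames.append(loo2.table.assign(subset=subset2))

    ratios = est.wald_ratios(hset)
    funnel = diag.funnel_data(ratios, {"IVW": ivw_all.beta}).to_frame()

    accounting = {
        "selected": n_selected,
        "proxy_substituted": len(substituted),
        "proxy_dropped": len(proxy_dropped),
        "harmonization_dropped": n_selected - len(proxy_dropped) - n_harmonized,
        "harmonized": n_harmonized,
        "outliers_removed": len(flags.flagged),
        "final": n_harmonized - len(flags.flagged),
    }
    logger.info("run_plan(%s): accounting %s", pair.name, accounting)

    loo_all = pd.concat(loo_frames, ignore_index=True)
    for c in ("beta", "se", "ci_low", "ci_high"):
        loo_all[c] = loo_all[c].map(lambda v: f"{v:.10g}")
    funnel_fmt = funnel.copy()
    for c in ("ratio", "precision"):
        funnel_fmt[c] = funnel_fmt[c].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")

    return PairResult(
        name=pair.name,
        estimates=pd.DataFrame(est_rows),
        heterogeneity=pd.DataFrame(het_rows),
        intercepts=pd.DataFrame(int_rows),
        loo=loo_all,
        funnel=funnel_fmt,
        accounting=accounting,
        flagged=flags.flagged,
    )


def run_plan(plan: AnalysisPlan, write: bool = True) -> AnalysisReport:
    """Execute every pair of the plan; see the module docstring for the
    per-pair sequence.  Estimator precondition failures abort the affected
    pair only; ``report.failures`` records them and the CLI exits nonzero.
    """
    opts = plan.resolved_options()
    results: dict[str, PairResult] = {}
    failures: dict[str, str] = {}
    for pair in plan.pairs:
        try:
            results[pair.name] = _run_pair(pair, opts, _pair_seed(plan.seed, pair.name))
        except (ValueError, FileNotFoundError, KeyError) as exc:
            logger.error("pair %s aborted: %s", pair.name, exc)
            failures[pair.name] = str(exc)

    # FDR family: the primary (all-variant) IVW test of each completed pair
    fdr_rows = []
    for name, res in results.items():
        row = res.estimates.query("method == 'IVW' and subset == 'all_variants'").iloc[0]
        fdr_rows.append({"pair": name, "pvalue": float(row["pvalue"])})
    fdr = pd.DataFrame(fdr_rows)
    if len(fdr):
        q = diag.fdr_adjust(fdr["pvalue"].to_numpy())
        fdr["qvalue"] = [f"{v:.10g}" for v in q]
        fdr["pvalue"] = fdr["pvalue"].map(lambda v: f"{v:.10g}")

    config_digest = hashlib.sha256(
        json.dumps(
            {
                "seed": plan.seed,
                "options": opts,
                "pairs": [pair.name for pair in plan.pairs],
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    try:
        pkg_version = version("mrkit")
    except PackageNotFoundError:  # pragma: no cover
        pkg_version = "unknown"
    provenance = {
        "config_sha256": config_digest,
        "seed": plan.seed,
        "package": "mrkit",
        "version": pkg_version,
        "options": opts,
        "accounting": {name: res.accounting for name, res in sorted(results.items())},
        "failures": failures,
    }

    report = AnalysisReport(pairs=results, fdr=fdr, provenance=provenance, failures=failures)
    if write:
        write_report(report, plan.output_dir)
    return report


def write_report(report: AnalysisReport, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, res in report.pairs.items():
        pdir = out / name
        pdir.mkdir(exist_ok=True)
        res.estimates.to_csv(pdir / "estimates.tsv", sep="\t", index=False)
        res.heterogeneity.to_csv(pdir / "heterogeneity.tsv", sep="\t", index=False)
        res.intercepts.to_csv(pdir / "intercepts.tsv", sep="\t", index=False)
        res.loo.to_csv(pdir / "loo.tsv", sep="\t", index=False)
        res.funnel.to_csv(pdir / "funnel.tsv", sep="\t", index=False)
    report.fdr.to_csv(out / "fdr.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=1, sort_keys=True) + "\n"
    )
    logger.info("write_report: outputs under %s", out)
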