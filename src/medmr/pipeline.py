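"""Orchestration of the full two-step mediation-MR decision procedure.

The study design this package automates proceeds in four gated stages:

1. **Forward screen** — for each candidate exposure, select instruments,
   harmonize against the outcome, run the five MR estimators plus
   sensitivity diagnostics, and pick the primary method: MR-Egger when its
   intercept test indicates directional pleiotropy (p < 0.05), IVW
   otherwise.
2. **Mediator screen** — the same forward screen over the metabolite
   battery, followed by BH FDR over the primary p-values and the joint
   rule p < 0.05 AND q < 0.2.  (The exposure screen is deliberately *not*
   FDR-corrected; only the large metabolite family is.)
3. **Reverse MR** — instruments are drawn from the *outcome* GWAS at a
   relaxed threshold (default 5e-6) and tested against each mediator;
   mediators the outcome influences (IVW p < 0.05) are excluded as
   reverse-causal.
4. **Two-step mediation** — β1 (exposure→outcome), β2 (exposure→mediator)
   and β3 (mediator→outcome), each by the primary-method rule, combined
   into a proportion mediated; chains whose indirect effect opposes the
   total effect are carried but flagged inconsistent.

Exposures yielding fewer than three usable instruments are reported as
underpowered (IVW still runs at two; a single instrument falls back to the
Wald ratio), never dropped silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from ._version import __version__
from .errors import EmptyIntersectionError, InsufficientInstrumentsError
from .harmonize import HarmonizedSet, harmonize
from .instruments import LDMatrix, build_instruments
from .mediation import MediationEstimate, proportion_mediated
from .mr_core import (
    MREstimate,
    cochran_q,
    ivw,
    leave_one_out,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from .multiple_testing import bh_fdr, joint_significance
from .summary_stats import SummaryStatsTable


class AnalysisConfig(BaseModel):
    """All thresholds and seeds of the decision procedure."""

    model_config = ConfigDict(frozen=True)

    p_threshold_forward: float = Field(default=1e-5, gt=0, le=1)
    p_threshold_reverse: float = Field(default=5e-6, gt=0, le=1)
    r2_threshold: float = Field(default=0.001, ge=0, le=1)
    window_kb: int = Field(default=10000, ge=0)
    min_F: float = Field(default=10.0, ge=0)
    fdr_q_max: float = Field(default=0.2, gt=0, le=1)
    p_max: float = Field(default=0.05, gt=0, le=1)
    egger_intercept_alpha: float = Field(default=0.05, gt=0, le=1)
    reverse_alpha: float = Field(default=0.05, gt=0, le=1)
    palindrome_policy: str = "drop_ambiguous"
    eaf_window: float = Field(default=0.08, ge=0, le=0.5)
    n_boot: int = Field(default=1000, ge=10)
    seed: int = 1


def choose_primary_method(ivw_est: MREstimate, egger_est: MREstimate,
                          intercept_pval: float, alpha: float = 0.05) -> str:
    """``"egger"`` when the intercept test fires (p < alpha, strict), else ``"ivw"``."""
    return "egger" if intercept_pval < alpha else "ivw"


def _harmonized_instruments(exposure, outcome, ld, config) -> tuple:
    """Instrument selection then harmonization; returns (HarmonizedSet, InstrumentSet)."""
    inst = build_instruments(
        exposure, ld,
        p_threshold=config.p_threshold_forward,
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
        min_F=config.min_F,
    )
    if len(inst) == 0:
        return None, inst
    try:
        h = harmonize(inst.table, outcome,
                      palindrome_policy=config.palindrome_policy,
                      eaf_window=config.eaf_window)
    except EmptyIntersectionError:
        return None, inst
    return h, inst


def _primary_estimate(h: HarmonizedSet, config: AnalysisConfig):
    """Apply the primary-method rule, degrading gracefully when underpowered.

    Returns a dict with the chosen estimate, its label, the Egger block
    (when computable) and an ``underpowered`` flag.
    """
    n = h.n_snp
    out = {
        "n_snp": n, "underpowered": n < 3, "method": None, "estimate": None,
        "ivw": None, "egger": None, "intercept": np.nan,
        "intercept_se": np.nan, "intercept_pval": np.nan,
        "q": np.nan, "q_df": 0, "q_pval": np.nan,
    }
    if n == 0:
        return out
    frame = h.mr_frame
    if n == 1:
        r = frame.iloc[0]
        est = wald_ratio(r["beta_exp"], r["se_exp"], r["beta_out"], r["se_out"])
        out.update(method="wald_ratio", estimate=est, ivw=est)
        return out
    ivw_est = ivw(h)
    out["ivw"] = ivw_est
    q, q_df, q_p = cochran_q(h)
    out.update(q=q, q_df=q_df, q_pval=q_p)
    if n < 3:
        out.update(method="ivw", estimate=ivw_est)
        return out
    egger = mr_egger(h)
    out.update(egger=egger.slope, intercept=egger.intercept,
               intercept_se=egger.intercept_se, intercept_pval=egger.intercept_pval)
    label = choose_primary_method(ivw_est, egger.slope, egger.intercept_pval,
                                  alpha=config.egger_intercept_alpha)
    out.update(method=label, estimate=egger.slope if label == "egger" else ivw_est)
    return out


def _screen_row(label: str, prim: dict, extra: dict | None = None) -> dict:
    est = prim["estimate"]
    row = {
        "exposure": label,
        "status": "underpowered" if prim["underpowered"] else "ok",
        "n_snp": prim["n_snp"],
        "primary_method": prim["method"],
        "beta": est.beta if est else np.nan,
        "se": est.se if est else np.nan,
        "pval": est.pval if est else np.nan,
        "or": est.or_point if est else np.nan,
        "or_lci": est.or_ci_low if est else np.nan,
        "or_uci": est.or_ci_high if est else np.nan,
        "q": prim["q"],
        "q_pval": prim["q_pval"],
        "egger_intercept": prim["intercept"],
        "egger_intercept_pval": prim["intercept_pval"],
    }
    row.update(extra or {})
    return row


def run_forward_screen(
    exposures: list,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: AnalysisConfig,
    all_methods: bool = True,
) -> pd.DataFrame:
    """One row per exposure: primary estimate, diagnostics, and (optionally)
    the weighted-median and mode supplements."""
    rows = []
    for k, exposure in enumerate(exposures):
        h, inst = _harmonized_instruments(exposure, outcome, ld, config)
        if h is None:
            rows.append(_screen_row(exposure.trait_label, {
                "n_snp": 0, "underpowered": True, "method": None, "estimate": None,
                "intercept": np.nan, "intercept_pval": np.nan,
                "q": np.nan, "q_pval": np.nan,
            }, {"n_selected": len(inst)}))
            continue
        prim = _primary_estimate(h, config)
        extra = {"n_selected": len(inst)}
        if all_methods and h.n_snp >= 3:
            seed = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0] % (2**31))
            wm = weighted_median(h, n_boot=config.n_boot, seed=seed)
            smode = mode_estimate(h, weighted=False, n_boot=config.n_boot, seed=seed)
            wmode = mode_estimate(h, weighted=True, n_boot=config.n_boot, seed=seed)
            extra.update(
                wm_beta=wm.beta, wm_se=wm.se, wm_pval=wm.pval,
                simple_mode_beta=smode.beta, simple_mode_pval=smode.pval,
                weighted_mode_beta=wmode.beta, weighted_mode_pval=wmode.pval,
            )
        rows.append(_screen_row(exposure.trait_label, prim, extra))
    cols = ["exposure", "status", "n_selected", "n_snp", "primary_method", "beta",
            "se", "pval", "or", "or_lci", "or_uci", "q", "q_pval",
            "egger_intercept", "egger_intercept_pval"]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=cols)
    ordered = [c for c in cols if c in df.columns] + [c for c in df.columns if c not in cols]
    return df[ordered]


def run_metabolite_screen(
    metabolites: list,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: AnalysisConfig,
    all_methods: bool = False,
) -> pd.DataFrame:
    """Forward screen over the metabolite battery + FDR + joint rule.

    q-values are computed over every metabolite that produced a primary
    p-value (the whole battery enters the family).
    """
    df = run_forward_screen(metabolites, outcome, ld, config, all_methods=all_methods)
    df["qval"] = np.nan
    df["significant"] = False
    tested = df["pval"].notna()
    if tested.any():
        q = bh_fdr(df.loc[tested, "pval"].to_numpy())
        df.loc[tested, "qval"] = q
        df.loc[tested, "significant"] = joint_significance(
            df.loc[tested, "pval"].to_numpy(), q, p_max=config.p_max, q_max=config.fdr_q_max
        )
    return df


def run_reverse_mr(
    outcome_as_exposure: SummaryStatsTable,
    targets: list,
    ld: LDMatrix,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Test whether the outcome causally shifts each target (reverse causality).

    Instruments come from the outcome GWAS at ``p_threshold_reverse``; each
    target is flagged when IVW p < ``reverse_alpha``.  Targets that cannot
    be tested (too few instruments) are retained with a warning status.
    """
    inst = build_instruments(
        outcome_as_exposure, ld,
        p_threshold=config.p_threshold_reverse,
        r2_threshold=config.r2_threshold,
        window_kb=config.window_kb,
        min_F=config.min_F,
    )
    rows = []
    for target in targets:
        row = {"target": target.trait_label, "n_snp": 0, "beta": np.nan,
               "se": np.nan, "pval": np.nan, "reverse_causal": False,
               "status": "ok"}
        if len(inst) == 0:
            row["status"] = "no_instruments"
            rows.append(row)
            continue
        try:
            h = harmonize(inst.table, target,
                          palindrome_policy=config.palindrome_policy,
                          eaf_window=config.eaf_window)
        except EmptyIntersectionError:
            row["status"] = "no_overlap"
            rows.append(row)
            continue
        row["n_snp"] = h.n_snp
        if h.n_snp < 2:
            row["status"] = "insufficient_instruments"
            rows.append(row)
            continue
        est = ivw(h)
        row.update(beta=est.beta, se=est.se, pval=est.pval,
                   reverse_causal=bool(est.pval < config.reverse_alpha))
        rows.append(row)
    return pd.DataFrame(rows)


def run_two_step(
    exposure: SummaryStatsTable,
    mediators: list,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Two-step mediation over mediators that already passed both screens.

    β1, β2 and β3 each come from the primary-method rule on their own
    instrument set; the proportion mediated uses the own-SE uncertainty
    pairing (the delta-method variant is reported alongside).
    """
    h1, _ = _harmonized_instruments(exposure, outcome, ld, config)
    if h1 is None:
        raise InsufficientInstrumentsError(
            f"no usable instruments for exposure {exposure.trait_label!r}"
        )
    p1 = _primary_estimate(h1, config)
    est1 = p1["estimate"]

    rows = []
    for mediator in mediators:
        h2, _ = _harmonized_instruments(exposure, mediator, ld, config)
        h3, _ = _harmonized_instruments(mediator, outcome, ld, config)
        if h2 is None or h3 is None:
            rows.append({"mediator": mediator.trait_label, "status": "underpowered"})
            continue
        p2 = _primary_estimate(h2, config)
        p3 = _primary_estimate(h3, config)
        est2, est3 = p2["estimate"], p3["estimate"]
        med = proportion_mediated(est1.beta, est2.beta, est3.beta,
                                  est2.se, est3.se, formula="own_se", se1=est1.se)
        med_delta = proportion_mediated(est1.beta, est2.beta, est3.beta,
                                        est2.se, est3.se, formula="delta", se1=est1.se)
        rows.append({
            "mediator": mediator.trait_label,
            "status": "ok",
            "beta1": est1.beta, "se1": est1.se, "method1": p1["method"],
            "beta2": est2.beta, "se2": est2.se, "method2": p2["method"],
            "beta3": est3.beta, "se3": est3.se, "method3": p3["method"],
            "indirect": med.indirect,
            "proportion": med.proportion,
            "ci_low": med.ci_low, "ci_high": med.ci_high,
            "ci_low_delta": med_delta.ci_low, "ci_high_delta": med_delta.ci_high,
            "consistent": med.consistent, "code": med.code,
        })
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Complete, reproducible output of one pipeline run."""

    config: AnalysisConfig
    forward: pd.DataFrame
    metabolites: pd.DataFrame
    reverse: pd.DataFrame
    mediation: pd.DataFrame
    notes: dict = field(default_factory=dict)


def run_study(
    exposures: list,
    mediators: list,
    outcome: SummaryStatsTable,
    ld: LDMatrix,
    config: AnalysisConfig,
) -> StudyReport:
    """Run all four stages and assemble a StudyReport.

    Mediation is attempted for the first ``ok``-status exposure against
    every mediator that passed both the FDR screen and the reverse-MR gate.
    """
    forward = run_forward_screen(exposures, outcome, ld, config)
    metab = run_metabolite_screen(mediators, outcome, ld, config)
    passed_fdr = set(metab.loc[metab["significant"], "exposure"])
    candidates = [m for m in mediators if m.trait_label in passed_fdr]
    reverse = run_reverse_mr(outcome, candidates, ld, config)
    excluded = set(reverse.loc[reverse["reverse_causal"], "target"])
    surviving = [m for m in candidates if m.trait_label not in excluded]
    ok_rows = forward[forward["status"] == "ok"]
    if len(ok_rows) and surviving:
        exp_label = ok_rows["exposure"].iloc[0]
        exposure = next(e for e in exposures if e.trait_label == exp_label)
        mediation = run_two_step(exposure, surviving, outcome, ld, config)
    else:
        mediation = pd.DataFrame()
    notes = {
        "n_exposures": len(exposures),
        "n_mediators": len(mediators),
        "n_mediators_fdr_significant": len(candidates),
        "n_mediators_reverse_excluded": len(excluded),
        "n_mediation_chains": len(mediation),
    }
    return StudyReport(config=config, forward=forward, metabolites=metab,
                       reverse=reverse, mediation=mediation, notes=notes)


def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def emit_report(report: StudyReport, outdir) -> list:
    """Write deterministic TSV tables and a JSON summary; returns the paths.

    Reruns with identical inputs, config and seed are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in (
        ("forward.tsv", report.forward),
        ("metabolites.tsv", report.metabolites),
        ("reverse.tsv", report.reverse),
        ("mediation.tsv", report.mediation),
    ):
        p = outdir / name
        _df_to_tsv(df, p)
        paths.append(p)
    payload = {
        "medmr_version": __version__,
        "config": report.config.model_dump(),
        "notes": report.notes,
        "mediation": report.mediation.to_dict(orient="records") if len(report.mediation) else [],
    }
    jpath = outdir / "report.json"
    jpath.write_text(json.dumps(payload, sort_keys=True, indent=2, default=str) + "\n")
    paths.append(jpath)
    return paths
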