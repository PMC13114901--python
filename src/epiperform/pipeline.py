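"""End-to-end orchestration: simulate → score → QC → clocks → associate.

``run_all`` runs every stage on one config, writes CSV/JSON artifacts
mirroring the analysis surface (per-test category frequencies, composite
scores, clock estimates and delta summary, correlation tables, tertile
tables, the DMP list), and records a manifest with the seed, every
decision flag and per-stage row/probe counts so a rerun is byte-for-byte
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    CorrelationResult,
    chronological_tertiles,
    dmp_scan,
    spearman,
    stratified_correlation,
    tertile_split,
)
from .clocks import delta_summary, estimate_cohort, estimates_table
from .methylation import (
    BetaMatrix,
    filter_probes,
    global_mean_beta,
    m_from_beta,
    quantile_normalize,
)
from .performance import score_cohort
from .synthetic import CohortConfig, generate_methylation, \
    generate_normative_table, generate_participants

__all__ = ["RunConfig", "run_all", "activity_correlation"]

ACTIVITY_CODES = {"low": 1, "moderate": 2, "high": 3}


@dataclass(frozen=True)
class RunConfig:
    """Flags and knobs for one full pipeline run."""

    outdir: Path
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc_threshold: float = 0.01
    max_fail_fraction: float = 0.0
    normalize_before_global_mean: bool = True
    missing_cpg_policy: str = "error"
    dmp_on_m_values: bool = True


def activity_correlation(scores, activity_levels) -> CorrelationResult:
    """Spearman of composite score vs ordinal activity (low=1/mod=2/high=3)."""
    unknown = set(activity_levels) - set(ACTIVITY_CODES)
    if unknown:
        raise ValueError(f"unknown activity labels: {sorted(unknown)}")
    coded = [ACTIVITY_CODES[a] for a in activity_levels]
    return spearman(coded, scores, x_name="activity", y_name="performance_score")


def _corr_row(result: CorrelationResult | None, pair: str) -> dict:
    if result is None:
        return {"pair": pair, "rho": np.nan, "p_value": np.nan,
                "n": 0, "method": "undefined"}
    return {"pair": pair, "rho": result.rho, "p_value": result.p_value,
            "n": result.n, "method": result.method}


def run_all(config: RunConfig) -> dict:
    """Run the whole analysis on a synthetic cohort; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.cohort.seed,
        "flags": {
            "qc_threshold": config.qc_threshold,
            "max_fail_fraction": config.max_fail_fraction,
            "normalize_before_global_mean": config.normalize_before_global_mean,
            "missing_cpg_policy": config.missing_cpg_policy,
            "dmp_on_m_values": config.dmp_on_m_values,
        },
        "stages": {},
        "warnings": [],
    }

    # --- simulate ---------------------------------------------------------
    participants = generate_participants(config.cohort)
    norms = generate_normative_table(config.cohort)
    matrix, truth, clock = generate_methylation(participants, config.cohort)
    ages = truth.ages
    manifest["stages"]["simulate"] = {
        "participants": len(participants),
        "cpgs": len(matrix.cpg_ids),
        "clock_cpgs": len(clock.coefficients),
    }

    # --- score ------------------------------------------------------------
    scores, summary = score_cohort(participants, norms)
    scores.to_csv(outdir / "scores.csv")
    summary.to_csv(outdir / "summary_categories.csv")
    manifest["stages"]["score"] = {"participants_scored": len(scores)}

    # --- qc + normalize ---------------------------------------------------
    if matrix.detection_p is not None:
        matrix, qc = filter_probes(matrix, config.qc_threshold,
                                   config.max_fail_fraction)
        qc.to_json(outdir / "qc_report.json")
        manifest["stages"]["qc"] = {"probes_removed": qc.probes_removed,
                                    "probes_kept": len(matrix.cpg_ids)}
    else:
        manifest["stages"]["qc"] = {"skipped": "no detection-p matrix"}
    normalized = quantile_normalize(matrix)
    basis = normalized if config.normalize_before_global_mean else matrix
    gmb = global_mean_beta(basis)
    gmb_raw = global_mean_beta(matrix)
    pd.DataFrame({"global_mean_beta": gmb,
                  "global_mean_beta_raw": gmb_raw}).to_csv(
        outdir / "global_methylation.csv", index_label="sample_id")

    # --- clocks -----------------------------------------------------------
    estimates = estimate_cohort(matrix, [clock], ages=ages,
                                missing_policy=config.missing_cpg_policy)
    est_table = estimates_table(estimates)
    est_table.to_csv(outdir / "clock_estimates.csv")
    deltas = delta_summary(estimates)
    deltas.to_csv(outdir / "delta_summary.csv")
    manifest["stages"]["clocks"] = {"estimates": len(estimates)}

    # --- associations -----------------------------------------------------
    total = scores["total"].astype(float)
    corr_rows = [
        _corr_row(spearman(ages, total), "chronological_age~performance"),
        _corr_row(spearman(gmb, total), "global_mean_beta~performance"),
        _corr_row(spearman(gmb_raw, total), "global_mean_beta_raw~performance"),
    ]
    clock_ages = est_table[clock.name]
    corr_rows.append(_corr_row(spearman(clock_ages, total),
                               f"{clock.name}~performance"))
    activity = [p.activity_level for p in participants]
    try:
        corr_rows.append(_corr_row(activity_correlation(total, activity),
                                   "activity~performance"))
    except ValueError as exc:
        manifest["warnings"].append(f"activity correlation skipped: {exc}")

    chron_split = chronological_tertiles(ages, ids=ages.index)
    for g, res in stratified_correlation(ages, total, chron_split).items():
        corr_rows.append(_corr_row(res, f"age~performance[tertile {g}]"))
    clock_split = tertile_split(clock_ages, ids=clock_ages.index,
                                basis=clock.name)
    for g, res in stratified_correlation(clock_ages, total,
                                         clock_split).items():
        corr_rows.append(_corr_row(res, f"{clock.name}~performance[tertile {g}]"))
    pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)

    tert = pd.DataFrame({"chronological": chron_split.labels,
                         clock.name: clock_split.labels})
    tert.to_csv(outdir / "tertiles.csv", index_label="sample_id")

    dmp_basis = normalized.values if not config.dmp_on_m_values else \
        pd.DataFrame(m_from_beta(normalized.values.to_numpy()),
                     index=normalized.values.index,
                     columns=normalized.values.columns)
    dmp = dmp_scan(dmp_basis, total.loc[dmp_basis.columns])
    dmp.to_csv(outdir / "dmp.csv")
    manifest["stages"]["associate"] = {
        "correlations": len(corr_rows),
        "dmp_tested": len(dmp),
        "dmp_significant": int(dmp["significant"].sum()),
    }

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
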