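"""End-to-end analysis runner.

Chains the stages: (simulate or load cohort) -> two-pass normative
z-scores -> annualized percent change -> optional cognitive score ->
correlations, regression models (with and without amyloid status, per
hemisphere), CCS regressions and the MCAR check on amyloid missingness —
and assembles everything into an :class:`AnalysisReport` with full n
bookkeeping. Deterministic given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .apc import cohort_apc
from .cognitive import cohort_ccs
from .cohort_io import has_battery, read_cohort, validate_cohort, write_cohort
from .errors import MCARNotApplicableError, ValidationError
from .inference import (
    apc_regression,
    ccs_regression,
    little_mcar_test,
    pearson_one_tailed,
)
from .normative import two_pass_adjusted_zscores
from .synthetic import SimulationParams, simulate_cohort, simulate_neuropsych

log = logging.getLogger("hippoatrophy")

HEMISPHERES = ("left", "right")


@dataclass
class AnalysisConfig:
    """Pipeline configuration; every field mirrors a config-file key."""

    cohort_csv: str | None = None  # load this CSV ...
    simulate: bool = True          # ... or simulate (the default)
    sim_params: SimulationParams = field(default_factory=SimulationParams)
    with_battery: bool = True
    normative_model: str = "quadratic"
    outlier_threshold: float = 3.0
    ccs_delta: float = 0.5
    correlation_direction: str = "positive"
    z_pass: str = "pass2"
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate_params", {})
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim_params"})
        if sim:
            base = SimulationParams().to_dict()
            for k in sim:
                if k not in base:
                    raise ValidationError(f"unknown simulate_params key '{k}'")
            base.update(sim)
            for key in ("education_fractions", "age_range_tp1"):
                base[key] = tuple(base[key])
            cfg.sim_params = SimulationParams(**base)
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "sim_params"}
        d["simulate_params"] = self.sim_params.to_dict()
        return d


@dataclass
class AnalysisReport:
    """All pipeline outputs plus provenance for the n bookkeeping."""

    demographics: dict
    volume_summary: pd.DataFrame
    correlations: dict
    regressions: dict       # (hemisphere, 'with_amyloid'|'without_amyloid') keys
    mcar: object | None
    ccs_regressions: dict   # empty when no battery
    ccs_table: pd.DataFrame | None
    zscores: object
    apc_records: pd.DataFrame
    provenance: dict


def _config_hash(config: AnalysisConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir", None)  # where results land does not change them
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _demographics(cohort: pd.DataFrame, ccs: pd.DataFrame | None) -> dict:
    n = len(cohort)
    age2 = cohort["age_tp1"] + cohort["interval"]
    amy = cohort["amyloid"]
    out = {
        "n": n,
        "age_tp1_mean": float(cohort["age_tp1"].mean()),
        "age_tp1_sd": float(cohort["age_tp1"].std(ddof=1)),
        "age_tp2_mean": float(age2.mean()),
        "age_tp2_sd": float(age2.std(ddof=1)),
        "interval_mean": float(cohort["interval"].mean()),
        "interval_sd": float(cohort["interval"].std(ddof=1)),
        "n_female": int((cohort["sex"] == "female").sum()),
        "n_male": int((cohort["sex"] == "male").sum()),
        "education_pct": {
            k: float((cohort["education"] == k).mean() * 100)
            for k in ("lt9", "9to12", "gt12")
        },
        "apoe4_carrier_pct": float((cohort["apoe4"] == "carrier").mean() * 100),
        "amyloid_n_assessed": int(amy.notna().sum()),
        "amyloid_positive_pct_of_assessed": (
            float((amy == "positive").sum() / amy.notna().sum() * 100)
            if amy.notna().any() else float("nan")
        ),
    }
    if ccs is not None:
        out["ccs_total_mean"] = float(ccs["total_change"].mean())
        out["ccs_total_sd"] = float(ccs["total_change"].std(ddof=1))
    return out


def _mcar_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Quantitative table for the amyloid MCAR check."""
    return pd.DataFrame(
        {
            "amyloid": cohort["amyloid"].map({"negative": 0.0, "positive": 1.0}),
            "age_tp1": cohort["age_tp1"].astype(float),
            "interval": cohort["interval"].astype(float),
            "icv": cohort["icv"].astype(float),
            "hippo_left_tp1": cohort["hippo_left_tp1"].astype(float),
            "hippo_right_tp1": cohort["hippo_right_tp1"].astype(float),
        }
    )


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Execute every stage and return the assembled report.

    When ``config.output_dir`` is set the cohort, z-scores, APC records,
    CCS table, report JSON and a Markdown report are written there.
    """
    provenance: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "stages": [],
    }

    if config.simulate:
        params = config.sim_params
        provenance["seed"] = params.seed
        cohort, truth = simulate_cohort(params)
        if config.with_battery:
            cohort = simulate_neuropsych(params, cohort)
        cohort = validate_cohort(cohort, strict=True)
        log.info("simulate: n=%d seed=%d", len(cohort), params.seed)
    else:
        if not config.cohort_csv:
            raise ValidationError("config.simulate is false but no cohort_csv given")
        cohort = read_cohort(config.cohort_csv)
        truth = None
        provenance["seed"] = None
        log.info("load: %s n=%d", config.cohort_csv, len(cohort))
    provenance["stages"].append({"stage": "cohort", "n_in": len(cohort),
                                 "n_out": len(cohort)})

    zs = two_pass_adjusted_zscores(
        cohort, threshold=config.outlier_threshold, model=config.normative_model
    )
    n_retained = int((~zs.table["excluded"]).sum())
    provenance["stages"].append(
        {"stage": "two_pass_zscores", "n_in": len(cohort), "n_out": n_retained,
         "excluded_ids": list(zs.excluded_ids)}
    )
    log.info("two-pass z: retained %d of %d (excluded %s)",
             n_retained, len(cohort), list(zs.excluded_ids))
    retained = cohort[~cohort["subject_id"].isin(zs.excluded_ids)].reset_index(drop=True)

    apc_records, apc_summary = cohort_apc(retained)
    provenance["stages"].append({"stage": "apc", "n_in": n_retained,
                                 "n_out": n_retained})

    battery = has_battery(retained)
    ccs = None
    if battery:
        ccs = cohort_ccs(retained, delta=config.ccs_delta)
        provenance["stages"].append({"stage": "ccs", "n_in": n_retained,
                                     "n_out": len(ccs)})

    # correlations: baseline adjusted z vs APC per hemisphere
    merged = zs.retained.merge(
        apc_records.pivot(index="subject_id", columns="hemisphere", values="apc"),
        left_on="subject_id", right_index=True,
    )
    correlations = {
        hemi: pearson_one_tailed(
            merged[f"{config.z_pass}_z_{hemi}"], merged[hemi],
            direction=config.correlation_direction,
        )
        for hemi in HEMISPHERES
    }

    regressions = {}
    for hemi in HEMISPHERES:
        for label, with_amy in (("without_amyloid", False), ("with_amyloid", True)):
            res = apc_regression(
                retained, zs, apc_records, hemi, include_amyloid=with_amy,
                z_pass=config.z_pass,
            )
            regressions[(hemi, label)] = res
            provenance["stages"].append(
                {"stage": f"regression_{hemi}_{label}", "n_in": n_retained,
                 "n_out": res.n}
            )

    try:
        mcar = little_mcar_test(_mcar_frame(retained), missing_column="amyloid")
    except MCARNotApplicableError:
        mcar = None

    ccs_regs = {}
    if battery:
        zmerged = zs.retained.merge(ccs[["subject_id", "total_change"]],
                                    on="subject_id")
        for hemi in HEMISPHERES:
            ccs_regs[hemi] = ccs_regression(
                zmerged["total_change"], zmerged[f"{config.z_pass}_z_{hemi}"]
            )

    report = AnalysisReport(
        demographics=_demographics(retained, ccs),
        volume_summary=apc_summary,
        correlations=correlations,
        regressions=regressions,
        mcar=mcar,
        ccs_regressions=ccs_regs,
        ccs_table=ccs,
        zscores=zs,
        apc_records=apc_records,
        provenance=provenance,
    )
    if config.output_dir:
        write_report(report, cohort, config.output_dir)
    return report


# ---------------------------------------------------------------------------
# report serialization


def report_to_dict(report: AnalysisReport) -> dict:
    return {
        "demographics": report.demographics,
        "volume_summary": report.volume_summary.to_dict(orient="records"),
        "correlations": {h: r.to_dict() for h, r in report.correlations.items()},
        "regressions": {
            f"{h}_{label}": res.to_dict()
            for (h, label), res in report.regressions.items()
        },
        "mcar": report.mcar.to_dict() if report.mcar is not None else None,
        "ccs_regressions": {
            h: r.to_dict() for h, r in report.ccs_regressions.items()
        },
        "provenance": report.provenance,
    }


def render_markdown(report: AnalysisReport) -> str:
    """Human-readable report mirroring the descriptive/inferential tables."""
    d = report.demographics
    lines = [
        "# Hippocampal atrophy analysis report",
        "",
        f"Retained sample: n = {d['n']}",
        "",
        "## Demographics",
        "",
        f"- Mean age timepoint 1 (SD): {d['age_tp1_mean']:.1f} ({d['age_tp1_sd']:.1f}) years",
        f"- Mean age timepoint 2 (SD): {d['age_tp2_mean']:.1f} ({d['age_tp2_sd']:.1f}) years",
        f"- Mean inter-scan interval (SD): {d['interval_mean']:.1f} ({d['interval_sd']:.1f}) years",
        f"- Sex: {d['n_female']} female / {d['n_male']} male",
        "- Education: "
        + ", ".join(f"{v:.1f}% {k}" for k, v in d["education_pct"].items()),
        f"- APOE-e4 carriers: {d['apoe4_carrier_pct']:.1f}%",
        f"- Amyloid PET assessed: {d['amyloid_n_assessed']}"
        f" ({d['amyloid_positive_pct_of_assessed']:.1f}% positive)",
    ]
    if "ccs_total_mean" in d:
        lines.append(
            f"- Total cognitive change (SD): {d['ccs_total_mean']:.1f} "
            f"({d['ccs_total_sd']:.1f})"
        )
    lines += ["", "## Hippocampal volumes and APC", ""]
    for _, row in report.volume_summary.iterrows():
        lines.append(
            f"- {row['hemisphere']}: APC {row['apc_mean']:.2f} ({row['apc_sd']:.2f}) %/y; "
            f"TP1 {row['v_tp1_mean']:.2f} ({row['v_tp1_sd']:.2f}) mm^3; "
            f"TP2 {row['v_tp2_mean']:.2f} ({row['v_tp2_sd']:.2f}) mm^3"
        )
    lines += ["", "## Baseline z-score vs APC correlations", ""]
    for hemi, r in report.correlations.items():
        lines.append(
            f"- {hemi}: r = {r.r:.3f}, one-tailed p = {r.p_one_tailed:.4f} "
            f"(n = {r.n}, direction {r.hypothesized_direction})"
        )
    for (hemi, label), res in report.regressions.items():
        lines += ["", f"## Regression: {hemi} APC, {label.replace('_', ' ')} "
                  f"(n = {res.n})", ""]
        lines.append("| term | coef | SE | t | p | 95% CI |")
        lines.append("|---|---|---|---|---|---|")
        for _, t in res.terms.iterrows():
            lines.append(
                f"| {t['term']} | {t['coef']:.3f} | {t['se']:.3f} | {t['t']:.2f} "
                f"| {t['p']:.3f} | [{t['ci_low']:.3f}, {t['ci_high']:.3f}] |"
            )
        lines.append(
            f"\nR^2 = {res.r_squared:.3f}, adjusted R^2 = {res.adj_r_squared:.3f}, "
            f"F = {res.f_stat:.2f}, model p = {res.f_pvalue:.3f}"
        )
    lines += ["", "## Amyloid missingness (MCAR check)", ""]
    if report.mcar is None:
        lines.append("- not applicable (no missing amyloid data)")
    else:
        m = report.mcar
        lines.append(
            f"- Little's chi-square = {m.chi2:.2f}, df = {m.df}, p = {m.p:.3f} "
            f"({m.n_patterns} missingness patterns)"
        )
    lines += ["", "## Cognitive change vs baseline z", ""]
    if not report.ccs_regressions:
        lines.append("- not computed (no neuropsychological battery in the cohort)")
    else:
        for hemi, res in report.ccs_regressions.items():
            row = res.terms.set_index("term").loc["baseline_z"]
            lines.append(
                f"- {hemi}: slope = {row['coef']:.3f} (SE {row['se']:.3f}), "
                f"two-tailed p = {row['p']:.3f}, n = {res.n}"
            )
    p = report.provenance
    lines += [
        "",
        "## Provenance",
        "",
        f"- package version: {p['package_version']}",
        f"- seed: {p['seed']}",
        f"- config hash: {p['config_hash']}",
        "- stage log: "
        + "; ".join(
            f"{s['stage']} {s['n_in']}->{s['n_out']}" for s in p["stages"]
        ),
        "",
        "Note: no correction for multiple comparisons is applied across "
        "hemispheres or models.",
        "",
    ]
    return "\n".join(lines)


def write_report(report: AnalysisReport, cohort: pd.DataFrame, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, out / "cohort.csv")
    report.zscores.table.to_csv(out / "zscores.csv", index=False)
    report.apc_records.to_csv(out / "apc.csv", index=False)
    if report.ccs_table is not None:
        report.ccs_table.to_csv(out / "ccs.csv", index=False)
    (out / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True,
                   default=_json_default)
        + "\n"
    )
    (out / "report.md").write_text(render_markdown(report))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
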