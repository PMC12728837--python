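"""End-to-end orchestration: simulate -> cohort -> registers -> analyses.

One YAML config drives the whole run. Outputs are tidy CSVs shaped like the
study's reporting artefacts — a prevalence ranking, a utilisation ranking
(total consultations and mean annual rates), a cost ranking with per-provider
components, and an adjusted-odds-ratio table — plus a JSON run manifest
(config hash, seed, row counts per stage, output digests) that fully
determines a rerun, and a one-page text summary.

Every stage is deterministic given the config and seed; any stage failure
aborts the run naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codebook import Codebook, default_codebook, load_codebook
from .cohort import build_cohort
from .costing import (
    consultation_rate,
    cost_summary,
    excess_cost_percent,
    prevalence_percent,
    rank_conditions,
)
from .inequalities import InequalityModel, default_spec, odds_ratio_report
from .registers import build_cp_register, build_ltc_register
from .synthetic import (
    PopulationBundle,
    SimulationConfig,
    read_bundle,
    simulate_population,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "run_pipeline", "emit_summary", "load_pipeline_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha256_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _sha256_file(path: Path) -> str:
    return _sha256_bytes(path.read_bytes())


def load_pipeline_config(path: str | Path) -> dict:
    """Read and minimally validate the pipeline YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineError("config: top level must be a mapping")
    known = {"simulate", "input_dir", "codebook", "ltcs", "use_recorded_duration", "seed"}
    unknown = set(cfg) - known
    if unknown:
        raise PipelineError(f"config: unknown keys {sorted(unknown)}")
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> Path:
    """Run the full pipeline from a config file (or dict); returns the out dir."""
    if isinstance(config, (str, Path)):
        cfg = load_pipeline_config(config)
    else:
        cfg = dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    counts: dict[str, int] = {}

    # -- codebook (validated before any simulation) -------------------------
    codebook_path = cfg.get("codebook")
    codebook: Codebook = _stage("codebook")(
        lambda: load_codebook(codebook_path) if codebook_path else default_codebook()
    )()
    completed.append("codebook")

    # -- input bundle -------------------------------------------------------
    if "input_dir" in cfg:
        bundle = _stage("read_bundle")(read_bundle)(cfg["input_dir"])
        sim_config = None
    else:
        sim_kwargs = dict(cfg.get("simulate") or {})
        if "seed" in cfg and "seed" not in sim_kwargs:
            sim_kwargs["seed"] = cfg["seed"]
        sim_config = SimulationConfig(**sim_kwargs)
        bundle = _stage("simulate")(simulate_population)(sim_config, codebook)
    extraction_date = bundle.extraction_date
    counts["patients"] = len(bundle.patients)
    counts["prescriptions"] = len(bundle.prescriptions)
    counts["diagnoses"] = len(bundle.diagnoses)
    counts["consultations"] = len(bundle.consultations)
    completed.append("input")
    logger.info("input: %d patients, %d prescriptions, %d diagnoses, %d consultations",
                *[counts[k] for k in ("patients", "prescriptions", "diagnoses", "consultations")])

    # -- cohort -------------------------------------------------------------
    cohort, exclusions = _stage("cohort")(build_cohort)(bundle.patients, extraction_date)
    counts["cohort"] = len(cohort)
    counts["excluded"] = exclusions.total
    completed.append("cohort")
    logger.info("cohort: %d eligible, %d excluded", len(cohort), exclusions.total)

    # -- registers ----------------------------------------------------------
    cp_register = _stage("registers")(build_cp_register)(
        cohort, bundle.prescriptions, bundle.diagnoses, codebook, extraction_date
    )
    counts["cp_register"] = int(cp_register["on_register"].sum())
    if "ltcs" in cfg:
        ltc_names = list(cfg["ltcs"])
    elif sim_config is not None:
        ltc_names = sorted(sim_config.ltc_prevalence)
    else:
        ltc_names = sorted(
            l.ltc_name for l in codebook.ltcs if l.ltc_name != "chronic_pain"
        )
    ltc_registers = {
        name: _stage("registers")(build_ltc_register)(
            cohort, bundle.diagnoses, codebook, name, extraction_date
        )
        for name in ltc_names
    }
    completed.append("registers")
    logger.info("registers: chronic_pain %d members", counts["cp_register"])

    # -- per-condition summaries -------------------------------------------
    use_recorded = bool(cfg.get("use_recorded_duration", False))
    n_cohort = len(cohort)
    registers = {"chronic_pain": cp_register, **ltc_registers}
    rows = []
    for name, reg in registers.items():
        members = reg.loc[reg["on_register"], ["patient_id"]]
        util = consultation_rate(reg, bundle.consultations, extraction_date, name)
        cost = cost_summary(
            reg, bundle.consultations, codebook, extraction_date, name, use_recorded
        )
        rows.append(
            {
                "ltc_name": name,
                "n_patients": len(members),
                "prevalence_percent": prevalence_percent(len(members), n_cohort)
                if n_cohort
                else 0.0,
                "total_consultations": util.total_consultations,
                "mean_annual_rate": util.mean_rate,
                "total_cost_gbp": round(cost.total_cost_gbp, 2),
                "per_patient_cost_gbp": cost.per_patient_cost_gbp,
                "gp_cost_gbp": round(cost.provider_cost_gbp("gp"), 2),
                "nurse_cost_gbp": round(cost.provider_cost_gbp("nurse"), 2),
                "other_hcp_cost_gbp": round(cost.provider_cost_gbp("other_hcp"), 2),
            }
        )
    summary_table = pd.DataFrame(rows)
    prevalence_table = rank_conditions(summary_table, "prevalence")[
        ["rank", "ltc_name", "n_patients", "prevalence_percent"]
    ]
    utilisation_table = rank_conditions(summary_table, "total_consultations")[
        ["rank", "ltc_name", "n_patients", "total_consultations", "mean_annual_rate"]
    ]
    cost_table = rank_conditions(summary_table, "total_cost")[
        [
            "rank",
            "ltc_name",
            "n_patients",
            "total_cost_gbp",
            "per_patient_cost_gbp",
            "gp_cost_gbp",
            "nurse_cost_gbp",
            "other_hcp_cost_gbp",
        ]
    ]
    completed.append("utilisation_costing")

    # -- inequalities -------------------------------------------------------
    spec = default_spec()
    model = _stage("inequalities")(InequalityModel)(cohort, cp_register, spec)
    or_table = _stage("inequalities")(model.fit)()
    table2 = odds_ratio_report(or_table, spec)
    counts["inequalities_n_used"] = or_table.n_used
    counts["inequalities_n_dropped_missing"] = or_table.n_dropped_missing
    completed.append("inequalities")
    logger.info("inequalities: fitted on %d rows (%d dropped for missingness)",
                or_table.n_used, or_table.n_dropped_missing)

    # -- write outputs ------------------------------------------------------
    outputs = {
        "cohort.csv": _cohort_frame(cohort),
        "exclusions.csv": exclusions.as_frame(),
        "register_chronic_pain.csv": cp_register,
        "registers_ltc.csv": _ltc_long(ltc_registers),
        "prevalence_ranking.csv": prevalence_table,
        "utilisation_ranking.csv": utilisation_table,
        "cost_ranking.csv": cost_table,
        "odds_ratios.csv": table2,
        "missingness_report.csv": pd.DataFrame(
            sorted(or_table.missingness.items()), columns=["covariate", "n_missing"]
        ),
    }
    digests = {}
    for fname, frame in outputs.items():
        path = out / fname
        frame.to_csv(path, index=False)
        digests[fname] = _sha256_file(path)

    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_hash": _sha256_bytes(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ),
        "seed": (sim_config.seed if sim_config is not None else None),
        "extraction_date": str(extraction_date.date()),
        "row_counts": counts,
        "output_digests": digests,
        "completed_stages": completed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    report = emit_summary(
        {
            "summary_table": summary_table,
            "odds_ratios": or_table,
            "n_cohort": n_cohort,
            "exclusions": exclusions,
        }
    )
    (out / "summary.txt").write_text(report)
    return out


def _cohort_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    out = cohort.copy()
    for col in ("birth_date", "registration_start", "registration_end"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    return out


def _ltc_long(ltc_registers: dict[str, pd.DataFrame]) -> pd.DataFrame:
    frames = []
    for name, reg in sorted(ltc_registers.items()):
        members = reg.loc[reg["on_register"], ["patient_id"]].copy()
        members.insert(0, "ltc_name", name)
        frames.append(members)
    if not frames:
        return pd.DataFrame(columns=["ltc_name", "patient_id"])
    return pd.concat(frames, ignore_index=True)


def emit_summary(outputs: dict) -> str:
    """One-page human-readable run report."""
    table: pd.DataFrame = outputs["summary_table"]
    or_table = outputs["odds_ratios"]
    n_cohort: int = outputs["n_cohort"]
    lines = [
        "chronic-pain register pipeline - run summary",
        "=" * 44,
        f"analysis cohort: {n_cohort} patients "
        f"({outputs['exclusions'].total} excluded)",
        "",
        "prevalence (% of cohort):",
    ]
    by_prev = table.sort_values(
        ["prevalence_percent", "ltc_name"], ascending=[False, True]
    )
    for _, row in by_prev.iterrows():
        lines.append(
            f"  {row['ltc_name']:<24s} {row['prevalence_percent']:5.1f}% "
            f"(n={row['n_patients']})"
        )
    lines += ["", "mean annual consultation rate / total cost:"]
    for _, row in by_prev.iterrows():
        lines.append(
            f"  {row['ltc_name']:<24s} {row['mean_annual_rate']:5.1f}/patient/yr   "
            f"GBP {row['total_cost_gbp']:>12,.2f} total, "
            f"GBP {row['per_patient_cost_gbp']}/patient"
        )
    top_aors = or_table.frame.sort_values("aor", ascending=False).head(5)
    lines += ["", "strongest adjusted odds ratios for chronic pain:"]
    for _, row in top_aors.iterrows():
        lines.append(
            f"  {row['covariate']}={row['level']:<16s} aOR {row['aor']:.2f} "
            f"({row['ci_low']:.2f} to {row['ci_high']:.2f})"
        )
    lines.append("")
    return "\n".join(lines)
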