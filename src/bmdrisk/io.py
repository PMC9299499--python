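"""Dataset readers/writers and the end-to-end analysis pipeline.

The pipeline mirrors the quantitative tail of the genetic-toxicology risk
framework: covariate-structure selection per model family, profile-likelihood
BMD confidence intervals per covariate level, cross-family combination into a
point of departure, human-equivalent-dose conversion and margin-of-exposure
characterization — emitted as one JSON report plus a Markdown rendering that
contains no numbers absent from the JSON.
"""
from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .bmd import (
    BmdEstimate,
    ci_ratio_report,
    combine_families,
    profile_bmd_ci,
    select_covariate_structure,
)
from .config import AnalysisConfig
from .hed import animal_to_hed, moe_range_profile
from .models import (
    DoseResponseDataset,
    DoseResponseRecord,
    FitOptions,
    GroupSummary,
)

__all__ = ["read_dataset", "write_dataset", "run_pipeline", "render_markdown", "save_report"]

logger = logging.getLogger("bmdrisk")

_INDIVIDUAL_COLS = {"dataset_id", "covariate_level", "dose", "response"}
_SUMMARY_COLS = {"dataset_id", "covariate_level", "dose", "n", "mean", "sd"}


class ParseError(ValueError):
    """Row-addressed dataset parsing failure."""


def _sniff_delimiter(path: Path) -> str:
    sample = path.read_text()[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_dataset(path: str | Path, config: AnalysisConfig | None = None) -> DoseResponseDataset:
    """Read a delimited-text dataset, individual or group-summary dialect.

    Individual header: dataset_id,covariate_level,dose,response
    Summary header:    dataset_id,covariate_level,dose,n,mean,sd
    Delimiter is auto-detected among comma and tab.  Errors name the
    offending file row (header = row 1).
    """
    path = Path(path)
    config = config or AnalysisConfig()
    df = pd.read_csv(path, sep=_sniff_delimiter(path), skipinitialspace=True)
    cols = set(df.columns)
    if _SUMMARY_COLS <= cols:
        dialect = "summary"
    elif _INDIVIDUAL_COLS <= cols:
        dialect = "individual"
    else:
        missing = sorted(_INDIVIDUAL_COLS - cols)
        raise ParseError(
            f"{path}: header matches neither dialect; for individual data the "
            f"missing column(s) are {missing}"
        )
    logger.info("read %s as %s-form data (%d rows)", path.name, dialect, len(df))

    def _num(row_i: int, name: str, value, positive: bool = False) -> float:
        try:
            x = float(value)
        except (TypeError, ValueError):
            raise ParseError(f"{path} row {row_i}: non-numeric {name} {value!r}") from None
        if math.isnan(x):
            raise ParseError(f"{path} row {row_i}: missing {name}")
        if positive and x <= 0:
            raise ParseError(
                f"{path} row {row_i}: {name} must be > 0 (lognormal support requires "
                f"positive responses), got {value!r}"
            )
        return x

    if dialect == "individual":
        records = []
        for i, row in df.iterrows():
            row_no = int(i) + 2  # header is row 1
            records.append(
                DoseResponseRecord(
                    dataset_id=str(row["dataset_id"]),
                    covariate_level=str(row[config.covariate_column]),
                    dose=_num(row_no, "dose", row["dose"]),
                    response=_num(row_no, "response", row["response"], positive=True),
                    subject_id=str(row["subject_id"]) if "subject_id" in cols else None,
                )
            )
        return DoseResponseDataset(
            records=records, endpoint=config.response_units, units=config.dose_units
        )
    summaries = []
    for i, row in df.iterrows():
        row_no = int(i) + 2
        summaries.append(
            GroupSummary(
                dataset_id=str(row["dataset_id"]),
                covariate_level=str(row[config.covariate_column]),
                dose=_num(row_no, "dose", row["dose"]),
                n=int(_num(row_no, "n", row["n"])),
                mean=_num(row_no, "mean", row["mean"], positive=True),
                sd=_num(row_no, "sd", row["sd"]),
            )
        )
    return DoseResponseDataset(
        summaries=summaries, endpoint=config.response_units, units=config.dose_units
    )


def write_dataset(dataset: DoseResponseDataset, path: str | Path) -> None:
    """Write the dataset in the same CSV dialect ``read_dataset`` accepts."""
    dataset.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _estimate_to_dict(e: BmdEstimate) -> dict:
    d = asdict(e)
    d["ci_ratio"] = e.ci_ratio
    return d


def run_pipeline(
    data: DoseResponseDataset | str | Path,
    config: AnalysisConfig | None = None,
    exposure_range: tuple[float, float] | None = None,
) -> dict:
    """Full analysis: per-family covariate BMD -> combined PoD -> HED -> MOE.

    Returns a JSON-serializable report.  Stage failures propagate with the
    stage name; no partial report is emitted.
    """
    config = config or AnalysisConfig()
    if not isinstance(data, DoseResponseDataset):
        data = read_dataset(data, config)
    opts = FitOptions(d_bounds=config.d_bounds)
    stage_log: list[str] = []

    def log(stage: str, msg: str) -> None:
        stage_log.append(f"[{stage}] {msg}")
        logger.info("[%s] %s", stage, msg)

    report: dict = {
        "config": config.echo(),
        "data": {
            "n_obs": data.n_obs,
            "levels": list(data.levels),
            "doses": list(data.doses),
            "form": "summary" if data.is_summary else "individual",
            "endpoint": data.endpoint,
        },
        "families": {},
    }
    estimates: list[BmdEstimate] = []
    try:
        for family in config.families:
            structure, fit = select_covariate_structure(
                data, family, alpha=config.alpha, opts=opts
            )
            log("fit", f"{family}: selected structure '{structure.describe()}', "
                f"loglik {fit.loglik:.4f}, {fit.n_free_params} free parameters")
            fam_estimates = []
            for level in data.levels:
                est = profile_bmd_ci(
                    data, family, structure, level=level, ces=config.ces,
                    ci_level=config.ci_level, fit=fit, opts=opts,
                )
                log("bmd", f"{family}/{level}: BMD={est.bmd:.4g} "
                    f"[{est.bmdl:.4g}, {est.bmdu:.4g}] {data.units}")
                fam_estimates.append(est)
            estimates.extend(fam_estimates)
            report["families"][family] = {
                "structure": structure.describe(),
                "level_specific": sorted(structure.level_specific),
                "loglik": fit.loglik,
                "n_free_params": fit.n_free_params,
                "converged": fit.converged,
                "params": {
                    "a": fit.params.a, "b": fit.params.b,
                    "c": fit.params.c, "d": fit.params.d, "var": fit.params.var,
                },
                "estimates": [_estimate_to_dict(e) for e in fam_estimates],
                "selection": fit.diagnostics.get("selection"),
            }
    except Exception as err:
        raise RuntimeError(f"stage 'covariate-bmd' failed: {err}") from err

    combined = combine_families(estimates)
    report["combined"] = [asdict(c) for c in combined]
    report["ci_ratios"] = ci_ratio_report(estimates).to_dict(orient="records")

    # PoD: the lowest combined BMDL across covariate levels
    pod = min(combined, key=lambda c: c.pod_bmdl)
    report["pod"] = {
        "rule": config.pod_rule,
        "covariate_level": pod.covariate_level,
        "value_mgkg": pod.pod_bmdl,
        "ces": config.ces,
    }
    log("pod", f"PoD = BMDL{config.ces * 100:g} {pod.pod_bmdl:.4g} mg/kg "
        f"({pod.covariate_level})")

    try:
        hed = animal_to_hed(pod.pod_bmdl, species=config.species)
    except Exception as err:
        raise RuntimeError(f"stage 'hed' failed: {err}") from err
    report["hed"] = asdict(hed)
    log("hed", f"HED {hed.hed_mgkg_printed:.2f} mg/kg -> {hed.hed_mgm2_printed:g} mg/m2 "
        f"(divisor {hed.bsa_divisor}, Km {hed.km_human:g})")

    if exposure_range is not None:
        try:
            profile = moe_range_profile(
                hed.hed_mgm2_printed, exposure_range[0], exposure_range[1],
                config.moe_lower_threshold, config.moe_upper_threshold,
            )
        except Exception as err:
            raise RuntimeError(f"stage 'moe' failed: {err}") from err
        report["moe"] = {
            "pod_hed_mgm2": hed.hed_mgm2_printed,
            "exposure_range_mgm2": list(exposure_range),
            "assessments": [asdict(a) for a in profile.assessments],
            "summary_zone": profile.summary_zone,
        }
        log("moe", f"exposure {exposure_range[0]:g}-{exposure_range[1]:g} mg/m2 -> "
            f"{profile.summary_zone} zone")
    report["logs"] = stage_log
    return report


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if isinstance(x, float):
        if math.isinf(x):
            return "inf"
        return f"{x:.4g}"
    return str(x)


def render_markdown(report: dict) -> str:
    """Human-readable report; every number shown also appears in the JSON."""
    cfg = report["config"]
    ces_pct = cfg["ces"] * 100
    lines = [
        "# Covariate benchmark-dose analysis report",
        "",
        f"Endpoint: {report['data']['endpoint']} | form: {report['data']['form']} | "
        f"n = {report['data']['n_obs']} | doses ({cfg['dose_units']}): "
        + ", ".join(_fmt(d) for d in report["data"]["doses"]),
        "",
        f"Settings: CES {ces_pct:g}% | CI {cfg['ci_level'] * 100:g}% | "
        f"LR alpha {cfg['alpha']:g} | families: " + ", ".join(cfg["families"]),
        "",
        f"## BMD confidence bounds (CES {ces_pct:g}%)",
        "",
        "| quantity | " + " | ".join(report["data"]["levels"]) + " |",
        "|---" * (len(report["data"]["levels"]) + 1) + "|",
    ]
    combined = {c["covariate_level"]: c for c in report["combined"]}
    lvls = report["data"]["levels"]
    lines.append(
        f"| BMDL{ces_pct:g} (mg/kg) | " + " | ".join(_fmt(combined[l]["pod_bmdl"]) for l in lvls) + " |"
    )
    lines.append(
        f"| BMDU{ces_pct:g} (mg/kg) | " + " | ".join(_fmt(combined[l]["pod_bmdu"]) for l in lvls) + " |"
    )
    lines += ["", "Lowest BMDL / highest BMDU across the fitted families.", ""]
    lines.append("## Per-family estimates")
    lines.append("")
    lines.append("| family | level | BMD | BMDL | BMDU | CI ratio |")
    lines.append("|---|---|---|---|---|---|")
    for fam, f in report["families"].items():
        for e in f["estimates"]:
            lines.append(
                f"| {fam} | {e['covariate_level']} | {_fmt(e['bmd'])} | "
                f"{_fmt(e['bmdl'])} | {_fmt(e['bmdu'])} | {_fmt(e['ci_ratio'])} |"
            )
    lines.append("")
    for fam, f in report["families"].items():
        lines.append(f"- {fam}: {f['structure']}; loglik {_fmt(f['loglik'])}")
    if "pod" in report:
        p = report["pod"]
        lines += [
            "",
            "## Point of departure and human-equivalent dose",
            "",
            f"PoD (lowest BMDL{ces_pct:g}, {p['covariate_level']}): "
            f"{_fmt(p['value_mgkg'])} mg/kg",
        ]
        h = report["hed"]
        lines.append(
            f"HED: {_fmt(h['pod_animal'])} / {_fmt(h['bsa_divisor'])} = "
            f"{h['hed_mgkg_printed']:.2f} mg/kg; x Km {_fmt(h['km_human'])} = "
            f"{_fmt(h['hed_mgm2_printed'])} mg/m2"
        )
    if "moe" in report:
        m = report["moe"]
        lines += ["", "## Margin of exposure", ""]
        for a in m["assessments"]:
            lines.append(
                f"- exposure {_fmt(a['exposure'])} mg/m2: MOE = {_fmt(a['moe'])} "
                f"-> {a['zone']} zone"
            )
        lines.append(f"- summary (worst case): **{m['summary_zone']} zone** "
                     f"(thresholds {_fmt(m['assessments'][0]['lower_threshold'])} / "
                     f"{_fmt(m['assessments'][0]['upper_threshold'])})")
    lines.append("")
    return "\n".join(lines)


def save_report(report: dict, json_path: str | Path, md_path: str | Path | None = None) -> None:
    """Persist the report; the JSON is byte-identical across reruns of the
    same inputs (any timestamp lives only in the separate ``meta`` field)."""
    import datetime

    payload = dict(report)
    payload["meta"] = {"generated_at": datetime.datetime.now().isoformat()}
    Path(json_path).write_text(json.dumps(payload, indent=2))
    if md_path is not None:
        Path(md_path).write_text(render_markdown(report))
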