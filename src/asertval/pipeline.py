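"""One-command end-to-end pipeline with manifest and consolidated report.

Stages: (optional) simulate -> match -> psychometrics -> validate -> detect
-> report.  JSON files are the canonical stage outputs; the markdown report
is derived from them.  All randomness flows from the single run seed, split
deterministically per stage, and every written file is digested into the run
manifest so reruns can be compared byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .convergent import (
    bootstrap_lme_slope,
    case_bootstrap,
    fit_lme,
    item_pair_correlations,
    weighted_group_correlation,
)
from .detection import (
    DetectionModelSpec,
    default_ladder,
    build_feature_table,
    model_selection_ladder,
    repeated_split_validation,
    summarize_metrics,
)
from .domain import Patient, RunConfig
from .io import (
    matched_frame,
    read_asert_table,
    read_clinical_table,
    read_patient_table,
    write_matched_table,
)
from .matching import attach_lags, filter_detection_cohort, match_concurrent
from .psychometrics import factor_alphas, pca_items, response_rate_summary
from .simulate import GeneratorConfig, generate_cohort, write_cohort

__all__ = ["RunManifest", "run_pipeline", "render_report", "stage_seed"]

logger = logging.getLogger(__name__)


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Config echo, seeds, per-stage counts and output digests for one run."""

    config: dict
    seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    digests: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    version: str = __version__

    def record_file(self, path: Path) -> None:
        self.digests[path.name] = _sha256(path)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def _psychometrics_stage(matched_df, patients, asserts) -> dict:
    items = matched_df[[f"q{k}" for k in range(1, 11)]].to_numpy(dtype=float)
    pca = pca_items(items)
    alphas = factor_alphas(items)
    filled = {}
    for a in asserts:
        filled[a.patient_id] = filled.get(a.patient_id, 0) + 1
    rates = response_rate_summary(patients, filled)
    return {
        "pca": {
            "loadings": [[round(v, 6) for v in row] for row in pca.loadings.tolist()],
            "sds": [round(v, 6) for v in pca.sds.tolist()],
            "proportions": [round(v, 6) for v in pca.proportions.tolist()],
            "cumulative": [round(v, 6) for v in pca.cumulative.tolist()],
            "zero_variance_items": list(pca.zero_variance_items),
        },
        "alphas": {k: round(v.alpha, 6) for k, v in alphas.items()},
        "response_rate": rates,
        "n_records": int(len(items)),
    }


def _validity_stage(matched_df: pd.DataFrame, B: int, seed: int) -> dict:
    out: dict = {"B": B, "seed": seed, "lme": {}, "correlations": {}, "item_pairs": {}}
    models = [
        ("madrs~depnsp", "madrs_total", "depnsp_sum"),
        ("ymrs~man", "ymrs_total", "man_sum"),
    ]
    for name, resp, pred in models:
        fit = fit_lme(matched_df, response=resp, predictor=pred)
        boot = bootstrap_lme_slope(
            matched_df,
            B=B,
            seed=stage_seed(seed, f"lme:{name}"),
            response=resp,
            predictor=pred,
        )
        out["lme"][name] = {
            "intercept": fit.intercept,
            "slope": fit.slope,
            "re_intercept_var": fit.re_intercept_var,
            "re_slope_var": fit.re_slope_var,
            "re_cov": fit.re_cov,
            "resid_var": fit.resid_var,
            "structure": fit.structure,
            "n_obs": fit.n_obs,
            "n_patients": fit.n_patients,
            "p_slope": boot.p_value,
            "slope_ci": [boot.ci_low, boot.ci_high],
        }
    pairs = [
        ("madrs~dep", "dep_sum", "madrs_total"),
        ("madrs~depnsp", "depnsp_sum", "madrs_total"),
        ("ymrs~man", "man_sum", "ymrs_total"),
        ("ymrs~mannsp", "man_sum", "ymrs_total"),
    ]
    for name, xcol, ycol in pairs:
        if name == "ymrs~mannsp":
            df = matched_df.copy()
            df["mannsp_sum"] = df["man_sum"] + df["nsp_sum"]
            wc = weighted_group_correlation(df, x="mannsp_sum", y=ycol)
        else:
            wc = weighted_group_correlation(matched_df, x=xcol, y=ycol)
        boot = case_bootstrap(
            lambda df, x=wc.x, y=wc.y: weighted_group_correlation(df, x=x, y=y).estimate,
            matched_df if name != "ymrs~mannsp" else df,
            B=B,
            seed=stage_seed(seed, f"wgr:{name}"),
        )
        out["correlations"][name] = {
            "rho_wgr": wc.estimate,
            "n_patients": int(len(wc.per_patient)),
            "n_excluded": wc.n_excluded,
            "p": boot.p_value,
            "ci": [boot.ci_low, boot.ci_high],
        }
    for label, wc in item_pair_correlations(matched_df).items():
        out["item_pairs"][label] = {
            "rho_wgr": wc.estimate,
            "n_patients": int(len(wc.per_patient)),
            "n_excluded": wc.n_excluded,
        }
    return out


def _detection_stage(
    matched_records,
    config: RunConfig,
    seed: int,
    run_ladder: bool = False,
) -> dict:
    out: dict = {}
    best_specs = {
        "dep": DetectionModelSpec("dep", ("depnsp_t", "depnsp_t-1"), "intercept"),
        "man": DetectionModelSpec("man", ("man_t",), "intercept"),
    }
    for outcome in ("dep", "man"):
        cohort = filter_detection_cohort(matched_records, outcome)
        block: dict = {
            "n_records": len(cohort),
            "n_patients": len({m.patient_id for m in cohort}),
        }
        if not cohort:
            block["note"] = "no patient with both relapse and nonrelapse records"
            out[outcome] = block
            continue
        df = matched_frame(cohort)
        label_col = "dep_relapse" if outcome == "dep" else "man_relapse"
        block["n_relapse"] = int(df[label_col].sum())
        spec = best_specs[outcome]
        if run_ladder:
            best, table = model_selection_ladder(
                df,
                default_ladder(outcome),
                reps=config.split_repetitions,
                ratio=config.split_ratio,
                target_specificity=config.target_specificity,
                seed=stage_seed(seed, f"ladder:{outcome}"),
            )
            spec = best
            block["ladder"] = table.to_dict(orient="records")
        rows = build_feature_table(df, spec)
        results = repeated_split_validation(
            rows,
            spec,
            ratio=config.split_ratio,
            reps=config.split_repetitions,
            target_specificity=config.target_specificity,
            seed=stage_seed(seed, f"detect:{outcome}"),
        )
        block["spec"] = spec.label
        block["n_feature_rows"] = int(len(rows))
        block["summary"] = summarize_metrics(results)
        out[outcome] = block
    return out


def run_pipeline(
    config: RunConfig,
    outdir: Path | str,
    generator: Optional[GeneratorConfig] = None,
    asert_path: Optional[Path] = None,
    clinical_path: Optional[Path] = None,
    patients_path: Optional[Path] = None,
    run_ladder: bool = False,
) -> RunManifest:
    """Execute all stages in order; a stage failure halts with a manifest
    recording the completed stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)
    manifest_path = outdir / "manifest.json"

    try:
        # Stage 1: inputs (synthetic or real).
        if generator is not None:
            paths = write_cohort(outdir, *generate_cohort(generator))
            asert_path = paths["asert"]
            clinical_path = paths["clinical"]
            patients_path = paths["patients"]
            for p in paths.values():
                manifest.record_file(p)
            manifest.completed_stages.append("simulate")
        else:
            for name, p in (
                ("asert", asert_path),
                ("clinical", clinical_path),
                ("patients", patients_path),
            ):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"real-data mode requires {name}.csv")
        asserts = read_asert_table(asert_path)
        clinical = read_clinical_table(clinical_path)
        patients = read_patient_table(patients_path)
        manifest.counts["asert_rows"] = len(asserts)
        manifest.counts["clinical_rows"] = len(clinical)
        manifest.counts["patients"] = len(patients)

        # Stage 2: matching.
        matched, report = match_concurrent(
            asserts, clinical, window_days=config.window_days
        )
        matched = attach_lags(matched, asserts, report)
        matched_path = outdir / "matched.csv"
        write_matched_table(matched, matched_path)
        manifest.record_file(matched_path)
        matching_path = outdir / "matching.json"
        _json_dump(report.as_dict(), matching_path)
        manifest.record_file(matching_path)
        manifest.counts["matched_rows"] = len(matched)
        manifest.completed_stages.append("match")

        stage_outputs: dict = {"matching": report.as_dict()}
        if not matched:
            logger.warning("empty matched set; downstream stages skipped")
        else:
            matched_df = matched_frame(matched)

            # Stage 3: psychometrics.
            psy = _psychometrics_stage(matched_df, patients, asserts)
            _json_dump(psy, outdir / "psychometrics.json")
            manifest.record_file(outdir / "psychometrics.json")
            manifest.completed_stages.append("psychometrics")
            stage_outputs["psychometrics"] = psy

            # Stage 4: convergent validity.
            val = _validity_stage(
                matched_df,
                B=config.bootstrap_resamples,
                seed=stage_seed(config.seed, "validate"),
            )
            _json_dump(val, outdir / "validity.json")
            manifest.record_file(outdir / "validity.json")
            manifest.completed_stages.append("validate")
            stage_outputs["validity"] = val

            # Stage 5: relapse detection.
            det = _detection_stage(
                matched, config, stage_seed(config.seed, "detect"), run_ladder
            )
            _json_dump(det, outdir / "detect.json")
            manifest.record_file(outdir / "detect.json")
            manifest.completed_stages.append("detect")
            stage_outputs["detection"] = det

        # Stage 6: report.
        report_md = render_report(stage_outputs)
        (outdir / "report.md").write_text(report_md)
        manifest.record_file(outdir / "report.md")
        manifest.completed_stages.append("report")
    finally:
        manifest.stage_seeds = {
            s: stage_seed(config.seed, s) for s in ("validate", "detect")
        }
        manifest.write(manifest_path)
    return manifest


def _fmt(v, nd=3) -> str:
    if v is None:
        return "-"
    if isinstance(v, float):
        return f"{v:.{nd}f}"
    return str(v)


def render_report(stage_outputs: dict) -> str:
    """Human-readable markdown report, a pure function of the stage JSON."""
    lines: list[str] = ["# Questionnaire validation and relapse detection report", ""]

    matching = stage_outputs.get("matching")
    if matching:
        lines += [
            "## Matching",
            "",
            f"- assessments: {matching['n_assessments']}",
            f"- self-reports: {matching['n_reports']}",
            f"- matched pairs: {matching['n_matched']}",
            f"- unmatched assessments: {matching['n_unmatched_assessments']}",
            f"- lag-1 attachments (4-10 days before): {matching['n_lag1']}",
            f"- lag-2 attachments (11-17 days before): {matching['n_lag2']}",
            "",
        ]
        if matching["n_matched"] == 0:
            lines += ["No matched records; downstream analyses were not run.", ""]
            return "\n".join(lines)

    psy = stage_outputs.get("psychometrics")
    if psy:
        lines += ["## Internal structure", ""]
        props = psy["pca"]["proportions"]
        sds = psy["pca"]["sds"]
        lines += ["| component | SD | proportion of variance | cumulative |",
                  "|---|---|---|---|"]
        for j in range(len(sds)):
            lines.append(
                f"| pc_{j + 1} | {_fmt(sds[j])} | {_fmt(props[j])} "
                f"| {_fmt(psy['pca']['cumulative'][j])} |"
            )
        lines += ["", "| item set | Cronbach alpha |", "|---|---|"]
        for k, v in psy["alphas"].items():
            lines.append(f"| {k} | {_fmt(v)} |")
        rr = psy["response_rate"]
        lines += [
            "",
            f"Response rate: mean {_fmt(rr['mean'])} (SD {_fmt(rr['sd'])}) "
            f"over {rr['n_patients']} patients.",
            "",
        ]
    else:
        lines += ["## Internal structure", "", "_Stage not run._", ""]

    val = stage_outputs.get("validity")
    if val:
        lines += ["## Convergent validity", "",
                  "| model | slope | intercept | p (bootstrap) | 95% CI |",
                  "|---|---|---|---|---|"]
        for name, m in val["lme"].items():
            lines.append(
                f"| {name} | {_fmt(m['slope'])} | {_fmt(m['intercept'])} "
                f"| {_fmt(m['p_slope'])} | [{_fmt(m['slope_ci'][0])}, "
                f"{_fmt(m['slope_ci'][1])}] |"
            )
        lines += ["", "| correlation | rho_wgr | p |", "|---|---|---|"]
        for name, c in val["correlations"].items():
            lines.append(f"| {name} | {_fmt(c['rho_wgr'])} | {_fmt(c['p'])} |")
        if val["item_pairs"]:
            lines += ["", "| item pair | rho_wgr |", "|---|---|"]
            for name, c in val["item_pairs"].items():
                lines.append(f"| {name} | {_fmt(c['rho_wgr'])} |")
        lines.append("")
    else:
        lines += ["## Convergent validity", "", "_Stage not run._", ""]

    det = stage_outputs.get("detection")
    if det:
        lines += ["## Relapse detection", ""]
        for outcome, block in det.items():
            title = "Depressive" if outcome == "dep" else "Manic"
            lines += [f"### {title} relapse", ""]
            if "summary" not in block:
                lines += [block.get("note", "_Not run._"), ""]
                continue
            lines += [
                f"Model: `{block['spec']}` on {block['n_feature_rows']} rows "
                f"({block['n_patients']} patients, {block['n_relapse']} relapses).",
                "",
                "| set | accuracy | sensitivity | specificity | AUROC |",
                "|---|---|---|---|---|",
            ]
            for set_label in ("train", "test"):
                s = block["summary"].get(set_label, {})
                if not s:
                    continue
                lines.append(
                    f"| {set_label} | {_fmt(s.get('accuracy', {}).get('mean'))} "
                    f"| {_fmt(s.get('sensitivity', {}).get('mean'))} "
                    f"| {_fmt(s.get('specificity', {}).get('mean'))} "
                    f"| {_fmt(s.get('auroc', {}).get('mean'))} |"
                )
            if "ladder" in block:
                lines += ["", "| simpler | more complex | win fraction | adopted |",
                          "|---|---|---|---|"]
                for p in block["ladder"]:
                    lines.append(
                        f"| {p['simple']} | {p['complex']} "
                        f"| {_fmt(p['win_fraction'])} | {p['adopted']} |"
                    )
            lines.append("")
    else:
        lines += ["## Relapse detection", "", "_Stage not run (no tables emitted)._", ""]

    return "\n".join(lines)
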