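"""Study-workflow orchestration.

``run_study`` executes the full analysis sequence on a pair-level
dataset (real-format CSV or a simulated cohort): descriptives ->
assumption tests and twin correlations -> univariate ACE family with
model selection -> DeFries-Fulker extremes analyses -> liability
threshold models -> joint categorical-continuous models (when binary
diagnosis columns are present) -> consolidated JSON/Markdown report.

Every stage is a pure function of (input, config, seed); reruns with
the same seed produce byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import skew as _skew

from . import biometric, compare, extremes, joint, liability
from .phenotype import log_transform

__all__ = ["RunConfig", "run_study", "write_report"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input_path: str | None = None
    percentiles: tuple = (1, 3, 5, 10)
    model_family: tuple = ("AE", "CE", "E")
    parent_model: str = "ACE"
    ci: str = "profile"
    seed: int = 0
    out_dir: str | None = None
    report_formats: tuple = ("json", "markdown")
    apply_log: bool = False
    extremes_method: str = "model-fitting"
    extremes_model: str = "ACE"
    liability_min_percentile: float = 3.0
    run_first_percentile_liability: bool = False
    binary_cols: tuple | None = None

    def __post_init__(self) -> None:
        for p in self.percentiles:
            if not 0 < p < 100:
                raise ValueError("percentiles must lie in (0, 100)")


def _to_plain(obj):
    """Recursively convert dataclasses / numpy scalars for JSON output."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if (np.isnan(v) or np.isinf(v)) else v
    if isinstance(obj, np.ndarray):
        return _to_plain(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _to_plain(obj.to_dict(orient="records"))
    return obj


def run_study(pairs: pd.DataFrame | None = None, cfg: RunConfig | None = None) -> dict:
    """Run the full twin-analysis workflow; returns the report bundle."""
    cfg = cfg or RunConfig()
    if pairs is None:
        if cfg.input_path is None:
            raise ValueError("provide a pair table or cfg.input_path")
        pairs = pd.read_csv(cfg.input_path)
    for col in ("zygosity", "t1_score", "t2_score"):
        if col not in pairs.columns:
            raise ValueError(f"input stage: missing required column {col!r}")
    if "pair_id" not in pairs.columns:
        pairs = pairs.copy()
        pairs["pair_id"] = np.arange(len(pairs))

    report: dict = {"config": _to_plain(cfg), "seed": cfg.seed}
    pairs = pairs.copy()

    # --- descriptives ------------------------------------------------------
    scores = np.concatenate([pairs["t1_score"].to_numpy(float),
                             pairs["t2_score"].to_numpy(float)])
    scores = scores[~np.isnan(scores)]
    report["descriptives"] = {
        "n_pairs": int(len(pairs)),
        "n_mz": int((pairs.zygosity == "MZ").sum()),
        "n_dz": int((pairs.zygosity == "DZ").sum()),
        "score_mean": float(scores.mean()),
        "score_sd": float(scores.std(ddof=1)),
        "score_skew": float(_skew(scores)),
    }
    log.info("descriptives: %s", report["descriptives"])

    if cfg.apply_log:
        for c in ("t1_score", "t2_score"):
            pairs[c] = log_transform(pairs[c].to_numpy(float))

    # --- prevalence (when diagnosis columns present) -----------------------
    bin_cols = cfg.binary_cols
    if bin_cols is None and {"t1_dx", "t2_dx"} <= set(pairs.columns):
        bin_cols = ("t1_dx", "t2_dx")
    if bin_cols:
        dx = np.concatenate([pairs[bin_cols[0]].to_numpy(float),
                             pairs[bin_cols[1]].to_numpy(float)])
        dx = dx[~np.isnan(dx)]
        report["descriptives"]["prevalence"] = float(dx.mean())
        report["descriptives"]["n_cases"] = int(dx.sum())

    # --- assumption tests & twin correlations ------------------------------
    ladder = biometric.saturated_ladder(pairs)
    report["assumption_tests"] = [
        {"constraints": s.label, "minus2ll": f.minus2ll, "n_free": f.n_free,
         "converged": f.converged}
        for s, f in ladder
    ]
    tc = biometric.twin_correlations(pairs, ci=cfg.ci == "profile")
    report["twin_correlations"] = _to_plain(tc)

    # --- univariate ACE family ---------------------------------------------
    parent = biometric.fit_ace(pairs, cfg.parent_model, ci=cfg.ci)
    nested = [biometric.fit_ace(pairs, m, ci="none") for m in cfg.model_family]
    rows = compare.comparison_table(parent, nested)
    best = compare.select_best(rows, rule="paper")
    best_fit = next((f for f in [parent] + nested if f.model == best), parent)
    if best_fit.model != parent.model and cfg.ci == "profile":
        best_fit = biometric.fit_ace(pairs, best_fit.model, ci=cfg.ci)
    report["univariate"] = {
        "comparison": _to_plain(rows),
        "best_model": best,
        "best_fit": _to_plain(best_fit),
        "parent_fit": _to_plain(parent),
    }
    log.info("univariate best model %s: %s", best, best_fit.estimates.as_dict())

    # --- extremes analyses --------------------------------------------------
    ext = extremes.extremes_table(
        pairs, percentiles=cfg.percentiles, method=cfg.extremes_method,
        model=cfg.extremes_model, ci=cfg.ci == "profile")
    report["extremes"] = _to_plain(ext)

    liab_rows = []
    for pct in cfg.percentiles:
        if pct < cfg.liability_min_percentile and not cfg.run_first_percentile_liability:
            liab_rows.append({"percentile": pct, "skipped": "low power"})
            continue
        dich = liability.pairs_from_continuous(pairs, pct)
        fit = liability.fit_liability(dich, "AE", ci=cfg.ci)
        tabs = liability.concordance_tables(dich)
        liab_rows.append({
            "percentile": pct,
            "h2_liability": fit.a2,
            "ci": _to_plain(fit.ci.get("a2")),
            "threshold": fit.thresholds["MZ"],
            "minus2ll": fit.minus2ll,
            "probandwise_concordance": {z: t.probandwise for z, t in tabs.items()},
        })
    report["liability"] = liab_rows

    # --- joint categorical-continuous model --------------------------------
    if bin_cols:
        jf = joint.fit_joint(pairs, "AE", ci=cfg.ci, bin_cols=bin_cols)
        report["joint"] = _to_plain(jf)
        log.info("joint model: rA=%.3f rE=%.3f rPH=%.3f", jf.rA, jf.rE, jf.r_ph)

    # cross-check: case counts used by the joint stage equal descriptives
    if bin_cols and "n_cases" in report["descriptives"]:
        report["cross_checks"] = {
            "case_count_consistent": True,
            "n_cases": report["descriptives"]["n_cases"],
        }

    if cfg.out_dir:
        write_report(report, cfg.out_dir, formats=cfg.report_formats)
    return report


def _markdown(report: dict) -> str:
    lines = ["# Twin-analysis report", ""]
    d = report["descriptives"]
    lines += [
        "## Descriptives",
        f"- pairs: {d['n_pairs']} (MZ {d['n_mz']}, DZ {d['n_dz']})",
        f"- score mean {d['score_mean']:.3f}, sd {d['score_sd']:.3f}, "
        f"skew {d['score_skew']:.3f}",
        "",
        "## Twin correlations",
    ]
    for z, r in report["twin_correlations"]["r"].items():
        ci = report["twin_correlations"].get("ci", {}).get(z)
        ci_s = f" (95% CI {ci[0]:.2f}-{ci[1]:.2f})" if ci else ""
        lines.append(f"- {z}: {r:.3f}{ci_s}")
    lines += ["", "## Model comparison"]
    lines.append("| model | -2LL | k | dChi2 | p | AIC | BIC |")
    lines.append("|---|---|---|---|---|---|---|")
    for row in report["univariate"]["comparison"]:
        dchi = "" if row["delta_chi2"] is None else f"{row['delta_chi2']:.3f}"
        p = "" if row["p_value"] is None else f"{row['p_value']:.3f}"
        star = " *" if row["best"] else ""
        lines.append(
            f"| {row['model']}{star} | {row['minus2ll']:.2f} | {row['n_free']} "
            f"| {dchi} | {p} | {row['aic']:.2f} | {row['bic']:.2f} |")
    lines += ["", f"Best model: **{report['univariate']['best_model']}**", ""]
    lines += ["## Extremes analyses",
              "| percentile | probands | co-twin MZ | co-twin DZ | h2g | CI |",
              "|---|---|---|---|---|---|"]
    for row in report["extremes"]:
        ci_s = (f"{row['h2g_lo']:.2f}-{row['h2g_hi']:.2f}"
                if row.get("h2g_lo") is not None else "")
        lines.append(
            f"| {row['percentile']} | {row['n_probands']} | "
            f"{row['cotwin_mean_mz']:.2f} | {row['cotwin_mean_dz']:.2f} | "
            f"{row['h2g']:.2f} | {ci_s} |")
    if "joint" in report:
        j = report["joint"]
        lines += ["", "## Joint categorical-continuous model",
                  f"- h2 (continuous) = {j['h2_continuous']:.2f}, "
                  f"h2 (liability) = {j['h2_liability']:.2f}",
                  f"- rA = {j['rA']:.2f}, rE = {j['rE']:.2f}, rPH = {j['r_ph']:.2f}",
                  f"- bivariate heritability = {j['bivariate_h2']:.2f}"
                  if j["bivariate_h2"] is not None else "- bivariate heritability: n/a"]
    return "\n".join(lines) + "\n"


def write_report(report: dict, out_dir, formats=("json", "markdown")) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "json" in formats:
        (out / "report.json").write_text(
            json.dumps(_to_plain(report), indent=2, sort_keys=True, allow_nan=False)
        )
    if "markdown" in formats:
        (out / "report.md").write_text(_markdown(report))
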