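"""End-to-end pipeline: simulate/load → exclude → match → align → bin →
enrichment scan → CLR scans (primary and sensitivity variants) → ROC scans →
risk scores, with a machine-readable run manifest.

All randomness flows from one root seed through named substreams, so a rerun
with the same config and seed is byte-identical, and any stage can be re-run
from cached upstream CSVs.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, load_risk_coefficients, dump_json
from .simulate import simulate_cohort
from .cohort import (apply_exclusions, match, align_all, matched_sets_frame)
from .panel import bin_monthly, cumulative_curve
from .enrichment import EnrichmentScan
from .clr import MonthlyCLRScan, cumulative_clr, unconditional_logistic
from .roc import ROCScan
from .risk import risk_scores

SENSITIVITY_SETS: dict[str, tuple[str, ...]] = {
    "primary": ("oc_ever", "household_size"),
    "covid": ("oc_ever", "household_size", "covid_era"),
    "season": ("oc_ever", "household_size", "season"),
    "gp_visits": ("oc_ever", "household_size", "gp_visits"),
    "symptoms": ("oc_ever", "household_size", "symptom_any"),
    "risk_score": ("oc_ever", "household_size", "risk_score"),
}


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {err}")
        self.stage = stage


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, seed: int | None = None) -> dict:
    """Run the full analysis and write the report bundle to config.out_dir.

    Returns a dict of in-memory results keyed by stage. Any stage failure
    raises :class:`StageError` naming the stage; outputs written so far are
    retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = config.seed if seed is None else seed
    results: dict = {}
    manifest = {
        "software": f"otcscan {__version__}",
        "seed": int(root_seed),
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "stages": [],
    }

    def stage(name):
        manifest["stages"].append(name)
        return name

    try:
        stage("data")
        if config.sim is not None:
            roster, log, gt = simulate_cohort(config.sim, seed=root_seed)
            roster.to_csv(out / "roster.csv", index=False)
            log.to_csv(out / "transactions.csv", index=False)
            dump_json(gt.to_jsonable(), out / "ground_truth.json")
            results["ground_truth"] = gt
        else:
            for p in (config.roster_path, config.transactions_path):
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            roster = pd.read_csv(config.roster_path)
            log = pd.read_csv(config.transactions_path)
        results["roster"], results["transactions"] = roster, log
    except Exception as e:
        raise StageError("data", e) from e

    try:
        stage("exclusions")
        eligible, flow = apply_exclusions(roster)
        results["flow_report"] = flow
        dump_json(flow, out / "flow_report.json")
    except Exception as e:
        raise StageError("exclusions", e) from e

    try:
        stage("matching")
        sets, match_report = match(eligible, ratio=config.match_ratio)
        sets = align_all(sets, eligible)
        msf = matched_sets_frame(sets)
        msf.to_csv(out / "matched_sets.csv", index=False)
        results["matched_sets"] = sets
        results["match_report"] = match_report
        dump_json(match_report, out / "match_report.json")
    except Exception as e:
        raise StageError("matching", e) from e

    try:
        stage("binning")
        panel = bin_monthly(log, sets,
                            known_participants=set(roster["participant_id"]))
        results["panel"] = panel
    except Exception as e:
        raise StageError("binning", e) from e

    try:
        stage("enrichment_scan")
        scan = EnrichmentScan(panel, target=config.target_categories,
                              variant=config.table_variant,
                              or_variant=config.or_variant,
                              target_variant=config.target_variant,
                              window_style=config.window_style,
                              bonferroni=config.bonferroni).fit()
        scan.table.to_csv(out / "enrichment_scan.csv", index=False)
        curves = cumulative_curve(panel, categories=list(config.target_categories))
        curves.to_csv(out / "cumulative_curves.csv")
        results["enrichment"] = scan
        results["cumulative_curves"] = curves
    except Exception as e:
        raise StageError("enrichment_scan", e) from e

    try:
        stage("risk_scores")
        coefs = load_risk_coefficients()
        rs = risk_scores(eligible, coefs)
        rs.to_csv(out / "risk_scores.csv")
        results["risk_scores"] = rs
    except Exception as e:
        raise StageError("risk_scores", e) from e

    try:
        stage("risk_table")
        rows = []
        for label, covs in (("unadjusted", ["oc_ever"]),
                            ("adjusted", ["age_years", "oc_ever",
                                          "postmenopausal", "hrt_ever"])):
            fit = unconditional_logistic(eligible, covs)
            ci = np.exp(fit.conf_int())
            for term in fit.params.index:
                if term == "const":
                    continue
                rows.append({"model": label, "term": term,
                             "or": float(np.exp(fit.params[term])),
                             "ci_lo": float(ci.loc[term, 0]),
                             "ci_hi": float(ci.loc[term, 1]),
                             "p": float(fit.pvalues[term])})
        risk_table = pd.DataFrame(rows)
        risk_table.to_csv(out / "risk_table.csv", index=False)
        results["risk_table"] = risk_table
    except Exception as e:
        raise StageError("risk_table", e) from e

    try:
        stage("clr_scans")
        clr_tables = []
        score_series = rs["score"]
        for variant, adj in SENSITIVITY_SETS.items():
            for cat_name, cats in (
                    ("combined", tuple(config.target_categories)),
                    ("pain", ("pain",)), ("indigestion", ("indigestion",))):
                if not set(cats) <= set(panel.categories):
                    continue
                res = MonthlyCLRScan(panel, eligible, category=cats,
                                     adjustments=adj,
                                     exposure=config.clr_exposure,
                                     window_style=config.window_style,
                                     risk_scores=score_series).fit()
                t = res.table.copy()
                t.insert(0, "category", cat_name)
                t.insert(0, "variant", variant)
                clr_tables.append(t)
                if variant == "primary":
                    results[f"clr_{cat_name}"] = res
        clr_all = pd.concat(clr_tables, ignore_index=True)
        clr_all.to_csv(out / "clr_scan.csv", index=False)
        cum = cumulative_clr(panel, eligible,
                             category=tuple(config.target_categories),
                             adjustments=SENSITIVITY_SETS["primary"])
        cum.to_csv(out / "clr_cumulative.csv", index=False)
        results["clr_cumulative"] = cum
    except Exception as e:
        raise StageError("clr_scans", e) from e

    try:
        stage("roc_scans")
        roc_tables = []
        for cat in config.target_categories:
            if cat not in panel.categories:
                continue
            res = ROCScan(panel, eligible, category=cat,
                          score=config.roc_score,
                          rng=np.random.default_rng(
                              np.random.SeedSequence([root_seed, 7]))).fit()
            roc_tables.append(res.table)
            results[f"roc_{cat}"] = res
        roc_all = pd.concat(roc_tables, ignore_index=True)
        roc_all.to_csv(out / "roc_scan.csv", index=False)
    except Exception as e:
        raise StageError("roc_scans", e) from e

    stage("report")
    summary = _summarise(results, config)
    (out / "summary.txt").write_text(summary)
    dump_json(manifest, out / "run_manifest.json")
    results["summary"] = summary
    results["manifest"] = manifest
    return results


def _summarise(results: dict, config: PipelineConfig) -> str:
    lines = ["otcscan pipeline summary", "=" * 30]
    flow = results["flow_report"]["eligible"]
    lines.append(f"eligible: {flow['cases']} cases, {flow['controls']} controls")
    mr = results["match_report"]
    lines.append(f"matched sets: {mr['n_sets']} "
                 f"({mr['n_control_slots']} control slots, "
                 f"{mr['n_unique_controls']} unique controls); "
                 f"median age diff {mr['age_diff_median']:.1f} y "
                 f"(IQR {mr['age_diff_iqr'][0]:.1f} to {mr['age_diff_iqr'][1]:.1f})")
    scan = results["enrichment"]
    lines.append(scan.summary().splitlines()[-1] if scan.argmax_month is not None
                 else "enrichment scan: no non-degenerate month")
    sig = scan.table[scan.table["p"] < 0.05]
    bonf = scan.table[scan.table["p"] * len(scan.table) < 0.05]
    lines.append(f"months with p<0.05: {len(sig)}/24; "
                 f"after Bonferroni: {len(bonf)}/24"
                 + ("" if len(bonf) else " (no month significant after Bonferroni)"))
    for cat in ("combined", "pain", "indigestion"):
        key = f"clr_{cat}"
        if key in results:
            t = results[key].exposure_table()
            inc = t[(t["ci_lo"] > 1) & t["converged"]]
            first = int(inc["month"].min()) if len(inc) else None
            lines.append(f"CLR {cat}: earliest month with CI>1: {first}")
    for cat in config.target_categories:
        key = f"roc_{cat}"
        if key in results:
            lines.append(results[key].summary())
    return "\n".join(lines) + "\n"
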