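"""End-to-end orchestration: simulate -> screen -> build score -> evaluate.

Every stage logs its filter decisions into a JSON audit structure (which
biomarker was removed by which rule, which cutoff candidates were dropped,
which rows were rejected on input), and identical seeds and configs produce
byte-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import screen as sc
from . import score as sco
from .config import RunConfig, sim_config_from_dict
from .io import write_cohort
from .trialsim import simulate_cohort, censoring_summary

__all__ = ["run_pipeline", "write_artifacts", "dump_json"]

MAX_CUTOFFS_PER_BIOMARKER = 4  # keeps the candidate product at trial scale


def dump_json(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n"


def _cohort_seeds(seed: int, names: list[str]) -> dict[str, int]:
    state = np.random.SeedSequence(seed).generate_state(len(names))
    return {name: int(s % 2**31) for name, s in zip(names, state)}


def _thin(cuts: list[float], k: int) -> list[float]:
    if len(cuts) <= k:
        return cuts
    idx = np.unique(np.round(np.linspace(0, len(cuts) - 1, k)).astype(int))
    return [cuts[i] for i in idx]


def run_pipeline(
    config: RunConfig,
    cohorts: dict[str, pd.DataFrame] | None = None,
) -> dict:
    """Run the full discovery pipeline; returns the artifact set in memory.

    ``cohorts`` may supply pre-loaded tables (e.g. from ``read_cohort``);
    otherwise cohorts are simulated per the config, with per-cohort seeds
    derived deterministically from ``config.seed``.
    """
    config.validate()
    audit: dict = {"stages": {}}

    # --- stage 1: cohorts
    if cohorts is None:
        names = sorted(config.cohorts)
        seeds = _cohort_seeds(config.seed, names)
        cohorts = {}
        for name in names:
            spec = config.cohorts[name]
            simcfg = sim_config_from_dict(
                config.simulation,
                n_treated=spec.n_treated,
                n_control=spec.n_control,
                cohort_label=name,
                seed=seeds[name],
            )
            cohorts[name] = simulate_cohort(simcfg)
    audit["stages"]["cohorts"] = {
        name: censoring_summary(df).to_dict(orient="records")
        for name, df in cohorts.items()
    }

    combined = pd.concat(cohorts.values(), ignore_index=True)
    panel = sc.derive_ratios(combined)
    biomarkers = config.biomarkers or sc.default_biomarkers()

    # --- stage 2: fraction scans, both arms
    have_control = (combined["arm"] == "control").any()
    scans_treated: list[sc.CutoffScanResult] = []
    scans_control: list[sc.CutoffScanResult] = []
    for marker in biomarkers:
        ref = panel.loc[combined["arm"] == "treated", marker]
        ref = ref[np.isfinite(ref)].to_numpy()
        for endpoint in sc.ENDPOINTS:
            scans_treated += sc.scan_biomarker(
                combined, panel, marker, endpoint, "treated",
                fractions=config.fractions, reference_values=ref,
                min_events=config.min_events, landmark=config.landmark,
            )
            if have_control:
                scans_control += sc.scan_biomarker(
                    combined, panel, marker, endpoint, "control",
                    fractions=config.fractions, reference_values=ref,
                    min_events=config.min_events, landmark=config.landmark,
                )
    cascade = sc.screening_cascade(
        scans_treated, scans_control, share=config.share, alpha=config.significance
    )
    audit["stages"]["cascade"] = cascade.audit

    # --- stage 3: rank survivors, narrow cutoffs, confirm per cohort
    def strength(marker: str) -> float:
        ps = [c.p for c in scans_treated if c.biomarker == marker and c.estimable]
        return float(np.mean(-np.log10(np.clip(ps, 1e-300, 1.0)))) if ps else 0.0

    ranked = sorted(cascade.retained, key=lambda m: (-strength(m), m))
    chosen = ranked[: config.max_biomarkers]
    cutoff_lists: dict[str, list[float]] = {}
    narrowing: dict[str, dict] = {}
    for marker in chosen:
        ref = panel.loc[combined["arm"] == "treated", marker]
        try:
            cands = sc.narrow_integer_cutoffs(ref, config.fraction_range)
        except ValueError as exc:
            narrowing[marker] = {"candidates": [], "dropped": str(exc)}
            continue
        confirmed = sc.confirm_integer_cutoffs(
            cohorts, marker, cands,
            alpha=config.significance, min_events=config.min_events,
            landmark=config.landmark,
        )
        kept = _thin(confirmed, MAX_CUTOFFS_PER_BIOMARKER)
        narrowing[marker] = {
            "candidates": cands,
            "confirmed": confirmed,
            "used": kept,
        }
        if kept:
            cutoff_lists[marker] = kept
    audit["stages"]["narrowing"] = narrowing

    # --- stage 4: candidate enumeration and selection
    selection = None
    model = None
    if cutoff_lists:
        candidates = sco.enumerate_candidates(
            cutoff_lists, config.combination_rule, config.count_threshold
        )
        selection = sco.select_candidate(
            candidates, cohorts,
            horizon=config.horizon, alpha=config.significance,
            min_events=config.min_events, landmark=config.landmark,
        )
        model = selection.selected
        audit["stages"]["selection"] = {
            "n_candidates": len(candidates),
            "selected": model.candidate_id if model else None,
            "warning": selection.warning,
        }
    else:
        audit["stages"]["selection"] = {
            "n_candidates": 0, "selected": None,
            "warning": "no biomarker survived screening and cutoff confirmation",
        }

    # --- stage 5: evaluation report
    report = None
    if model is not None:
        report = ev.assemble_report(
            model, cohorts,
            horizon=config.horizon, alpha=config.significance,
            min_events=config.min_events, landmark=config.landmark,
        )

    return {
        "config": config.to_dict(),
        "cohorts": cohorts,
        "scans": sc.scan_table(scans_treated + scans_control),
        "audit": audit,
        "selection": selection,
        "model": model,
        "report": report,
    }


def write_artifacts(result: dict, outdir) -> list[Path]:
    """Write the artifact set as UTF-8 delimited text and JSON files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, df in result["cohorts"].items():
        p = out / f"cohort_{name}.csv"
        write_cohort(df, p)
        written.append(p)

    p = out / "scans.csv"
    result["scans"].to_csv(p, index=False, float_format="%.10g")
    written.append(p)

    p = out / "audit.json"
    p.write_text(dump_json(result["audit"]))
    written.append(p)

    model = result["model"]
    p = out / "model.json"
    p.write_text(dump_json(model.to_dict() if model else None))
    written.append(p)

    sel = result["selection"]
    if sel is not None:
        p = out / "selection.csv"
        sel.table.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    if result["report"] is not None:
        p = out / "report.json"
        p.write_text(dump_json(result["report"]))
        written.append(p)
        p = out / "summary.txt"
        p.write_text(ev.render_summary(result["report"]))
        written.append(p)
    return written
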