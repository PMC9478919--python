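"""Final evaluation: predictive-vs-prognostic assessment and reporting.

A *prognostic* biomarker separates outcomes regardless of treatment; a
*predictive* one modifies the treatment effect. The decisive check is the
within-stratum treatment hazard ratio in a randomized two-arm cohort: if the
treated-vs-control HR differs between score-high and score-low patients, the
score carries predictive information. Both the informal criterion
(discordant CI significance across strata) and a formal treatment-by-score
interaction Cox model are computed, because the informal criterion alone is
statistically fragile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import survstats as ss
from .screen import derive_ratios, landmark_subset
from .score import CB_SET, ORR_SET, ScoreCandidate, classify, rule_count

__all__ = [
    "StratumFit",
    "PredictiveAssessment",
    "predictive_assessment",
    "auc_comparison",
    "km_by_group",
    "assemble_report",
]


@dataclass
class StratumFit:
    """Treatment (treated vs control) Cox fit within one risk stratum."""

    stratum: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    estimable: bool
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "stratum": self.stratum, "hr": self.hr, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p, "n": self.n,
            "n_events": self.n_events, "estimable": self.estimable,
            "reason": self.reason,
        }


@dataclass
class PredictiveAssessment:
    endpoint: str
    high: StratumFit
    low: StratumFit
    interaction_coef: float
    interaction_p: float
    predictive_discordant: bool   # one stratum CI excludes 1, the other does not
    predictive_interaction: bool  # interaction Wald p <= alpha

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "high": self.high.to_dict(),
            "low": self.low.to_dict(),
            "interaction_coef": self.interaction_coef,
            "interaction_p": self.interaction_p,
            "predictive_discordant": self.predictive_discordant,
            "predictive_interaction": self.predictive_interaction,
        }


def _treatment_fit(sub, times, events, label, min_events) -> StratumFit:
    treated = (sub["arm"] == "treated").to_numpy(dtype=float)
    n = len(sub)
    n_ev = int(events.sum())
    try:
        if min(events[treated == 1].sum(), events[treated == 0].sum()) < min_events:
            raise ValueError(f"fewer than {min_events} events in an arm")
        fit = ss.fit_cox(times, events, treated[:, None])
        return StratumFit(
            stratum=label, hr=float(fit.hr[0]), ci_low=float(fit.ci_low[0]),
            ci_high=float(fit.ci_high[0]), p=float(fit.wald_p[0]),
            n=n, n_events=n_ev, estimable=fit.converged,
            reason=None if fit.converged else "non-convergence",
        )
    except ValueError as exc:
        return StratumFit(
            stratum=label, hr=math.nan, ci_low=math.nan, ci_high=math.nan,
            p=math.nan, n=n, n_events=n_ev, estimable=False, reason=str(exc),
        )


def predictive_assessment(
    cohort: pd.DataFrame,
    candidate: ScoreCandidate,
    endpoints=("OS", "PFS"),
    alpha: float = ss.ALPHA,
    min_events: int = 10,
    landmark: bool = True,
) -> dict[str, PredictiveAssessment]:
    """Within-stratum treatment effects of a two-arm cohort.

    Fits the treatment indicator separately within the score-high and
    score-low strata (disjoint sets whose union is the evaluable cohort) and
    a joint Cox model with a treatment-by-risk interaction term, per
    endpoint. The score is flagged predictive when the stratum CIs are
    discordant with respect to 1, or when the interaction p <= alpha.
    """
    arms = set(cohort["arm"].unique())
    if not {"treated", "control"} <= arms:
        raise ValueError("both arms required for a predictive assessment")
    panel = derive_ratios(cohort)
    risk = classify(panel, candidate)
    tp = candidate.landmark_timepoint

    out: dict[str, PredictiveAssessment] = {}
    for endpoint in endpoints:
        sub, times, events = landmark_subset(cohort, endpoint, tp, landmark)
        r = risk.loc[sub.index]
        ok = r.notna().to_numpy()
        sub, times, events, r = sub[ok], times[ok], events[ok], r[ok]
        high_m = (r == "high").to_numpy()

        fits = {}
        for label, mask in (("high", high_m), ("low", ~high_m)):
            fits[label] = _treatment_fit(
                sub[mask], times[mask], events[mask], label, min_events
            )

        treated = (sub["arm"] == "treated").to_numpy(dtype=float)
        inter_coef = inter_p = math.nan
        try:
            X = np.column_stack([treated, high_m.astype(float), treated * high_m])
            fit = ss.fit_cox(times, events, X)
            if fit.converged:
                inter_coef, inter_p = float(fit.coef[2]), float(fit.wald_p[2])
        except (ValueError, np.linalg.LinAlgError):
            pass

        hi, lo = fits["high"], fits["low"]
        discordant = False
        if hi.estimable and lo.estimable:
            hi_sig = not (hi.ci_low <= 1.0 <= hi.ci_high)
            lo_sig = not (lo.ci_low <= 1.0 <= lo.ci_high)
            discordant = hi_sig != lo_sig
        out[endpoint] = PredictiveAssessment(
            endpoint=endpoint, high=hi, low=lo,
            interaction_coef=inter_coef, interaction_p=inter_p,
            predictive_discordant=discordant,
            predictive_interaction=bool(np.isfinite(inter_p) and inter_p <= alpha),
        )
    return out


def auc_comparison(
    cohort: pd.DataFrame,
    candidate: ScoreCandidate,
    single_biomarkers: list[str] | None = None,
    endpoints=("OS", "PFS"),
    horizon: float = 12.0,
    landmark: bool = True,
) -> pd.DataFrame:
    """AUC of the ordinal score against each of its single biomarkers.

    The score enters as the number of positive rules (0..#rules); single
    biomarkers enter on their continuous scale. One row per marker x
    endpoint, flagging whether the score's AUC is at least the marker's.
    """
    treated = cohort[cohort["arm"] == "treated"] if "arm" in cohort else cohort
    panel = derive_ratios(treated)
    counts = rule_count(panel, candidate)
    if single_biomarkers is None:
        single_biomarkers = [b for b, _ in candidate.rules]
    tp = candidate.landmark_timepoint

    rows = []
    for endpoint in endpoints:
        sub, times, events = landmark_subset(treated, endpoint, tp, landmark)
        c = counts.loc[sub.index]
        ok = c.notna().to_numpy()
        try:
            score_auc = ss.td_roc_auc(
                c[ok].to_numpy(dtype=float), times[ok], events[ok], horizon
            ).auc
        except ValueError:
            score_auc = math.nan
        rows.append(
            {"marker": "score", "endpoint": endpoint, "auc": score_auc,
             "score_auc_ge": True}
        )
        for marker in single_biomarkers:
            v = panel.loc[sub.index, marker]
            mok = ok & v.notna().to_numpy()
            try:
                auc = ss.td_roc_auc(
                    v[mok].to_numpy(dtype=float), times[mok], events[mok], horizon
                ).auc
            except ValueError:
                auc = math.nan
            rows.append(
                {
                    "marker": marker, "endpoint": endpoint, "auc": auc,
                    "score_auc_ge": bool(score_auc >= auc)
                    if np.isfinite(score_auc) and np.isfinite(auc) else False,
                }
            )
    return pd.DataFrame(rows)


def km_by_group(
    cohort: pd.DataFrame,
    candidate: ScoreCandidate,
    endpoint: str = "OS",
    landmark: bool = True,
) -> dict[str, dict]:
    """Kaplan-Meier series per (risk group x arm) cell, from the landmark."""
    panel = derive_ratios(cohort)
    risk = classify(panel, candidate)
    tp = candidate.landmark_timepoint
    sub, times, events = landmark_subset(cohort, endpoint, tp, landmark)
    r = risk.loc[sub.index]
    ok = r.notna().to_numpy()
    sub, times, events, r = sub[ok], times[ok], events[ok], r[ok]

    out: dict[str, dict] = {}
    for (grp, arm), mask in (
        ((g, a), (r == g).to_numpy() & (sub["arm"] == a).to_numpy())
        for g in ("high", "low")
        for a in sorted(sub["arm"].unique())
    ):
        n = int(mask.sum())
        cell = {"n": n}
        if n and events[mask].sum() > 0:
            km = ss.km_estimate(times[mask], events[mask])
            cell.update(
                times=[float(x) for x in km.times],
                survival=[float(x) for x in km.survival],
                median=float(km.median) if np.isfinite(km.median) else None,
                n_events=int(km.n_event.sum()),
            )
        out[f"{grp}|{arm}"] = cell
    return out


def assemble_report(
    model: ScoreCandidate,
    cohorts: dict[str, pd.DataFrame],
    horizon: float = 12.0,
    alpha: float = ss.ALPHA,
    min_events: int = 10,
    landmark: bool = True,
) -> dict:
    """Single JSON-serializable evaluation report over all cohorts.

    Per cohort: evaluable-count accounting, KM series by risk x arm, AUC
    comparison table, and — when both arms are present — the within-stratum
    treatment HRs with the interaction test. Byte-identical for identical
    inputs.
    """
    if not cohorts:
        raise ValueError("missing required sections: no cohorts")
    report: dict = {
        "model": model.to_dict(),
        "horizon_months": float(horizon),
        "alpha": alpha,
        "landmark": landmark,
        "cohorts": {},
    }
    for name in sorted(cohorts):
        df = cohorts[name]
        panel = derive_ratios(df)
        risk = classify(panel, model)
        section: dict = {
            "n": int(len(df)),
            "n_evaluable": int(risk.notna().sum()),
            "n_high": int((risk == "high").sum()),
            "n_low": int((risk == "low").sum()),
            "km": km_by_group(df, model, "OS", landmark),
            "auc": auc_comparison(
                df, model, horizon=horizon, landmark=landmark
            ).to_dict(orient="records"),
        }
        if {"treated", "control"} <= set(df["arm"].unique()):
            section["predictive"] = {
                ep: pa.to_dict()
                for ep, pa in predictive_assessment(
                    df, model, alpha=alpha, min_events=min_events, landmark=landmark
                ).items()
            }
        else:
            section["predictive"] = None
            section["gaps"] = ["single-arm cohort: no treatment-effect contrast"]
        report["cohorts"][name] = section
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of an evaluation report."""
    lines = []
    m = report["model"]
    rules = ", ".join(f"{b} >= {c:g}" for b, c in m["rules"])
    lines.append(f"score {m['candidate_id'] or '(unnamed)'}: {rules}")
    lines.append(f"combination rule: {m['combination_rule']}")
    for name, sec in report["cohorts"].items():
        lines.append(
            f"[{name}] n={sec['n']} evaluable={sec['n_evaluable']} "
            f"high={sec['n_high']} low={sec['n_low']}"
        )
        for row in sec["auc"]:
            lines.append(
                f"  AUC {row['endpoint']:>3} {row['marker']:<10} = {row['auc']:.3f}"
            )
        if sec.get("predictive"):
            for ep, pa in sec["predictive"].items():
                hi, lo = pa["high"], pa["low"]
                lines.append(
                    f"  {ep} treatment HR high-risk {hi['hr']:.2f} "
                    f"({hi['ci_low']:.2f}-{hi['ci_high']:.2f}, p={hi['p']:.3f}); "
                    f"low-risk {lo['hr']:.2f} "
                    f"({lo['ci_low']:.2f}-{lo['ci_high']:.2f}, p={lo['p']:.3f}); "
                    f"interaction p={pa['interaction_p']:.3f}"
                )
    return "\n".join(lines) + "\n"
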