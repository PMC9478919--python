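"""Threshold-combination risk scores: enumeration, classification, selection.

A score candidate is a set of (biomarker, absolute cutoff) rules combined
into a single high/low risk call. Candidates are enumerated as the Cartesian
product of per-biomarker cutoff options, patients are classified by counting
boundary-inclusive rule hits (value >= cutoff), and the final model is the
candidate with the best worst-case (min across cohorts) OS AUC among those
significant for OS, PFS, clinical benefit and objective response in every
cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import survstats as ss
from .screen import clinical_covariates, derive_ratios, landmark_subset
from .trialsim import LANDMARK_MONTHS

__all__ = [
    "ScoreCandidate",
    "SelectionResult",
    "enumerate_candidates",
    "classify",
    "rule_count",
    "select_candidate",
    "candidate_from_dict",
]

COMBINATION_RULES = ("any_high", "majority", "all_high", "count_threshold")

# responses counting as clinical benefit / objective response
CB_SET = ("CR", "PR", "SD")
ORR_SET = ("CR", "PR")


@dataclass(frozen=True)
class ScoreCandidate:
    """A threshold-combination score: rules plus a combination rule."""

    rules: tuple[tuple[str, float], ...]   # ((biomarker, absolute cutoff), ...)
    combination_rule: str = "any_high"
    count_threshold: int | None = None     # only for combination_rule="count_threshold"
    candidate_id: str = ""

    def __post_init__(self):
        if not self.rules:
            raise ValueError("a candidate needs at least one rule")
        if any(cut <= 0 for _, cut in self.rules):
            raise ValueError("cutoffs must be positive")
        if self.combination_rule not in COMBINATION_RULES:
            raise ValueError(f"unknown combination rule {self.combination_rule!r}")
        if self.combination_rule == "count_threshold":
            k = self.count_threshold
            if k is None or not 1 <= k <= len(self.rules):
                raise ValueError("count_threshold must satisfy 1 <= k <= #rules")

    @property
    def required_hits(self) -> int:
        n = len(self.rules)
        return {
            "any_high": 1,
            "majority": n // 2 + 1,
            "all_high": n,
            "count_threshold": self.count_threshold or 1,
        }[self.combination_rule]

    @property
    def landmark_timepoint(self) -> str:
        """Latest timepoint among the rule biomarkers (the score's landmark)."""
        tps = [b.rsplit("_", 1)[-1] for b, _ in self.rules]
        return max(tps, key=lambda tp: LANDMARK_MONTHS[tp])

    def to_dict(self) -> dict:
        return {
            "candidate_id": self.candidate_id,
            "rules": [[b, c] for b, c in self.rules],
            "combination_rule": self.combination_rule,
            "count_threshold": self.count_threshold,
        }


def candidate_from_dict(d: dict) -> ScoreCandidate:
    return ScoreCandidate(
        rules=tuple((str(b), float(c)) for b, c in d["rules"]),
        combination_rule=d.get("combination_rule", "any_high"),
        count_threshold=d.get("count_threshold"),
        candidate_id=d.get("candidate_id", ""),
    )


def enumerate_candidates(
    cutoff_candidates: dict[str, list[float]],
    combination_rule: str = "any_high",
    count_threshold: int | None = None,
) -> list[ScoreCandidate]:
    """Cartesian product of per-biomarker cutoff options (one per biomarker)."""
    for marker, cuts in cutoff_candidates.items():
        if not cuts:
            raise ValueError(f"empty cutoff list for {marker!r}")
    markers = sorted(cutoff_candidates)
    grids = [cutoff_candidates[m] for m in markers]
    total = math.prod(len(g) for g in grids)
    width = max(2, len(str(total)))
    out = []
    for i, combo in enumerate(itertools.product(*grids), start=1):
        out.append(
            ScoreCandidate(
                rules=tuple(zip(markers, [float(c) for c in combo])),
                combination_rule=combination_rule,
                count_threshold=count_threshold,
                candidate_id=f"C{i:0{width}d}",
            )
        )
    return out


def rule_count(panel: pd.DataFrame, candidate: ScoreCandidate) -> pd.Series:
    """Number of positive rules per patient (NaN when any ratio is missing)."""
    for marker, _ in candidate.rules:
        if marker not in panel.columns:
            raise ValueError(f"candidate references unknown biomarker {marker!r}")
    hits = pd.Series(0.0, index=panel.index)
    evaluable = pd.Series(True, index=panel.index)
    for marker, cut in candidate.rules:
        v = panel[marker]
        evaluable &= v.notna()
        hits += (v >= cut).astype(float)
    return hits.where(evaluable)


def classify(panel: pd.DataFrame, candidate: ScoreCandidate) -> pd.Series:
    """Per-patient risk call: "high" / "low", NA when any rule biomarker missing."""
    counts = rule_count(panel, candidate)
    out = pd.Series(pd.NA, index=panel.index, dtype="object", name=candidate.candidate_id)
    out[counts >= candidate.required_hits] = "high"
    out[counts < candidate.required_hits] = "low"
    return out


@dataclass
class SelectionResult:
    table: pd.DataFrame
    selected: ScoreCandidate | None
    warning: str | None = None
    candidates: list[ScoreCandidate] = field(default_factory=list)


def _evaluate_candidate_in_cohort(
    candidate: ScoreCandidate,
    cohort: pd.DataFrame,
    horizon: float,
    min_events: int,
    landmark: bool,
) -> dict:
    """Per-cohort metrics: Cox HR/p (uni+multi) for OS/PFS, RR for CB/ORR,
    time-dependent AUC for OS/PFS and ordinal AUC for CB/ORR."""
    treated = cohort[cohort["arm"] == "treated"] if "arm" in cohort else cohort
    panel = derive_ratios(treated)
    counts = rule_count(panel, candidate)
    risk_high = counts >= candidate.required_hits
    tp = candidate.landmark_timepoint
    row: dict = {"n_evaluable": int(counts.notna().sum())}

    for endpoint in ("OS", "PFS"):
        sub, times, events = landmark_subset(treated, endpoint, tp, landmark)
        c = counts.loc[sub.index]
        ok = c.notna().to_numpy()
        t, e = times[ok], events[ok]
        high = risk_high.loc[sub.index].to_numpy()[ok]
        ordinal = c.to_numpy(dtype=float)[ok]
        key = endpoint.lower()
        for analysis in ("univariate", "multivariate"):
            hr = p = math.nan
            try:
                X = high.astype(float)[:, None]
                if analysis == "multivariate":
                    cmat = clinical_covariates(sub[ok])
                    cc = cmat.notna().all(axis=1).to_numpy()
                    X = np.hstack([X[cc], cmat[cc].to_numpy(dtype=float)])
                    fit = ss.fit_cox(t[cc], e[cc], X)
                else:
                    fit = ss.fit_cox(t, e, X)
                if fit.converged and min(e[high].sum(), e[~high].sum()) >= min_events:
                    hr, p = float(fit.hr[0]), float(fit.wald_p[0])
            except (ValueError, np.linalg.LinAlgError):
                pass
            suffix = "uni" if analysis == "univariate" else "multi"
            row[f"hr_{key}_{suffix}"] = hr
            row[f"p_{key}_{suffix}"] = p
        try:
            row[f"auc_{key}"] = ss.td_roc_auc(ordinal, t, e, horizon).auc
        except ValueError:
            row[f"auc_{key}"] = math.nan

    resp = treated["response"]
    known = resp != "NE"
    c_all = counts[known]
    ok = c_all.notna()
    ordinal = c_all[ok].to_numpy(dtype=float)
    high = risk_high[known][ok].to_numpy()
    for name, members in (("cb", CB_SET), ("orr", ORR_SET)):
        y = resp[known][ok].isin(members).to_numpy()
        try:
            tab = [
                [int(y[high].sum()), int((~y[high]).sum())],
                [int(y[~high].sum()), int((~y[~high]).sum())],
            ]
            rr = ss.rr_from_table(tab)
            row[f"rr_{name}"] = rr.rr
            row[f"p_{name}"] = rr.p_value if rr.defined else math.nan
        except ValueError:
            row[f"rr_{name}"] = math.nan
            row[f"p_{name}"] = math.nan
        try:
            row[f"auc_{name}"] = ss.roc_auc(ordinal, y)
        except ValueError:
            row[f"auc_{name}"] = math.nan
    return row


def select_candidate(
    candidates: list[ScoreCandidate],
    cohorts: dict[str, pd.DataFrame],
    horizon: float = 12.0,
    alpha: float = ss.ALPHA,
    min_events: int = 10,
    landmark: bool = True,
) -> SelectionResult:
    """Rank candidates across cohorts and select the final score.

    A candidate is *eligible* when it is significant (p <= alpha) for OS and
    PFS (univariate Cox of high vs low) and for CB and ORR (relative risk) in
    every cohort. Among eligible candidates the winner maximizes the minimum
    OS AUC across cohorts; exact ties break lexicographically on
    candidate_id. Deterministic given cohorts and candidate list.
    """
    if not candidates:
        raise ValueError("no candidates")
    rows = []
    eligibility: dict[str, bool] = {}
    min_auc: dict[str, float] = {}
    for cand in candidates:
        sig_all = True
        aucs = []
        for cname in sorted(cohorts):
            row = _evaluate_candidate_in_cohort(
                cand, cohorts[cname], horizon, min_events, landmark
            )
            row.update(candidate_id=cand.candidate_id, cohort=cname)
            rows.append(row)
            pvals = [row["p_os_uni"], row["p_pfs_uni"], row["p_cb"], row["p_orr"]]
            if any(not np.isfinite(p) or p > alpha for p in pvals):
                sig_all = False
            aucs.append(row["auc_os"])
        eligibility[cand.candidate_id] = sig_all
        min_auc[cand.candidate_id] = (
            float(np.min(aucs)) if np.all(np.isfinite(aucs)) else -math.inf
        )
    table = pd.DataFrame(rows)
    table["significant_all"] = table["candidate_id"].map(eligibility)
    table["min_os_auc"] = table["candidate_id"].map(min_auc)
    front = ["candidate_id", "cohort", "significant_all", "min_os_auc"]
    table = table[front + [c for c in table.columns if c not in front]]

    eligible = [c for c in candidates if eligibility[c.candidate_id]]
    if not eligible:
        return SelectionResult(
            table=table, selected=None, candidates=candidates,
            warning="no candidate significant for all endpoints in all cohorts",
        )
    best = sorted(
        eligible, key=lambda c: (-min_auc[c.candidate_id], c.candidate_id)
    )[0]
    return SelectionResult(table=table, selected=best, candidates=candidates)
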