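"""Biomarker derivation and the screening cascade.

The screen turns raw cohort tables into candidate biomarkers and filters them
the way a predictive-biomarker discovery would in a two-arm trial:

1. derive blood-count ratio biomarkers (NLR, PLR, LMR, NMR) per timepoint;
2. scan each biomarker over patient-fraction cutoffs (deciles 10-90% plus
   quartiles 25/75%) with univariate or covariate-adjusted Cox models of OS
   and PFS, separately per arm, using a landmark convention for on-treatment
   timepoints;
3. retain biomarkers that are consistently associated with both endpoints in
   the treated arm but not in the control arm (control-arm association marks
   a *prognostic*, treatment-agnostic biomarker), are ratios rather than
   absolute counts, and have a consistent direction of effect;
4. narrow each survivor's cutoff from fractions to absolute integer values
   spanning its 25-50% quantile band, confirmed by re-scanning per cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survstats import ALPHA, CoxFit, fit_cox
from .trialsim import CELL_TYPES, LANDMARK_MONTHS, RATIO_DEFS, TIMEPOINTS

__all__ = [
    "DEFAULT_FRACTIONS",
    "CutoffScanResult",
    "CascadeResult",
    "derive_ratios",
    "dichotomize",
    "clinical_covariates",
    "landmark_subset",
    "scan_biomarker",
    "screening_cascade",
    "narrow_integer_cutoffs",
    "confirm_integer_cutoffs",
    "default_biomarkers",
    "is_ratio_biomarker",
    "scan_table",
]

# decile patient fractions plus the 25/75% quartiles
DEFAULT_FRACTIONS = (0.10, 0.20, 0.25, 0.30, 0.40, 0.50, 0.60, 0.70, 0.75, 0.80, 0.90)

ENDPOINTS = ("OS", "PFS")
_TIME_COLS = {"OS": ("os_time", "os_event"), "PFS": ("pfs_time", "pfs_event")}


class DegenerateCutoffError(ValueError):
    """All biomarker values identical: no quantile cutoff exists."""


@dataclass
class CutoffScanResult:
    """One cell of the cutoff scan: a Cox fit of high-vs-low at one cutoff."""

    biomarker: str
    cutoff_kind: str          # "fraction" | "absolute"
    cutoff_value: float
    endpoint: str             # "OS" | "PFS"
    arm: str
    analysis: str             # "univariate" | "multivariate"
    hr: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p: float = math.nan
    n_high: int = 0
    n_low: int = 0
    n_events: int = 0
    estimable: bool = False
    reason: str | None = None

    @property
    def significant(self) -> bool:
        return self.estimable and self.p <= ALPHA


@dataclass
class CascadeResult:
    retained: list[str]
    audit: dict[str, dict] = field(default_factory=dict)


def default_biomarkers(timepoints=TIMEPOINTS, include_counts: bool = True) -> list[str]:
    """The screened universe: 4 ratios (+6 absolute counts) per timepoint."""
    names = [f"{r}_{tp}" for r in RATIO_DEFS for tp in timepoints]
    if include_counts:
        names += [f"{c}_{tp}" for c in CELL_TYPES for tp in timepoints]
    return names


def is_ratio_biomarker(biomarker: str) -> bool:
    return biomarker.split("_")[0] in RATIO_DEFS


def _timepoint_of(biomarker: str) -> str:
    tp = biomarker.rsplit("_", 1)[-1]
    if tp not in TIMEPOINTS:
        raise ValueError(f"biomarker {biomarker!r} has no recognizable timepoint")
    return tp


def derive_ratios(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-patient biomarker panel: ratio and absolute-count columns per timepoint.

    Ratios are NaN (non-evaluable) whenever a component count is missing or a
    denominator is zero — never infinite.
    """
    panel = pd.DataFrame(index=cohort.index)
    for tp in TIMEPOINTS:
        for ratio, (num, den) in RATIO_DEFS.items():
            num_v = cohort[f"count_{num}_{tp}"]
            den_v = cohort[f"count_{den}_{tp}"]
            val = num_v / den_v.where(den_v > 0)
            panel[f"{ratio}_{tp}"] = val
        for cell in CELL_TYPES:
            panel[f"{cell}_{tp}"] = cohort[f"count_{cell}_{tp}"]
    return panel


def dichotomize(
    values,
    cutoff_kind: str,
    cutoff_value: float,
    reference_values=None,
) -> tuple[np.ndarray, float]:
    """High/low labels for a biomarker; returns (high-mask, absolute cutoff).

    Fraction cutoffs are the empirical (linear-interpolation) quantile of the
    reference values — by convention the treated-arm combined cohort — at the
    given fraction; value >= cutoff labels a patient high. NaN inputs yield
    False in the mask (callers restrict to evaluable patients first).
    """
    values = np.asarray(values, dtype=float)
    if cutoff_kind == "fraction":
        if not 0.0 < cutoff_value < 1.0:
            raise ValueError("fraction cutoff must be in (0, 1)")
        ref = values if reference_values is None else np.asarray(reference_values, float)
        ref = ref[np.isfinite(ref)]
        if ref.size == 0:
            raise DegenerateCutoffError("no finite reference values")
        if np.ptp(ref) == 0.0:
            raise DegenerateCutoffError("all reference values identical")
        cutoff = float(np.quantile(ref, cutoff_value, method="linear"))
    elif cutoff_kind == "absolute":
        if cutoff_value <= 0:
            raise ValueError("absolute cutoff must be positive")
        cutoff = float(cutoff_value)
    else:
        raise ValueError(f"unknown cutoff_kind {cutoff_kind!r}")
    with np.errstate(invalid="ignore"):
        high = values >= cutoff
    high[~np.isfinite(values)] = False
    return high, cutoff


def clinical_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Adjustment covariates for the multivariate Cox models.

    Sex, age, race (dummy-coded against a white reference), ECOG performance
    status, metastasis, and pre-treatment PD-L1 dichotomized at 1% tumor
    positivity (5% for cohorts labelled BIRCH, matching that trial's
    enrollment assay threshold).
    """
    pdl1_thr = np.where(cohort["cohort"].astype(str).str.upper() == "BIRCH", 0.05, 0.01)
    return pd.DataFrame(
        {
            "sex_male": (cohort["sex"] == "male").astype(float),
            "age": cohort["age"].astype(float),
            "race_asian": (cohort["race"] == "asian").astype(float),
            "race_other": (cohort["race"] == "other").astype(float),
            "ecog_ps": cohort["ecog_ps"].astype(float),
            "metastasis": (cohort["metastasis"] == "yes").astype(float),
            "pdl1_high": (cohort["pdl1_level"].astype(float) >= pdl1_thr).astype(float),
        },
        index=cohort.index,
    )


def landmark_subset(
    cohort: pd.DataFrame, endpoint: str, timepoint: str, landmark: bool = True
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Endpoint times/events conditioned on being event-free at the timepoint.

    For a biomarker measured at time t, only patients still event-free and
    under follow-up at t enter the analysis, with survival measured from t
    (guards immortal-time bias). With ``landmark=False`` times are left on
    the original scale and only marker availability restricts the analysis.
    """
    tcol, ecol = _TIME_COLS[endpoint]
    t_lm = LANDMARK_MONTHS[timepoint] if landmark else 0.0
    sub = cohort[cohort[tcol] > t_lm]
    times = sub[tcol].to_numpy(dtype=float) - t_lm
    events = sub[ecol].to_numpy(dtype=float)
    return sub, times, events


def _scan_cell(
    times: np.ndarray,
    events: np.ndarray,
    high: np.ndarray,
    covariates: np.ndarray | None,
    min_events: int,
) -> tuple[CoxFit | None, str | None]:
    n_high = int(high.sum())
    n_low = int((~high).sum())
    if n_high == 0 or n_low == 0:
        return None, "degenerate split"
    ev_high = int(events[high].sum())
    ev_low = int(events[~high].sum())
    if min(ev_high, ev_low) < min_events:
        return None, f"fewer than {min_events} events in a stratum"
    X = high.astype(float)[:, None]
    if covariates is not None:
        keep = [j for j in range(covariates.shape[1]) if np.ptp(covariates[:, j]) > 0]
        X = np.hstack([X, covariates[:, keep]])
    try:
        fit = fit_cox(times, events, X)
    except ValueError as exc:
        return None, str(exc)
    if not fit.converged:
        return fit, "non-convergence"
    return fit, None


def scan_biomarker(
    cohort: pd.DataFrame,
    panel: pd.DataFrame,
    biomarker: str,
    endpoint: str,
    arm: str,
    analysis: str = "univariate",
    fractions=DEFAULT_FRACTIONS,
    reference_values=None,
    min_events: int = 10,
    landmark: bool = True,
) -> list[CutoffScanResult]:
    """Cox scan of one biomarker over patient-fraction cutoffs in one arm.

    ``reference_values`` fixes the quantile reference (the treated-arm
    combined cohort by convention); when None the scanned arm's own values
    are used. Cells with fewer than ``min_events`` events in either stratum
    are returned flagged not-estimable rather than dropped.
    """
    tp = _timepoint_of(biomarker)
    armed = cohort[cohort["arm"] == arm]
    sub, times, events = landmark_subset(armed, endpoint, tp, landmark)
    if events.sum() == 0:
        raise ValueError("no events at the landmark")
    values = panel.loc[sub.index, biomarker].to_numpy(dtype=float)
    ok = np.isfinite(values)
    sub, times, events, values = sub[ok], times[ok], events[ok], values[ok]

    if reference_values is None:
        reference_values = values
    cov = None
    if analysis == "multivariate":
        cmat = clinical_covariates(sub)
        cc = cmat.notna().all(axis=1).to_numpy()
        sub, times, events, values = sub[cc], times[cc], events[cc], values[cc]
        cov = cmat[cc].to_numpy(dtype=float)
    elif analysis != "univariate":
        raise ValueError(f"unknown analysis {analysis!r}")

    out = []
    for f in fractions:
        res = CutoffScanResult(
            biomarker=biomarker, cutoff_kind="fraction", cutoff_value=float(f),
            endpoint=endpoint, arm=arm, analysis=analysis,
        )
        try:
            high, _ = dichotomize(values, "fraction", f, reference_values)
        except DegenerateCutoffError as exc:
            res.reason = str(exc)
            out.append(res)
            continue
        res.n_high = int(high.sum())
        res.n_low = int((~high).sum())
        fit, reason = _scan_cell(times, events, high, cov, min_events)
        if fit is not None and reason is None:
            res.hr = float(fit.hr[0])
            res.ci_low = float(fit.ci_low[0])
            res.ci_high = float(fit.ci_high[0])
            res.p = float(fit.wald_p[0])
            res.n_events = fit.n_events
            res.estimable = True
        else:
            res.reason = reason
        out.append(res)
    return out


def _share_significant(cells: list[CutoffScanResult]) -> float:
    if not cells:
        return 0.0
    return float(np.mean([c.significant for c in cells]))


def screening_cascade(
    scans_treated: list[CutoffScanResult],
    scans_control: list[CutoffScanResult],
    share: float = 0.8,
    alpha: float = ALPHA,
) -> CascadeResult:
    """Apply the four retention rules to per-arm scan results.

    A biomarker is retained iff (a) it is significant (p <= alpha) in at
    least ``share`` of its fraction cutoffs in the treated arm for *both* OS
    and PFS; (b) it does NOT satisfy the same rule in the control arm
    (control-arm association marks it prognostic); (c) it is a ratio, not an
    absolute count; (d) all its significant treated-arm hazard ratios lie on
    the same side of 1. The audit trail records, per biomarker, which rule
    removed it and the per-arm/endpoint significant shares.
    """
    if not scans_treated:
        raise ValueError("empty scan input")

    def by_marker(cells):
        d: dict[str, dict[str, list[CutoffScanResult]]] = {}
        for c in cells:
            d.setdefault(c.biomarker, {}).setdefault(c.endpoint, []).append(c)
        return d

    treated = by_marker(scans_treated)
    control = by_marker(scans_control)
    retained: list[str] = []
    audit: dict[str, dict] = {}
    for marker in sorted(treated):
        tr = treated[marker]
        co = control.get(marker, {})
        shares = {
            "treated": {ep: _share_significant(tr.get(ep, [])) for ep in ENDPOINTS},
            "control": {ep: _share_significant(co.get(ep, [])) for ep in ENDPOINTS},
        }
        removed_by = None
        treated_hits = all(shares["treated"][ep] >= share for ep in ENDPOINTS)
        control_hits = all(shares["control"][ep] >= share for ep in ENDPOINTS)
        sig_hrs = [
            c.hr for ep in ENDPOINTS for c in tr.get(ep, []) if c.significant
        ]
        if not treated_hits:
            removed_by = "treated_not_significant"
        elif control_hits:
            removed_by = "control_prognostic"
        elif not is_ratio_biomarker(marker):
            removed_by = "absolute_count"
        elif sig_hrs and not (all(h > 1 for h in sig_hrs) or all(h < 1 for h in sig_hrs)):
            removed_by = "inconsistent_direction"
        audit[marker] = {
            "retained": removed_by is None,
            "removed_by": removed_by,
            "shares": shares,
        }
        if removed_by is None:
            retained.append(marker)
    return CascadeResult(retained=retained, audit=audit)


def narrow_integer_cutoffs(
    values,
    fraction_range: tuple[float, float] = (0.25, 0.50),
    step: float | None = None,
) -> list[float]:
    """Absolute cutoff candidates: step-multiples inside a quantile band.

    Candidates are every multiple of ``step`` lying within the closed
    interval between the empirical quantiles at the two fractions (linear
    interpolation). The step defaults to 10 for platelet-ratio-scale markers
    (median value > 50) and 1 otherwise.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values")
    if step is None:
        step = 10.0 if float(np.median(v)) > 50.0 else 1.0
    qlo, qhi = np.quantile(v, fraction_range, method="linear")
    lo = math.ceil(qlo / step - 1e-9) * step
    hi = math.floor(qhi / step + 1e-9) * step
    if lo > hi:
        raise ValueError("empty integer range (quantiles closer than step)")
    k = int(round((hi - lo) / step))
    return [float(lo + i * step) for i in range(k + 1)]


def confirm_integer_cutoffs(
    cohorts: dict[str, pd.DataFrame],
    biomarker: str,
    candidates: list[float],
    analyses=("univariate", "multivariate"),
    endpoints=ENDPOINTS,
    alpha: float = ALPHA,
    min_events: int = 10,
    landmark: bool = True,
) -> list[float]:
    """Keep the candidate cutoffs significant in every required cohort.

    Each candidate is re-scanned (treated arm, both endpoints, each analysis)
    per cohort; a candidate survives only if every such cell is estimable and
    significant at ``alpha``.
    """
    tp = _timepoint_of(biomarker)
    surviving = []
    for cut in candidates:
        ok = True
        for cohort in cohorts.values():
            panel = derive_ratios(cohort)
            armed = cohort[cohort["arm"] == "treated"]
            for endpoint in endpoints:
                sub, times, events = landmark_subset(armed, endpoint, tp, landmark)
                values = panel.loc[sub.index, biomarker].to_numpy(dtype=float)
                fin = np.isfinite(values)
                sub_f, times_f, events_f, vals = sub[fin], times[fin], events[fin], values[fin]
                for analysis in analyses:
                    cov = None
                    s, t, e, v = sub_f, times_f, events_f, vals
                    if analysis == "multivariate":
                        cmat = clinical_covariates(s)
                        cc = cmat.notna().all(axis=1).to_numpy()
                        s, t, e, v = s[cc], t[cc], e[cc], v[cc]
                        cov = cmat[cc].to_numpy(dtype=float)
                    high, _ = dichotomize(v, "absolute", cut)
                    fit, reason = _scan_cell(t, e, high, cov, min_events)
                    if fit is None or reason is not None or fit.wald_p[0] > alpha:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            surviving.append(cut)
    return surviving


def scan_table(results: list[CutoffScanResult]) -> pd.DataFrame:
    """Long-format table of scan cells (one row per cell) for export."""
    return pd.DataFrame(
        [
            {
                "biomarker": r.biomarker,
                "cutoff_kind": r.cutoff_kind,
                "cutoff_value": r.cutoff_value,
                "endpoint": r.endpoint,
                "arm": r.arm,
                "analysis": r.analysis,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n_high": r.n_high,
                "n_low": r.n_low,
                "n_events": r.n_events,
                "estimable": r.estimable,
                "reason": r.reason if r.reason else "",
            }
            for r in results
        ]
    )
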