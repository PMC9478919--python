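"""Verification experiments: simulation studies that exercise the pipeline.

Each experiment regenerates its data from a seed and measures one property
of the implementation — oracle agreement of the Cox fitter, algebraic
identities among the estimators, type-I error of the cutoff scan, recovery
of planted predictive/prognostic biomarkers and cutoffs, the
predictive-assessment signature, and bytewise determinism of the pipeline.
They are used by the test suite and by ``scripts/acceptance.py``.

The brute-force partial-likelihood oracle here is a deliberate O(n^2)
re-derivation from the definition of the risk set; it shares no code with
the vectorized Newton fitter it checks.
"""

from __future__ import annotations

import math
import tempfile
from pathlib import Path

import numpy as np

from . import evaluate as ev
from . import screen as sc
from . import score as sco
from . import survstats as ss
from .config import CohortSpec, RunConfig
from .pipeline import run_pipeline, write_artifacts
from .trialsim import BiomarkerEffect, SimConfig, simulate_cohort

__all__ = [
    "cox_oracle_gap",
    "algebraic_identity_gaps",
    "null_scan_type_one_error",
    "cascade_recovery",
    "cutoff_recovery",
    "predictive_pattern",
    "pipeline_determinism",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s % 2**31) for s in np.random.SeedSequence(seed).generate_state(n)]


# ---------------------------------------------------------------------------
# criterion experiments
# ---------------------------------------------------------------------------


def _naive_partial_loglik(beta, times, events, x, ties="efron") -> float:
    times = np.asarray(times, float)
    events = np.asarray(events).astype(bool)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(times[events]):
        deaths = events & (times == t)
        at_risk = times >= t
        d = int(deaths.sum())
        s_risk = float(np.exp(beta * x[at_risk]).sum())
        s_tied = float(np.exp(beta * x[deaths]).sum())
        ll += beta * float(x[deaths].sum())
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            ll -= math.log(s_risk - frac * s_tied)
    return ll


def _golden_section_max(f, lo, hi, tol=1e-6) -> float:
    invphi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


def cox_oracle_gap(seed: int, n_fixtures: int = 24) -> float:
    """Max |Newton coefficient - golden-section maximizer| over small random
    1-covariate fixtures (n <= 20), half of them with tied event times.
    Fixtures whose partial likelihood is monotone (separation: no finite
    maximizer) are regenerated."""
    gaps = []
    seeds = _child_seeds(seed, n_fixtures)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        ties = i % 2 == 1
        while True:
            n = int(rng.integers(8, 21))
            t = rng.exponential(5.0, n)
            if ties:
                t = np.ceil(t)
            e = (rng.random(n) < 0.7).astype(float)
            x = rng.standard_normal(n)
            if e.sum() < 2 or np.ptp(x) == 0:
                continue
            fit = ss.fit_cox(t, e, x, ties_method="efron" if not ties else "efron")
            if not fit.converged:
                continue
            ref = _golden_section_max(
                lambda b: _naive_partial_loglik(b, t, e, x), -10.0, 10.0
            )
            gaps.append(abs(fit.coef[0] - ref))
            break
    return float(max(gaps))


def algebraic_identity_gaps(seed: int) -> dict[str, float]:
    """Exact identities among the estimators, as max absolute deviations."""
    rng = np.random.default_rng(seed)
    out = {}

    # log-rank == squared Cox score test at beta=0 (no ties)
    t = rng.permutation(np.arange(1.0, 31.0))
    e = np.ones(30)
    g = (np.arange(30) % 2).astype(float)
    lr = ss.logrank_test(t, e, g)
    _, score, hess = ss.cox_derivatives([0.0], t, e, g[:, None])
    out["logrank_vs_cox_score"] = abs(lr.statistic - score[0] ** 2 / (-hess[0, 0]))

    # KM == empirical survival without censoring
    tt = rng.exponential(3.0, 50)
    km = ss.km_estimate(tt, np.ones(50))
    out["km_vs_empirical"] = float(
        max(abs(s - (tt > u).mean()) for u, s in zip(km.times, km.survival))
    )

    # td-ROC AUC == pairwise Mann-Whitney AUC without censoring
    t2 = rng.exponential(5.0, 40)
    m2 = -t2 + rng.normal(0, 4, 40)
    tau = float(np.median(t2))
    auc = ss.td_roc_auc(m2, t2, np.ones(40), tau).auc
    case = t2 <= tau
    num = sum(
        1.0 if a > b else (0.5 if a == b else 0.0)
        for a in m2[case]
        for b in m2[~case]
    )
    out["tdauc_vs_pairwise"] = abs(auc - num / (case.sum() * (~case).sum()))

    # NMR == NLR * LMR wherever all three are defined
    df = simulate_cohort(SimConfig(n_treated=200, n_control=0, seed=seed))
    panel = sc.derive_ratios(df)
    gaps = []
    for tp in ("T1", "T2", "T3"):
        prod = panel[f"nlr_{tp}"] * panel[f"lmr_{tp}"]
        ok = prod.notna() & panel[f"nmr_{tp}"].notna()
        gaps.append(
            float((panel.loc[ok, f"nmr_{tp}"] - prod[ok]).abs().max())
        )
    out["nmr_identity"] = max(gaps)
    return out


NULL_FRACTIONS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def null_scan_type_one_error(
    seed: int, replicates: int = 200, n_per_arm: int = 200
) -> float:
    """Pooled rejection rate at p <= 0.05 of the fraction scan on cohorts
    with no planted effects (baseline ratios, both endpoints, decile
    fractions)."""
    rejections = total = 0
    for s in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_treated=n_per_arm, n_control=n_per_arm,
            treatment_log_hr=0.0, seed=s,
        )
        df = simulate_cohort(cfg)
        panel = sc.derive_ratios(df)
        for marker in ("nlr_T1", "plr_T1", "lmr_T1", "nmr_T1"):
            ref = panel.loc[df["arm"] == "treated", marker].dropna().to_numpy()
            for endpoint in ("OS", "PFS"):
                for cell in sc.scan_biomarker(
                    df, panel, marker, endpoint, "treated",
                    fractions=NULL_FRACTIONS, reference_values=ref,
                ):
                    if cell.estimable:
                        total += 1
                        rejections += cell.p <= 0.05
    return rejections / total


CASCADE_MARKERS = ("plr_T3", "nmr_T2", "nlr_T3", "lmr_T3")


def cascade_recovery(
    seed: int, replicates: int = 50, n_treated: int = 750, n_control: int = 350
) -> dict[str, float]:
    """Retention of a planted treated-only (predictive) biomarker and removal
    of a planted both-arm (prognostic) one by the screening cascade.

    The predictive marker is plr_T3 and the prognostic one nmr_T2 — the one
    ratio pair sharing no component cell count, so neither signal leaks into
    the other through correlated counts.
    """
    retained = removed = joint = 0
    for s in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_treated=n_treated, n_control=n_control, seed=s,
            predictive_effects=[BiomarkerEffect("plr", "T3", 0.6)],
            prognostic_effects=[BiomarkerEffect("nmr", "T2", 0.6)],
        )
        df = simulate_cohort(cfg)
        panel = sc.derive_ratios(df)
        scans_t, scans_c = [], []
        for marker in CASCADE_MARKERS:
            ref = panel.loc[df["arm"] == "treated", marker].dropna().to_numpy()
            for endpoint in ("OS", "PFS"):
                for arm, sink in (("treated", scans_t), ("control", scans_c)):
                    sink += sc.scan_biomarker(
                        df, panel, marker, endpoint, arm,
                        fractions=NULL_FRACTIONS, reference_values=ref,
                    )
        res = sc.screening_cascade(scans_t, scans_c)
        got_ret = "plr_T3" in res.retained
        got_rem = res.audit["nmr_T2"]["removed_by"] == "control_prognostic"
        retained += got_ret
        removed += got_rem
        joint += got_ret and got_rem
    return {
        "retention_rate": retained / replicates,
        "removal_rate": removed / replicates,
        "joint_rate": joint / replicates,
    }


def cutoff_recovery(
    seed: int, replicates: int = 30, n_treated: int = 1000
) -> float:
    """Share of replicates where cutoff narrowing plus candidate selection
    recover a planted hazard step at plr_T3 = 140 within one grid step."""
    hits = 0
    for s in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_treated=n_treated, n_control=0, seed=s,
            treatment_log_hr=0.0, response_slope=2.0,
            prognostic_effects=[BiomarkerEffect("plr", "T3", 0.9, threshold=140.0)],
        )
        df = simulate_cohort(cfg)
        panel = sc.derive_ratios(df)
        try:
            cands = sc.narrow_integer_cutoffs(panel["plr_T3"])
        except ValueError:
            continue
        sel = sco.select_candidate(
            sco.enumerate_candidates({"plr_T3": cands}), {"training": df}
        )
        if sel.selected is not None:
            hits += abs(sel.selected.rules[0][1] - 140.0) <= 10.0
    return hits / replicates


def predictive_pattern(
    seed: int, replicates: int = 50, n_treated: int = 750, n_control: int = 350
) -> dict[str, float]:
    """Reproduction of the predictive signature when the treatment effect is
    confined to score-low patients: low-stratum treatment HR with CI
    excluding 1, high-stratum CI covering 1, interaction p <= 0.05."""
    cand = sco.ScoreCandidate(rules=(("plr_T3", 140.0),), candidate_id="M")
    ok = 0
    low_hrs, high_hrs = [], []
    for s in _child_seeds(seed, replicates):
        cfg = SimConfig(
            n_treated=n_treated, n_control=n_control, seed=s,
            treatment_log_hr=0.0,
            predictive_effects=[
                BiomarkerEffect("plr", "T3", 0.8, threshold=140.0, side="low")
            ],
        )
        df = simulate_cohort(cfg)
        pa = ev.predictive_assessment(df, cand, endpoints=("OS",))["OS"]
        lo, hi = pa.low, pa.high
        if lo.estimable and hi.estimable:
            low_hrs.append(lo.hr)
            high_hrs.append(hi.hr)
            ok += (
                not (lo.ci_low <= 1.0 <= lo.ci_high)
                and (hi.ci_low <= 1.0 <= hi.ci_high)
                and np.isfinite(pa.interaction_p)
                and pa.interaction_p <= 0.05
            )
    return {
        "pattern_rate": ok / replicates,
        "median_low_stratum_hr": float(np.median(low_hrs)),
        "median_high_stratum_hr": float(np.median(high_hrs)),
    }


def _determinism_config(seed: int) -> RunConfig:
    return RunConfig(
        seed=seed,
        cohorts={"training": CohortSpec(140, 100), "validation1": CohortSpec(120, 0)},
        simulation=dict(
            predictive_effects=[dict(biomarker="plr", timepoint="T3", log_hr=0.9)],
            response_slope=2.0,
        ),
        biomarkers=["plr_T3", "nmr_T2", "nlr_T3"],
        min_events=5,
    )


def pipeline_determinism(seed: int) -> bool:
    """Identical seed and config twice: every artifact byte-identical."""
    with tempfile.TemporaryDirectory() as tmp:
        dirs = []
        for tag in ("a", "b"):
            out = Path(tmp) / tag
            write_artifacts(run_pipeline(_determinism_config(seed)), out)
            dirs.append(out)
        names = sorted(p.name for p in dirs[0].iterdir())
        if names != sorted(p.name for p in dirs[1].iterdir()):
            return False
        return all(
            (dirs[0] / n).read_bytes() == (dirs[1] / n).read_bytes() for n in names
        )
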