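"""Shared fixtures and independent brute-force oracles.

The oracles here recompute quantities from first principles (naive risk-set
sums, pairwise counts, golden-section search) and deliberately share no code
with the package internals they check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from bctscore.trialsim import CELL_TYPES, TIMEPOINTS


def naive_cox_loglik(beta: float, times, events, x, ties: str = "efron") -> float:
    """O(n^2) partial log-likelihood for a single covariate, from scratch."""
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


def golden_section_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Maximize a unimodal function on [lo, hi] by golden-section search."""
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


def pairwise_auc(marker_cases, marker_controls) -> float:
    """Direct pairwise-count Mann-Whitney AUC (ties 1/2)."""
    num = 0.0
    for mc in marker_cases:
        for mu in marker_controls:
            num += 1.0 if mc > mu else (0.5 if mc == mu else 0.0)
    return num / (len(marker_cases) * len(marker_controls))


def survival_fixture(rng: np.random.Generator, n: int, ties: bool):
    """A small random 1-covariate survival dataset with >=1 event."""
    while True:
        t = rng.exponential(5.0, n)
        if ties:
            t = np.ceil(t)
        e = (rng.random(n) < 0.7).astype(float)
        x = rng.standard_normal(n)
        if e.sum() >= 2 and np.ptp(x) > 0:
            return t, e, x


def toy_cohort(marker_values, os_times, os_events, arm="treated") -> pd.DataFrame:
    """Minimal schema-complete cohort whose nlr_T1 equals ``marker_values``.

    Lymphocytes are fixed at 1.0 so the neutrophil count IS the NLR.
    """
    marker_values = np.asarray(marker_values, float)
    n = marker_values.size
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:03d}" for i in range(n)],
            "cohort": "SIM",
            "arm": arm if isinstance(arm, str) else arm,
            "sex": "male",
            "age": 60.0,
            "race": "white",
            "ecog_ps": 1,
            "metastasis": "no",
            "pdl1_level": 0.2,
            "os_time": np.asarray(os_times, float),
            "os_event": np.asarray(os_events, float),
            "response": "SD",
        }
    )
    df["pfs_time"] = df["os_time"]
    df["pfs_event"] = df["os_event"]
    for cell in CELL_TYPES:
        for tp in TIMEPOINTS:
            df[f"count_{cell}_{tp}"] = 1.0
    for tp in TIMEPOINTS:
        df[f"count_neutrophils_{tp}"] = marker_values
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
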