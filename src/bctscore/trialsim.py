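"""Synthetic two-arm trial generator with longitudinal blood counts.

Emulates the structure of an immunotherapy-vs-chemotherapy NSCLC trial
programme: a treated arm and a control arm, absolute differential blood cell
counts (neutrophils, lymphocytes, monocytes, platelets, red cells, white
cells; units 10^9/L) measured pre-treatment (T1) and at about 6 (T2) and 12
(T3) weeks on treatment, right-censored overall and progression-free survival
in months, and RECIST-style response categories.

Log-counts of each cell type are multivariate normal across the three
timepoints with exchangeable correlation, so derived ratios (NLR, PLR, LMR,
NMR) are log-normal with realistic scales. Survival is generated from an
exponential-baseline proportional-hazards model whose linear predictor sums
*prognostic* biomarker effects (both arms) and *predictive* effects (treated
arm only); effects act either per standard deviation of the log-ratio or as a
step at an absolute threshold. Death before a timepoint makes that
timepoint's counts missing, mimicking how on-treatment bloods are only drawn
from patients still under observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES",
    "TIMEPOINTS",
    "RATIO_DEFS",
    "LANDMARK_MONTHS",
    "BiomarkerEffect",
    "SimConfig",
    "simulate_cohort",
    "censoring_summary",
]

CELL_TYPES = ("neutrophils", "lymphocytes", "monocytes", "platelets", "rbc", "wbc")
TIMEPOINTS = ("T1", "T2", "T3")

# ratio biomarkers: name -> (numerator cell, denominator cell)
RATIO_DEFS = {
    "nlr": ("neutrophils", "lymphocytes"),
    "plr": ("platelets", "lymphocytes"),
    "lmr": ("lymphocytes", "monocytes"),
    "nmr": ("neutrophils", "monocytes"),
}

_DAYS_PER_MONTH = 365.25 / 12.0
# blood-draw timepoints: baseline, ~6 weeks and ~12 weeks on treatment
LANDMARK_MONTHS = {
    "T1": 0.0,
    "T2": 42.0 / _DAYS_PER_MONTH,
    "T3": 84.0 / _DAYS_PER_MONTH,
}

# typical adult differential counts (10^9/L), log-normal parameters
_DEFAULT_LOG_MEANS = {
    "neutrophils": math.log(4.5),
    "lymphocytes": math.log(1.5),
    "monocytes": math.log(0.6),
    "platelets": math.log(250.0),
    "rbc": math.log(4.5),
    "wbc": math.log(7.0),
}
_DEFAULT_LOG_SDS = {
    "neutrophils": 0.35,
    "lymphocytes": 0.35,
    "monocytes": 0.35,
    "platelets": 0.30,
    "rbc": 0.10,
    "wbc": 0.30,
}


@dataclass(frozen=True)
class BiomarkerEffect:
    """A planted proportional-hazards effect of one biomarker at one timepoint.

    With ``threshold=None`` the effect is ``log_hr`` per standard deviation of
    the (log-scale) biomarker. With a threshold it is a step: patients on the
    given ``side`` of the threshold ("high": value >= threshold, "low":
    value < threshold) carry the full ``log_hr``.
    """

    biomarker: str     # ratio name ("nlr", ...) or a raw cell type
    timepoint: str     # "T1" | "T2" | "T3"
    log_hr: float
    threshold: float | None = None
    side: str = "high"


@dataclass
class SimConfig:
    n_treated: int = 1479
    n_control: int = 707
    baseline_hazard: float = 0.05        # deaths per month (median OS ~14 mo)
    progression_hazard: float = 0.15     # progressions per month (median PFS ~4 mo)
    followup_max: float = 36.0           # administrative censoring, months
    accrual_censor_rate: float = 0.02    # independent exponential censoring
    count_log_means: dict = field(default_factory=lambda: dict(_DEFAULT_LOG_MEANS))
    count_log_sds: dict = field(default_factory=lambda: dict(_DEFAULT_LOG_SDS))
    timepoint_correlation: float = 0.7   # within-patient corr of log-counts
    prognostic_effects: list[BiomarkerEffect] = field(default_factory=list)
    predictive_effects: list[BiomarkerEffect] = field(default_factory=list)
    treatment_log_hr: float = -0.3       # treated-arm main effect on the hazard
    response_base_prob: float = 0.15     # objective-response probability at eta=0
    response_slope: float = 1.0          # good-risk (low eta) patients respond more
    missing_prob: float = 0.05           # extra independent missingness at T2/T3
    cohort_label: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_treated <= 0 or self.n_control < 0:
            raise ValueError("sample sizes must be positive (control may be 0)")
        if self.baseline_hazard <= 0 or self.progression_hazard <= 0:
            raise ValueError("hazards must be strictly positive")
        if self.followup_max < 0 or self.accrual_censor_rate < 0:
            raise ValueError("followup_max and accrual_censor_rate must be >= 0")
        if not 0.0 <= self.timepoint_correlation < 1.0:
            raise ValueError("timepoint_correlation must be in [0, 1)")
        if not 0.0 <= self.response_base_prob <= 1.0:
            raise ValueError("response_base_prob must be in [0, 1]")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        for cell in CELL_TYPES:
            if cell not in self.count_log_means or cell not in self.count_log_sds:
                raise ValueError(f"missing log-normal parameters for {cell!r}")
            if self.count_log_sds[cell] <= 0:
                raise ValueError(f"log-sd for {cell!r} must be strictly positive")
        known = set(RATIO_DEFS) | set(CELL_TYPES)
        for eff in [*self.prognostic_effects, *self.predictive_effects]:
            if eff.biomarker not in known:
                raise ValueError(f"effect references unknown biomarker {eff.biomarker!r}")
            if eff.timepoint not in TIMEPOINTS:
                raise ValueError(f"effect references unknown timepoint {eff.timepoint!r}")
            if eff.side not in ("high", "low"):
                raise ValueError("effect side must be 'high' or 'low'")

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=int(seed))


def _log_ratio_moments(cfg: SimConfig, biomarker: str) -> tuple[float, float]:
    """Population mean and sd of the log biomarker (ratio or raw count)."""
    if biomarker in RATIO_DEFS:
        num, den = RATIO_DEFS[biomarker]
        mu = cfg.count_log_means[num] - cfg.count_log_means[den]
        sd = math.hypot(cfg.count_log_sds[num], cfg.count_log_sds[den])
    else:
        mu = cfg.count_log_means[biomarker]
        sd = cfg.count_log_sds[biomarker]
    return mu, sd


def _effect_value(cfg: SimConfig, eff: BiomarkerEffect, values: np.ndarray) -> np.ndarray:
    """Per-patient hazard contribution of one effect on true biomarker values."""
    if eff.threshold is None:
        mu, sd = _log_ratio_moments(cfg, eff.biomarker)
        return eff.log_hr * (np.log(values) - mu) / sd
    hit = values >= eff.threshold if eff.side == "high" else values < eff.threshold
    return eff.log_hr * hit.astype(float)


def simulate_cohort(config: SimConfig) -> pd.DataFrame:
    """Generate one cohort as a wide table (one row per patient).

    Columns: ``patient_id``, ``cohort``, ``arm``, clinical covariates,
    ``count_<cell>_<T1|T2|T3>``, ``os_time``/``os_event``,
    ``pfs_time``/``pfs_event``, ``response``. Fully reproducible from
    ``config.seed``.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_treated + cfg.n_control
    treated = np.zeros(n, dtype=bool)
    treated[: cfg.n_treated] = True

    # --- longitudinal log-normal counts, exchangeable correlation over T1-T3
    rho = cfg.timepoint_correlation
    corr = np.full((3, 3), rho) + np.eye(3) * (1 - rho)
    L = np.linalg.cholesky(corr)
    counts: dict[tuple[str, str], np.ndarray] = {}
    for cell in CELL_TYPES:
        z = rng.standard_normal((n, 3)) @ L.T
        logc = cfg.count_log_means[cell] + cfg.count_log_sds[cell] * z
        for j, tp in enumerate(TIMEPOINTS):
            counts[(cell, tp)] = np.exp(logc[:, j])

    def true_value(biomarker: str, tp: str) -> np.ndarray:
        if biomarker in RATIO_DEFS:
            num, den = RATIO_DEFS[biomarker]
            return counts[(num, tp)] / counts[(den, tp)]
        return counts[(biomarker, tp)]

    # --- proportional-hazards linear predictor
    eta = np.zeros(n)
    for eff in cfg.prognostic_effects:
        eta += _effect_value(cfg, eff, true_value(eff.biomarker, eff.timepoint))
    for eff in cfg.predictive_effects:
        eta += treated * _effect_value(cfg, eff, true_value(eff.biomarker, eff.timepoint))
    eta += treated * cfg.treatment_log_hr

    # --- survival by inverse transform from exponential baselines
    hazard_death = cfg.baseline_hazard * np.exp(eta)
    hazard_prog = cfg.progression_hazard * np.exp(eta)
    t_death = rng.exponential(1.0 / hazard_death)
    t_prog = rng.exponential(1.0 / hazard_prog)
    if cfg.accrual_censor_rate > 0:
        t_cens = rng.exponential(1.0 / cfg.accrual_censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    obs_end = np.minimum(t_cens, cfg.followup_max)

    os_time = np.minimum(t_death, obs_end)
    os_event = (t_death <= obs_end).astype(int)
    pfs_raw = np.minimum(t_prog, t_death)
    pfs_time = np.minimum(pfs_raw, obs_end)
    pfs_event = (pfs_raw <= obs_end).astype(int)

    # --- missing on-treatment bloods: observation ended before the draw,
    # plus optional independent missingness
    for tp in ("T2", "T3"):
        gone = os_time < LANDMARK_MONTHS[tp]
        miss = gone | (rng.random(n) < cfg.missing_prob)
        for cell in CELL_TYPES:
            v = counts[(cell, tp)].copy()
            v[miss] = np.nan
            counts[(cell, tp)] = v

    # --- clinical covariates (independent of outcome by construction)
    sex = np.where(rng.random(n) < 0.6, "male", "female")
    age = np.clip(rng.normal(63.0, 9.0, size=n), 30.0, 88.0).round(1)
    race = rng.choice(["white", "asian", "other"], size=n, p=[0.7, 0.2, 0.1])
    ecog = rng.choice([0, 1, 2], size=n, p=[0.35, 0.55, 0.10])
    metastasis = np.where(rng.random(n) < 0.4, "yes", "no")
    pdl1 = rng.beta(2.0, 5.0, size=n).round(4)

    # --- response: logistic model sharing -eta (good-risk patients respond)
    def _sigmoid(x):
        return 1.0 / (1.0 + np.exp(-x))

    logit = math.log(cfg.response_base_prob / (1 - cfg.response_base_prob)) if (
        0 < cfg.response_base_prob < 1
    ) else (math.inf if cfg.response_base_prob == 1 else -math.inf)
    p_resp = _sigmoid(logit - cfg.response_slope * eta)
    responder = rng.random(n) < p_resp
    cr = rng.random(n) < 0.15
    p_sd = _sigmoid(math.log(0.5 / 0.5) - cfg.response_slope * eta)
    stable = rng.random(n) < p_sd
    ne = rng.random(n) < 0.03
    response = np.where(
        responder, np.where(cr, "CR", "PR"),
        np.where(stable, "SD", np.where(ne, "NE", "PD")),
    )

    data = {
        "patient_id": [f"{cfg.cohort_label}-{i:05d}" for i in range(n)],
        "cohort": cfg.cohort_label,
        "arm": np.where(treated, "treated", "control"),
        "sex": sex,
        "age": age,
        "race": race,
        "ecog_ps": ecog,
        "metastasis": metastasis,
        "pdl1_level": pdl1,
    }
    for cell in CELL_TYPES:
        for tp in TIMEPOINTS:
            data[f"count_{cell}_{tp}"] = counts[(cell, tp)]
    data.update(
        os_time=os_time, os_event=os_event,
        pfs_time=pfs_time, pfs_event=pfs_event,
        response=response,
    )
    return pd.DataFrame(data)


def censoring_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-arm event counts and censoring fractions for OS and PFS."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for arm, sub in cohort.groupby("arm", sort=True):
        n = len(sub)
        rows.append(
            {
                "arm": arm,
                "n": n,
                "os_events": int(sub["os_event"].sum()),
                "os_censored": int(n - sub["os_event"].sum()),
                "os_censoring_fraction": float(1.0 - sub["os_event"].mean()),
                "pfs_events": int(sub["pfs_event"].sum()),
                "pfs_censoring_fraction": float(1.0 - sub["pfs_event"].mean()),
            }
        )
    return pd.DataFrame(rows)
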