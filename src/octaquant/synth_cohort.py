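"""Synthetic eye-level cohort generator with inter-eye correlation.

Emulates the statistical structure of a two-visit diabetic-retinopathy
cohort: ~192 patients contributing one or two eyes (~309 eyes), systemic
covariates on a clinically realistic scale, eye-level OCTA metrics with a
shared patient component, and binary progression / visual-acuity-decline
outcomes drawn from a logistic model with a patient-level random effect on
the logit scale (which is what induces the fellow-eye correlation a GEE or
cluster-robust analysis must absorb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .outcomes import STEP_LEVEL, etdrs_step

#: severity category -> baseline ETDRS level used by the simulator.
#: Categories are mapped onto steps 1-3 so a two-step worsening from any
#: baseline category remains representable on the collapsed step scale.
SEVERITY_LEVEL = {0: 10, 1: 20, 2: 35}

# (mean, patient-level SD, eye-level SD) on the clinical scale
_OCTA_METRICS = {
    "SCP_FAZ_area": (0.35, 0.13, 0.11),
    "SCP_FAZ_perimeter": (2.90, 0.75, 0.62),
    "SCP_FAZ_circularity": (1.39, 0.23, 0.19),
    "SCP_LV_PD": (7.90, 1.10, 0.95),
    "SCP_CP_PD": (18.50, 2.05, 1.75),
    "SCP_LV_VD": (3.75, 0.46, 0.39),
    "SCP_CP_VD": (15.20, 2.00, 1.70),
    "DCP_PD": (22.80, 2.40, 2.00),
    "DCP_VD": (16.50, 2.60, 2.20),
    "DCP_FAZ_area": (1.60, 0.50, 0.42),
    "DCP_FAZ_perimeter": (7.20, 2.60, 2.20),
    "DCP_FAZ_circularity": (1.64, 0.53, 0.45),
    "CC_FV_size": (450.0, 66.0, 56.0),
    "CC_FV_number": (3330.0, 690.0, 580.0),
}


@dataclass
class CohortSimParams:
    """Cohort simulation parameters.

    ``dr_coefs`` / ``va_coefs`` are per-unit log-odds on mean-centered
    covariates; intercepts default to ``None``, meaning they are calibrated
    so the marginal outcome prevalence matches the targets (15.9% DR
    progression, 13% VA decline) under the patient random effect.
    """

    n_patients: int = 192
    eyes_per_patient_probs: tuple[float, float] = (0.391, 0.609)
    patient_random_effect_sd: float = 0.8
    dr_coefs: dict[str, float] = field(default_factory=lambda: {
        "SCP_LV_VD": float(np.log(2.878)),
        "SCP_FAZ_perimeter": float(np.log(1.583)),
        "hba1c": 0.15,
        "bmi": 0.06,
        "axial_length": -0.29,
    })
    va_coefs: dict[str, float] = field(default_factory=lambda: {
        "SCP_LV_PD": float(np.log(1.609)),
        "bmi": 0.09,
    })
    dr_intercept: float | None = None
    va_intercept: float | None = None
    target_prevalence_dr: float = 0.159
    target_prevalence_va: float = 0.130
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.eyes_per_patient_probs, float)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("eyes_per_patient_probs must be non-negative and sum to 1")
        if len(p) != 2:
            raise ValueError("at most two eyes per patient are supported")
        if self.patient_random_effect_sd < 0:
            raise ValueError("patient_random_effect_sd must be >= 0")

    @property
    def expected_eyes(self) -> float:
        p1, p2 = self.eyes_per_patient_probs
        return self.n_patients * (p1 + 2 * p2)


def calibrate_intercept(
    lp_centered: np.ndarray, target_prevalence: float, random_effect_sd: float,
    n_quad: int = 21,
) -> float:
    """Intercept giving a target marginal prevalence for given linear predictors.

    Averages expit(lp + c + b) over Gauss-Hermite quadrature of the random
    effect b ~ N(0, sd^2) and over the supplied centered linear predictors,
    then solves for c by bisection.  Deterministic given its inputs.
    """
    if not 0 < target_prevalence < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    b = nodes * random_effect_sd

    def marginal(c: float) -> float:
        # lp: (n,), b: (q,) -> quadrature over b, then mean over lp
        probs = expit(lp_centered[:, None] + c + b[None, :]) @ weights
        return float(probs.mean())

    return float(brentq(lambda c: marginal(c) - target_prevalence, -12.0, 12.0, xtol=1e-10))


def _centered(df: pd.DataFrame, coefs: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, beta in coefs.items():
        if name not in df.columns:
            raise ValueError(f"outcome-model coefficient {name!r} is not a generated covariate")
        x = df[name].to_numpy(float)
        lp += beta * (x - x.mean())
    return lp


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate one eye-level cohort table.

    One row per eye, nested in patients; columns cover demographics,
    systemic covariates, eye-level OCTA metrics, the two ETDRS visits and
    the two acuity visits (consistent with the drawn outcomes), plus
    ``dr_progressed_true`` / ``va_declined_true`` flags for validation.
    """
    rng = np.random.default_rng(params.seed)
    n_pat = params.n_patients
    p1, _ = params.eyes_per_patient_probs

    n_eyes_per_pat = np.where(rng.random(n_pat) < p1, 1, 2)

    # patient-level draws
    pat = {
        "age": rng.normal(62.3, 9.2, n_pat),
        "sex_female": (rng.random(n_pat) < 0.32).astype(int),
        "race": rng.choice(["chinese", "indian", "malay", "other"],
                           size=n_pat, p=(0.828, 0.094, 0.064, 0.014)),
        "dm_duration": np.clip(rng.normal(17.4, 9.5, n_pat), 5.0, None),
        "hba1c": np.clip(rng.normal(8.0, 1.5, n_pat), 4.5, 15.0),
        "bmi": np.clip(rng.normal(25.9, 4.2, n_pat), 15.0, 45.0),
        "map": rng.normal(97.1, 12.2, n_pat),
        "dbp": rng.normal(78.0, 10.0, n_pat),
        "axial_length_pat": rng.normal(24.07, 1.15, n_pat),
        "severity_pat": rng.choice([0, 1, 2], size=n_pat, p=(0.381, 0.380, 0.239)),
        "random_effect": rng.normal(0.0, params.patient_random_effect_sd, n_pat)
        if params.patient_random_effect_sd > 0 else np.zeros(n_pat),
    }
    octa_pat = {
        name: rng.normal(0.0, sd_pat, n_pat)
        for name, (_, sd_pat, _) in _OCTA_METRICS.items()
    }

    rows = []
    for i in range(n_pat):
        lateralities = ["OD", "OS"] if n_eyes_per_pat[i] == 2 else [rng.choice(["OD", "OS"])]
        for lat in lateralities:
            severity = int(pat["severity_pat"][i]) if rng.random() < 0.85 else int(
                rng.choice([0, 1, 2], p=(0.381, 0.380, 0.239))
            )
            row = {
                "patient_id": f"P{i:04d}",
                "eye_id": f"P{i:04d}_{lat}",
                "laterality": lat,
                "age": pat["age"][i],
                "sex_female": pat["sex_female"][i],
                "race": pat["race"][i],
                "dm_duration": pat["dm_duration"][i],
                "hba1c": pat["hba1c"][i],
                "bmi": pat["bmi"][i],
                "map": pat["map"][i],
                "dbp": pat["dbp"][i],
                "axial_length": pat["axial_length_pat"][i] + rng.normal(0, 0.25),
                "va_baseline": float(np.clip(rng.normal(0.28, 0.20), 0.0, 1.2)),
                "iop": rng.normal(17.5, 3.1),
                "lens_status": "pseudophakic" if rng.random() < 0.25 else "phakic",
                "dr_severity": severity,
                "etdrs_baseline": SEVERITY_LEVEL[severity],
                "_re": pat["random_effect"][i],
            }
            for name, (mean, _, sd_eye) in _OCTA_METRICS.items():
                row[name] = mean + octa_pat[name][i] + rng.normal(0, sd_eye)
            rows.append(row)
    df = pd.DataFrame(rows)

    # derived composite metrics and monotone CC flow-deficit densities
    df["SCP_PD"] = df["SCP_LV_PD"] + df["SCP_CP_PD"]
    df["SCP_VD"] = df["SCP_LV_VD"] + df["SCP_CP_VD"]
    base = 17.3 + 0.9 * rng.standard_normal(len(df))
    gaps = np.abs(rng.normal([[1.65, 2.40, 1.90, 1.50]] * len(df),
                             [[0.25, 0.30, 0.30, 0.30]] * len(df)))
    df["CC_FV_density"] = base
    df["CC_FV_density_200"] = base - gaps[:, 0]
    df["CC_FV_density_400"] = df["CC_FV_density_200"] - gaps[:, 1]
    df["CC_FV_density_600"] = df["CC_FV_density_400"] - gaps[:, 2]
    df["CC_FV_density_800"] = df["CC_FV_density_600"] - gaps[:, 3]

    # outcomes: logit(p) = intercept + centered linear predictor + patient effect
    for outcome, coefs, intercept, target in (
        ("dr", params.dr_coefs, params.dr_intercept, params.target_prevalence_dr),
        ("va", params.va_coefs, params.va_intercept, params.target_prevalence_va),
    ):
        lp = _centered(df, coefs)
        if intercept is None:
            intercept = calibrate_intercept(lp, target, params.patient_random_effect_sd)
        p = expit(intercept + lp + df["_re"].to_numpy())
        df[f"_{outcome}_p"] = p
        df[f"{outcome}_event"] = rng.random(len(df)) < p

    # follow-up visits consistent with the drawn outcomes
    steps_b = df["etdrs_baseline"].map(etdrs_step).to_numpy()
    steps_f = steps_b.copy()
    prog = df["dr_event"].to_numpy()
    steps_f[prog] += 2
    extra = prog & (rng.random(len(df)) < 0.15) & (steps_f + 1 <= 5)
    steps_f[extra] += 1
    minor = ~prog & (rng.random(len(df)) < 0.18)
    steps_f[minor] = np.minimum(steps_f[minor] + 1, 5)
    df["etdrs_followup"] = [STEP_LEVEL[int(s)] for s in steps_f]

    decl = df["va_event"].to_numpy()
    delta = np.where(decl, rng.uniform(0.12, 0.35, len(df)), rng.uniform(-0.08, 0.10, len(df)))
    df["va_followup"] = np.clip(df["va_baseline"].to_numpy() + delta, 0.0, 1.6)

    df = df.rename(columns={"dr_event": "dr_progressed_true", "va_event": "va_declined_true"})
    return df.drop(columns=["_re", "_dr_p", "_va_p"])
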