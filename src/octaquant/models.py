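"""Risk models: GEE group comparisons, cluster-robust logistic ORs, and a
prediction-model ladder scored by AUC, Brier score and Hosmer-Lemeshow.

Two eyes of one patient are correlated, so inference never treats eyes as
independent: group comparisons use a marginal (GEE) model with an
exchangeable working correlation and robust sandwich variance clustered on
patient, and logistic odds ratios use cluster-robust (sandwich) standard
errors on patient id.  Discrimination and calibration are evaluated
in-sample on the fitted cohort unless cross-validation is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold


class SeparationError(RuntimeError):
    """Raised when a logistic fit shows (quasi-)complete separation."""


@dataclass
class ModelSpec:
    outcome: str
    predictors: list[str]
    cluster_var: str = "patient_id"
    label: str = ""
    exposure: str | None = None  # predictor whose OR is reported

    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self.predictors)


@dataclass
class ModelFit:
    label: str
    coefficients: dict[str, float]
    or_and_ci: dict[str, tuple[float, float, float]]  # name -> (OR, lo, hi)
    p_values: dict[str, float]
    auc: float
    brier: float
    hl_stat: float
    hl_p: float
    n_obs: int
    exposure: str | None = None
    fitted_probs: np.ndarray | None = field(default=None, repr=False)

    def exposure_or(self) -> tuple[float, float, float] | None:
        if self.exposure is None:
            return None
        return self.or_and_ci[self.exposure]


# ---------------------------------------------------------------------------
# scoring primitives
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both outcome classes")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def brier_score(probabilities, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((p - y) ** 2))


def hosmer_lemeshow(probabilities, labels, n_groups: int = 10) -> tuple[float, float]:
    """Hosmer-Lemeshow goodness-of-fit statistic and p-value.

    Observations are binned by deciles of predicted probability (ties kept in
    one bin); the statistic is sum over bins of (O-E)^2 / (E (1 - E/n)) and
    is referred to a chi-square with ``n_groups - 2`` degrees of freedom.
    """
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    if n_groups < 3:
        raise ValueError("hosmer_lemeshow needs n_groups >= 3 (df = n_groups - 2 > 0)")
    if len(p) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} observations for {n_groups} bins")
    if len(np.unique(y)) < 2:
        raise ValueError("Hosmer-Lemeshow needs both outcome classes")
    bins = pd.qcut(p, n_groups, duplicates="drop")
    grouped = pd.DataFrame({"p": p, "y": y, "bin": bins}).groupby("bin", observed=True)
    stat = 0.0
    n_bins = 0
    for _, g in grouped:
        n_g = len(g)
        if n_g == 0:
            continue
        obs = g["y"].sum()
        exp = g["p"].sum()
        denom = exp * (1.0 - exp / n_g)
        if denom <= 0:
            raise ValueError("a bin has zero expected variance; cannot form the statistic")
        stat += (obs - exp) ** 2 / denom
        n_bins += 1
    df = n_bins - 2
    if df <= 0:
        raise ValueError("too few distinct probability bins for the chi-square reference")
    return float(stat), float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# group comparisons (GEE)
# ---------------------------------------------------------------------------

def compare_groups(
    table: pd.DataFrame, variable: str, group_label: str, cluster_var: str = "patient_id"
) -> float:
    """P-value for a two-group difference, inter-eye correlation adjusted.

    Fits a marginal model of the variable on group with an exchangeable
    working correlation clustered on ``cluster_var`` and robust sandwich
    variance: identity/Gaussian for continuous variables, logit/binomial for
    binary ones.  Two standard small-sample corrections are applied: the
    bias-reduced (Mancl-DeRouen) sandwich estimator, and a t reference with
    ``n_clusters - 2`` degrees of freedom instead of the normal.  For
    categorical variables with more than two levels the direction is flipped
    (group ~ variable dummies) and a joint Wald test on the variable terms
    is returned.
    """
    data = table[[variable, group_label, cluster_var]].dropna().copy()
    groups_vals = data[group_label].unique()
    if len(groups_vals) != 2:
        raise ValueError(f"{group_label!r} must have exactly two levels, got {len(groups_vals)}")
    if any((data[group_label] == g).sum() < 2 for g in groups_vals):
        raise ValueError("each group needs at least two eyes")
    data["_grp"] = (data[group_label] == groups_vals.max()).astype(float)

    var = data[variable]
    n_levels = var.nunique()
    if n_levels < 2:
        raise ValueError(f"{variable!r} has no variation")
    numeric = pd.api.types.is_numeric_dtype(var)

    n_clusters = data[cluster_var].nunique()

    def _t_pvalue(res, term: str) -> float:
        tval = res.params[term] / res.bse[term]
        df = max(n_clusters - len(res.params), 1)
        return float(2.0 * stats.t.sf(abs(tval), df))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if numeric and n_levels > 2:
            res = sm.GEE.from_formula(
                f"{variable} ~ _grp",
                groups=data[cluster_var],
                data=data,
                cov_struct=sm.cov_struct.Exchangeable(),
                family=sm.families.Gaussian(),
            ).fit(cov_type="bias_reduced")
            return _t_pvalue(res, "_grp")
        if n_levels == 2:
            data["_var"] = (var == var.max()).astype(float)
            res = sm.GEE.from_formula(
                "_var ~ _grp",
                groups=data[cluster_var],
                data=data,
                cov_struct=sm.cov_struct.Exchangeable(),
                family=sm.families.Binomial(),
            ).fit(cov_type="bias_reduced")
            return _t_pvalue(res, "_grp")
        # multi-level categorical: joint Wald test of the variable dummies
        res = sm.GEE.from_formula(
            f"_grp ~ C({variable})",
            groups=data[cluster_var],
            data=data,
            cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Binomial(),
        ).fit()
        terms = [name for name in res.params.index if name.startswith(f"C({variable})")]
        constraint = ", ".join(f"{t} = 0" for t in terms)
        return float(res.wald_test(constraint, scalar=True).pvalue)


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------

_SEPARATION_COEF = 15.0


def _fit_cluster_logit(table: pd.DataFrame, spec: ModelSpec):
    data = table[[spec.outcome, *spec.predictors, spec.cluster_var]].dropna().copy()
    y = data[spec.outcome].astype(float)
    if y.nunique() < 2:
        raise ValueError(f"outcome {spec.outcome!r} has a single class")
    data[spec.outcome] = y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.glm(spec.formula(), data=data, family=sm.families.Binomial())
        res = model.fit(cov_type="cluster", cov_kwds={"groups": data[spec.cluster_var]})
    params = res.params.drop("Intercept", errors="ignore")
    if np.any(np.abs(params.values) > _SEPARATION_COEF) or not np.all(np.isfinite(res.bse)):
        raise SeparationError(
            f"model {spec.label or spec.formula()!r}: coefficients suggest complete "
            "separation or a singular design"
        )
    return res, data


def _cv_probs(res_data: pd.DataFrame, spec: ModelSpec, n_splits: int = 5) -> np.ndarray:
    """Cluster-aware cross-validated predicted probabilities."""
    probs = np.empty(len(res_data))
    splitter = GroupKFold(n_splits=n_splits)
    groups = res_data[spec.cluster_var]
    for train, test in splitter.split(res_data, groups=groups):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.glm(
                spec.formula(), data=res_data.iloc[train], family=sm.families.Binomial()
            ).fit()
            probs[test] = fit.predict(res_data.iloc[test]).to_numpy()
    return probs


def fit_adjusted_logistic(
    table: pd.DataFrame,
    spec: ModelSpec,
    exposure: str | None = None,
    hl_groups: int = 10,
    cross_validate: bool = False,
) -> ModelFit:
    """Adjusted logistic model with cluster-robust (patient-level) variance.

    Returns odds ratios with 95% Wald confidence intervals and p-values for
    every predictor, plus in-sample AUC, Brier score and Hosmer-Lemeshow
    calibration (cross-validated predictions when ``cross_validate``).
    Raises :class:`SeparationError` on complete separation.
    """
    exposure = exposure or spec.exposure
    res, data = _fit_cluster_logit(table, spec)
    conf = res.conf_int()
    or_ci = {
        name: (float(np.exp(res.params[name])), float(np.exp(conf.loc[name, 0])),
               float(np.exp(conf.loc[name, 1])))
        for name in res.params.index
        if name != "Intercept"
    }
    probs = (
        _cv_probs(data, spec) if cross_validate else res.predict(data).to_numpy()
    )
    y = data[spec.outcome].to_numpy()
    try:
        hl_stat, hl_p = hosmer_lemeshow(probs, y, hl_groups)
    except ValueError:
        hl_stat, hl_p = float("nan"), float("nan")
    return ModelFit(
        label=spec.label,
        coefficients={k: float(v) for k, v in res.params.items()},
        or_and_ci=or_ci,
        p_values={k: float(v) for k, v in res.pvalues.items()},
        auc=roc_auc(probs, y),
        brier=brier_score(probs, y),
        hl_stat=hl_stat,
        hl_p=hl_p,
        n_obs=int(res.nobs),
        exposure=exposure,
        fitted_probs=probs,
    )


# ---------------------------------------------------------------------------
# model ladders
# ---------------------------------------------------------------------------

def dr_progression_ladder(
    octa_perimeter: str = "SCP_FAZ_perimeter", octa_lv_vd: str = "SCP_LV_VD"
) -> list[ModelSpec]:
    """Preset nested models for the DR-progression outcome.

    Model 1: established systemic factors (age, diabetes duration, HbA1c,
    mean arterial pressure, DR severity).  Model 2: cohort-proposed factors
    (axial length, BMI, HbA1c, DR severity).  Models 3-5 add the superficial
    FAZ perimeter and/or large-vessel VD to Model 2.
    """
    established = ["age", "dm_duration", "hba1c", "map", "dr_severity"]
    proposed = ["axial_length", "bmi", "hba1c", "dr_severity"]
    return [
        ModelSpec("dr_progressed", established, label="Model 1"),
        ModelSpec("dr_progressed", proposed, label="Model 2"),
        ModelSpec("dr_progressed", proposed + [octa_perimeter], label="Model 3",
                  exposure=octa_perimeter),
        ModelSpec("dr_progressed", proposed + [octa_lv_vd], label="Model 4",
                  exposure=octa_lv_vd),
        ModelSpec("dr_progressed", proposed + [octa_perimeter, octa_lv_vd], label="Model 5"),
    ]


def va_decline_ladder(
    octa_lv_pd: str = "SCP_LV_PD", octa_lv_vd: str = "SCP_LV_VD"
) -> list[ModelSpec]:
    """Preset nested models for the VA-decline outcome (systemic base =
    diastolic BP, BMI, HbA1c, baseline best-corrected VA, DR severity)."""
    base = ["dbp", "bmi", "hba1c", "va_baseline", "dr_severity"]
    return [
        ModelSpec("va_declined", base, label="Model 1"),
        ModelSpec("va_declined", base + [octa_lv_pd], label="Model 2", exposure=octa_lv_pd),
        ModelSpec("va_declined", base + [octa_lv_vd], label="Model 3", exposure=octa_lv_vd),
    ]


def run_model_ladder(
    table: pd.DataFrame, ladder: list[ModelSpec], cross_validate: bool = False
) -> pd.DataFrame:
    """Fit every model of a ladder and report one row per model.

    Columns: label, n_obs, AUC, HL statistic and p, Brier score, and (where
    the spec names an exposure) its OR with 95% CI and p-value.
    """
    rows = []
    for spec in ladder:
        fit = fit_adjusted_logistic(table, spec, cross_validate=cross_validate)
        row = {
            "label": fit.label,
            "n_obs": fit.n_obs,
            "auc": fit.auc,
            "hl_stat": fit.hl_stat,
            "hl_p": fit.hl_p,
            "brier": fit.brier,
            "exposure": fit.exposure,
            "or": np.nan,
            "or_lo": np.nan,
            "or_hi": np.nan,
            "or_p": np.nan,
        }
        if fit.exposure is not None:
            orv, lo, hi = fit.or_and_ci[fit.exposure]
            row.update({"or": orv, "or_lo": lo, "or_hi": hi,
                        "or_p": fit.p_values[fit.exposure]})
        rows.append(row)
    return pd.DataFrame(rows)


def stratified_analysis(
    table: pd.DataFrame, spec: ModelSpec, stratum_var: str
) -> dict[str, ModelFit]:
    """Refit a model within each stratum (e.g. phakic vs pseudophakic eyes).

    Strata where the outcome is degenerate or the fit separates are skipped
    with a warning; the returned dict maps stratum value to its ModelFit.
    """
    fits: dict[str, ModelFit] = {}
    for value, sub in table.groupby(stratum_var):
        try:
            fits[str(value)] = fit_adjusted_logistic(sub, spec)
        except (ValueError, SeparationError) as exc:
            warnings.warn(f"stratum {stratum_var}={value!r} skipped: {exc}", stacklevel=2)
    return fits


def plot_roc_curves(table: pd.DataFrame, ladder: list[ModelSpec], path) -> None:
    """Overlay ROC curves of a fitted ladder and save them as a figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    for spec in ladder:
        fit = fit_adjusted_logistic(table, spec)
        data = table[[spec.outcome, *spec.predictors, spec.cluster_var]].dropna()
        fpr, tpr, _ = roc_curve(data[spec.outcome].astype(float), fit.fitted_probs)
        ax.plot(fpr, tpr, label=f"{spec.label} (AUC {fit.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
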