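"""Survival analysis of the metabolic subtypes.

Kaplan-Meier estimation and log-rank testing by subtype, Cox
proportional-hazards ladders (unadjusted; age/sex/HPV[/smoking]-adjusted;
fully adjusted for the complete clinical covariate set) for overall and
progression-free survival, a proportional-hazards check via a
subtype-with-time interaction entered on episode-split data, stratification
by smoking history and HPV status, and a three-year alive/dead logistic
regression with ROC comparison of HPV-only, subtype-only and HPV+subtype
models.

Model fitting is delegated to lifelines (Efron tie handling) and
statsmodels; this module owns the covariate encodings, the stratification
scheme and the report layout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import roc_auc_score, roc_curve
import statsmodels.api as sm

HORIZON_YEARS = 3.0

# categorical vocabulary; the first level is the model reference
CATEGORICAL_LEVELS = {
    "sex": ["Male", "Female"],
    "race": ["White", "Black"],
    "hpv_status": ["Unrelated", "Related"],
    "smoking": ["Never", "Former", "Current"],
    "alcohol": ["<1 drink/week", "1+ drink/week"],
    "marital": ["Married or partnered", "Single"],
    "tumor_site": ["Oropharynx", "Oral cavity", "Larynx", "Other"],
    "stage": ["I", "II", "III", "IV"],
    "treatment": ["Radiotherapy", "Chemoradiotherapy with Cisplatin",
                  "Chemoradiotherapy with Carboplatin and Paclitaxel"],
    "feeding_tube": ["No", "Yes"],
    "ecog": ["Active", "Restricted", "Non-working"],
    "comorbidity": ["No", "Yes"],
}
CONTINUOUS_COVARIATES = ["age", "bmi", "albumin", "hemoglobin", "nlr", "plr"]

BASIC_ADJUSTMENT = ["age", "sex", "hpv_status"]
FULL_ADJUSTMENT = BASIC_ADJUSTMENT + [
    "race", "bmi", "alcohol", "marital", "tumor_site", "stage", "treatment",
    "ecog", "feeding_tube", "comorbidity", "albumin", "hemoglobin", "nlr",
    "plr",
]


# ------------------------------------------------------------ Kaplan-Meier

@dataclass
class KMCurve:
    times: np.ndarray       # event/censor time grid (step locations)
    survival: np.ndarray    # S(t) immediately after each grid time
    at_risk: np.ndarray
    censor_times: np.ndarray


def km_curve(times, events) -> KMCurve:
    """Product-limit survival curve."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("empty input")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter().fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(grid).to_numpy(float)
    return KMCurve(grid, surv, at_risk, times[events == 0])


def survival_at(curve: KMCurve, t: float) -> float:
    """Evaluate the right-continuous step function S(t)."""
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[idx]) if idx >= 0 else 1.0


def logrank_test(groups) -> tuple[float, int, float]:
    """Log-rank test over >= 2 groups given as (times, events) pairs."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t = np.asarray(t, float)
        e = np.asarray(e, int)
        if t.size == 0:
            raise ValueError(f"group {g} has no subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    events_all = np.concatenate(events)
    if events_all.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), events_all)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# -------------------------------------------------------------------- Cox

@dataclass
class CoxResult:
    summary: pd.DataFrame       # coef, hr, se, ci_lower, ci_upper, p per covar
    n: int
    n_events: int
    n_dropped_missing: int
    log_likelihood: float
    converged: bool
    warnings: list = field(default_factory=list)

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def ci(self, covariate: str) -> tuple[float, float]:
        row = self.summary.loc[covariate]
        return float(row["ci_lower"]), float(row["ci_upper"])


def cox_fit(covariates: pd.DataFrame, times, events,
            ties: str = "efron") -> CoxResult:
    """Cox proportional-hazards fit (Efron partial likelihood for ties).

    Rows with any missing covariate are dropped and counted. Constant or
    collinear covariate columns raise informative errors.
    """
    if ties != "efron":
        raise ValueError("only Efron tie handling is supported")
    df = covariates.copy()
    df["_time"] = np.asarray(times, float)
    df["_event"] = np.asarray(events, int)
    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if df["_event"].sum() == 0:
        raise ValueError("no events after dropping missing covariates")
    X = df.drop(columns=["_time", "_event"])
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"constant covariate: {col!r}")
    mat = X.to_numpy(float)
    if np.linalg.matrix_rank(mat - mat.mean(axis=0)) < mat.shape[1]:
        raise ValueError(
            f"rank-deficient (collinear) covariates: {list(X.columns)}")

    cph = CoxPHFitter()
    notes: list = []
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as exc:  # monotone likelihood / non-convergence
            notes.append(f"unpenalized fit failed ({exc}); refit with "
                         "a small ridge penalty")
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="_time", event_col="_event")
    for w in caught:
        if "convergence" in str(w.message).lower() or \
                "collinear" in str(w.message).lower():
            notes.append(str(w.message))
            converged = False
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "hr": s["exp(coef)"],
        "se": s["se(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxResult(summary, n=len(df), n_events=int(df["_event"].sum()),
                     n_dropped_missing=n_dropped,
                     log_likelihood=float(cph.log_likelihood_),
                     converged=converged, warnings=notes)


def ph_test(times, events, covariate, transform: str = "identity") -> float:
    """Proportional-hazards check via a covariate-with-time interaction.

    The data are episode-split at the observed event times, the
    time-varying term covariate * g(t) (g = identity or log) is added to a
    model containing the covariate, and the Wald p-value of the interaction
    coefficient is returned.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    z = np.asarray(covariate, float)
    g = np.log if transform == "log" else (lambda t: t)
    if transform not in ("identity", "log"):
        raise ValueError("transform must be 'identity' or 'log'")
    ev_times = np.unique(times[events == 1])
    rows = []
    for i, (t_i, e_i, z_i) in enumerate(zip(times, events, z)):
        cuts = ev_times[ev_times < t_i]
        stops = np.append(cuts, t_i)
        starts = np.concatenate([[0.0], stops[:-1]])
        for s0, s1 in zip(starts, stops):
            rows.append((i, s0, s1, z_i, z_i * g(s1),
                         int(e_i and s1 == t_i)))
    long = pd.DataFrame(
        rows, columns=["id", "start", "stop", "z", "z_t", "event"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            ctv = CoxTimeVaryingFitter()
            ctv.fit(long, id_col="id", start_col="start", stop_col="stop",
                    event_col="event")
        except Exception:  # extreme violations: stabilize with a ridge
            ctv = CoxTimeVaryingFitter(penalizer=0.1)
            ctv.fit(long, id_col="id", start_col="start", stop_col="stop",
                    event_col="event")
    return float(ctv.summary.loc["z_t", "p"])


# -------------------------------------------------- three-year & logistic

def three_year_status(times, events, horizon: float = HORIZON_YEARS
                      ) -> pd.Series:
    """Alive(0)/dead(1) at the horizon; censored-before-horizon is NaN.

    Dead = event at or before the horizon; alive = followed past the
    horizon regardless of later status; subjects censored before the
    horizon carry no three-year status and are excluded (their count is
    ``result.attrs['n_excluded']``).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    status = np.where(
        (events == 1) & (times <= horizon), 1.0,
        np.where(times > horizon, 0.0, np.nan))
    out = pd.Series(status, name="dead_by_horizon")
    out.attrs["n_excluded"] = int(np.isnan(status).sum())
    return out


@dataclass
class LogisticResult:
    params: pd.Series
    fitted: np.ndarray
    llf: float
    separated: bool


def logistic_fit(X: pd.DataFrame, y) -> LogisticResult:
    """Maximum-likelihood logistic regression (IRLS via statsmodels).

    Perfect separation is flagged and coefficients are capped at +-20
    rather than left divergent.
    """
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    design = sm.add_constant(X.astype(float), has_constant="add")
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        params = fit.params
        llf = float(fit.llf)
    except Exception:
        separated = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, method="lbfgs", maxiter=200)
        params = fit.params
        llf = float(fit.llf)
    if np.abs(params.to_numpy()).max() > 20:
        separated = True
        params = params.clip(-20, 20)
    lin = design.to_numpy(float) @ params.to_numpy(float)
    fitted = 1.0 / (1.0 + np.exp(-lin))
    return LogisticResult(params=params, fitted=fitted, llf=llf,
                          separated=separated)


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, y) -> ROCResult:
    """ROC curve plus Mann-Whitney AUC (ties get half credit)."""
    y = np.asarray(y, int)
    scores = np.asarray(scores, float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, scores, drop_intermediate=False)
    return ROCResult(fpr, tpr, thr, float(roc_auc_score(y, scores)))


# ------------------------------------------------------------- stratified

def build_design(df: pd.DataFrame, covariates, drop_constant: bool = False
                 ) -> pd.DataFrame:
    """One-hot design with the first listed vocabulary level as reference."""
    cols = {}
    for cov in covariates:
        if cov in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[cov]
            for level in levels[1:]:
                cols[f"{cov}[{level}]"] = (df[cov] == level).astype(float) \
                    .where(df[cov].notna())
        else:
            cols[cov] = df[cov].astype(float)
    out = pd.DataFrame(cols, index=df.index)
    if drop_constant:
        out = out.loc[:, out.nunique(dropna=True) > 1]
    return out


def _subtype_indicator(df: pd.DataFrame) -> pd.Series:
    return (df["subtype"] == "A").astype(float).rename("subtype[A]")


def _cox_ladder(df: pd.DataFrame, time_col: str, event_col: str,
                include_smoking: bool) -> dict:
    ladder = {}
    basic = BASIC_ADJUSTMENT + (["smoking"] if include_smoking else [])
    full = FULL_ADJUSTMENT + (["smoking"] if include_smoking else [])
    specs = {"unadjusted": [], "adjusted": basic, "fully_adjusted": full}
    for name, covs in specs.items():
        design = build_design(df, covs, drop_constant=True)
        design.insert(0, "subtype[A]", _subtype_indicator(df))
        try:
            res = cox_fit(design, df[time_col], df[event_col])
            ladder[name] = {
                "hr": res.hazard_ratio("subtype[A]"),
                "ci": list(res.ci("subtype[A]")),
                "p": float(res.summary.loc["subtype[A]", "p"]),
                "n": res.n, "n_events": res.n_events,
                "n_dropped_missing": res.n_dropped_missing,
                "converged": res.converged,
                "warnings": res.warnings,
            }
        except Exception as exc:
            ladder[name] = {"failed": str(exc)}
    return ladder


def _km_block(df: pd.DataFrame, time_col: str, event_col: str,
              horizon: float) -> dict:
    block: dict = {"three_year_survival": {}, "curves": {}}
    groups = []
    for subtype in ("A", "B"):
        sub = df[df["subtype"] == subtype]
        if len(sub) == 0:
            continue
        curve = km_curve(sub[time_col], sub[event_col])
        block["curves"][subtype] = curve
        block["three_year_survival"][subtype] = survival_at(curve, horizon)
        groups.append((sub[time_col].to_numpy(), sub[event_col].to_numpy()))
    if len(groups) == 2:
        chi2, df_, p = logrank_test(groups)
        block["logrank"] = {"chi2": chi2, "df": df_, "p": p}
    return block


def _roc_block(df: pd.DataFrame, horizon: float) -> dict:
    status = three_year_status(df["os_time"], df["os_event"], horizon)
    keep = status.notna().to_numpy()
    y = status.to_numpy()[keep]
    out: dict = {"n": int(keep.sum()),
                 "n_excluded_censored": status.attrs["n_excluded"]}
    if len(np.unique(y)) < 2:
        out["failed"] = "only one outcome class within the horizon"
        return out
    sub = df.loc[keep]
    hpv = build_design(sub, ["hpv_status"])
    subt = _subtype_indicator(sub).to_frame()
    both = pd.concat([hpv, subt], axis=1)
    for name, X in (("hpv_only", hpv), ("subtype_only", subt),
                    ("hpv_plus_subtype", both)):
        try:
            fit = logistic_fit(X, y)
            roc = roc_auc(fit.fitted, y)
            out[name] = {"auc": roc.auc, "separated": fit.separated,
                         "params": fit.params.to_dict()}
        except Exception as exc:
            out[name] = {"failed": str(exc)}
    return out


STRATA = ("full", "never_smokers", "ever_smokers",
          "ever_smokers_hpv_related", "ever_smokers_hpv_unrelated")


def _stratum_mask(df: pd.DataFrame, stratum: str) -> pd.Series:
    ever = df["smoking"].isin(["Former", "Current"])
    masks = {
        "full": pd.Series(True, index=df.index),
        "never_smokers": df["smoking"] == "Never",
        "ever_smokers": ever,
        "ever_smokers_hpv_related": ever & (df["hpv_status"] == "Related"),
        "ever_smokers_hpv_unrelated": ever & (df["hpv_status"] == "Unrelated"),
    }
    return masks[stratum]


def stratified_analysis(clinical: pd.DataFrame, subtype_labels=None,
                        horizon: float = HORIZON_YEARS,
                        strata=STRATA) -> dict:
    """Full survival report by smoking/HPV stratum.

    ``clinical`` must carry os/pfs outcome columns and either a ``subtype``
    column or ``subtype_labels`` (aligned, values 'A'/'B'). Subjects with
    ``followed == False`` are excluded up front. Per stratum: KM curves and
    three-year survival by subtype, the log-rank test, the three-model Cox
    ladder for OS and PFS, and (full / ever-smoker strata) the three-year
    logistic ROC comparison.
    """
    df = clinical.copy()
    if subtype_labels is not None:
        df["subtype"] = np.asarray(subtype_labels)
    if "subtype" not in df.columns:
        raise ValueError("no subtype labels supplied")
    if "followed" in df.columns:
        df = df[df["followed"]].copy()
    report: dict = {"n_total": len(df)}
    for stratum in strata:
        sub = df[_stratum_mask(df, stratum)]
        entry: dict = {"n": len(sub),
                       "n_subtype_A": int((sub["subtype"] == "A").sum())}
        if len(sub) == 0 or sub["os_event"].sum() == 0:
            entry["skipped"] = "no subjects or no events in stratum"
            report[stratum] = entry
            continue
        entry["os"] = _km_block(sub, "os_time", "os_event", horizon)
        entry["os"]["cox"] = _cox_ladder(
            sub, "os_time", "os_event", include_smoking=(stratum == "full"))
        if sub["pfs_event"].sum() > 0:
            entry["pfs"] = _km_block(sub, "pfs_time", "pfs_event", horizon)
            entry["pfs"]["cox"] = _cox_ladder(
                sub, "pfs_time", "pfs_event",
                include_smoking=(stratum == "full"))
        if stratum in ("full", "ever_smokers"):
            entry["three_year_roc"] = _roc_block(sub, horizon)
        report[stratum] = entry
    return report
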