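"""Survival statistics for prognostic evaluation of the digital grade.

Kaplan-Meier product-limit curves, multi-group log-rank tests, Harrell's
concordance index and Cox proportional-hazards regression (Efron tie
handling) are computed with lifelines; TNM-stage regrouping and the
four-level digital-grade x TNM combination are implemented here.

C-index orientation: risk scores follow the Cox linear-predictor convention
(higher score = higher hazard = shorter survival).  Digital grades order the
other way (higher class = longer survival), so grade-based scores are negated
before concordance so that informative predictors score above 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index


@dataclass
class KMCurve:
    times: np.ndarray  # event/censor times in ascending order
    survival: np.ndarray  # S(t) step values at those times
    at_risk: np.ndarray
    median: float  # months; nan if the curve never reaches 0.5

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxResult:
    covariate: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    c_index: float


def km_estimate(times, events) -> KMCurve:
    """Product-limit survival estimate; censored subjects leave the risk set."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty survival data")
    if (times < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return KMCurve(grid, surv, at_risk, median)


def logrank_test(groups: list[tuple[np.ndarray, np.ndarray]]):
    """Log-rank test across >=2 groups; returns (chi2 statistic, p-value)."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any(len(t) == 0 for t, _ in groups):
        raise ValueError("log-rank test received an empty group")
    times = np.concatenate([np.asarray(t, float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, int) for _, e in groups])
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def harrell_c(times, events, risk_scores) -> float:
    """Harrell's C for risk scores (higher risk = shorter expected survival).

    Tied risk scores in a comparable pair count 0.5; pairs made incomparable
    by censoring are excluded.  Raises if no pair is comparable.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    risk = np.asarray(risk_scores, float)
    if not (len(times) == len(events) == len(risk)):
        raise ValueError("length mismatch")
    if events.sum() == 0:
        raise ValueError("concordance undefined: no comparable pairs (no events)")
    # lifelines' convention scores concordance of *predicted survival times*
    return float(concordance_index(times, -risk, events))


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "os_months",
    event_col: str = "event",
    penalizer: float = 0.0,
) -> list[CoxResult]:
    """Cox proportional-hazards fit (Efron ties) for the listed covariates.

    One model containing all listed covariates is fitted (univariate when a
    single covariate is passed); per-covariate Wald statistics and the
    model's concordance index are returned.  A small ridge ``penalizer``
    keeps the fit finite under complete separation (a coefficient diverging
    because one group's events all precede the other's); unpenalized fits
    that diverge are flagged with a warning.
    """
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
        if df[c].dtype == object:
            raise ValueError(f"covariate {c!r} must be numeric-coded")
    corr = df[covariates].astype(float).corr().to_numpy()
    if len(covariates) > 1 and np.any(np.abs(corr - np.eye(len(corr))) > 1 - 1e-9):
        raise ValueError("collinear covariates in multivariate fit")
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df[covariates + [time_col, event_col]], duration_col=time_col,
            event_col=event_col)
    summary = cph.summary
    results = []
    for c in covariates:
        row = summary.loc[c]
        if abs(float(row["coef"])) > 10:
            import warnings

            warnings.warn(
                f"covariate {c!r}: |log-HR| > 10 suggests complete separation",
                stacklevel=2,
            )
        results.append(
            CoxResult(
                covariate=c,
                coef=float(row["coef"]),
                hazard_ratio=float(row["exp(coef)"]),
                ci_lower=float(row["exp(coef) lower 95%"]),
                ci_upper=float(row["exp(coef) upper 95%"]),
                p_value=float(row["p"]),
                c_index=float(cph.concordance_index_),
            )
        )
    return results


# ---- TNM regrouping ----------------------------------------------------------

_TNM_MAJOR = {"IA": "I", "IB": "I", "I": "I",
              "IIA": "II", "IIB": "II", "II": "II",
              "IIIA": "III", "IIIB": "III", "IIIC": "III", "III": "III"}

_TNM6_LEVELS = ("I", "IIA", "IIB", "IIIA", "IIIB", "IIIC")


def regroup_tnm(stage: str) -> dict[str, str]:
    """Map an AJCC stage (IA..IIIC) onto the TNM-2 / TNM-3 / TNM-6 regroupings.

    TNM-2: I+II vs III; TNM-3: I vs II vs III; TNM-6: I, IIA, IIB, IIIA,
    IIIB, IIIC.  Stage-IV patients must be excluded upstream.
    """
    stage = str(stage).strip().upper()
    if stage.startswith("IV"):
        raise ValueError("stage IV patients are excluded from TNM regrouping; "
                         "filter them out before calling regroup_tnm")
    if stage not in _TNM_MAJOR:
        raise ValueError(f"unknown TNM stage {stage!r}")
    major = _TNM_MAJOR[stage]
    tnm6 = "I" if major == "I" else stage
    if tnm6 not in _TNM6_LEVELS:  # bare II / III without substage
        tnm6 = major + "A"
    return {
        "tnm2": "I+II" if major in ("I", "II") else "III",
        "tnm3": major,
        "tnm6": tnm6,
    }


def combine_signature_tnm(grade: int, tnm2: str) -> int:
    """Four-level code from the binary digital grade and the TNM-2 group.

    Ordered from best to worst prognosis expectation:
    0 = long-term & I+II, 1 = long-term & III,
    2 = short-term & I+II, 3 = short-term & III.
    """
    if grade not in (0, 1):
        raise ValueError("binary digital grade must be 0 or 1")
    if tnm2 not in ("I+II", "III"):
        raise ValueError(f"invalid TNM-2 group {tnm2!r}")
    return (0 if grade == 1 else 2) + (0 if tnm2 == "I+II" else 1)


def survival_report(
    patients: pd.DataFrame,
    grade_col: str = "digital_grade",
    time_col: str = "os_months",
    event_col: str = "event",
) -> dict:
    """KM curves per grade, log-rank p, Cox HR/C-index for the digital grade.

    ``patients`` needs one row per patient with time, event and the grade.
    The Cox covariate is coded so that the hazard ratio contrasts the longer-
    survival grade against the shorter one (HR < 1 expected for an
    informative grade).
    """
    df = patients.dropna(subset=[grade_col]).copy()
    groups = []
    km = {}
    for val, sub in sorted(df.groupby(grade_col)):
        groups.append((sub[time_col].to_numpy(), sub[event_col].to_numpy()))
        curve = km_estimate(sub[time_col].to_numpy(), sub[event_col].to_numpy())
        km[str(val)] = {"median": curve.median, "n": len(sub)}
    out = {
        "km": km,
        "logrank_statistic": None,
        "logrank_p": None,
        "cox_hr": None,
        "cox_ci": None,
        "cox_p": None,
        "harrell_c": None,
        "n": len(df),
    }
    if len(groups) < 2:  # degenerate grading: every patient in one class
        out["note"] = "digital grade is constant; group comparisons undefined"
        return out
    stat, p = logrank_test(groups)
    cox = cox_fit(df.assign(**{grade_col: df[grade_col].astype(float)}),
                  [grade_col], time_col, event_col, penalizer=0.1)[0]
    c = harrell_c(df[time_col], df[event_col], -df[grade_col].astype(float))
    out.update(
        logrank_statistic=stat, logrank_p=p, cox_hr=cox.hazard_ratio,
        cox_ci=[cox.ci_lower, cox.ci_upper], cox_p=cox.p_value, harrell_c=c,
    )
    return out
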