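"""Editing-based prognosis: per-site Cox signs, the editing risk score,
grade/stage association, median-split survival comparison and multivariate
adjustment.

The risk score of a patient is

    Risk = sum_i  beta_i * Exp_gene(i) * Edit_i

summed over the qualifying editing sites with degree > 0 in that patient,
where beta_i in {+1, -1} is the sign of the univariate Cox regression
coefficient of survival on the site's editing degree ("risky" vs "protective"
editing), Exp_gene(i) is the normalized expression of the host gene and
Edit_i the editing degree.  Patients are split into high/low risk at the
median score (ties go low), compared by Kaplan-Meier curves with the log-rank
test, and the score is adjusted for gender, age, BMI, grade and stage in a
multivariate proportional-hazards fit (Efron ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import warnings

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["RiskModel", "SurvivalComparison", "univariate_sign",
           "build_risk_model", "risk_score", "grade_stage_association",
           "km_logrank", "multivariate_adjustment", "subset_prognosis"]


@dataclass
class RiskModel:
    """Per-site Cox signs: frame indexed by site id with columns
    gene_id, beta (+1/-1), cox_coef, cox_p."""

    table: pd.DataFrame

    @property
    def sites(self) -> list[str]:
        return list(self.table.index)

    def prognostic_sites(self, alpha: float = 0.05) -> list[str]:
        """Sites whose editing degree is associated with survival at raw
        univariate Cox p < alpha."""
        return list(self.table.index[self.table["cox_p"] < alpha])


@dataclass
class SurvivalComparison:
    groups: pd.Series  # patient -> "high" | "low"
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float


def _fit_cox(df: pd.DataFrame, duration_col="time", event_col="event",
             penalizer: float = 0.0) -> CoxPHFitter | None:
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            cph.fit(df, duration_col=duration_col, event_col=event_col)
    except (ConvergenceError, ValueError) as exc:
        if penalizer == 0.0:
            log.info("Cox fit failed (%s); retrying with small ridge penalty", exc)
            return _fit_cox(df, duration_col, event_col, penalizer=0.1)
        log.warning("Cox fit failed: %s", exc)
        return None
    return cph


def univariate_sign(degrees: pd.Series, survival: pd.DataFrame,
                    ) -> tuple[int, float, float] | None:
    """Sign of the univariate Cox coefficient of survival on editing degree.

    ``degrees`` is per-patient (absent = 0).  Returns (sign, coefficient,
    p-value), or None when the fit is not identifiable (fewer than 10
    patients, no event variation, constant degree, or non-convergence).
    """
    df = pd.DataFrame({"time": survival["time"], "event": survival["event"],
                       "degree": degrees.reindex(survival.index).fillna(0.0)})
    df = df.dropna()
    if len(df) < 10 or df["event"].nunique() < 2 or df["degree"].nunique() < 2:
        log.info("univariate Cox skipped: degenerate input (n=%d)", len(df))
        return None
    cph = _fit_cox(df)
    if cph is None:
        return None
    coef = float(cph.params_["degree"])
    p = float(cph.summary.loc["degree", "p"])
    return (1 if coef >= 0 else -1, coef, p)


def build_risk_model(site_ids: list[str], site_gene: pd.Series,
                     degrees: pd.DataFrame, survival: pd.DataFrame) -> RiskModel:
    """Univariate Cox per qualifying site; non-identifiable sites are
    excluded with a log message."""
    rows = []
    for sid in site_ids:
        if sid not in degrees.index:
            continue
        res = univariate_sign(degrees.loc[sid], survival)
        if res is None:
            log.info("risk model: %s excluded (no stable univariate fit)", sid)
            continue
        sign, coef, p = res
        rows.append((sid, site_gene.get(sid, ""), sign, coef, p))
    table = pd.DataFrame(rows, columns=["site_id", "gene_id", "beta",
                                        "cox_coef", "cox_p"]).set_index("site_id")
    return RiskModel(table=table)


def risk_score(model: RiskModel, expression: pd.DataFrame,
               degrees: pd.DataFrame, patients: list[str]) -> pd.Series:
    """Per-patient risk score; patients with no qualifying edited site score 0."""
    scores = pd.Series(0.0, index=patients, name="risk_score")
    for sid, row in model.table.iterrows():
        gene = row["gene_id"]
        if not gene or gene not in expression.index or sid not in degrees.index:
            continue
        deg = degrees.loc[sid].reindex(patients).fillna(0.0)
        expr = expression.loc[gene].reindex(patients).fillna(0.0)
        scores += row["beta"] * expr * deg
    n_zero = int((scores == 0).sum())
    if n_zero:
        log.info("risk score: %d patients with no qualifying edited site (score 0)",
                 n_zero)
    return scores


def _collapse_34(values: pd.Series) -> pd.Series:
    """Grade/stage 4 merged into "3 plus" (small-group collapsing)."""
    return values.clip(upper=3)


def grade_stage_association(scores: pd.Series, clinical: pd.DataFrame,
                            ) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between adjacent ordinal groups of
    tumor grade and stage (1, 2, 3-plus), on the risk scores.

    Exact p-values for small tie-free groups, normal approximation with tie
    correction otherwise.  Empty contrasts are skipped.
    """
    rows = []
    for var in ("grade", "stage"):
        groups = _collapse_34(clinical[var])
        for a, b in ((1, 2), (2, 3)):
            xa = scores[clinical.index[groups == a]].dropna()
            xb = scores[clinical.index[groups == b]].dropna()
            if len(xa) == 0 or len(xb) == 0:
                log.info("association: %s %d vs %d skipped (empty group)", var, a, b)
                continue
            exact = (len(xa) <= 20 and len(xb) <= 20
                     and len(np.unique(np.r_[xa, xb])) == len(xa) + len(xb))
            stat, p = stats.mannwhitneyu(
                xa, xb, alternative="two-sided",
                method="exact" if exact else "asymptotic")
            rows.append((var, f"{a}", "3plus" if b == 3 else f"{b}",
                         len(xa), len(xb), float(stat), float(p),
                         float(np.median(xa)), float(np.median(xb))))
    return pd.DataFrame(rows, columns=["variable", "group_a", "group_b", "n_a",
                                       "n_b", "u_stat", "p", "median_a",
                                       "median_b"])


def km_logrank(scores: pd.Series, survival: pd.DataFrame,
               min_patients: int = 20) -> SurvivalComparison:
    """Median-split Kaplan-Meier comparison with the log-rank test.

    Patients exactly at the median score go to the low-risk group.
    """
    common = scores.index.intersection(survival.index)
    if len(common) < min_patients:
        raise ValueError(f"need at least {min_patients} patients, got {len(common)}")
    s = scores[common]
    groups = pd.Series(np.where(s > s.median(), "high", "low"), index=common,
                       name="risk_group")
    curves = {}
    for name in ("high", "low"):
        members = common[groups == name]
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[members, "time"], survival.loc[members, "event"],
                label=name)
        curves[name] = kmf.survival_function_
        if survival.loc[members, "event"].sum() == 0:
            log.warning("km_logrank: group %r has zero events", name)
    hi, lo = common[groups == "high"], common[groups == "low"]
    res = logrank_test(survival.loc[hi, "time"], survival.loc[lo, "time"],
                       survival.loc[hi, "event"], survival.loc[lo, "event"])
    return SurvivalComparison(groups=groups, km_curves=curves,
                              logrank_stat=float(res.test_statistic),
                              logrank_p=float(res.p_value))


def _design_matrix(scores: pd.Series, clinical: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame({
        "time": clinical["time"], "event": clinical["event"],
        "risk_score": scores.reindex(clinical.index),
        "gender_male": (clinical["gender"].str.lower() == "male").astype(float),
        "age": clinical["age"], "bmi": clinical["bmi"],
    })
    for var, prefix in (("grade", "G"), ("stage", "T")):
        for level in (2, 3, 4):
            df[f"{var}_{prefix}{level}"] = (clinical[var] == level).astype(float)
    return df.dropna()


def multivariate_adjustment(scores: pd.Series, clinical: pd.DataFrame,
                            ) -> pd.DataFrame:
    """Proportional-hazards fit of survival on the risk score adjusted for
    gender, age, BMI and reference-coded grade/stage (G1/T1 reference).

    Constant (or fully collinear) covariates are dropped with a log message.
    Returns per-covariate hazard ratios with 95% CIs and Wald p-values.
    """
    df = _design_matrix(scores, clinical)
    keep = []
    for col in df.columns:
        if col in ("time", "event"):
            keep.append(col)
        elif df[col].nunique() > 1:
            keep.append(col)
        else:
            log.info("multivariate Cox: dropping constant covariate %r", col)
    cph = _fit_cox(df[keep])
    if cph is None:
        raise RuntimeError("multivariate Cox fit failed to converge")
    s = cph.summary
    return pd.DataFrame({
        "HR": np.exp(s["coef"]),
        "ci_low": np.exp(s["coef lower 95%"]),
        "ci_high": np.exp(s["coef upper 95%"]),
        "p": s["p"],
    })


def subset_prognosis(model: RiskModel, site_subset: list[str],
                     expression: pd.DataFrame, degrees: pd.DataFrame,
                     survival: pd.DataFrame,
                     patient_filter: pd.Series | None = None,
                     min_patients: int = 20) -> SurvivalComparison:
    """Median-split survival analysis restricted to a site subset (e.g. the
    prognostic sites) and an optional patient filter (e.g. an etiology flag).

    Refuses (ValueError) when fewer than 2 sites or ``min_patients`` patients
    remain.
    """
    sub = [s for s in site_subset if s in model.table.index]
    if len(sub) < 2:
        raise ValueError(f"site subset too small ({len(sub)} sites; need >= 2)")
    patients = list(survival.index)
    if patient_filter is not None:
        patients = [p for p in patients if bool(patient_filter.get(p, False))]
    if len(patients) < min_patients:
        raise ValueError(f"cohort subset too small ({len(patients)} patients; "
                         f"need >= {min_patients})")
    sub_model = RiskModel(table=model.table.loc[sub])
    scores = risk_score(sub_model, expression, degrees, patients)
    return km_logrank(scores, survival.loc[patients], min_patients=min_patients)
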