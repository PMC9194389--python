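"""CRT response labelling and outcome statistics.

Implements the statistical toolkit used to relate the contraction
pattern to CRT super-response and long-term outcome:

* response labels — response: absolute LVEF increase >= 5 points at
  6 months; super-response: follow-up LVEF >= 50% or an absolute
  increase > 15 points;
* 2x2 contingency analysis — cross-product odds ratios with Woolf
  (log-scale) confidence intervals, Pearson chi-square (no continuity
  correction) or Fisher's exact test when expected cells are small,
  Bonferroni adjustment for multiple pairwise comparisons;
* logistic regression — Newton maximum likelihood with Wald standard
  errors, per-SD standardisation of continuous predictors, and a
  stepwise wrapper (univariate P < 0.05 to enter, multivariable
  P > 0.05 to leave);
* survival — Kaplan-Meier product-limit curves and the log-rank test
  for the combined end point (all-cause death or HF hospitalisation).

Regression and survival computations are delegated to statsmodels and
lifelines; contingency-table quantities are computed directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .patterns import PatternLabel

#: pairwise pattern contrasts in reporting order (group1 vs group2)
PAIRWISE_CONTRASTS = (
    (PatternLabel.MILD, PatternLabel.U_SHAPED),
    (PatternLabel.MILD, PatternLabel.HETEROGENEOUS),
    (PatternLabel.MILD, PatternLabel.HOMOGENEOUS),
    (PatternLabel.U_SHAPED, PatternLabel.HETEROGENEOUS),
    (PatternLabel.U_SHAPED, PatternLabel.HOMOGENEOUS),
    (PatternLabel.HOMOGENEOUS, PatternLabel.HETEROGENEOUS),
)


@dataclass
class PatientRecord:
    """One patient: imaging indices, pattern, echo course, outcome."""

    id: str
    pattern: PatternLabel
    psd_deg: float
    pbw_deg: float
    scar_burden_pct: float
    lvef_baseline_pct: float
    lvef_6mo_pct: float
    lvedd_baseline_mm: float
    lvedd_6mo_mm: float
    age_yr: float
    male: bool
    v5v6_s: bool
    nyha: int
    qrsd_ms: float
    followup_months: float
    event: bool

    def __post_init__(self):
        for v in (self.lvef_baseline_pct, self.lvef_6mo_pct):
            if not 0 < v < 100:
                raise ValueError(f"LVEF must lie in (0, 100), got {v}")
        if self.followup_months < 0:
            raise ValueError("followup_months must be >= 0")


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort table with one row per patient plus derived labels."""
    df = pd.DataFrame([{
        "id": r.id,
        "pattern": r.pattern.value,
        "psd_deg": r.psd_deg,
        "pbw_deg": r.pbw_deg,
        "scar_burden_pct": r.scar_burden_pct,
        "lvef_baseline_pct": r.lvef_baseline_pct,
        "lvef_6mo_pct": r.lvef_6mo_pct,
        "lvedd_baseline_mm": r.lvedd_baseline_mm,
        "lvedd_6mo_mm": r.lvedd_6mo_mm,
        "age_yr": r.age_yr,
        "male": int(r.male),
        "v5v6_s": int(r.v5v6_s),
        "nyha": r.nyha,
        "qrsd_ms": r.qrsd_ms,
        "followup_months": r.followup_months,
        "event": int(r.event),
    } for r in records])
    df["response"] = [
        int(label_response(r.lvef_baseline_pct, r.lvef_6mo_pct)) for r in records
    ]
    df["super_response"] = [
        int(label_super_response(r.lvef_baseline_pct, r.lvef_6mo_pct)) for r in records
    ]
    return df


# ---------------------------------------------------------------------------
# response labels


def label_response(lvef_baseline: float, lvef_6mo: float) -> bool:
    """CRT response: absolute LVEF increase of at least 5 points."""
    return (lvef_6mo - lvef_baseline) >= 5.0


def label_super_response(lvef_baseline: float, lvef_6mo: float) -> bool:
    """CRT super-response: follow-up LVEF >= 50% or increase > 15 points."""
    return lvef_6mo >= 50.0 or (lvef_6mo - lvef_baseline) > 15.0


# ---------------------------------------------------------------------------
# 2x2 contingency analysis


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b) = group-1 success/failure, (c, d) = group-2."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_flags(cls, success1, success2) -> "ContingencyTable2x2":
        s1 = np.asarray(success1, dtype=bool)
        s2 = np.asarray(success2, dtype=bool)
        return cls(int(s1.sum()), int((~s1).sum()), int(s2.sum()), int((~s2).sum()))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    or_defined: bool
    ci_defined: bool


def odds_ratio_ci(t: ContingencyTable2x2, z: Optional[float] = None,
                  conf_level: float = 0.95) -> OddsRatioResult:
    """Cross-product odds ratio with a Woolf (log) confidence interval.

    OR = (a*d)/(b*c); CI = exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
    ``z`` defaults to the normal quantile for ``conf_level`` (1.959964
    for 95%).  No continuity correction: a zero off-diagonal cell leaves
    the OR undefined, and any zero cell leaves the CI undefined; both
    are flagged rather than patched.
    """
    if z is None:
        z = float(sps.norm.ppf(0.5 + conf_level / 2.0))
    a, b, c, d = t.a, t.b, t.c, t.d
    or_defined = b * c > 0
    ci_defined = a * b * c * d > 0
    if not or_defined:
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), False, False)
    or_ = (a * d) / (b * c)
    if not ci_defined:
        return OddsRatioResult(or_, float("nan"), float("nan"), True, False)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - z * se), np.exp(np.log(or_) + z * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), True, True)


def pearson_chi2(t: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square without continuity correction, df = 1."""
    if t.n == 0:
        raise ValueError("empty contingency table")
    stat, p, _, _ = sps.chi2_contingency(t.as_array(), correction=False)
    return float(stat), float(p)


def fisher_exact(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (hypergeometric, sum of probabilities
    no larger than the observed table's)."""
    return float(sps.fisher_exact(t.as_array(), alternative="two-sided")[1])


def expected_cells(t: ContingencyTable2x2) -> np.ndarray:
    arr = t.as_array()
    return np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()


def compare_proportions(t: ContingencyTable2x2) -> tuple[str, float]:
    """Chi-square p, or Fisher's exact p when any expected cell < 5."""
    if (expected_cells(t) < 5).any():
        return "fisher", fisher_exact(t)
    return "chi2", pearson_chi2(t)[1]


def bonferroni(pvals, m: Optional[int] = None):
    """Bonferroni adjustment p_adj = min(1, m * p); m defaults to len(pvals)."""
    p = np.atleast_1d(np.asarray(pvals, dtype=float))
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# logistic regression


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass
class LogisticResult:
    """Fitted logistic model: coefficients, Wald SEs, odds ratios."""

    params: pd.Series       # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    odds_ratios: pd.Series  # exp(params), predictors only
    ci_low: pd.Series
    ci_high: pd.Series
    converged: bool
    scale: dict = field(default_factory=dict)  # predictor -> SD used for per-SD scaling


def logistic_fit(design: pd.DataFrame, y, per_sd: Sequence[str] = (),
                 conf_level: float = 0.95, maxiter: int = 100) -> LogisticResult:
    """Newton maximum-likelihood logistic regression with Wald SEs.

    Columns named in ``per_sd`` are standardised by their sample SD
    (ddof=1) before fitting, so their odds ratios are per-SD.  Perfect
    separation (including a constant outcome) raises SeparationError;
    non-convergence raises RuntimeError.
    """
    X = design.astype(float).copy()
    yv = np.asarray(y, dtype=float)
    if len(np.unique(yv)) < 2:
        raise SeparationError("outcome is constant; model is degenerate")
    scale = {}
    for col in per_sd:
        sd = float(X[col].std(ddof=1))
        if sd <= 0:
            raise ValueError(f"cannot scale constant predictor {col!r} per SD")
        X[col] = X[col] / sd
        scale[col] = sd
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            fit = sm.Logit(yv, Xc).fit(method="newton", maxiter=maxiter, disp=False)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise RuntimeError("logistic regression failed to converge")
    if np.abs(fit.params).max() > 15:  # quasi-separation: exploding coefficients
        raise SeparationError("coefficients diverged; data are (quasi-)separated")
    z = float(sps.norm.ppf(0.5 + conf_level / 2.0))
    pred = [c for c in fit.params.index if c != "const"]
    return LogisticResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        odds_ratios=np.exp(fit.params[pred]),
        ci_low=np.exp(fit.params[pred] - z * fit.bse[pred]),
        ci_high=np.exp(fit.params[pred] + z * fit.bse[pred]),
        converged=True,
        scale=scale,
    )


def stepwise_logistic(df: pd.DataFrame, candidates: Sequence[str], outcome: str,
                      entry_p: float = 0.05, stay_p: float = 0.05,
                      per_sd: Sequence[str] = ()) -> tuple[list, Optional[LogisticResult], pd.DataFrame]:
    """Stepwise selection: univariate P < entry to enter, multivariable
    P > stay to leave.

    Candidates are screened univariately; those significant enter in
    ascending univariate-P order, and after each entry any included
    variable whose multivariable Wald P exceeds ``stay_p`` is dropped.
    Returns (selected variables, final fit or None, univariate table).
    Candidates whose univariate fit separates are recorded with NaN P
    and skipped.
    """
    rows = []
    for var in candidates:
        try:
            res = logistic_fit(df[[var]], df[outcome],
                               per_sd=[var] if var in per_sd else [])
            rows.append({"variable": var, "odds_ratio": res.odds_ratios[var],
                         "ci_low": res.ci_low[var], "ci_high": res.ci_high[var],
                         "p": res.pvalues[var]})
        except (SeparationError, RuntimeError, ValueError):
            rows.append({"variable": var, "odds_ratio": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
    uni = pd.DataFrame(rows)
    eligible = uni.dropna(subset=["p"]).query("p < @entry_p").sort_values("p")
    selected: list = []
    final: Optional[LogisticResult] = None
    for var in eligible["variable"]:
        trial = selected + [var]
        try:
            fit = logistic_fit(df[trial], df[outcome],
                               per_sd=[v for v in trial if v in per_sd])
        except (SeparationError, RuntimeError):
            continue
        # backward pass: drop worst non-significant variable until stable
        while True:
            pv = fit.pvalues.drop("const")
            worst = pv.idxmax()
            if pv[worst] <= stay_p or len(trial) == 1:
                break
            trial = [v for v in trial if v != worst]
            fit = logistic_fit(df[trial], df[outcome],
                               per_sd=[v for v in trial if v in per_sd])
        selected, final = trial, fit
    return selected, final, uni


# ---------------------------------------------------------------------------
# survival


@dataclass
class SurvivalCurve:
    """Kaplan-Meier step function: event times, risk sets, survival."""

    event_times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimator(times, events) -> SurvivalCurve:
    """Product-limit survival estimate (delegates to lifelines)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    surv = kmf.survival_function_["KM_estimate"]
    return SurvivalCurve(
        event_times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        survival=surv.loc[ev.index].to_numpy(dtype=float),
    )


def log_rank(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square and p across groups (df = n_groups - 1)."""
    res = multivariate_logrank_test(np.asarray(times, dtype=float),
                                    np.asarray(groups),
                                    np.asarray(events, dtype=int))
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# the full outcome table


def pattern_table(df: pd.DataFrame, g1: PatternLabel, g2: PatternLabel,
                  outcome: str = "super_response") -> ContingencyTable2x2:
    """2x2 table of outcome by pattern membership (g1 rows first)."""
    s1 = df.loc[df["pattern"] == g1.value, outcome].astype(bool)
    s2 = df.loc[df["pattern"] == g2.value, outcome].astype(bool)
    return ContingencyTable2x2.from_flags(s1, s2)


def build_table2(df: pd.DataFrame,
                 continuous_per_sd: Sequence[str] = ("psd_deg", "pbw_deg", "scar_burden_pct"),
                 binary_covariates: Sequence[str] = ("male", "v5v6_s"),
                 outcome: str = "super_response") -> dict:
    """Univariate and stepwise-multivariable analysis of super-response.

    Returns a dict with:

    * ``pairwise`` — all six pattern contrasts: counts, cross-product OR
      with Woolf CI, chi-square/Fisher p (test chosen by expected-cell
      rule) and Bonferroni-adjusted p;
    * ``univariate`` — per-SD continuous predictors and binary
      covariates, univariate logistic ORs with Wald CIs;
    * ``multivariable`` — the stepwise model (entry P < 0.05, stay
      P <= 0.05) over pattern indicators and the other candidates;
    * ``selected`` — names retained by the stepwise procedure.
    """
    rows = []
    pvals = []
    for g1, g2 in PAIRWISE_CONTRASTS:
        t = pattern_table(df, g1, g2, outcome)
        orr = odds_ratio_ci(t)
        if t.n > 0 and min(t.a + t.b, t.c + t.d) > 0:
            test, p = compare_proportions(t)
        else:
            test, p = "none", np.nan
        pvals.append(p)
        rows.append({
            "contrast": f"{g1.value} vs {g2.value}",
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "odds_ratio": orr.odds_ratio, "ci_low": orr.ci_low, "ci_high": orr.ci_high,
            "or_defined": orr.or_defined, "ci_defined": orr.ci_defined,
            "test": test, "p": p,
        })
    pairwise = pd.DataFrame(rows)
    pairwise["p_bonferroni"] = bonferroni(pairwise["p"].to_numpy(), len(PAIRWISE_CONTRASTS))

    # candidate predictors for regression: pattern indicators vs the
    # reference (heterogeneous, the least-responding group) + covariates
    work = df.copy()
    indicator_cols = []
    for lbl in (PatternLabel.MILD, PatternLabel.U_SHAPED, PatternLabel.HOMOGENEOUS):
        col = f"is_{lbl.value.lower()}"
        work[col] = (work["pattern"] == lbl.value).astype(int)
        indicator_cols.append(col)
    candidates = list(indicator_cols) + list(continuous_per_sd) + list(binary_covariates)
    candidates = [c for c in candidates if c in work.columns]
    selected, final, uni = stepwise_logistic(
        work, candidates, outcome, per_sd=continuous_per_sd)
    if final is not None:
        multi = pd.DataFrame({
            "variable": final.odds_ratios.index,
            "odds_ratio": final.odds_ratios.to_numpy(),
            "ci_low": final.ci_low.to_numpy(),
            "ci_high": final.ci_high.to_numpy(),
            "p": final.pvalues.drop("const").to_numpy(),
        })
    else:
        multi = pd.DataFrame(columns=["variable", "odds_ratio", "ci_low", "ci_high", "p"])
    return {"pairwise": pairwise, "univariate": uni, "multivariable": multi,
            "selected": selected}
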