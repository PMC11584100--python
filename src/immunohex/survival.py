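"""Optimal-cutoff survival stratification, Cox modeling, and the combined
prognostic score (CPBS).

Continuous indicators are dichotomized at the cutoff minimizing the log-rank
p-value over all admissible splits (both groups at least a configured
fraction of the cohort) — the "Cutoff Finder" approach.  Indicators passing
a univariate screen (log-rank p < 0.05) enter a multivariable Cox
proportional-hazards model (Efron ties, via lifelines) evaluated with
Harrell's concordance index.  The CPBS sums binary poor-prognosis indicators
and maps the total to low/intermediate/high risk groups per subtype model.

Note: scanning many candidate cutoffs inflates the type-I error of the
minimum p-value; no multiple-testing correction is applied here (by design,
mirroring common optimal-cutpoint practice), so screen results on null
covariates are anti-conservative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["CutoffResult", "CoxModelResult", "CpbsResult",
           "logrank_statistic", "optimal_cutoff", "univariate_screen",
           "fit_multivariable_cox", "harrell_c", "cpbs_score",
           "CPBS_MODELS"]


# -- log-rank ---------------------------------------------------------------

def logrank_statistic(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi², p).

    Vectorized Mantel–Haenszel form: at every distinct event time the
    observed minus expected events in group 1 and the hypergeometric
    variance are accumulated.  Matches ``lifelines.statistics.logrank_test``.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group, dtype=bool)
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order]
    n = len(t)
    uniq, start = np.unique(t, return_index=True)
    # at-risk counts just before each distinct time
    at_risk = n - start
    n1_cum = np.concatenate([[0], np.cumsum(g)])
    at_risk1 = n1_cum[n] - n1_cum[start]
    # events at each distinct time
    d = np.add.reduceat(e.astype(float), start)
    d1 = np.add.reduceat((e & g).astype(float), start)
    mask = (d > 0) & (at_risk > 1)
    N, N1, D, D1 = at_risk[mask], at_risk1[mask], d[mask], d1[mask]
    exp1 = D * N1 / N
    var1 = D * (N1 / N) * (1 - N1 / N) * (N - D) / (N - 1)
    v = var1.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = float((D1.sum() - exp1.sum()) ** 2 / v)
    return chi2, float(stats.chi2.sf(chi2, 1))


# -- optimal cutoff ---------------------------------------------------------

@dataclass
class CutoffResult:
    variable: str
    cutoff: float
    chi2: float
    p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    n_low: int
    n_high: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def optimal_cutoff(values, times, events, min_group_fraction: float = 0.1,
                   variable: str = "") -> CutoffResult:
    """Best dichotomizing cutoff by exhaustive log-rank scan.

    Candidates are the midpoints between consecutive sorted distinct values;
    splits leaving either group below ``min_group_fraction`` of the cohort
    are inadmissible.  Returns the cutoff with the smallest log-rank p
    (ties: larger χ², then lower cutoff) together with the Cox hazard ratio
    of the high vs. low group.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(v)
    if len(np.unique(v)) < 2:
        raise ValueError("cannot dichotomize: all values identical")
    if e.sum() < 1:
        raise ValueError("cannot dichotomize: no events observed")
    uniq = np.unique(v)
    best = None
    min_n = min_group_fraction * n
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = (lo + hi) / 2.0
        high = v > cut
        n_high = int(high.sum())
        if n_high < min_n or (n - n_high) < min_n:
            continue
        chi2, p = logrank_statistic(t, e, high)
        if best is None or (p, -chi2, cut) < (best[1], -best[0], best[2]):
            best = (chi2, p, cut, n_high)
    if best is None:
        raise ValueError(
            f"no admissible split at min_group_fraction={min_group_fraction}")
    chi2, p, cut, n_high = best
    hr, lo_ci, hi_ci = _binary_cox_hr(v > cut, t, e)
    return CutoffResult(variable=variable, cutoff=float(cut), chi2=chi2, p=p,
                        hazard_ratio=hr, hr_ci_low=lo_ci, hr_ci_high=hi_ci,
                        n_low=n - n_high, n_high=n_high)


def _binary_cox_hr(high, times, events):
    df = pd.DataFrame({"x": np.asarray(high, dtype=float),
                       "time": times, "event": events})
    try:
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["x"]))
        lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
        return hr, float(lo), float(hi)
    except Exception as exc:  # monotone likelihood etc.
        log.warning("binary Cox fit failed (%s); HR unreported", exc)
        return np.nan, np.nan, np.nan


def univariate_screen(cohort: pd.DataFrame, variables: list[str],
                      alpha: float = 0.05, min_group_fraction: float = 0.1,
                      time_col: str = "time_months", event_col: str = "event",
                      ) -> tuple[list[str], dict[str, CutoffResult]]:
    """Optimal-cutoff log-rank screen; keeps variables with p < alpha.

    Variables whose cutoff scan fails (constant values, no admissible split)
    are skipped with a log message.  Returns (retained names, per-variable
    cutoff results for all variables that could be scanned).
    """
    results: dict[str, CutoffResult] = {}
    retained: list[str] = []
    for var in variables:
        try:
            res = optimal_cutoff(cohort[var], cohort[time_col], cohort[event_col],
                                 min_group_fraction=min_group_fraction,
                                 variable=var)
        except (ValueError, KeyError) as exc:
            log.info("skipping %s in univariate screen: %s", var, exc)
            continue
        results[var] = res
        if res.p < alpha:
            retained.append(var)
    return retained, results


# -- Cox model --------------------------------------------------------------

@dataclass
class CoxModelResult:
    covariates: list[str]
    summary: pd.DataFrame = field(repr=False)  # HR, CI, p, Wald χ² per covariate
    lr_statistic: float
    lr_p: float
    c_index: float
    linear_predictor: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "covariates": self.covariates,
            "per_covariate": self.summary.to_dict(orient="index"),
            "lr_statistic": self.lr_statistic,
            "lr_p": self.lr_p,
            "c_index": self.c_index,
        }


def fit_multivariable_cox(cohort: pd.DataFrame, covariates: list[str],
                          time_col: str = "time_months",
                          event_col: str = "event") -> CoxModelResult:
    """Multivariable Cox PH fit (Efron ties) with Harrell's C on the fit.

    Requires at least ``len(covariates) + 5`` events.  Separation or
    non-convergence is surfaced as a ValueError with the lifelines
    diagnostic attached.
    """
    if not covariates:
        raise ValueError("no covariates to fit")
    n_events = int(cohort[event_col].sum())
    if n_events < len(covariates) + 5:
        raise ValueError(
            f"too few events ({n_events}) for {len(covariates)} covariates")
    df = cohort[covariates + [time_col, event_col]].astype(float)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except Exception as exc:
        raise ValueError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "hazard_ratio": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
        "wald_chi2": s["z"] ** 2,
        "coef": s["coef"],
    })
    lp = cph.predict_partial_hazard(df).to_numpy()
    lr = cph.log_likelihood_ratio_test()
    c = harrell_c(np.log(lp), df[time_col].to_numpy(), df[event_col].to_numpy())
    return CoxModelResult(covariates=list(covariates), summary=summary,
                          lr_statistic=float(lr.test_statistic),
                          lr_p=float(lr.p_value), c_index=c,
                          linear_predictor=np.log(lp))


def harrell_c(risk, times, events) -> float:
    """Harrell's concordance index of a risk score.

    A pair (i, j) is comparable when the earlier time is an event and the
    other subject is still at risk at that time (later time, or equal time
    with the other censored).  Concordant when the event-earlier subject has
    the higher risk; risk ties count ½.  Pairs of events at identical times
    are not comparable.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    conc = 0.0
    comp = 0
    idx = np.arange(len(t))
    for i in idx[e]:
        later = (t > t[i]) | ((t == t[i]) & ~e & (idx != i))
        m = int(later.sum())
        if m == 0:
            continue
        comp += m
        conc += np.sum(r[i] > r[later]) + 0.5 * np.sum(r[i] == r[later])
    if comp == 0:
        raise ValueError("concordance undefined: no comparable pairs")
    return float(conc / comp)


# -- combined prognostic score ----------------------------------------------

#: risk-group mapping per subtype model: (arity, {total: group})
CPBS_MODELS = {
    "ER+HER2-": (4, {0: "low", 1: "intermediate",
                     2: "high", 3: "high", 4: "high"}),
    "TNBC": (3, {0: "low", 1: "low", 2: "intermediate", 3: "high"}),
}


@dataclass(frozen=True)
class CpbsResult:
    scores: tuple
    total: int
    risk_group: str
    model: str


def cpbs_score(scores, model: str) -> CpbsResult:
    """Combined prognostic score from oriented binary indicators.

    Each input is 0 (good prognosis) or 1 (poor prognosis); the inputs must
    already be oriented (poor = node-positive; entropy above cutoff; CD8
    density below cutoff; Immunodrop above cutoff; pT2).  The ER+HER2−
    model sums 4 indicators (risk groups 0 / 1 / 2–4 = low / intermediate /
    high); the TNBC model sums 3 (0–1 / 2 / 3).
    """
    if model not in CPBS_MODELS:
        raise ValueError(f"unknown CPBS model {model!r}; use one of {list(CPBS_MODELS)}")
    arity, mapping = CPBS_MODELS[model]
    scores = tuple(scores)
    if len(scores) != arity:
        raise ValueError(f"{model} CPBS needs exactly {arity} scores, got {len(scores)}")
    if any(s not in (0, 1) for s in scores):
        raise ValueError(f"scores must be binary 0/1, got {scores}")
    total = int(sum(scores))
    return CpbsResult(scores=scores, total=total,
                      risk_group=mapping[total], model=model)


def orient_binary(values, cutoff_result: CutoffResult) -> np.ndarray:
    """Binary poor-prognosis indicator from a cutoff: the side of the cutoff
    with the higher hazard (HR of high>cutoff group > 1 → high side is poor)."""
    above = np.asarray(values, dtype=float) > cutoff_result.cutoff
    if np.isnan(cutoff_result.hazard_ratio) or cutoff_result.hazard_ratio >= 1.0:
        return above.astype(int)
    return (~above).astype(int)
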