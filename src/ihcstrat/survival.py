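"""Outcome statistics for the stratified cohorts.

Kaplan-Meier estimation and log-rank comparison, Cox proportional-hazards
screening and multivariate fitting (lifelines), Schoenfeld-residual
proportional-hazards testing with an extended time-varying-coefficient Cox
fallback, restricted-mean-survival-time comparison at a horizon tau
(24 months by default), the combined clinical + DL-group linear-predictor
score with a cohort-median cutoff, likelihood-ratio testing of nested Cox
models, Benjamini-Hochberg adjustment, and cohort-comparison tables
(Pearson chi-squared / Fisher's exact / Wilcoxon rank-sum).

The Schoenfeld test follows Grambsch & Therneau (1994): with unscaled
Schoenfeld residuals s_i at event times, a centered time transform g, d
events and the fitted covariance V of beta,

    per-term  T_k = d * (V z)_k^2 / (V_kk * sum(g - gbar)^2)
    global    T   = d * z' V z / sum(g - gbar)^2,  z = sum_i (g_i - gbar) s_i

each referred to a chi-squared distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "SurvivalRecord",
    "CoxFit",
    "TimeVaryingCoxFit",
    "RMSTResult",
    "CombinedScore",
    "km_fit",
    "logrank_test",
    "cox_fit",
    "univariate_screen",
    "schoenfeld_ph_test",
    "extended_cox_timevarying",
    "rmst",
    "rmst_compare",
    "combined_score",
    "concordance_index",
    "likelihood_ratio_test",
    "bh_adjust",
    "compare_cohorts",
    "format_pvalue",
    "km_plot",
]

log = logging.getLogger(__name__)

TIME = "time_months"
EVENT = "event"


@dataclass
class SurvivalRecord:
    """One patient's follow-up: time in months, event indicator, covariates."""

    patient_id: str
    time: float
    event: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError("time must be finite and positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    rows = [
        {"patient_id": r.patient_id, TIME: r.time, EVENT: r.event, **r.covariates}
        for r in records
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    fitters: dict
    medians: dict

    def survival_table(self, group) -> pd.DataFrame:
        f = self.fitters[group]
        out = f.survival_function_.reset_index()
        out.columns = ["time", "survival"]
        return out


def km_fit(
    df: pd.DataFrame,
    group_col: str | None = None,
    time_col: str = TIME,
    event_col: str = EVENT,
) -> KMResult:
    """Product-limit estimator per group; median = first time S(t) <= 0.5."""
    groups = [None] if group_col is None else sorted(df[group_col].dropna().unique())
    fitters, medians = {}, {}
    for g in groups:
        sub = df if g is None else df[df[group_col] == g]
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(sub[time_col], sub[event_col])
        fitters[g] = kmf
        med = kmf.median_survival_time_
        medians[g] = float(med) if np.isfinite(med) else float("nan")
    return KMResult(fitters=fitters, medians=medians)


def logrank_test(
    df: pd.DataFrame,
    group_col: str,
    time_col: str = TIME,
    event_col: str = EVENT,
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-squared statistic, p)."""
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {groups}")
    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    if df[event_col].sum() == 0:
        raise ValueError("no events in either group; log-rank p undefined")
    r = _ll_logrank(a[time_col], b[time_col], a[event_col], b[event_col])
    return float(r.test_statistic), float(r.p_value)


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def _encode(
    df: pd.DataFrame,
    terms: Sequence[str],
    encoding: Mapping[str, object] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Design matrix with reference-level dummy coding for categorical terms.

    The first level in sorted order is the baseline. ``encoding`` (from a
    previous fit) pins the level sets so new cohorts are coded identically.
    """
    design = pd.DataFrame(index=df.index)
    enc: dict[str, object] = {}
    for term in terms:
        col = df[term]
        spec = None if encoding is None else encoding.get(term)
        if spec == "numeric" or (spec is None and pd.api.types.is_numeric_dtype(col)):
            design[term] = col.astype(float)
            enc[term] = "numeric"
        else:
            levels = list(spec) if spec is not None else sorted(map(str, col.dropna().unique()))
            if len(levels) < 2:
                raise ValueError(f"term {term!r} has a single level; cannot enter a Cox model")
            vals = col.astype(str)
            unseen = set(vals.dropna()) - set(levels)
            if unseen:
                raise ValueError(f"term {term!r}: unseen levels {sorted(unseen)}")
            for lev in levels[1:]:
                design[f"{term}[{lev}]"] = (vals == lev).astype(float)
            enc[term] = levels
    return design, enc


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model plus its design bookkeeping."""

    coefficients: pd.DataFrame  # index: design column; beta, hr, ci_low, ci_high, p
    log_likelihood: float
    null_log_likelihood: float
    n: int
    n_events: int
    terms: tuple
    encoding: dict
    model: CoxPHFitter
    data: pd.DataFrame  # design + time/event actually fitted
    time_col: str = TIME
    event_col: str = EVENT
    ph_test: pd.DataFrame | None = None

    @property
    def beta(self) -> pd.Series:
        return self.coefficients["beta"]

    def linear_predictor(self, df: pd.DataFrame) -> pd.Series:
        """Sum_j beta_j x_ij on the original (uncentered) design scale."""
        design, _ = _encode(df, self.terms, self.encoding)
        design = design[self.coefficients.index]
        return design @ self.beta


def cox_fit(
    df: pd.DataFrame,
    terms: Sequence[str],
    time_col: str = TIME,
    event_col: str = EVENT,
    encoding: Mapping[str, object] | None = None,
    penalizer: float = 0.0,
) -> CoxFit:
    """Cox partial-likelihood fit with Wald CIs and p-values.

    Categorical terms are dummy-coded against the first sorted level. Raises
    on zero events, constant covariates, and convergence failure (complete
    separation surfaces as the latter).
    """
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event to fit a Cox model")
    design, enc = _encode(df, terms, encoding)
    for c in design.columns:
        if design[c].nunique() <= 1:
            raise ValueError(f"constant covariate column {c!r}")
    data = design.copy()
    data[time_col] = df[time_col].to_numpy(float)
    data[event_col] = df[event_col].to_numpy(int)
    n_missing = int(data.isna().any(axis=1).sum())
    if n_missing:
        log.info("cox_fit: dropping %d rows with missing covariates", n_missing)
        data = data.dropna()
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as err:  # noqa: BLE001 - surface as a model-fit failure
        raise RuntimeError(f"Cox model failed to converge: {err}") from err
    summ = cph.summary
    coef = pd.DataFrame(
        {
            "beta": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    llf = float(cph.log_likelihood_)
    lrt = cph.log_likelihood_ratio_test()
    null_llf = llf - float(lrt.test_statistic) / 2.0
    return CoxFit(
        coefficients=coef,
        log_likelihood=llf,
        null_log_likelihood=null_llf,
        n=int(len(data)),
        n_events=int(data[event_col].sum()),
        terms=tuple(terms),
        encoding=enc,
        model=cph,
        data=data,
        time_col=time_col,
        event_col=event_col,
    )


def univariate_screen(
    df: pd.DataFrame,
    candidates: Sequence[str],
    alpha_in: float = 0.1,
    exclude: Sequence[str] = (),
    time_col: str = TIME,
    event_col: str = EVENT,
) -> tuple[list[str], pd.DataFrame]:
    """Univariate Cox screen: keep terms with LRT p < alpha_in.

    Terms listed in ``exclude`` (e.g. a biomarker collinear with the group
    under study) are dropped regardless of their p-value.
    """
    if not candidates:
        raise ValueError("no candidate terms")
    rows, selected = [], []
    for term in candidates:
        fit = cox_fit(df, [term], time_col=time_col, event_col=event_col)
        lr = fit.model.log_likelihood_ratio_test()
        p = float(lr.p_value)
        keep = (p < alpha_in) and (term not in exclude)
        rows.append({"term": term, "p": p, "selected": keep,
                     "excluded": term in exclude})
        if keep:
            selected.append(term)
    return selected, pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# Schoenfeld proportional-hazards test
# ---------------------------------------------------------------------------

def _time_transform(name_or_fn, times: np.ndarray, events: np.ndarray):
    if callable(name_or_fn):
        return np.asarray(name_or_fn(times), float)
    if name_or_fn == "identity":
        return times.astype(float)
    if name_or_fn == "log":
        return np.log(times)
    if name_or_fn == "rank":
        return sps.rankdata(times).astype(float)
    if name_or_fn == "km":
        km = KaplanMeierFitter().fit(times, events)
        sf = km.survival_function_.iloc[:, 0]
        knots = sf.index.to_numpy(float)
        surv = sf.to_numpy(float)
        idx = np.searchsorted(knots, times, side="left") - 1  # S(t-)
        s_left = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return 1.0 - s_left
    raise ValueError(f"unknown time transform {name_or_fn!r}")


def schoenfeld_ph_test(fit: CoxFit, transform="km") -> pd.DataFrame:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Correlates unscaled Schoenfeld residuals with a centered transform of
    event time (default: the KM transform 1 - S(t-)). Returns one row per
    design column plus a GLOBAL row; for a single-covariate model the global
    row equals the term row.
    """
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for a Schoenfeld test")
    resid = fit.model.compute_residuals(fit.data, "schoenfeld")
    cols = list(fit.coefficients.index)
    resid = resid[cols]
    times_all = fit.data[fit.time_col].to_numpy(float)
    events_all = fit.data[fit.event_col].to_numpy(int)
    g_all = _time_transform(transform, times_all, events_all)
    g = pd.Series(g_all, index=fit.data.index).loc[resid.index].to_numpy(float)
    gg = g - g.mean()
    d = len(resid)
    V = fit.model.variance_matrix_.loc[cols, cols].to_numpy(float)
    S = resid.to_numpy(float)
    z = S.T @ gg
    denom = float(np.sum(gg**2))
    w = V @ z
    rows = []
    for k, c in enumerate(cols):
        stat = d * w[k] ** 2 / (V[k, k] * denom)
        rows.append({"term": c, "chisq": stat, "df": 1, "p": sps.chi2.sf(stat, 1)})
    gstat = d * float(z @ V @ z) / denom
    gdf = len(cols)
    rows.append({"term": "GLOBAL", "chisq": gstat, "df": gdf, "p": sps.chi2.sf(gstat, gdf)})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# extended Cox with time-varying coefficient
# ---------------------------------------------------------------------------

@dataclass
class TimeVaryingCoxFit:
    """beta(t) = beta0 + beta1 * f(t) for one flagged term."""

    term: str
    beta0: float
    beta1: float
    beta1_ci: tuple[float, float]
    beta1_p: float
    summary: pd.DataFrame
    time_function: str
    model: object | None = None


def _episode_split(df: pd.DataFrame, time_col: str, event_col: str) -> pd.DataFrame:
    """Split each subject's follow-up at every distinct event time.

    Produces counting-process rows (start, stop] with the event indicator on
    the final interval only -- the exact representation the time-varying
    partial likelihood needs for continuous covariate-by-time interactions.
    """
    ev_times = np.unique(df.loc[df[event_col] == 1, time_col].to_numpy(float))
    rows = []
    for i, rec in df.reset_index(drop=True).iterrows():
        t, e = float(rec[time_col]), int(rec[event_col])
        cuts = ev_times[ev_times < t]
        bounds = np.concatenate([[0.0], cuts, [t]])
        for j in range(len(bounds) - 1):
            row = rec.to_dict()
            row["_id"] = i
            row["_start"] = bounds[j]
            row["_stop"] = bounds[j + 1]
            row["_event"] = e if j == len(bounds) - 2 else 0
            rows.append(row)
    return pd.DataFrame(rows)


def extended_cox_timevarying(
    df: pd.DataFrame,
    term: str,
    time_function="log",
    time_col: str = TIME,
    event_col: str = EVENT,
    extra_terms: Sequence[str] = (),
) -> TimeVaryingCoxFit:
    """Extended Cox model with a time-dependent coefficient for ``term``.

    Episode-splits the data at event times and adds the interaction
    ``term * f(stop)`` (default f = natural log of time). When f is constant
    over events the interaction is unidentifiable and the model honestly
    degenerates to the plain Cox fit (beta1 = 0).
    """
    design, enc = _encode(df, [term, *extra_terms])
    base_cols = list(design.columns)
    work = design.copy()
    work[time_col] = df[time_col].to_numpy(float)
    work[event_col] = df[event_col].to_numpy(int)
    long = _episode_split(work, time_col, event_col)
    fname = time_function if isinstance(time_function, str) else "user"
    fvals = _time_transform(
        time_function, long["_stop"].to_numpy(float), long["_event"].to_numpy(int)
    )
    term_cols = [c for c in base_cols if c == term or c.startswith(f"{term}[")]
    tv_cols = []
    for c in term_cols:
        long[f"{c}:tv"] = long[c] * fvals
        tv_cols.append(f"{c}:tv")
    if all(long[c].nunique() <= 1 for c in tv_cols):
        plain = cox_fit(df, [term, *extra_terms], time_col=time_col, event_col=event_col)
        c0 = term_cols[0]
        return TimeVaryingCoxFit(
            term=term,
            beta0=float(plain.coefficients.loc[c0, "beta"]),
            beta1=0.0,
            beta1_ci=(float("nan"), float("nan")),
            beta1_p=float("nan"),
            summary=plain.coefficients,
            time_function=fname,
        )
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        long[["_id", "_start", "_stop", "_event", *base_cols, *tv_cols]],
        id_col="_id",
        start_col="_start",
        stop_col="_stop",
        event_col="_event",
    )
    summ = ctv.summary
    c0, ctv_col = term_cols[0], tv_cols[0]
    return TimeVaryingCoxFit(
        term=term,
        beta0=float(summ.loc[c0, "coef"]),
        beta1=float(summ.loc[ctv_col, "coef"]),
        beta1_ci=(
            float(summ.loc[ctv_col, "coef lower 95%"]),
            float(summ.loc[ctv_col, "coef upper 95%"]),
        ),
        beta1_p=float(summ.loc[ctv_col, "p"]),
        summary=summ,
        time_function=fname,
        model=ctv,
    )


# ---------------------------------------------------------------------------
# restricted mean survival time
# ---------------------------------------------------------------------------

@dataclass
class RMSTResult:
    tau: float
    groups: tuple
    rmst: dict  # group -> (estimate, se, ci_low, ci_high)
    difference: float
    diff_se: float
    diff_ci: tuple[float, float]
    p: float
    tau_clipped: bool = False


def _rmst_one(times: np.ndarray, events: np.ndarray, tau: float) -> tuple[float, float]:
    """RMST to tau and its Greenwood-style variance from the KM curve.

    Area under the step function, with variance
    sum over event times t_i <= tau of A_i^2 d_i / (n_i (n_i - d_i)),
    A_i the area under S from t_i to tau.
    """
    kmf = KaplanMeierFitter().fit(times, events)
    sf = kmf.survival_function_.iloc[:, 0]
    knots = sf.index.to_numpy(float)  # starts at 0, ascending
    surv = sf.to_numpy(float)  # S right-continuous: S = surv[j] on [t_j, t_{j+1})
    nxt = np.append(knots[1:], np.inf)
    widths = np.clip(np.minimum(nxt, tau) - np.minimum(knots, tau), 0.0, None)
    seg = surv * widths
    suffix = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    est = float(suffix[0])  # area from knot 0 (= time 0) to tau

    et = kmf.event_table.reindex(sf.index)
    d = et["observed"].to_numpy(float)
    n_at_risk = et["at_risk"].to_numpy(float)
    # area from each event time to tau; terms with n==d have zero remaining
    # area (S hits 0) and are excluded
    use = (d > 0) & (knots <= tau) & (n_at_risk > d)
    a = suffix[np.flatnonzero(use)]
    var = float(np.sum(a**2 * d[use] / (n_at_risk[use] * (n_at_risk[use] - d[use]))))
    return est, var


def rmst(
    df: pd.DataFrame,
    tau: float = 24.0,
    time_col: str = TIME,
    event_col: str = EVENT,
) -> tuple[float, float]:
    """Restricted mean survival time of one sample: (estimate, standard error)."""
    est, var = _rmst_one(df[time_col].to_numpy(float), df[event_col].to_numpy(int), tau)
    return est, float(np.sqrt(var))


def rmst_compare(
    df: pd.DataFrame,
    group_col: str,
    tau: float = 24.0,
    time_col: str = TIME,
    event_col: str = EVENT,
) -> RMSTResult:
    """Compare two groups by restricted mean survival time at horizon tau.

    If either group's follow-up ends before tau, tau is clipped to the
    shorter maximum follow-up (with a warning) so both areas are estimable.
    """
    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("rmst_compare needs exactly 2 groups")
    max_fu = min(df.loc[df[group_col] == g, time_col].max() for g in groups)
    clipped = False
    if tau > max_fu:
        warnings.warn(
            f"tau={tau} exceeds the shortest maximum follow-up ({max_fu:.3g}); clipping",
            RuntimeWarning,
            stacklevel=2,
        )
        tau, clipped = float(max_fu), True
    z975 = sps.norm.ppf(0.975)
    per = {}
    for g in groups:
        sub = df[df[group_col] == g]
        est, var = _rmst_one(sub[time_col].to_numpy(float), sub[event_col].to_numpy(int), tau)
        se = float(np.sqrt(var))
        per[g] = (est, se, est - z975 * se, est + z975 * se)
    diff = per[groups[1]][0] - per[groups[0]][0]
    se = float(np.hypot(per[groups[0]][1], per[groups[1]][1]))
    zstat = diff / se if se > 0 else np.inf * np.sign(diff)
    p = float(2.0 * sps.norm.sf(abs(zstat)))
    return RMSTResult(
        tau=tau,
        groups=tuple(groups),
        rmst=per,
        difference=float(diff),
        diff_se=se,
        diff_ci=(diff - z975 * se, diff + z975 * se),
        p=p,
        tau_clipped=clipped,
    )


# ---------------------------------------------------------------------------
# combined clinical + DL score
# ---------------------------------------------------------------------------

@dataclass
class CombinedScore:
    scores: pd.DataFrame  # patient_id (if available), lp, risk_group
    threshold: float
    threshold_policy: str


def combined_score(
    fit: CoxFit,
    df: pd.DataFrame,
    threshold: float | None = None,
    threshold_policy: str = "cohort-median",
) -> CombinedScore:
    """Linear predictor of the combined model, thresholded into risk groups.

    The training threshold is the median linear predictor; the
    "cohort-median" policy recomputes the median within whatever cohort is
    scored (the validation-cohort adaptation). Patients with missing
    covariates are excluded with a log entry. ``risk_group`` is
    "high_score" iff lp > threshold (higher lp = higher hazard).
    """
    design, _ = _encode(df, fit.terms, fit.encoding)
    keep = ~design.isna().any(axis=1)
    if (~keep).any():
        log.info("combined_score: excluding %d patients with missing covariates",
                 int((~keep).sum()))
    design = design.loc[keep, fit.coefficients.index]
    lp = design @ fit.beta
    if threshold is None:
        if threshold_policy != "cohort-median":
            raise ValueError(f"unknown threshold policy {threshold_policy!r}")
        threshold = float(lp.median())
    out = pd.DataFrame(index=design.index)
    if "patient_id" in df.columns:
        out["patient_id"] = df.loc[keep, "patient_id"]
    out["lp"] = lp
    out["risk_group"] = np.where(lp > threshold, "high_score", "low_score")
    return CombinedScore(scores=out, threshold=float(threshold),
                         threshold_policy=threshold_policy)


def concordance_index(
    df: pd.DataFrame,
    risk_scores,
    time_col: str = TIME,
    event_col: str = EVENT,
) -> float:
    """Harrell's C for a risk score (higher score = higher hazard).

    Provided as a labelled substitute for discrimination metrics whose
    exact definition (time horizon, direction) is not pinned down; 0.5 is
    chance, 1.0 perfect ranking of event order by risk.
    """
    from lifelines.utils import concordance_index as _ci

    return float(
        _ci(df[time_col], -np.asarray(risk_scores, float), df[event_col])
    )


def likelihood_ratio_test(nested: CoxFit, full: CoxFit) -> tuple[float, int, float]:
    """2 * (llf_full - llf_nested) ~ chi-squared on the added parameters."""
    if not set(nested.terms) <= set(full.terms):
        raise ValueError("models are not nested")
    if nested.n != full.n or nested.n_events != full.n_events:
        raise ValueError("nested and full models must be fit on the same records")
    df_added = len(full.coefficients) - len(nested.coefficients)
    if df_added < 0:
        raise ValueError("full model has fewer parameters than the nested one")
    stat = 2.0 * (full.log_likelihood - nested.log_likelihood)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df_added)) if df_added > 0 else 1.0
    return float(stat), int(df_added), p


# ---------------------------------------------------------------------------
# multiple testing and cohort comparison
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_cohorts(
    clinical: pd.DataFrame,
    group_col: str,
    variables: Sequence[str] | None = None,
    continuous: Sequence[str] = (),
    missing_labels: Sequence[str] = ("Unknown",),
    seed: int = 0,
    fisher_resamples: int = 20000,
) -> pd.DataFrame:
    """Per-variable two-group comparison table with a BH-adjusted column.

    Categorical variables: Pearson chi-squared without continuity correction
    when all expected counts are >= 5, otherwise Fisher's exact test (exact
    for 2x2; seeded Monte-Carlo for larger tables). Continuous variables:
    Wilcoxon rank-sum. Rows with missing / "Unknown" values are excluded
    from the test but counted in the output.
    """
    glevels = sorted(clinical[group_col].dropna().unique())
    if len(glevels) != 2:
        raise ValueError("grouping must have exactly 2 levels")
    if variables is None:
        variables = [c for c in clinical.columns if c not in (group_col, "patient_id")]
    rows = []
    for var in variables:
        sub = clinical[[var, group_col]].copy()
        miss = sub[var].isna() | sub[var].astype(str).isin(missing_labels)
        n_missing = int(miss.sum())
        sub = sub[~miss]
        if sub[var].nunique() < 2:
            raise ValueError(f"variable {var!r} has a single level after missing removal")
        if var in continuous or (
            pd.api.types.is_numeric_dtype(sub[var]) and var not in continuous
            and sub[var].nunique() > 5
        ):
            x = sub.loc[sub[group_col] == glevels[0], var].to_numpy(float)
            y = sub.loc[sub[group_col] == glevels[1], var].to_numpy(float)
            stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
            test = "Wilcoxon rank-sum"
        else:
            tab = pd.crosstab(sub[var], sub[group_col]).to_numpy()
            expected = sps.contingency.expected_freq(tab)
            if np.all(expected >= 5):
                res = sps.chi2_contingency(tab, correction=False)
                stat, p, test = float(res.statistic), float(res.pvalue), "Pearson chi-squared"
            elif tab.shape == (2, 2):
                stat, p = sps.fisher_exact(tab)
                test = "Fisher exact"
            else:
                method = sps.MonteCarloMethod(
                    n_resamples=fisher_resamples, rng=np.random.default_rng(seed)
                )
                res = sps.fisher_exact(tab, method=method)
                stat, p = float("nan"), float(res.pvalue)
                test = "Fisher exact (Monte-Carlo)"
        rows.append(
            {"variable": var, "test": test, "statistic": float(stat), "p": float(p),
             "n_used": int(len(sub)), "n_missing": n_missing}
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    out["p_display"] = out["p"].map(format_pvalue)
    out["p_adjusted_display"] = out["p_adjusted"].map(format_pvalue)
    return out.set_index("variable")


def format_pvalue(p: float) -> str:
    """Table-style p-value rounding: <0.001 floor, 3 decimals below 0.2,
    1 decimal at or above 0.2. Raw values are always kept alongside."""
    if not np.isfinite(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    if p < 0.2:
        return f"{round(p, 3):g}"
    return f"{round(p, 1):g}"


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def km_plot(df: pd.DataFrame, group_col: str, path,
            time_col: str = TIME, event_col: str = EVENT) -> None:
    """Write a Kaplan-Meier figure, one curve per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    res = km_fit(df, group_col, time_col, event_col)
    for g, f in res.fitters.items():
        f.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
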