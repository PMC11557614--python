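"""Prognostic analysis plan: nonparametric screens, Cox models with a
step-function time split, Kaplan-Meier curves, and model comparison.

The centrepiece is a Cox proportional-hazards fit (Efron or Breslow ties,
counting-process input supported) wrapped with Harrell's C-index, AIC and
a scaled-Schoenfeld proportionality check.  Postoperative performance
status loses prognostic value over time, so the plan splits follow-up at a
fixed day (default 300) and estimates separate early/late hazard ratios
for it; :func:`build_episodes` produces the counting-process table for
that model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "AnalysisConfig",
    "AnalysisError",
    "CoxModelResult",
    "KMCurve",
    "normality_screen",
    "group_compare",
    "spearman",
    "build_episodes",
    "cox_fit",
    "concordance_index",
    "proportionality_check",
    "km_curves",
    "analysis_report",
]

DAYS_PER_MONTH = 30.4375


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the analysis plan (defaults mirror the published plan)."""

    split_day: float = 300.0
    ties: str = "efron"
    significance: float = 0.05
    bh_correction: bool = False  # off by default: p-values reported unadjusted
    time_transform: str = "rank"  # for the proportionality check


# ---------------------------------------------------------------------------
# screens


def normality_screen(values: Sequence[float]) -> dict:
    """Shapiro-Wilk screen; ``normal`` is True iff p >= 0.05."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise AnalysisError("normality_screen: need at least 3 observations")
    if np.ptp(x) == 0:
        raise AnalysisError("normality_screen: zero variance")
    stat, p = stats.shapiro(x)
    return {"statistic": float(stat), "p": float(p), "normal": bool(p >= 0.05)}


def group_compare(values: Sequence[float], groups: Sequence) -> dict:
    """Mann-Whitney U for two groups, Kruskal-Wallis for three or more."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise AnalysisError("group_compare: need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    medians = {str(g): float(np.median(s)) for g, s in zip(levels, samples)}
    if len(levels) == 2:
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        test = "mann_whitney"
    else:
        stat, p = stats.kruskal(*samples)
        test = "kruskal_wallis"
    return {
        "test": test,
        "statistic": float(stat),
        "p": float(p),
        "group_medians": medians,
    }


def spearman(x: Sequence[float], y: Sequence[float]) -> dict:
    """Spearman rank correlation with two-sided p (ties handled by ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise AnalysisError("spearman: need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("spearman: constant vector")
    rs, p = stats.spearmanr(x, y)
    return {"rs": float(rs), "p": float(p), "n": int(len(x))}


# ---------------------------------------------------------------------------
# episode splitting (step-function covariate)


def build_episodes(cohort: pd.DataFrame, split_day: float = 300.0) -> pd.DataFrame:
    """Counting-process table with KPS split at ``split_day``.

    Cases exiting at or before the split contribute one episode; later
    exits contribute ``[0, split)`` and ``[split, exit]``.  Intervals are
    half-open ``(start, stop]`` so an event exactly at the split belongs
    to the first interval.  ``kps_early`` carries the KPS value in the
    first interval and 0 afterwards; ``kps_late`` vice versa.
    """
    required = {"survival_days", "event", "kps_post"}
    missing = required - set(cohort.columns)
    if missing:
        raise AnalysisError(f"build_episodes: missing columns {sorted(missing)}")
    if (cohort["survival_days"] < 0).any():
        raise AnalysisError("build_episodes: negative survival_days")
    passthrough = [
        c for c in cohort.columns if c not in ("survival_days", "event")
    ]
    rows = []
    for rec in cohort.itertuples(index=False):
        d = rec._asdict()
        t = float(d["survival_days"])
        ev = bool(d["event"])
        kps = float(d["kps_post"])
        base = {c: d[c] for c in passthrough}
        if t <= split_day:
            rows.append(
                {**base, "start": 0.0, "stop": t, "event": ev,
                 "kps_early": kps, "kps_late": 0.0}
            )
        else:
            rows.append(
                {**base, "start": 0.0, "stop": split_day, "event": False,
                 "kps_early": kps, "kps_late": 0.0}
            )
            rows.append(
                {**base, "start": split_day, "stop": t, "event": ev,
                 "kps_early": 0.0, "kps_late": kps}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design matrix helpers


_DERIVED = {
    "mgmt_methylated": lambda df: (df["mgmt"] == "methylated").astype(float),
    "sex_male": lambda df: (df["sex"] == "male").astype(float),
    "eor_fraction": lambda df: df["eor_percent"].astype(float) / 100.0,
}


def design_matrix(df: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Numeric design columns; categorical encodings resolved by name."""
    cols = {}
    for name in predictors:
        if name in df.columns and pd.api.types.is_numeric_dtype(df[name]):
            cols[name] = df[name].astype(float)
        elif name in _DERIVED:
            needed = {"mgmt_methylated": "mgmt", "sex_male": "sex",
                      "eor_fraction": "eor_percent"}[name]
            if needed not in df.columns:
                raise AnalysisError(
                    f"design_matrix: column {needed!r} required for {name!r}"
                )
            cols[name] = _DERIVED[name](df)
        else:
            raise AnalysisError(f"design_matrix: unknown predictor {name!r}")
    return pd.DataFrame(cols, index=df.index)


# ---------------------------------------------------------------------------
# Cox model


@dataclass
class CoxModelResult:
    """Per-predictor hazard ratios plus model-level comparison metrics."""

    table: pd.DataFrame  # index predictor; hr, ci95_low, ci95_high, p, coef, se
    c_index: float
    aic: float
    n_used: int
    n_events: int
    log_likelihood: float
    ties: str
    params: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    _design: pd.DataFrame = field(repr=False, default=None)
    _start: np.ndarray = field(repr=False, default=None)
    _stop: np.ndarray = field(repr=False, default=None)
    _event: np.ndarray = field(repr=False, default=None)

    def linear_predictor(self) -> np.ndarray:
        x = self._design.to_numpy()
        return (x - x.mean(axis=0)) @ self.params


def _extract_survival_arrays(data: pd.DataFrame):
    if {"start", "stop"}.issubset(data.columns):
        start = data["start"].to_numpy(dtype=float)
        stop = data["stop"].to_numpy(dtype=float)
    elif {"survival_days"}.issubset(data.columns):
        start = np.zeros(len(data))
        stop = data["survival_days"].to_numpy(dtype=float)
    else:
        raise AnalysisError(
            "cox_fit: need either start/stop or survival_days columns"
        )
    if "event" not in data.columns:
        raise AnalysisError("cox_fit: missing 'event' column")
    event = data["event"].to_numpy(dtype=bool)
    if (stop <= start).any():
        raise AnalysisError("cox_fit: episodes must satisfy start < stop")
    return start, stop, event


def concordance_index(
    stop: np.ndarray,
    lp: np.ndarray,
    event: np.ndarray,
    start: Optional[np.ndarray] = None,
) -> float:
    """Harrell's C for (possibly counting-process) survival data.

    A pair is comparable when one record has an event at time t and the
    other is at risk at t (start < t <= stop) without an event at t;
    concordant when the failing record has the higher linear predictor.
    """
    stop = np.asarray(stop, dtype=float)
    lp = np.asarray(lp, dtype=float)
    event = np.asarray(event, dtype=bool)
    start = np.zeros_like(stop) if start is None else np.asarray(start, float)
    conc = 0.0
    ties = 0.0
    total = 0
    for i in np.flatnonzero(event):
        t = stop[i]
        at_risk = (start < t) & (stop >= t)
        at_risk[i] = False
        # records that also fail exactly at t are incomparable
        at_risk &= ~(event & (stop == t))
        m = int(at_risk.sum())
        if m == 0:
            continue
        total += m
        diff = lp[i] - lp[at_risk]
        conc += float((diff > 0).sum())
        ties += float((diff == 0).sum())
    if total == 0:
        return float("nan")
    return (conc + 0.5 * ties) / total


def cox_fit(
    data: pd.DataFrame,
    predictors: Sequence[str],
    ties: str = "efron",
) -> CoxModelResult:
    """Cox proportional-hazards fit on a cohort or episode table.

    Uses the partial likelihood with Efron (default) or Breslow tie
    handling, Wald 95% intervals, complete-case deletion, and attaches
    Harrell's C-index and AIC (-2 logPL + 2k).
    """
    if ties not in ("efron", "breslow"):
        raise AnalysisError(f"cox_fit: unknown ties {ties!r}")
    X = design_matrix(data, predictors)
    start, stop, event = _extract_survival_arrays(data)
    keep = X.notna().all(axis=1).to_numpy() & np.isfinite(stop)
    X = X.loc[keep]
    start, stop, event = start[keep], stop[keep], event[keep]
    n_events = int(event.sum())
    if n_events < 2:
        raise AnalysisError("cox_fit: need at least 2 events")
    for name in X.columns:
        if X[name].nunique() < 2:
            raise AnalysisError(f"cox_fit: constant predictor {name!r}")

    xc = X.to_numpy() - X.to_numpy().mean(axis=0)
    model = sm.PHReg(
        stop, xc, status=event.astype(int), entry=start, ties=ties
    )
    try:
        res = model.fit(disp=False)
    except Exception as exc:  # pragma: no cover - numeric failure path
        raise AnalysisError(f"cox_fit: fit failed for {list(X.columns)}: {exc}")
    params = np.asarray(res.params)
    if not np.isfinite(params).all() or np.abs(params).max() > 50:
        bad = X.columns[int(np.argmax(np.abs(params)))]
        raise AnalysisError(f"cox_fit: non-convergence or separation on {bad!r}")
    se = np.asarray(res.bse)
    z = params / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "hr": np.exp(params),
            "ci95_low": np.exp(params - 1.959963984540054 * se),
            "ci95_high": np.exp(params + 1.959963984540054 * se),
            "p": p,
            "coef": params,
            "se": se,
        },
        index=list(X.columns),
    )
    if "case_id" in data.columns:
        n_used = int(data.loc[keep, "case_id"].nunique())
    else:
        n_used = int(keep.sum())
    lp = xc @ params
    c = concordance_index(stop, lp, event, start=start)
    k = len(params)
    aic = -2.0 * float(res.llf) + 2.0 * k
    return CoxModelResult(
        table=table,
        c_index=float(c),
        aic=float(aic),
        n_used=n_used,
        n_events=n_events,
        log_likelihood=float(res.llf),
        ties=ties,
        params=params,
        cov=np.asarray(res.cov_params()),
        _design=X,
        _start=start,
        _stop=stop,
        _event=event,
    )


def proportionality_check(
    result: CoxModelResult, time_transform: str = "rank"
) -> pd.DataFrame:
    """Scaled Schoenfeld residual correlation-with-time test.

    For each event, the Schoenfeld residual is the covariate of the
    failing record minus the risk-weighted mean over the risk set; scaled
    residuals (Grambsch-Therneau scaling ``beta + d * V * r``) are
    correlated with (transformed) event time.  A predictor is flagged
    ``violated`` when the two-sided correlation p-value is below 0.05.
    """
    X = result._design.to_numpy()
    X = X - X.mean(axis=0)
    start, stop, event = result._start, result._stop, result._event
    lp = X @ result.params
    w = np.exp(lp)
    ev_idx = np.flatnonzero(event)
    order = np.argsort(stop[ev_idx], kind="stable")
    ev_idx = ev_idx[order]
    times = stop[ev_idx]
    resid = np.empty((len(ev_idx), X.shape[1]))
    for r, i in enumerate(ev_idx):
        t = stop[i]
        at_risk = (start < t) & (stop >= t)
        ww = w[at_risk]
        xbar = (ww[:, None] * X[at_risk]).sum(axis=0) / ww.sum()
        resid[r] = X[i] - xbar
    d = len(ev_idx)
    scaled = result.params[None, :] + d * resid @ result.cov.T
    if time_transform == "rank":
        tvals = stats.rankdata(times)
    elif time_transform == "identity":
        tvals = times
    else:
        raise AnalysisError(f"unknown time_transform {time_transform!r}")
    rows = []
    for j, name in enumerate(result._design.columns):
        col = scaled[:, j]
        if np.ptp(col) == 0:
            rho, p = 0.0, 1.0
        else:
            rho, p = stats.pearsonr(tvals, col)
        rows.append(
            {"predictor": name, "rho": float(rho), "p": float(p),
             "violated": bool(p < 0.05)}
        )
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass(frozen=True)
class KMCurve:
    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int
    median_days: float


def _km_one(durations, events, label) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(durations, events, label=label)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_[label].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(
        kmf.survival_function_.index, method="ffill"
    ).to_numpy()
    return KMCurve(
        label=label,
        times=times,
        survival=surv,
        at_risk=at_risk,
        n=int(len(durations)),
        n_events=int(np.asarray(events).sum()),
        median_days=float(kmf.median_survival_time_),
    )


def km_curves(
    cohort: pd.DataFrame, group_by: str, custom_groups: Optional[Sequence] = None
) -> tuple[list[KMCurve], float]:
    """Per-stratum product-limit curves plus a two-sided log-rank p.

    ``group_by`` is one of ``median_split_csa``, ``median_split_si``,
    ``eor_category``, ``all`` or ``custom`` (labels via *custom_groups*).
    Median splits use <= median vs > median.
    """
    t = cohort["survival_days"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy(dtype=bool)
    if group_by == "median_split_csa":
        med = np.median(cohort["csa_cm2"])
        labels = np.where(cohort["csa_cm2"] <= med, "CSA<=median", "CSA>median")
    elif group_by == "median_split_si":
        med = np.median(cohort["si"])
        labels = np.where(cohort["si"] <= med, "SI<=median", "SI>median")
    elif group_by == "eor_category":
        labels = np.where(cohort["eor_percent"] >= 100.0, "GTR", "STR")
    elif group_by == "all":
        labels = np.repeat("all", len(cohort))
    elif group_by == "custom":
        if custom_groups is None:
            raise AnalysisError("km_curves: custom grouping needs custom_groups")
        labels = np.asarray(custom_groups).astype(str)
    else:
        raise AnalysisError(f"km_curves: unknown group_by {group_by!r}")
    curves = []
    for g in pd.unique(labels):
        sel = labels == g
        if sel.sum() == 0 or e[sel].sum() == 0:
            raise AnalysisError(f"km_curves: stratum {g!r} has no events")
        curves.append(_km_one(t[sel], e[sel], str(g)))
    if len(pd.unique(labels)) > 1:
        lr = multivariate_logrank_test(t, labels, e)
        p = float(lr.p_value)
    else:
        p = float("nan")
    return curves, p


# ---------------------------------------------------------------------------
# full report


MEASURE_COLUMNS = ["tsa_cm2", "csa_cm2", "volume_ml", "av_per_cm", "si"]

MULTIVARIABLE_SETS = {
    "csa_model": ["csa_cm2", "volume_ml", "mgmt_methylated", "age",
                  "kps_early", "kps_late", "eor_fraction"],
    "si_model": ["si", "volume_ml", "mgmt_methylated", "age",
                 "kps_early", "kps_late", "eor_fraction"],
}


def analysis_report(
    cohort: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> dict:
    """Run the full plan on a cohort table.

    Returns a dict with keys ``descriptive``, ``spearman``,
    ``group_tests``, ``univariable_cox``, ``multivariable`` (two fixed
    models: CSA-based and SI-based, each with volume, MGMT, age, split
    KPS and EOR), ``km`` and ``config``.  Row order of the input does not
    affect any number.
    """
    required = set(MEASURE_COLUMNS) | {
        "age", "sex", "mgmt", "kps_post", "eor_percent", "survival_days", "event",
    }
    missing = sorted(required - set(cohort.columns))
    if missing:
        raise AnalysisError(f"analysis_report: missing columns {missing}")
    cohort = cohort.sort_values(
        list(cohort.columns), kind="stable"
    ).reset_index(drop=True)

    descriptive = {}
    for col in MEASURE_COLUMNS + ["eor_percent"]:
        v = cohort[col].dropna()
        descriptive[col] = {
            "median": float(v.median()),
            "q1": float(v.quantile(0.25)),
            "q3": float(v.quantile(0.75)),
        }
    months = cohort["survival_days"] / DAYS_PER_MONTH
    descriptive["survival_months"] = {
        "median": float(months.median()),
        "q1": float(months.quantile(0.25)),
        "q3": float(months.quantile(0.75)),
    }

    spearman_rows = []
    for measure in MEASURE_COLUMNS:
        for other in ("age", "eor_percent", "kps_post"):
            r = spearman(cohort[measure], cohort[other])
            spearman_rows.append({"measure": measure, "versus": other, **r})
    spearman_table = pd.DataFrame(spearman_rows)

    group_rows = []
    for measure in MEASURE_COLUMNS:
        for split in ("sex", "mgmt"):
            g = group_compare(cohort[measure], cohort[split])
            group_rows.append({"measure": measure, "by": split, **g})
    group_table = pd.DataFrame(group_rows)

    uni_rows = []
    for measure in MEASURE_COLUMNS:
        fit = cox_fit(cohort, [measure], ties=config.ties)
        row = fit.table.iloc[0]
        uni_rows.append(
            {"predictor": measure, "hr": row["hr"], "ci95_low": row["ci95_low"],
             "ci95_high": row["ci95_high"], "p": row["p"], "n_used": fit.n_used}
        )
    uni_table = pd.DataFrame(uni_rows).set_index("predictor")

    episodes = build_episodes(cohort, split_day=config.split_day)
    multivariable = {}
    for name, predictors in MULTIVARIABLE_SETS.items():
        multivariable[name] = cox_fit(episodes, predictors, ties=config.ties)

    km = {}
    for group_by in ("median_split_csa", "median_split_si", "eor_category"):
        try:
            curves, p = km_curves(cohort, group_by)
            km[group_by] = {"curves": curves, "logrank_p": p}
        except AnalysisError:
            km[group_by] = None

    return {
        "descriptive": descriptive,
        "spearman": spearman_table,
        "group_tests": group_table,
        "univariable_cox": uni_table,
        "multivariable": multivariable,
        "km": km,
        "config": dataclasses.asdict(config),
        "n": int(len(cohort)),
        "n_events": int(cohort["event"].sum()),
    }
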