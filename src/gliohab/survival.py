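"""Progression-free-survival analysis of habitat features.

Within each IDH genotype, patients are split at the median of a habitat
feature (median goes to the low subgroup); subgroups are compared with
Kaplan-Meier curves and the log-rank test, and the subgroup effect is
quantified as a Cox proportional-hazards hazard ratio with a Wald CI on
the log scale (Efron handling for tied event times, since monthly PFS
resolution guarantees ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

log = logging.getLogger(__name__)


def median_split(values) -> tuple[np.ndarray, float]:
    """Split at the sample median: value <= median -> 'low', else 'high'.

    Returns (labels, threshold).  Requires >= 4 non-missing values and a
    non-degenerate spread.
    """
    x = np.asarray(values, dtype=float)
    if np.isfinite(x).sum() < 4:
        raise ValueError("median split needs at least 4 non-missing values")
    thr = float(np.nanmedian(x))
    if np.nanmin(x) == np.nanmax(x):
        raise ValueError("all values identical; no median split possible")
    labels = np.where(x > thr, "high", "low")
    return labels, thr


@dataclass
class KmCurve:
    group: str
    n: int
    events: int
    median: float  # NaN if the curve never reaches 0.5
    table: pd.DataFrame  # columns: time, survival


@dataclass
class SurvivalResult:
    curves: dict[str, KmCurve]
    logrank_statistic: float | None
    logrank_p: float | None


def kaplan_meier(time, event, group=None) -> SurvivalResult:
    """Product-limit survival estimates, optionally per subgroup with a
    two-group log-rank test.

    The median is the earliest time at which the KM estimate drops to
    0.5 or below (NaN if it never does).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("at least one event is required")
    groups = np.asarray(group) if group is not None else np.repeat("all", time.size)
    names = list(pd.unique(groups))
    curves = {}
    for name in names:
        sel = groups == name
        if sel.sum() == 0:
            raise ValueError(f"subgroup {name!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        surv = kmf.survival_function_.iloc[:, 0]
        med = surv.index[surv <= 0.5]
        curves[str(name)] = KmCurve(
            group=str(name),
            n=int(sel.sum()),
            events=int(event[sel].sum()),
            median=float(med[0]) if len(med) else float("nan"),
            table=pd.DataFrame({"time": surv.index.to_numpy(), "survival": surv.to_numpy()}),
        )
    stat = p = None
    if len(names) == 2:
        a, b = (groups == names[0]), (groups == names[1])
        res = logrank_test(time[a], time[b], event_observed_A=event[a], event_observed_B=event[b])
        stat, p = float(res.test_statistic), float(res.p_value)
    return SurvivalResult(curves=curves, logrank_statistic=stat, logrank_p=p)


@dataclass
class CoxResult:
    hr: float
    ci: tuple[float, float]
    p: float
    coef: float
    se: float
    penalized: bool = False  # monotone-likelihood fallback used


def cox_fit(time, event, indicator, ties: str = "efron") -> CoxResult:
    """Two-group Cox proportional-hazards fit (HR for indicator = 1).

    Monotone partial likelihood (all events effectively separating the
    groups, diverging coefficient) falls back to a ridge-penalized fit
    and is flagged.
    """
    df = pd.DataFrame(
        {
            "time": np.asarray(time, dtype=float),
            "event": np.asarray(event, dtype=int),
            "x": np.asarray(indicator, dtype=float),
        }
    )
    if df.loc[df["x"] == 1, "event"].sum() < 1 or df.loc[df["x"] == 0, "event"].sum() < 1:
        raise ValueError("each subgroup needs at least one event for a finite estimate")

    def _fit(penalizer):
        cph = CoxPHFitter(penalizer=penalizer)
        cph.fit(df, duration_col="time", event_col="event")
        return cph

    penalized = False
    try:
        cph = _fit(0.0)
        if abs(float(cph.params_.iloc[0])) > 15:
            raise RuntimeError("diverging coefficient")
    except Exception:
        log.warning("cox_fit: monotone likelihood suspected; penalized fallback")
        penalized = True
        cph = _fit(0.1)
    coef = float(cph.params_.iloc[0])
    se = float(cph.standard_errors_.iloc[0])
    z = 1.959963984540054
    return CoxResult(
        hr=float(np.exp(coef)),
        ci=(float(np.exp(coef - z * se)), float(np.exp(coef + z * se))),
        p=float(cph.summary["p"].iloc[0]),
        coef=coef,
        se=se,
        penalized=penalized,
    )


def habitat_survival_analysis(
    table: pd.DataFrame,
    feature_cols: list[str],
    time_col: str = "pfs_months",
    event_col: str = "progression",
    genotype_col: str = "genotype",
) -> pd.DataFrame:
    """Median-split KM/log-rank/Cox screen of habitat features per genotype.

    One row per (genotype, feature): subgroup sizes, event counts, median
    PFS per subgroup, log-rank p, and the high-vs-low hazard ratio.
    Features that cannot be split or fitted are reported with NaNs.
    """
    rows = []
    for genotype, sub in table.groupby(genotype_col):
        for col in feature_cols:
            row: dict = {"genotype": genotype, "feature": col}
            try:
                labels, thr = median_split(sub[col].to_numpy())
                res = kaplan_meier(sub[time_col], sub[event_col], labels)
                cox = cox_fit(sub[time_col], sub[event_col], (labels == "high").astype(int))
                row.update(
                    threshold=thr,
                    n_low=res.curves["low"].n, n_high=res.curves["high"].n,
                    events_low=res.curves["low"].events, events_high=res.curves["high"].events,
                    median_low=res.curves["low"].median, median_high=res.curves["high"].median,
                    logrank_p=res.logrank_p,
                    hr=cox.hr, hr_ci_low=cox.ci[0], hr_ci_high=cox.ci[1], hr_p=cox.p,
                    penalized=cox.penalized,
                )
            except ValueError as exc:
                log.info("survival screen skipped %s/%s: %s", genotype, col, exc)
                row.update(threshold=np.nan, hr=np.nan, logrank_p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
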