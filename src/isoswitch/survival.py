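"""Quartile-stratified survival analysis: KM curves, log-rank, hazard ratio.

Patients are split on an expression covariate into top-quartile (High) and
bottom-quartile (Low) groups — floor(n/4) each, the middle half excluded —
then compared by the Kaplan-Meier product-limit estimator, the two-group
log-rank test, and a hazard ratio with 95% CI.  The default HR comes from a
proportional-hazards fit with a single binary covariate (Efron tie handling,
Wald CI); a Mantel-Haenszel O/E ratio is available as a cross-check.

Estimation is delegated to lifelines (KaplanMeierFitter, logrank_test,
CoxPHFitter); this module owns the stratification and reporting contracts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io_formats import SurvivalTable, ValidationError


@dataclass
class StratifiedCohort:
    """Top/bottom expression quartiles of a cohort; middle half excluded."""

    high_ids: list[str]
    low_ids: list[str]
    high_cut: float          # smallest expression in High
    low_cut: float           # largest expression in Low
    excluded_ids: list[str]


@dataclass
class KMCurve:
    """Product-limit survival step function for one group."""

    times: np.ndarray              # distinct observed times
    survival: np.ndarray           # S(t) at those times
    at_risk: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalFit:
    hazard_ratio: float            # High vs Low; NaN if non-estimable
    ci_low: float
    ci_high: float
    logrank_chi2: float
    logrank_p: float
    method: str
    non_estimable: bool = False


def stratify_quartiles(
    table: SurvivalTable,
    fraction: float = 0.25,
) -> StratifiedCohort:
    """Select top and bottom expression fractions, floor(n * fraction) each.

    Sorting is stable with ties broken by sample id, so the split is
    deterministic; fully tied expression triggers a warning but still splits.
    """
    if not 0 < fraction <= 0.5:
        raise ValidationError("fraction must be in (0, 0.5]")
    t = table.table
    if len(t) < 8:
        raise ValidationError("need >= 8 samples to stratify")
    k = int(np.floor(len(t) * fraction))
    order = t.sort_values(["expression", "sample_id"], kind="stable")
    if order["expression"].nunique() == 1:
        warnings.warn("all expression values tied; split is id-ordered")
    low = order.head(k)
    high = order.tail(k)
    middle = order.iloc[k: len(t) - k]
    return StratifiedCohort(
        high_ids=list(high["sample_id"]),
        low_ids=list(low["sample_id"]),
        high_cut=float(high["expression"].min()),
        low_cut=float(low["expression"].max()),
        excluded_ids=list(middle["sample_id"]),
    )


def _subset(table: SurvivalTable, ids: list[str]) -> pd.DataFrame:
    t = table.table.set_index("sample_id")
    return t.loc[ids].reset_index()


def km_estimate(records: pd.DataFrame) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    ``records`` needs ``time`` and ``event`` columns.  Individuals censored at
    an event time remain at risk through that time (standard convention).
    """
    if len(records) == 0:
        raise ValidationError("empty group")
    if (records["time"] < 0).any():
        raise ValidationError("negative time")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(float)
    # drop the t=0 anchor row lifelines prepends unless 0 is observed
    observed = np.sort(records["time"].unique())
    mask = np.isin(times, observed)
    ev = kmf.event_table
    return KMCurve(
        times=times[mask],
        survival=sf.to_numpy(float)[mask],
        at_risk=ev["at_risk"].to_numpy(float)[np.isin(ev.index.to_numpy(float),
                                                      times[mask])],
        censor_times=np.sort(
            records.loc[records["event"] == 0, "time"].to_numpy(float)
        ),
    )


def logrank(high: pd.DataFrame, low: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p)."""
    if len(high) == 0 or len(low) == 0:
        raise ValidationError("both groups must be non-empty")
    if high["event"].sum() + low["event"].sum() == 0:
        warnings.warn("no events in either group; log-rank is vacuous")
        return 0.0, 1.0
    res = _ll_logrank(high["time"], low["time"],
                      event_observed_A=high["event"],
                      event_observed_B=low["event"])
    return float(res.test_statistic), float(res.p_value)


def _oe_hazard_ratio(high: pd.DataFrame, low: pd.DataFrame):
    """Mantel-Haenszel (O/E) hazard-ratio estimate with log-scale Wald CI."""
    df = pd.concat([
        high.assign(group=1), low.assign(group=0)
    ], ignore_index=True)
    event_times = np.sort(df.loc[df["event"] == 1, "time"].unique())
    o1 = e1 = o0 = e0 = 0.0
    for t in event_times:
        at_risk = df["time"] >= t
        n = at_risk.sum()
        n1 = (at_risk & (df["group"] == 1)).sum()
        d = ((df["time"] == t) & (df["event"] == 1)).sum()
        d1 = ((df["time"] == t) & (df["event"] == 1) & (df["group"] == 1)).sum()
        o1 += d1
        o0 += d - d1
        e1 += d * n1 / n
        e0 += d * (n - n1) / n
    if o1 == 0 or o0 == 0 or e1 == 0 or e0 == 0:
        return np.nan, np.nan, np.nan
    hr = (o1 / e1) / (o0 / e0)
    se = np.sqrt(1 / e1 + 1 / e0)       # log-scale Peto-style SE
    return hr, hr * np.exp(-1.96 * se), hr * np.exp(1.96 * se)


def hazard_ratio(
    high: pd.DataFrame,
    low: pd.DataFrame,
    method: Literal["cox", "oe"] = "cox",
) -> SurvivalFit:
    """Hazard ratio (High vs Low) with 95% CI plus the log-rank test.

    ``cox``: proportional-hazards fit on a binary group covariate with Efron
    tie handling and a Wald CI.  ``oe``: Mantel-Haenszel observed/expected
    ratio.  With zero events in a group the HR is non-estimable and reported
    as such.
    """
    chi2, p = logrank(high, low)
    if high["event"].sum() == 0 or low["event"].sum() == 0:
        return SurvivalFit(np.nan, np.nan, np.nan, chi2, p, method,
                           non_estimable=True)
    if method == "cox":
        df = pd.concat([high.assign(group=1), low.assign(group=0)],
                       ignore_index=True)[["time", "event", "group"]]
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["group"]))
        lo_, hi_ = np.exp(cph.confidence_intervals_.loc["group"])
        return SurvivalFit(hr, float(lo_), float(hi_), chi2, p, "cox")
    if method == "oe":
        hr, lo_, hi_ = _oe_hazard_ratio(high, low)
        return SurvivalFit(float(hr), float(lo_), float(hi_), chi2, p, "oe",
                           non_estimable=not np.isfinite(hr))
    raise ValidationError(f"unknown method {method!r}")


def analyze_cohort(
    table: SurvivalTable,
    fraction: float = 0.25,
    method: Literal["cox", "oe"] = "cox",
) -> tuple[StratifiedCohort, SurvivalFit, KMCurve, KMCurve]:
    """Quartile-stratify, then fit: the standard High-vs-Low workflow."""
    cohort = stratify_quartiles(table, fraction)
    high = _subset(table, cohort.high_ids)
    low = _subset(table, cohort.low_ids)
    fit = hazard_ratio(high, low, method=method)
    return cohort, fit, km_estimate(high), km_estimate(low)


def plot_km(high_curve: KMCurve, low_curve: KMCurve, path,
            labels=("High", "Low")) -> None:
    """Write a two-group KM step plot (SVG/PNG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve, label, color in zip((high_curve, low_curve), labels,
                                   ("crimson", "black")):
        t = np.concatenate([[0.0], curve.times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=label, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
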