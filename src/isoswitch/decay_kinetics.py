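"""mRNA decay analysis: ddCt quantification, half-life fits, CHX recovery.

Transcript abundance from RT-qPCR is quantified by the classical 2^-ddCt
method against a stable reference gene and the t = 0 calibrator, assuming
amplification efficiency 2.  Under transcription blockade (actinomycin D) a
transcript decaying with first-order kinetics satisfies

    log2 RQ(t) = -t / t_half,

so half-life is estimated by ordinary least squares of log2(RQ) on time: the
half-life is -1/slope hours and the decay rate k = ln 2 / t_half per hour.
A transcript is classified *stable* when its fitted half-life exceeds the
observation window or the slope is not significantly negative (one-sided
p >= 0.05), mirroring time courses where no decay is seen within 12 h.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CtTable, ValidationError


@dataclass
class RelativeQuantity:
    """Long-format 2^-ddCt values relative to the calibrator timepoint."""

    records: pd.DataFrame   # target_id, condition, timepoint, replicate, rq
    reference_target: str
    calibrator_timepoint: float


@dataclass
class HalfLifeEstimate:
    target_id: str
    k_per_hour: float                    # ln2 / half_life; NaN if indeterminate
    half_life_hours: float
    r_squared: float
    classification: Literal["unstable", "stable", "indeterminate"]
    slope_p_one_sided: float
    n_points: int


@dataclass
class RecoveryFold:
    """Ratio of mean RQ under actD+CHX to mean RQ under actD alone."""

    target_id: str
    timepoint: float
    fold: float
    ci_low: float
    ci_high: float
    n_bootstrap: int


def ddct_quantify(
    cts: CtTable,
    reference_target: str | None = None,
    calibrator_timepoint: float = 0.0,
) -> RelativeQuantity:
    """Compute RQ = 2^-ddCt per (target, condition, timepoint, replicate).

    dCt = Ct_target - Ct_reference within each (condition, timepoint,
    replicate); ddCt subtracts the mean dCt of the same (target, condition)
    at the calibrator timepoint, so mean RQ at the calibrator is 1 by
    construction.
    """
    ref = reference_target or cts.reference_target
    rec = cts.records
    ref_ct = rec[rec["target_id"] == ref].set_index(
        ["condition", "timepoint", "replicate"]
    )["ct"]
    targets = rec[rec["target_id"] != ref].copy()
    keys = list(zip(targets["condition"], targets["timepoint"],
                    targets["replicate"]))
    missing = [k for k in keys if k not in ref_ct.index]
    if missing:
        raise ValidationError(
            f"reference {ref!r} missing at (condition, timepoint, replicate) "
            f"{missing[0]}"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref_ct.loc[keys].to_numpy()
    out = []
    for (target, cond), sub in targets.groupby(["target_id", "condition"]):
        cal = sub[sub["timepoint"] == calibrator_timepoint]
        if cal.empty:
            raise ValidationError(
                f"no calibrator (t={calibrator_timepoint}) measurements for "
                f"{target!r} under {cond!r}"
            )
        ddct = sub["dct"] - cal["dct"].mean()
        sub = sub.assign(rq=np.exp2(-ddct))
        out.append(sub[["target_id", "condition", "timepoint", "replicate", "rq"]])
    return RelativeQuantity(
        records=pd.concat(out, ignore_index=True),
        reference_target=ref,
        calibrator_timepoint=calibrator_timepoint,
    )


def fit_half_life(
    rq: RelativeQuantity,
    target_id: str,
    *,
    condition: str | None = None,
    max_time: float | None = None,
) -> HalfLifeEstimate:
    """OLS fit of log2(RQ) on time; half-life in hours-per-halving.

    Points with nonpositive RQ are excluded with a warning; with fewer than 3
    distinct timepoints remaining the estimate is *indeterminate*.  ``max_time``
    (default: last observed timepoint) is the observation window used by the
    stability classification.
    """
    import warnings

    rec = rq.records
    sub = rec[rec["target_id"] == target_id]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    if sub.empty:
        raise ValidationError(f"no RQ records for target {target_id!r}")
    bad = sub["rq"] <= 0
    if bad.any():
        warnings.warn(f"{target_id}: excluding {int(bad.sum())} nonpositive RQ points")
        sub = sub[~bad]
    window = float(max_time if max_time is not None else
                   (sub["timepoint"].max() if len(sub) else 0.0))
    if sub["timepoint"].nunique() < 3:
        return HalfLifeEstimate(target_id, np.nan, np.nan, np.nan,
                                "indeterminate", np.nan, len(sub))
    t = sub["timepoint"].to_numpy(float)
    y = np.log2(sub["rq"].to_numpy(float))
    fit = stats.linregress(t, y)
    slope = fit.slope
    # one-sided test for decay (slope < 0); exact-fit stderr of 0 handled below
    if fit.stderr == 0:
        p_one = 0.0 if slope < 0 else 1.0
    else:
        tt = slope / fit.stderr
        p_one = float(stats.t.sf(-tt, df=len(t) - 2))
    half_life = -1.0 / slope if slope < 0 else np.inf
    k = np.log(2) / half_life if np.isfinite(half_life) else 0.0
    stable = (not np.isfinite(half_life)) or half_life > window or p_one >= 0.05
    return HalfLifeEstimate(
        target_id=target_id, k_per_hour=float(k),
        half_life_hours=float(half_life), r_squared=float(fit.rvalue ** 2),
        classification="stable" if stable else "unstable",
        slope_p_one_sided=p_one, n_points=len(t),
    )


def fit_all_half_lives(rq: RelativeQuantity, **kwargs) -> pd.DataFrame:
    """Fit every target in an RQ set; one row per target."""
    rows = []
    for target in rq.records["target_id"].unique():
        est = fit_half_life(rq, target, **kwargs)
        rows.append(vars(est))
    return pd.DataFrame(rows)


def chx_recovery(
    rq: RelativeQuantity,
    target_id: str,
    timepoint: float,
    *,
    condition_actd: str = "actD",
    condition_chx: str = "actD+CHX",
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> RecoveryFold:
    """Fold recovery = mean RQ(actD+CHX) / mean RQ(actD) at one timepoint.

    A fold well above 1 indicates decay suppressed by translation blockade,
    the signature of co-translational degradation.  CI is a seeded percentile
    bootstrap over replicates.
    """
    rec = rq.records
    sel = (rec["target_id"] == target_id) & (rec["timepoint"] == timepoint)
    a = rec.loc[sel & (rec["condition"] == condition_actd), "rq"].to_numpy()
    b = rec.loc[sel & (rec["condition"] == condition_chx), "rq"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError(
            f"need >= 2 replicates per condition at t={timepoint} for "
            f"{target_id!r} (got {len(a)}, {len(b)})"
        )
    if a.mean() <= 0:
        raise ValidationError(f"zero/negative mean RQ under {condition_actd!r}")
    fold = float(b.mean() / a.mean())
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        ra = rng.choice(a, size=len(a), replace=True)
        rb = rng.choice(b, size=len(b), replace=True)
        boots[i] = rb.mean() / ra.mean() if ra.mean() > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return RecoveryFold(target_id=target_id, timepoint=timepoint, fold=fold,
                        ci_low=float(lo), ci_high=float(hi),
                        n_bootstrap=n_bootstrap)
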