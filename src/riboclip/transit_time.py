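"""Ribosome half-transit time from paired PMS/PRS labeling time courses.

In a transit-time experiment, radiolabel incorporation is followed in the
postmitochondrial supernatant (PMS: all nascent plus released polypeptides)
and the postribosomal supernatant (PRS: released polypeptides only).  Both
series rise linearly once labeling reaches steady state, with the PRS line
lagging the PMS line by the half-transit time 1/2-tau -- the average time for
a ribosome to traverse half an mRNA's coding sequence.  The classical
estimator fits each series by ordinary least squares and reports the
difference of the time-axis intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


class EstimationError(ValueError):
    """Raised when a half-transit time cannot be estimated (e.g. flat series)."""


TIMECOURSE_COLUMNS = ["condition", "replicate", "time_min", "pms_cpm", "prs_cpm"]


@dataclass
class TimeCourse:
    """One labeling time course: times (min) with paired PMS and PRS signals."""

    condition: str
    time_min: np.ndarray
    pms: np.ndarray
    prs: np.ndarray
    replicate: str = "1"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.pms = np.asarray(self.pms, dtype=float)
        self.prs = np.asarray(self.prs, dtype=float)
        if not (len(self.time_min) == len(self.pms) == len(self.prs)):
            raise ValueError("time, PMS and PRS series must have equal length")
        if len(self.time_min) < 3:
            raise ValueError("need at least 3 time points")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.pms < 0) or np.any(self.prs < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class HalfTransitEstimate:
    """OLS fits of PMS and PRS series and the derived half-transit time (min)."""

    condition: str
    slope_pms: float
    slope_prs: float
    t0_pms: float
    t0_prs: float
    half_transit: float
    ci95: tuple[float, float]
    r2_pms: float
    r2_prs: float
    lag_at_mean_ordinate: float
    n_points: int
    bootstrap: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, r^2 by least squares."""
    res = stats.linregress(t, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def _half_from_fits(sp, ip, sr, ir) -> tuple[float, float, float, float]:
    """t0_pms, t0_prs, half-transit, and lag evaluated at the mean ordinate."""
    t0_pms = -ip / sp
    t0_prs = -ir / sr
    half = t0_prs - t0_pms
    # when slopes differ the horizontal displacement depends on the ordinate;
    # evaluate it at the midpoint of the two fitted lines' mean level
    ybar = (ip + ir) / 2 + (sp + sr) / 2 * ((t0_pms + t0_prs) / 2)
    lag = (ybar - ir) / sr - (ybar - ip) / sp
    return t0_pms, t0_prs, half, lag


def fit_half_transit(
    tc: TimeCourse,
    linear_window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> HalfTransitEstimate:
    """Estimate the half-transit time from one PMS/PRS time course.

    Both series are fit by OLS (optionally restricted to ``linear_window``,
    a closed [t_min, t_max] range excluding early lag points); 1/2-tau is the
    difference of the time-axis intercepts t0 = -intercept/slope.  The 95% CI
    comes from a seeded nonparametric bootstrap over time points.
    """
    t, pms, prs = tc.time_min, tc.pms, tc.prs
    if linear_window is not None:
        lo, hi = linear_window
        keep = (t >= lo) & (t <= hi)
        t, pms, prs = t[keep], pms[keep], prs[keep]
    if len(t) < 3:
        raise EstimationError("need at least 3 points inside the linear window")

    sp, ip, r2p = _ols(t, pms)
    sr, ir, r2r = _ols(t, prs)
    if sp <= 0 or sr <= 0:
        raise EstimationError(
            f"{tc.condition}: non-positive slope (PMS {sp:.3g}, PRS {sr:.3g}); "
            "no half-transit time reported"
        )
    t0_pms, t0_prs, half, lag = _half_from_fits(sp, ip, sr, ir)

    rng = np.random.default_rng(seed)
    n = len(t)
    boot = np.empty(0)
    ci = (half, half)
    if n_boot > 0:
        chunks: list[np.ndarray] = []
        total = 0
        attempts = 0
        while total < n_boot and attempts < 20:
            need = n_boot - total
            idx = rng.integers(0, n, size=(max(need, 16), n))
            tb, yp, yr = t[idx], pms[idx], prs[idx]
            tm = tb.mean(axis=1)
            var_t = tb.var(axis=1)
            # a resample needs >= 2 distinct times and positive slopes
            with np.errstate(invalid="ignore", divide="ignore"):
                bp = ((tb * yp).mean(axis=1) - tm * yp.mean(axis=1)) / var_t
                br = ((tb * yr).mean(axis=1) - tm * yr.mean(axis=1)) / var_t
                ap = yp.mean(axis=1) - bp * tm
                ar = yr.mean(axis=1) - br * tm
                h = (-ar / br) - (-ap / bp)
            ok = (var_t > 0) & (bp > 0) & (br > 0) & np.isfinite(h)
            chunks.append(h[ok][:need])
            total += len(chunks[-1])
            attempts += 1
        boot = np.concatenate(chunks) if chunks else np.empty(0)
        if boot.size >= 10:
            ci = (float(np.quantile(boot, 0.025)), float(np.quantile(boot, 0.975)))
    return HalfTransitEstimate(
        condition=tc.condition,
        slope_pms=sp,
        slope_prs=sr,
        t0_pms=t0_pms,
        t0_prs=t0_prs,
        half_transit=half,
        ci95=ci,
        r2_pms=r2p,
        r2_prs=r2r,
        lag_at_mean_ordinate=lag,
        n_points=int(n),
        bootstrap=boot,
    )


def average_replicates(courses: list[TimeCourse]) -> TimeCourse:
    """Point-wise mean of replicate time courses sharing a time grid.

    Transit experiments report the mean of several labeling replicates per
    condition; fitting the averaged series uses all replicates while keeping
    a single pair of regression lines.
    """
    if not courses:
        raise ValueError("no time courses")
    cond = courses[0].condition
    t = courses[0].time_min
    for tc in courses[1:]:
        if tc.condition != cond:
            raise ValueError("cannot average time courses from different conditions")
        if not np.array_equal(tc.time_min, t):
            raise ValueError("replicates must share the same time points")
    return TimeCourse(
        condition=cond,
        time_min=t,
        pms=np.mean([tc.pms for tc in courses], axis=0),
        prs=np.mean([tc.prs for tc in courses], axis=0),
        replicate="mean",
    )


def fit_conditions(
    courses: list[TimeCourse],
    linear_window: tuple[float, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, HalfTransitEstimate]:
    """Average replicates per condition and fit each averaged series."""
    by_cond: dict[str, list[TimeCourse]] = {}
    for tc in courses:
        by_cond.setdefault(tc.condition, []).append(tc)
    return {
        cond: fit_half_transit(
            average_replicates(tcs), linear_window=linear_window, n_boot=n_boot, seed=seed
        )
        for cond, tcs in sorted(by_cond.items())
    }


def compare_half_transit(estimates: dict[str, HalfTransitEstimate]) -> pd.DataFrame:
    """Pairwise half-transit differences with bootstrap p-values.

    The p-value for a pair is the two-sided bootstrap tail probability of the
    difference of (independently resampled) estimates crossing zero, with the
    usual +1 small-sample correction.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two conditions to compare")
    rows = []
    for a, b in combinations(estimates.keys(), 2):
        ea, eb = estimates[a], estimates[b]
        diff = ea.half_transit - eb.half_transit
        if ea.bootstrap.size and eb.bootstrap.size:
            m = min(ea.bootstrap.size, eb.bootstrap.size)
            d = ea.bootstrap[:m] - eb.bootstrap[:m]
            lo = (np.sum(d <= 0) + 1) / (m + 1)
            hi = (np.sum(d >= 0) + 1) / (m + 1)
            p = min(1.0, 2 * min(lo, hi))
        else:
            p = np.nan
        rows.append(
            {
                "condition_a": a,
                "condition_b": b,
                "half_transit_a": ea.half_transit,
                "half_transit_b": eb.half_transit,
                "difference": diff,
                "p_bootstrap": p,
            }
        )
    return pd.DataFrame(rows)


def read_timecourses(path: str) -> list[TimeCourse]:
    """Read a TSV (condition, replicate, time_min, pms_cpm, prs_cpm)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    out = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            TimeCourse(
                condition=str(cond),
                replicate=str(rep),
                time_min=grp.time_min.to_numpy(),
                pms=grp.pms_cpm.to_numpy(),
                prs=grp.prs_cpm.to_numpy(),
            )
        )
    return out


def estimates_to_frame(estimates: dict[str, HalfTransitEstimate]) -> pd.DataFrame:
    rows = []
    for cond, e in estimates.items():
        rows.append(
            {
                "condition": cond,
                "half_transit_min": e.half_transit,
                "ci95_low": e.ci95[0],
                "ci95_high": e.ci95[1],
                "slope_pms": e.slope_pms,
                "slope_prs": e.slope_prs,
                "t0_pms": e.t0_pms,
                "t0_prs": e.t0_prs,
                "r2_pms": e.r2_pms,
                "r2_prs": e.r2_prs,
                "lag_at_mean_ordinate": e.lag_at_mean_ordinate,
                "n_points": e.n_points,
            }
        )
    return pd.DataFrame(rows)
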