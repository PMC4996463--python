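"""Survival statistics: Kaplan-Meier, log-rank, univariate Cox, threshold scan.

The biomarker-discovery procedure splits a cohort at every admissible marker
threshold, computes the two-group log-rank p-value at each, and selects the
threshold minimizing a 3-candidate moving average of the p-profile — the
minimum of a "low p-value region" rather than an isolated fluke. The selected
split is summarized by its raw log-rank p, the univariate Cox hazard ratio
with Wald 95% CI, and the Kaplan-Meier medians of the two groups.

Kaplan-Meier medians use the midpoint convention (as in R's survfit): the
earliest time where the survival curve falls to or below 0.5; when the curve
sits exactly at 0.5, the midpoint of that time and the next drop. With no
censoring this reproduces the ordinary sample median. Days convert to months
at 30.42 days/month.

The log-rank statistic is computed in-package (vectorized observed-minus-
expected chi-square) so that threshold scans and Monte-Carlo calibrations
stay fast; it is validated against lifelines in the test suite. Cox fits use
statsmodels' proportional-hazards regression (Breslow ties by default,
Efron available).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

DAYS_PER_MONTH = 30.42


class DegenerateGroupError(ValueError):
    """A survival comparison received an empty group."""


class NoValidThresholdError(ValueError):
    """No candidate threshold satisfies the group-size floor."""


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_curve(times_days, events) -> pd.DataFrame:
    """Kaplan-Meier curve coordinates: columns time_days, survival."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times_days, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time_days": sf.index.values, "survival": sf.iloc[:, 0].values})


def km_median(times_days, events, days_per_month: float = DAYS_PER_MONTH) -> float:
    """Kaplan-Meier median survival in months (NaN if the curve stays > 0.5).

    Midpoint convention: if the curve hits exactly 0.5, the median is the
    average of that time and the next time the curve drops strictly below.
    """
    events = np.asarray(events, dtype=bool)
    if not events.any():
        warnings.warn("no events: Kaplan-Meier median undefined", stacklevel=2)
        return float("nan")
    curve = km_curve(times_days, events)
    s = curve["survival"].values
    t = curve["time_days"].values
    atol = 1e-12
    below = np.flatnonzero(s <= 0.5 + atol)
    if below.size == 0:
        return float("nan")
    first = below[0]
    median_days = t[first]
    if abs(s[first] - 0.5) <= atol:
        strictly = np.flatnonzero(s < 0.5 - atol)
        if strictly.size:
            median_days = 0.5 * (median_days + t[strictly[0]])
        else:
            return float("nan")  # curve plateaus at exactly 0.5
    return float(median_days) / days_per_month


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def logrank(times_a, events_a, times_b, events_b) -> float:
    """Two-group 1-df log-rank chi-square p-value."""
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if times_a.size == 0 or times_b.size == 0:
        raise DegenerateGroupError("both groups must be non-empty")
    times = np.concatenate([times_a, times_b])
    events = np.concatenate(
        [np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)]
    )
    group = np.concatenate([np.zeros(times_a.size, bool), np.ones(times_b.size, bool)])
    if not events.any():
        raise DegenerateGroupError("no events in either group")
    return _logrank_p(times, events, group)


def _logrank_p(times: np.ndarray, events: np.ndarray, group_b: np.ndarray) -> float:
    """Vectorized O-E/V log-rank p for a boolean group indicator."""
    order = np.argsort(times, kind="stable")
    t, e, g = times[order], events[order], group_b[order]
    n = t.size
    # distinct event times and per-time counts
    uniq, first_idx = np.unique(t, return_index=True)
    # at-risk counts just before each distinct time
    n_total = n - first_idx
    cum_b = np.concatenate([[0], np.cumsum(g)])
    n_b = g.sum() - cum_b[first_idx]
    # events at each distinct time, overall and in group b
    d_total = np.add.reduceat((e).astype(np.int64), first_idx)
    d_b = np.add.reduceat((e & g).astype(np.int64), first_idx)
    keep = d_total > 0
    n_tot, n_bb, d_tot, d_bb = n_total[keep], n_b[keep], d_total[keep], d_b[keep]
    expected = d_tot * n_bb / n_tot
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (
            d_tot * (n_bb / n_tot) * (1.0 - n_bb / n_tot)
            * (n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0)
        )
    v = var.sum()
    if v <= 0:
        return 1.0
    chi2 = (d_bb.sum() - expected.sum()) ** 2 / v
    return float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    hr: float
    ci: tuple[float, float]
    p: float
    log_hr: float
    se: float
    converged: bool = True


def cox_univariate(times, events, indicator, ties: str = "breslow") -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    ``indicator`` is typically the boolean high-marker group; the hazard
    ratio is for indicator=1 relative to indicator=0, with a Wald 95% CI.
    Monotone partial likelihood (complete separation in time) is flagged as
    a non-converged result rather than raised.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    x = np.asarray(indicator, dtype=float).reshape(-1, 1)
    if np.unique(x).size < 2:
        raise DegenerateGroupError("indicator must take both levels")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = PHReg(times, x, status=events, ties=ties).fit(disp=False)
    beta = float(fit.params[0])
    se = float(fit.bse[0])
    converged = bool(np.isfinite(beta) and np.isfinite(se) and abs(beta) < 15 and se < 1e3)
    with np.errstate(over="ignore"):  # separation: bounds may overflow to inf
        lo, hi = np.exp(beta - 1.959964 * se), np.exp(beta + 1.959964 * se)
    return CoxResult(
        hr=float(np.exp(beta)),
        ci=(float(lo), float(hi)),
        p=float(fit.pvalues[0]),
        log_hr=beta,
        se=se,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# threshold scan
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    """Outcome of one marker-threshold split of a cohort."""

    marker: str
    threshold: float
    n_low: int
    n_high: int
    logrank_p: float
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float
    median_low_months: float
    median_high_months: float
    median_difference_months: float
    converged: bool = True

    def to_dict(self) -> dict:
        d = {
            "marker": self.marker,
            "threshold": self.threshold,
            "n_low": self.n_low,
            "n_high": self.n_high,
            "logrank_p": self.logrank_p,
            "hr": self.hr,
            "hr_ci_low": self.hr_ci[0],
            "hr_ci_high": self.hr_ci[1],
            "hr_p": self.hr_p,
            "median_low_months": self.median_low_months,
            "median_high_months": self.median_high_months,
            "median_difference_months": self.median_difference_months,
            "converged": self.converged,
        }
        return d


def evaluate_split(
    times,
    events,
    marker_values,
    threshold: float,
    marker: str = "marker",
    ties: str = "breslow",
    days_per_month: float = DAYS_PER_MONTH,
) -> SplitResult:
    """Full statistics of the split marker <= threshold vs marker > threshold.

    The hazard ratio is for the high-marker group relative to the low one;
    the median difference is median(low) - median(high) in months.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    marker_values = np.asarray(marker_values, dtype=float)
    high = marker_values > threshold
    if high.all() or not high.any():
        raise DegenerateGroupError("threshold does not split the cohort")
    p = _logrank_p(times, events, high)
    cox = cox_univariate(times, events, high, ties=ties)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        med_low = km_median(times[~high], events[~high], days_per_month)
        med_high = km_median(times[high], events[high], days_per_month)
    return SplitResult(
        marker=marker,
        threshold=float(threshold),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        logrank_p=p,
        hr=cox.hr,
        hr_ci=cox.ci,
        hr_p=cox.p,
        median_low_months=med_low,
        median_high_months=med_high,
        median_difference_months=med_low - med_high,
        converged=cox.converged,
    )


def threshold_scan(
    times,
    events,
    marker_values,
    marker: str = "marker",
    min_group_fraction: float = 0.15,
    ties: str = "breslow",
    days_per_month: float = DAYS_PER_MONTH,
) -> tuple[SplitResult, pd.DataFrame]:
    """Scan all admissible thresholds of one marker; pick the best split.

    Candidates are midpoints between consecutive sorted unique marker values;
    a candidate is admissible when both groups hold at least
    max(3, ceil(min_group_fraction * n)) patients. The winner minimizes a
    3-candidate centered moving average of the log-rank p-profile (isolated
    single-threshold minima are flukes, not "low p-value regions"); ties go
    to the smaller raw p, then the smaller threshold. Returns the winning
    SplitResult and the full scan profile.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    marker_values = np.asarray(marker_values, dtype=float)
    if np.isnan(marker_values).any():
        raise ValueError("marker must be present for all patients")
    n = times.size
    uniq = np.unique(marker_values)
    if uniq.size < 2:
        raise NoValidThresholdError("marker is constant")
    candidates = 0.5 * (uniq[:-1] + uniq[1:])
    floor = max(3, int(np.ceil(min_group_fraction * n)))
    n_low = np.searchsorted(np.sort(marker_values), candidates, side="right")
    ok = (n_low >= floor) & (n - n_low >= floor)
    candidates = candidates[ok]
    if candidates.size == 0:
        raise NoValidThresholdError(
            f"no threshold leaves both groups with >= {floor} patients"
        )
    pvals = np.array(
        [_logrank_p(times, events, marker_values > c) for c in candidates]
    )
    smooth = (
        pd.Series(pvals).rolling(window=3, center=True, min_periods=1).mean().values
    )
    best = np.lexsort((candidates, pvals, smooth))[0]
    result = evaluate_split(
        times, events, marker_values, candidates[best],
        marker=marker, ties=ties, days_per_month=days_per_month,
    )
    profile = pd.DataFrame(
        {
            "threshold": candidates,
            "n_low": n_low[ok],
            "n_high": n - n_low[ok],
            "logrank_p": pvals,
            "logrank_p_smooth": smooth,
        }
    )
    return result, profile


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

@dataclass
class SpearmanResult:
    rho: float
    p: float
    interpretation: str = field(default="")


def spearman(x, y) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    The interpretation label follows the conventional bands: |rho| < 0.1 "no
    correlation", |rho| > 0.7 "strong correlation", otherwise "intermediate".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant input: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    a = abs(rho)
    label = "none" if a < 0.1 else ("strong" if a > 0.7 else "intermediate")
    return SpearmanResult(rho=float(rho), p=float(p), interpretation=label)
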