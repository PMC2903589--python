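"""Censored survival analysis: Kaplan-Meier curves, log-rank tests, Cox
proportional-hazards regression, and survival-optimized cut-point selection.

The cut-point scanner reproduces the X-tile idea: every admissible split of
a continuous marker (here the SSP distance) is scored with the two-group
log-rank statistic and the maximizing threshold is reported.  Because the
maximum of many correlated tests is anti-conservative, the minimum p-value
is also reported after the Miller-Siegmund correction; validating the chosen
cut-point on an independent cohort remains the honest check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "CoxFit",
    "CutpointResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "xtile_cutpoint",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up: time in months and death/censor indicator."""

    time: float
    event: bool  # True = death observed, False = censored

    def __post_init__(self):
        if not np.isfinite(self.time) or self.time <= 0:
            raise ValueError(f"time must be finite and positive, got {self.time}")


def _unpack(records) -> tuple[np.ndarray, np.ndarray]:
    records = list(records)
    if not records:
        raise ValueError("no survival records")
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([bool(r.event) for r in records])
    return t, e


@dataclass
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    times: np.ndarray  # ordered distinct event times
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    median: float | None  # first time with S(t) <= 0.5, None if never reached

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_estimate(records) -> KMCurve:
    """Kaplan-Meier product-limit estimate from censored records."""
    t, e = _unpack(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    times = event_rows.index.to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=float)
    surv = np.array([float(kmf.predict(tt)) for tt in times])
    below = np.flatnonzero(surv <= 0.5)
    median = float(times[below[0]]) if below.size else None
    return KMCurve(times=times, survival=surv, at_risk=at_risk, median=median)


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(*groups) -> LogRankResult:
    """Log-rank chi-square test across two or more survival groups."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, grp in enumerate(groups):
        t, e = _unpack(grp)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.shape[0], gi))
    t = np.concatenate(times)
    e = np.concatenate(events)
    lab = np.concatenate(labels)
    df = len(groups) - 1
    if e.sum() == 0:
        return LogRankResult(statistic=0.0, df=df, p_value=1.0)
    res = multivariate_logrank_test(t, lab, e)
    stat = float(res.test_statistic)
    if not np.isfinite(stat):
        return LogRankResult(statistic=0.0, df=df, p_value=1.0)
    return LogRankResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


@dataclass
class CoxFit:
    """Cox proportional-hazards fit: one row per covariate.

    ``summary`` columns: coef, hr, ci_low, ci_high, p (Wald, 95% CI).
    """

    summary: pd.DataFrame
    ties: str
    n_used: int
    n_dropped: int
    n_events: int

    def hazard_ratio(self, covariate) -> float:
        return float(self.summary.loc[covariate, "hr"])


def cox_fit(records, covariates: pd.DataFrame, ties: str = "efron") -> CoxFit:
    """Fit a Cox model by partial-likelihood Newton iteration.

    Rows with any missing covariate are dropped (and counted in
    ``n_dropped``), matching how published multivariable tables report a
    complete-case n.  Efron tie handling is the default; pass
    ``ties="breslow"`` for parity with software whose default is Breslow.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _unpack(records)
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != t.shape[0]:
        raise ValueError("covariate rows must align with records")
    keep = ~cov.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    t, e, cov = t[keep], e[keep], cov.loc[keep]
    if e.sum() == 0:
        raise ValueError("no observed events")

    model = PHReg(t, cov.to_numpy(dtype=float), status=e.astype(int), ties=ties)
    res = model.fit(disp=False)
    beta = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not (np.isfinite(beta).all() and np.isfinite(se).all()) or np.any(np.abs(beta) > 50):
        raise RuntimeError(
            "Cox fit did not converge (possible monotone likelihood / perfect "
            f"separation); coefficients={beta}, se={se}"
        )
    z = stats.norm.ppf(0.975)
    summary = pd.DataFrame(
        {
            "coef": beta,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - z * se),
            "ci_high": np.exp(beta + z * se),
            "p": 2 * stats.norm.sf(np.abs(beta) / se),
        },
        index=list(cov.columns),
    )
    return CoxFit(
        summary=summary,
        ties=ties,
        n_used=int(keep.sum()),
        n_dropped=n_dropped,
        n_events=int(e.sum()),
    )


def _logrank_two_group(t: np.ndarray, e: np.ndarray, in_g1: np.ndarray) -> float:
    """Two-group log-rank chi-square, direct O-E computation."""
    order = np.argsort(t, kind="stable")
    t, e, in_g1 = t[order], e[order], in_g1[order]
    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & in_g1).sum()
        dying = e & (t == et)
        d = dying.sum()
        d1 = (dying & in_g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0.0:
        return 0.0
    return float(o_minus_e**2 / var)


def _logrank_scan(t: np.ndarray, e: np.ndarray, score_order: np.ndarray) -> np.ndarray:
    """Log-rank chi-square for every prefix split of the score-sorted samples.

    Entry k-1 is the statistic for group1 = the k lowest-score samples,
    k = 1..n-1.  One cumulative sum per event time vectorizes the whole scan.
    """
    n = t.shape[0]
    event_times = np.unique(t[e])
    if event_times.size == 0:
        return np.zeros(n - 1)
    R = t[None, :] >= event_times[:, None]  # at risk (J, n)
    D = e[None, :] & (t[None, :] == event_times[:, None])  # dying (J, n)
    nj = R.sum(axis=1, keepdims=True).astype(float)
    dj = D.sum(axis=1, keepdims=True).astype(float)
    N1 = R[:, score_order].cumsum(axis=1).astype(float)  # (J, n): n1 at cut k
    D1 = D[:, score_order].cumsum(axis=1).astype(float)
    frac = N1 / nj
    oe = (D1 - dj * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vj = dj * frac * (1.0 - frac) * (nj - dj) / np.maximum(nj - 1.0, 1.0)
    v = vj.sum(axis=0)
    chi2 = np.zeros(n)
    mask = v > 0
    chi2[mask] = oe[mask] ** 2 / v[mask]
    return chi2[: n - 1]


@dataclass
class CutpointResult:
    """Best survival split of a continuous marker with multiplicity control."""

    cutpoint: float
    statistic: float
    p_naive: float
    p_corrected: float
    n_low: int  # scores below the cut-point
    n_high: int  # scores at or above
    scan: pd.DataFrame  # candidate, statistic, p for every admissible split


def miller_siegmund_minp(p_min: float, eps_low: float, eps_high: float) -> float:
    """Correct a minimum p-value from a cut-point scan over a score range.

    ``eps_low``/``eps_high`` are the fractions of samples below the smallest
    and the largest admissible cut-points.  Approximation for the maximally
    selected chi-square statistic; conservative for very small scans.
    """
    if not 0 < eps_low < eps_high < 1:
        raise ValueError("need 0 < eps_low < eps_high < 1")
    if p_min >= 0.5:
        return 1.0
    z = stats.norm.ppf(1 - p_min / 2)
    phi = stats.norm.pdf(z)
    with np.errstate(invalid="ignore"):
        corrected = phi * (z - 1.0 / z) * np.log(
            eps_high * (1 - eps_low) / (eps_low * (1 - eps_high))
        ) + 4 * phi / z
    if not np.isfinite(corrected):  # z overflow at extremely small p
        return p_min
    return float(min(1.0, max(corrected, p_min)))


def xtile_cutpoint(scores, records, min_group: int = 5) -> CutpointResult:
    """Scan all admissible splits of a score for the strongest survival split.

    Candidates are midpoints between consecutive distinct sorted scores with
    at least ``min_group`` samples on each side.  Each candidate is scored
    with the two-group log-rank statistic; the maximizer is returned with its
    naive p and the Miller-Siegmund corrected p.
    """
    scores = np.asarray(list(scores), dtype=float)
    t, e = _unpack(records)
    if scores.shape[0] != t.shape[0]:
        raise ValueError("scores and records must align")
    distinct = np.unique(scores)
    if distinct.size < 2:
        raise ValueError("no cut-point exists: all scores identical")
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    n = scores.shape[0]
    n_below = np.array([(scores < c).sum() for c in mids])
    keep = (n_below >= min_group) & (n_below <= n - min_group)
    admissible = mids[keep]
    if admissible.size == 0:
        raise ValueError(f"no split leaves at least {min_group} samples per side")

    score_order = np.argsort(scores, kind="stable")
    all_stats = _logrank_scan(t, e, score_order)  # stat for every prefix size
    stats_at = all_stats[n_below[keep] - 1]
    best = int(np.argmax(stats_at))
    chi2 = float(stats_at[best])
    p_naive = float(stats.chi2.sf(chi2, 1))
    eps_low = (scores < admissible[0]).sum() / n
    eps_high = (scores < admissible[-1]).sum() / n
    if len(admissible) == 1:
        p_corrected = p_naive  # single test: nothing selected over
    else:
        p_corrected = miller_siegmund_minp(p_naive, eps_low, eps_high)
    scan = pd.DataFrame(
        {
            "candidate": admissible,
            "statistic": stats_at,
            "p": stats.chi2.sf(stats_at, 1),
        }
    )
    cut = float(admissible[best])
    return CutpointResult(
        cutpoint=cut,
        statistic=chi2,
        p_naive=p_naive,
        p_corrected=p_corrected,
        n_low=int((scores < cut).sum()),
        n_high=int((scores >= cut).sum()),
        scan=scan,
    )
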