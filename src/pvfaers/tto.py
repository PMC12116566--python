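"""Time-to-onset: onset intervals, per-pair summaries and Weibull modelling.

Onset is the interval in whole days from therapy initiation (earliest valid
THER start date of the matched drug) to the event date.  Only strictly
positive onsets enter the analysis; records with a missing date, a start
date after the event date, or a zero interval are excluded with a reason
code.

The onset distribution per drug-event pair is summarised by median and
quartiles and modelled with a two-parameter Weibull

    f(t) = (k/lam) (t/lam)^(k-1) exp(-(t/lam)^k),  t > 0

fitted by maximum likelihood on (log k, log lam), with Wald 95% CIs from
the observed information on the log scale.  The shape CI classifies the
hazard: entirely below 1 -> early-failure (decreasing hazard), covering 1
-> random (constant), entirely above 1 -> late-failure (increasing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .faers_io import yyyymmdd_to_datetime

Z975 = 1.959963984540054

EXCLUSION_REASONS = ("missing_date", "erroneous_date", "zero_onset")


def compute_tto(cases: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Onset records per (report, drug, PT) from a case table.

    ``cases`` is the output of :func:`pvfaers.cohort.build_cases` (one row
    per report with ``event_dt``, ``therapy_start_dt`` and the set of SOC
    PTs).  Each retained report contributes one record per PT, all sharing
    the report's onset.

    Returns
    -------
    (records, excluded) : records has columns primaryid, drug, pt,
        onset_days (positive int); excluded has primaryid, drug, reason with
        reason in ``missing_date`` (either date absent), ``erroneous_date``
        (start after event) or ``zero_onset`` (start equals event).  The
        reasons partition the dropped reports.
    """
    event = yyyymmdd_to_datetime(pd.Series(cases["event_dt"], dtype="Int64"))
    start = yyyymmdd_to_datetime(pd.Series(cases["therapy_start_dt"], dtype="Int64"))
    onset = (event - start).dt.days

    missing = event.isna() | start.isna()
    erroneous = ~missing & (onset < 0)
    zero = ~missing & (onset == 0)
    keep = ~missing & (onset > 0)

    reason = pd.Series(pd.NA, index=cases.index, dtype="string")
    reason[missing] = "missing_date"
    reason[erroneous] = "erroneous_date"
    reason[zero] = "zero_onset"
    excluded = pd.DataFrame(
        {
            "primaryid": cases.loc[~keep, "primaryid"].to_numpy(),
            "drug": cases.loc[~keep, "drug"].to_numpy(),
            "reason": reason[~keep].to_numpy(),
        }
    )

    kept = cases.loc[keep]
    rows = []
    for pid, drug, pts, days in zip(
        kept["primaryid"], kept["drug"], kept["pts"], onset[keep].astype(int)
    ):
        for pt in sorted(pts):
            rows.append({"primaryid": pid, "drug": drug, "pt": pt, "onset_days": int(days)})
    records = pd.DataFrame(rows, columns=["primaryid", "drug", "pt", "onset_days"])
    return records, excluded


@dataclass
class TTOSummary:
    drug: str
    pt: str
    n: int
    median_days: float
    q1_days: float
    q3_days: float


def summarize_tto(records: pd.DataFrame, min_n: int = 1) -> pd.DataFrame:
    """Median and quartiles of onset days per (drug, pt) group.

    The median is the middle order statistic (mean of the two central values
    for even n, hence half-day medians); quartiles use linear interpolation.
    Groups below ``min_n`` are not emitted.
    """
    out = []
    for (drug, pt), grp in records.groupby(["drug", "pt"], sort=True):
        v = grp["onset_days"].to_numpy(dtype=float)
        if len(v) < min_n:
            continue
        out.append(
            {
                "drug": drug,
                "pt": pt,
                "n": len(v),
                "median_days": float(np.median(v)),
                "q1_days": float(np.percentile(v, 25)),
                "q3_days": float(np.percentile(v, 75)),
            }
        )
    return pd.DataFrame(out, columns=["drug", "pt", "n", "median_days", "q1_days", "q3_days"])


@dataclass
class WeibullFit:
    """Maximum-likelihood Weibull fit with Wald CIs (log-scale) and the
    hazard-shape classification."""

    shape: float
    shape_lo: float
    shape_hi: float
    scale: float
    scale_lo: float
    scale_hi: float
    n: int
    loglik: float
    hazard_class: str  # early-failure | random | late-failure


def _weibull_negloglik(theta: np.ndarray, t: np.ndarray) -> float:
    k = math.exp(theta[0])
    lam = math.exp(theta[1])
    z = t / lam
    return -float(
        len(t) * (math.log(k) - math.log(lam))
        + (k - 1.0) * np.sum(np.log(z))
        - np.sum(z**k)
    )


def _weibull_grad(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Gradient of the negative log-likelihood wrt (log k, log lam)."""
    k = math.exp(theta[0])
    lam = math.exp(theta[1])
    logz = np.log(t / lam)
    zk = np.exp(k * logz)
    n = len(t)
    dl_dk = n / k + np.sum(logz) - np.sum(zk * logz)  # d loglik / dk
    dl_dlam = -n * k / lam + (k / lam) * np.sum(zk)  # d loglik / dlam
    return -np.array([dl_dk * k, dl_dlam * lam])


def moments_start(t: np.ndarray) -> tuple[float, float]:
    """Method-of-moments style start: k from the coefficient of variation
    (k ~ cv^-1.086), lam from the mean and gamma function."""
    mean = float(np.mean(t))
    sd = float(np.std(t, ddof=1)) if len(t) > 1 else mean
    cv = sd / mean if mean > 0 else 1.0
    k0 = min(max(cv ** (-1.086) if cv > 0 else 1.0, 0.05), 50.0)
    lam0 = mean / special.gamma(1.0 + 1.0 / k0)
    return k0, lam0


def fit_weibull(
    onsets: np.ndarray | list[float],
    min_n: int = 10,
    fix_shape: float | None = None,
) -> WeibullFit:
    """Fit the two-parameter Weibull to positive onset times by MLE.

    Optimisation runs on (log k, log lam) from a method-of-moments start
    with analytic gradients (BFGS, gradient tolerance 1e-8); the observed
    information on the log scale gives Wald 95% CIs, back-transformed by
    exponentiation so the bounds stay positive.

    ``fix_shape`` pins k (the exponential model is ``fix_shape=1``, whose
    scale MLE is the closed form (mean of t^k)^(1/k)); its CI collapses to
    the fixed value.
    """
    t = np.asarray(onsets, dtype=float)
    if len(t) < min_n:
        raise ValueError(f"Weibull fit requires at least {min_n} onsets, got {len(t)}")
    if np.any(t <= 0):
        raise ValueError("onset times must be strictly positive")

    if fix_shape is not None:
        if fix_shape <= 0:
            raise ValueError("fix_shape must be positive")
        k = float(fix_shape)
        # profile MLE: lam^k = mean(t^k)
        lam = float(np.mean(t**k)) ** (1.0 / k)
        # observed information for log lam at the profile MLE: n k^2
        se = 1.0 / math.sqrt(len(t)) / k
        ll = -_weibull_negloglik(np.array([math.log(k), math.log(lam)]), t)
        return WeibullFit(
            shape=k, shape_lo=k, shape_hi=k,
            scale=lam,
            scale_lo=lam * math.exp(-Z975 * se),
            scale_hi=lam * math.exp(Z975 * se),
            n=len(t), loglik=ll,
            hazard_class="random" if k == 1.0 else
            ("early-failure" if k < 1.0 else "late-failure"),
        )

    k0, lam0 = moments_start(t)
    x0 = np.array([math.log(k0), math.log(lam0)])
    n = len(t)
    # optimise the mean negative log-likelihood so the gradient tolerance is
    # per observation, independent of sample size
    res = optimize.minimize(
        lambda th: _weibull_negloglik(th, t) / n,
        x0,
        jac=lambda th: _weibull_grad(th, t) / n,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if np.linalg.norm(_weibull_grad(res.x, t)) / n > 1e-8:
        polish = optimize.minimize(
            lambda th: _weibull_negloglik(th, t) / n,
            res.x,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000},
        )
        if polish.fun <= res.fun:
            res = polish
    if np.linalg.norm(_weibull_grad(res.x, t)) / n > 1e-6:
        raise RuntimeError(
            f"Weibull MLE did not converge from start (k={k0:.4g}, lam={lam0:.4g}): "
            f"{res.message}"
        )
    res.fun = res.fun * n

    # observed information: central-difference Hessian of the NLL on the
    # log-parameter scale
    hess = _numeric_hessian(lambda th: _weibull_negloglik(th, t), res.x)
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    k_hat, lam_hat = math.exp(res.x[0]), math.exp(res.x[1])
    k_lo, k_hi = k_hat * math.exp(-Z975 * se[0]), k_hat * math.exp(Z975 * se[0])
    lam_lo, lam_hi = lam_hat * math.exp(-Z975 * se[1]), lam_hat * math.exp(Z975 * se[1])

    if k_hi < 1.0:
        hazard = "early-failure"
    elif k_lo > 1.0:
        hazard = "late-failure"
    else:
        hazard = "random"

    return WeibullFit(
        shape=k_hat, shape_lo=k_lo, shape_hi=k_hi,
        scale=lam_hat, scale_lo=lam_lo, scale_hi=lam_hi,
        n=len(t), loglik=-res.fun, hazard_class=hazard,
    )


def _numeric_hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n = len(x)
    hess = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h * h)
    return hess


def weibull_loglik(t: np.ndarray | list[float], k: float, lam: float) -> float:
    """Weibull log-likelihood at (k, lam) — exposed for diagnostics."""
    t = np.asarray(t, dtype=float)
    return -_weibull_negloglik(np.array([math.log(k), math.log(lam)]), t)


def fit_weibull_by_pair(
    records: pd.DataFrame, min_n: int = 10
) -> pd.DataFrame:
    """Weibull fit per (drug, pt) group with at least ``min_n`` onsets."""
    out = []
    for (drug, pt), grp in records.groupby(["drug", "pt"], sort=True):
        v = grp["onset_days"].to_numpy(dtype=float)
        if len(v) < min_n:
            continue
        fit = fit_weibull(v, min_n=min_n)
        out.append(
            {
                "drug": drug, "pt": pt, "n": fit.n,
                "k": fit.shape, "k_lo": fit.shape_lo, "k_hi": fit.shape_hi,
                "lambda": fit.scale, "lambda_lo": fit.scale_lo, "lambda_hi": fit.scale_hi,
                "class": fit.hazard_class, "loglik": fit.loglik,
            }
        )
    return pd.DataFrame(
        out,
        columns=["drug", "pt", "n", "k", "k_lo", "k_hi",
                 "lambda", "lambda_lo", "lambda_hi", "class", "loglik"],
    )
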