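"""Risk-factor logistic regression for dermatologic-event occurrence.

Within one drug's deduplicated report universe, a report is a case (1) when
it carries a dermatologic event and a non-case (0) otherwise.  Candidate
risk factors follow the usual pharmacovigilance banding: hospitalization
(HO outcome), age >= 65 years, and extreme body weight (< 50 or > 100 kg,
reference 50-100 kg).  Reports missing any covariate are excluded.

The model is plain maximum-likelihood logistic regression with intercept,
fitted by iteratively reweighted least squares (IRLS); Wald CIs and
p-values per covariate.  No interactions, no regularisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import convert_age_years, convert_weight_kg
from .faers_io import QuarterBundle

Z975 = 1.959963984540054

COVARIATES = ("hospitalized", "age_ge65", "weight_extreme")


def build_design(
    bundle: QuarterBundle,
    drug_ids: set[int],
    derm_ids: set[int],
) -> pd.DataFrame:
    """One binary covariate row per complete report mentioning the drug.

    Columns: outcome (derm case yes/no), hospitalized (HO outcome),
    age_ge65 (age >= 65 y), weight_extreme (< 50 or > 100 kg).  Reports with
    missing age or weight are dropped; the number dropped is recorded in
    ``df.attrs['n_excluded']``.
    """
    demo = bundle.demo[bundle.demo["primaryid"].isin(list(drug_ids))]
    ho_ids = set(
        bundle.outc.loc[bundle.outc["outc_cod"] == "HO", "primaryid"].astype(int)
    )

    age = np.array(
        [convert_age_years(a, c) for a, c in zip(demo["age"], demo["age_cod"])],
        dtype=object,
    )
    wt = np.array(
        [convert_weight_kg(w, c) for w, c in zip(demo["wt"], demo["wt_cod"])],
        dtype=object,
    )
    complete = np.array([a is not None and w is not None for a, w in zip(age, wt)])

    pid = demo["primaryid"].astype(int).to_numpy()
    rows = pd.DataFrame(
        {
            "primaryid": pid[complete],
            "outcome": [int(p in derm_ids) for p in pid[complete]],
            "hospitalized": [int(p in ho_ids) for p in pid[complete]],
            "age_ge65": [int(a >= 65.0) for a in age[complete]],
            "weight_extreme": [int(w < 50.0 or w > 100.0) for w in wt[complete]],
        }
    )
    rows.attrs["n_excluded"] = int((~complete).sum())
    return rows.reset_index(drop=True)


@dataclass
class LogisticFit:
    """IRLS logistic fit: per-term coefficient, SE, OR with Wald CI and
    p-value; the deviance trace across iterations is kept for diagnostics."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    n: int
    converged: bool
    deviance_trace: list[float] = field(default_factory=list)

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def summary(self) -> pd.DataFrame:
        or_ = np.exp(self.coef)
        lo = np.exp(self.coef - Z975 * self.se)
        hi = np.exp(self.coef + Z975 * self.se)
        z = self.coef / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "se": self.se,
                "or": or_,
                "ci_lo": lo,
                "ci_hi": hi,
                "p": p,
            }
        )


class SeparationError(RuntimeError):
    pass


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def fit_logistic(
    rows: pd.DataFrame,
    covariates: tuple[str, ...] = COVARIATES,
    outcome: str = "outcome",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS with intercept.

    Convergence is declared when the score (gradient) norm drops below
    ``tol``; the deviance trace is monitored and step-halving keeps it
    non-increasing.  Quasi-complete separation (fitted probabilities
    saturating with diverging coefficients) raises
    :class:`SeparationError` naming the covariate.
    """
    y = rows[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[c].to_numpy(dtype=float) for c in covariates]
    )
    terms = ["intercept", *covariates]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix (collinear covariates)")

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    dev = _deviance(y, mu)
    trace = [dev]
    converged = False
    for _ in range(max_iter):
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        grad = X.T @ (y - mu)
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        xtwx = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(xtwx, grad)
        except np.linalg.LinAlgError as err:
            raise SeparationError(
                f"information matrix singular; suspect separation in {covariates}"
            ) from err
        # step-halving keeps the deviance non-increasing
        lam = 1.0
        for _half in range(30):
            cand = beta + lam * step
            mu_c = 1.0 / (1.0 + np.exp(-(X @ cand)))
            dev_c = _deviance(y, mu_c)
            if dev_c <= dev + 1e-10:
                break
            lam *= 0.5
        beta, mu, dev = cand, mu_c, dev_c
        trace.append(dev)
        if np.max(np.abs(beta)) > 30.0:
            bad = terms[int(np.argmax(np.abs(beta)))]
            raise SeparationError(f"coefficient diverging for {bad!r}: complete separation")
    else:
        grad = X.T @ (y - mu)
        converged = bool(np.linalg.norm(grad) < tol)

    w = np.maximum(mu * (1.0 - mu), 1e-12)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        terms=terms, coef=beta, se=se, n=len(y), converged=converged,
        deviance_trace=trace,
    )


def risk_table(fit: LogisticFit, rows: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate table with reference/alternative counts and the OR with
    Wald CI and p-value (intercept omitted)."""
    s = fit.summary()
    s = s[s["term"] != "intercept"].reset_index(drop=True)
    n_ref = [int((rows[t] == 0).sum()) for t in s["term"]]
    n_alt = [int((rows[t] == 1).sum()) for t in s["term"]]
    return pd.DataFrame(
        {
            "covariate": s["term"],
            "n_ref": n_ref,
            "n_alt": n_alt,
            "or": s["or"],
            "ci_lo": s["ci_lo"],
            "ci_hi": s["ci_hi"],
            "p": s["p"],
        }
    )
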