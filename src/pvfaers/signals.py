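"""Disproportionality statistics for drug-event pairs.

For a drug-event pair the report universe is cross-classified into the
classic 2x2 table

    a = reports with the drug and the event
    b = reports with the drug, without the event
    c = reports with the event, without the drug
    d = reports with neither

and four frequentist/Bayesian signal statistics are computed:

* ROR  — reporting odds ratio (a d)/(b c) with a Wald 95% CI on the log
  scale; the signal rule is "lower 95% bound > 1" with a minimum report
  count.
* PRR  — proportional reporting ratio [a/(a+b)]/[c/(c+d)] with the Pearson
  chi-square of the table (no continuity correction by default).
* IC   — the Bayesian information component log2((a+0.5)/(E+0.5)) with
  E = (a+b)(a+c)/N, and its closed-form shrinkage lower credibility bound
  IC025 = IC - 3.3 (a+0.5)^{-1/2} - 2 (a+0.5)^{-3/2}.
* EBGM — the empirical-Bayes geometric mean of the relative reporting rate
  under the two-component gamma (gamma-Poisson shrinker / MGPS) prior, with
  EBGM05 its 5th posterior percentile.

Zero cells: the Haldane-Anscombe +0.5 correction is applied to all four
cells, but only when some cell is zero, and the result is flagged; clean
tables keep exact arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .cohort import MeddraStub, normalize_name
from .faers_io import QuarterBundle

Z975 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-event counts against the report universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected a under independence: (a+b)(a+c)/N."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self) -> tuple[float, float, float, float]:
        """Working cells: +0.5 on all four cells iff some cell is zero."""
        if self.has_zero_cell():
            return self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5
        return float(self.a), float(self.b), float(self.c), float(self.d)


def build_contingency(
    universe: set[int], drug_ids: set[int], event_ids: set[int]
) -> ContingencyTable:
    """Cross-classify the (deduplicated) report universe by drug and event
    mention."""
    if not drug_ids <= universe or not event_ids <= universe:
        raise ValueError("drug_ids and event_ids must be subsets of the universe")
    a = len(drug_ids & event_ids)
    b = len(drug_ids) - a
    c = len(event_ids) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def ror(t: ContingencyTable, correction: bool = True) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI.

    With ``correction`` (default) a zero cell triggers the Haldane-Anscombe
    +0.5 on all cells; with it disabled a zero cell yields NaNs (undefined,
    flagged by the caller rather than silently dropped).
    """
    if t.has_zero_cell() and not correction:
        return math.nan, math.nan, math.nan
    a, b, c, d = t.corrected()
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(est) - Z975 * se)
    hi = math.exp(math.log(est) + Z975 * se)
    return est, lo, hi


def prr_chi2(
    t: ContingencyTable, yates: bool = False, correction: bool = True
) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson chi-square of the table.

    The chi-square is computed on the raw counts (continuity correction off
    by default; ``yates`` subtracts 0.5 from |O-E|).  PRR uses the corrected
    cells under the same zero-cell policy as :func:`ror`.
    """
    if (t.a + t.b == 0) or (t.c + t.d == 0):
        return math.nan, math.nan
    if t.has_zero_cell() and not correction:
        prr = math.nan
    else:
        a, b, c, d = t.corrected()
        prr = (a / (a + b)) / (c / (c + d))
    # Pearson chi-square on the observed table
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return prr, math.nan
    chi2 = 0.0
    for obs, er, ec in ((a, row1, col1), (b, row1, col2), (c, row2, col1), (d, row2, col2)):
        e = er * ec / n
        dev = abs(obs - e)
        if yates:
            dev = max(dev - 0.5, 0.0)
        chi2 += dev * dev / e
    return prr, chi2


def ic_bcpnn(t: ContingencyTable) -> tuple[float, float]:
    """Information component with the closed-form shrinkage lower bound.

    IC = log2((a+0.5)/(E+0.5)) with E=(a+b)(a+c)/N;
    IC025 = IC - 3.3 (a+0.5)^(-1/2) - 2 (a+0.5)^(-3/2).
    Defined for a = 0.
    """
    if t.n == 0:
        raise ValueError("empty universe")
    e = t.expected_a
    a_s = t.a + 0.5
    ic = math.log2(a_s / (e + 0.5))
    ic025 = ic - 3.3 * a_s ** (-0.5) - 2.0 * a_s ** (-1.5)
    return ic, ic025


@dataclass(frozen=True)
class MgpsPrior:
    """Two-component gamma mixture prior on the relative reporting rate.

    Defaults are the canonical gamma-Poisson-shrinker starting prior:
    w Gamma(alpha1, beta1) + (1-w) Gamma(alpha2, beta2) with
    (0.2, 0.1) / (2.0, 4.0) and w = 1/3 (shape/rate parameterisation).
    """

    alpha1: float = 0.2
    beta1: float = 0.1
    alpha2: float = 2.0
    beta2: float = 4.0
    w: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0 <= self.w <= 1:
            raise ValueError("mixture weight must lie in [0, 1]")

    def components(self) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
        return (self.w, self.alpha1, self.beta1), (1.0 - self.w, self.alpha2, self.beta2)


DEFAULT_MGPS_PRIOR = MgpsPrior()


def _log_nb_marginal(a: np.ndarray, e: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """log P(a) when a|lam ~ Poisson(lam e), lam ~ Gamma(alpha, rate beta):
    a negative-binomial with size alpha and success prob beta/(beta+e)."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    return (
        special.gammaln(alpha + a)
        - special.gammaln(alpha)
        - special.gammaln(a + 1.0)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


def _posterior_mixture(
    a: int, e: float, prior: MgpsPrior
) -> list[tuple[float, float, float]]:
    """Posterior of lam given a: mixture of Gamma(alpha_j + a, beta_j + e)
    with marginal-likelihood-updated weights.  Returns [(q, shape, rate)]."""
    if e <= 0:
        raise ValueError("expected count must be positive")
    logw = []
    for wj, alpha, beta in prior.components():
        if wj == 0:
            logw.append(-np.inf)
        else:
            logw.append(math.log(wj) + float(_log_nb_marginal(a, e, alpha, beta)))
    m = max(logw)
    q = np.exp(np.array(logw) - m)
    q = q / q.sum()
    comps = prior.components()
    return [
        (float(q[j]), comps[j][1] + a, comps[j][2] + e) for j in range(2) if q[j] > 0
    ]


def ebgm_mgps(
    t: ContingencyTable, prior: MgpsPrior = DEFAULT_MGPS_PRIOR
) -> tuple[float, float]:
    """Empirical-Bayes geometric mean and its 5th posterior percentile.

    EBGM = exp(E[ln lam | a]) under the posterior gamma mixture; EBGM05 is
    the 0.05 quantile of that mixture, found by root-finding the mixture
    CDF (bisection via brentq on a bracket from the component quantiles).
    """
    e = t.expected_a
    if e <= 0:
        raise ValueError("expected count (a+b)(a+c)/N must be positive")
    post = _posterior_mixture(t.a, e, prior)
    mean_log = sum(q * (special.digamma(shape) - math.log(rate)) for q, shape, rate in post)
    ebgm = math.exp(mean_log)

    def cdf(x: float) -> float:
        return sum(q * stats.gamma.cdf(x, shape, scale=1.0 / rate) for q, shape, rate in post)

    lo = min(stats.gamma.ppf(1e-4, shape, scale=1.0 / rate) for _, shape, rate in post)
    hi = max(stats.gamma.ppf(1.0 - 1e-9, shape, scale=1.0 / rate) for _, shape, rate in post)
    lo = max(lo, 1e-300)
    try:
        ebgm05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi, xtol=1e-12, rtol=1e-12)
    except ValueError as err:  # bracket failure
        raise RuntimeError(
            f"EBGM05 root-find failed for a={t.a}, E={e:.4g}, bracket=({lo:.3g},{hi:.3g})"
        ) from err
    return ebgm, ebgm05


def mixture_loglik(
    a: np.ndarray, e: np.ndarray, prior: MgpsPrior
) -> float:
    """Marginal log-likelihood of observed counts under the NB mixture."""
    l1 = _log_nb_marginal(a, e, prior.alpha1, prior.beta1)
    l2 = _log_nb_marginal(a, e, prior.alpha2, prior.beta2)
    w = np.clip(prior.w, 1e-12, 1 - 1e-12)
    m = np.maximum(l1, l2)
    return float(np.sum(m + np.log(w * np.exp(l1 - m) + (1 - w) * np.exp(l2 - m))))


def fit_mgps_prior(
    tables: list[ContingencyTable] | tuple[np.ndarray, np.ndarray],
    start: MgpsPrior = DEFAULT_MGPS_PRIOR,
    max_iter: int = 200,
    tol: float = 1e-7,
) -> tuple[MgpsPrior, list[float]]:
    """Empirical-Bayes hyperparameter fit by EM on the NB mixture.

    ``tables`` is either a list of contingency tables or a pair of arrays
    (observed counts, expected counts).  E-step: posterior component
    responsibilities per pair; M-step: weighted NB maximum likelihood per
    component (Nelder-Mead on log(alpha), log(beta)).  Returns the fitted
    prior (components ordered by ascending prior mean, removing label
    switching) and the marginal log-likelihood trace, which is
    non-decreasing up to the inner optimiser tolerance.  Falls back to
    ``start`` with a warning when the fit does not improve.
    """
    if isinstance(tables, tuple):
        a = np.asarray(tables[0], dtype=float)
        e = np.asarray(tables[1], dtype=float)
    else:
        a = np.array([t.a for t in tables], dtype=float)
        e = np.array([t.expected_a for t in tables], dtype=float)
    if len(a) < 50:
        raise ValueError("MGPS prior fitting requires at least 50 pairs")
    keep = e > 0
    a, e = a[keep], e[keep]

    prior = start
    trace = [mixture_loglik(a, e, prior)]
    for _ in range(max_iter):
        l1 = _log_nb_marginal(a, e, prior.alpha1, prior.beta1)
        l2 = _log_nb_marginal(a, e, prior.alpha2, prior.beta2)
        w = np.clip(prior.w, 1e-12, 1 - 1e-12)
        m = np.maximum(l1, l2)
        denom = w * np.exp(l1 - m) + (1 - w) * np.exp(l2 - m)
        r1 = w * np.exp(l1 - m) / denom  # responsibility of component 1

        def _mstep(resp: np.ndarray, alpha0: float, beta0: float) -> tuple[float, float]:
            def nll(theta):
                al, be = math.exp(theta[0]), math.exp(theta[1])
                return -float(np.sum(resp * _log_nb_marginal(a, e, al, be)))

            res = optimize.minimize(
                nll,
                [math.log(alpha0), math.log(beta0)],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
            )
            return math.exp(res.x[0]), math.exp(res.x[1])

        a1, b1 = _mstep(r1, prior.alpha1, prior.beta1)
        a2, b2 = _mstep(1.0 - r1, prior.alpha2, prior.beta2)
        new_w = float(np.mean(r1))
        prior = MgpsPrior(a1, b1, a2, b2, new_w)
        trace.append(mixture_loglik(a, e, prior))
        if abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1.0):
            break

    if trace[-1] < trace[0] - 1e-6:
        import warnings

        warnings.warn("MGPS prior EM failed to improve; returning the starting prior")
        return start, trace
    # canonical order: component 1 has the smaller prior mean alpha/beta
    if prior.alpha1 / prior.beta1 > prior.alpha2 / prior.beta2:
        prior = MgpsPrior(prior.alpha2, prior.beta2, prior.alpha1, prior.beta1, 1.0 - prior.w)
    return prior, trace


@dataclass
class SignalResult:
    """All four disproportionality statistics for one drug-event pair."""

    drug: str
    event: str
    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    is_signal: bool = False
    corrected: bool = False


def classify_signal(r: SignalResult, min_count: int = 3) -> bool:
    """Positive signal iff the lower 95% ROR bound exceeds 1 and the pair
    has at least ``min_count`` reports."""
    return bool(r.ror_lo > 1.0 and r.a >= min_count)


def compute_signal(
    t: ContingencyTable,
    drug: str,
    event: str,
    prior: MgpsPrior = DEFAULT_MGPS_PRIOR,
    min_count: int = 3,
    yates: bool = False,
) -> SignalResult:
    """All four statistics plus the signal flag for one pair."""
    est, lo, hi = ror(t)
    prr, chi2 = prr_chi2(t, yates=yates)
    ic, ic025 = ic_bcpnn(t)
    ebgm, ebgm05 = ebgm_mgps(t, prior)
    r = SignalResult(
        drug=drug, event=event, a=t.a,
        ror=est, ror_lo=lo, ror_hi=hi,
        prr=prr, chi2=chi2, ic=ic, ic025=ic025,
        ebgm=ebgm, ebgm05=ebgm05,
        corrected=t.has_zero_cell(),
    )
    r.is_signal = classify_signal(r, min_count=min_count)
    return r


def _event_ids_by_pt(
    reac: pd.DataFrame, pts: set[str]
) -> dict[str, set[int]]:
    norm = reac["pt"].map(normalize_name, na_action="ignore")
    out: dict[str, set[int]] = {}
    for pt in pts:
        hit = norm == pt
        out[pt] = set(reac.loc[hit.fillna(False), "primaryid"].astype(int))
    return out


def pt_scan(
    bundle: QuarterBundle,
    drug_ids: set[int],
    meddra: MeddraStub,
    soc_code: int,
    drug: str = "",
    prior: MgpsPrior = DEFAULT_MGPS_PRIOR,
    min_count: int = 3,
) -> list[SignalResult]:
    """One :class:`SignalResult` per preferred term of the SOC with a >= 1
    for the drug, ordered by ROR descending (ties: a descending, then PT
    name ascending).

    ``bundle`` must already be deduplicated; the universe is its demo table.
    """
    universe = bundle.primaryids()
    events = _event_ids_by_pt(bundle.reac, meddra.pts_in_soc(soc_code))
    results = []
    for pt, ids in events.items():
        t = build_contingency(universe, drug_ids, ids)
        if t.a < 1:
            continue
        results.append(
            compute_signal(t, drug=drug, event=pt, prior=prior, min_count=min_count)
        )
    results.sort(key=lambda r: (-r.ror, -r.a, r.event))
    return results


def soc_signal(
    bundle: QuarterBundle,
    drug_ids: set[int],
    meddra: MeddraStub,
    soc_code: int,
    drug: str = "",
    prior: MgpsPrior = DEFAULT_MGPS_PRIOR,
    min_count: int = 3,
    unit: str = "report",
) -> SignalResult:
    """Drug-level signal against the whole SOC (the per-drug summary row).

    ``unit`` selects the counting unit: ``report`` (one deduplicated report
    counts once; default) or ``report_pt`` (each distinct report x PT
    mention is a unit, so the universe is the reaction-row set).
    """
    if unit not in ("report", "report_pt"):
        raise ValueError("unit must be 'report' or 'report_pt'")
    soc_name = next(
        (name for code, name in meddra.mapping.values() if code == soc_code), str(soc_code)
    )
    if unit == "report":
        from .cohort import filter_soc

        universe = bundle.primaryids()
        event_ids = filter_soc(bundle.reac, meddra, soc_code)
        t = build_contingency(universe, drug_ids, event_ids)
    else:
        reac = bundle.reac.copy()
        norm = reac["pt"].map(normalize_name, na_action="ignore")
        reac = reac.assign(_pt=norm).dropna(subset=["_pt"]).drop_duplicates(
            subset=["primaryid", "_pt"]
        )
        in_soc = reac["_pt"].isin(meddra.pts_in_soc(soc_code))
        on_drug = reac["primaryid"].astype(int).isin(list(drug_ids))
        a = int((in_soc & on_drug).sum())
        b = int((~in_soc & on_drug).sum())
        c = int((in_soc & ~on_drug).sum())
        d = int((~in_soc & ~on_drug).sum())
        t = ContingencyTable(a, b, c, d)
    return compute_signal(t, drug=drug, event=soc_name, prior=prior, min_count=min_count)


def results_to_frame(results: list[SignalResult]) -> pd.DataFrame:
    """Flatten scan results for TSV/JSON output."""
    cols = ["drug", "event", "a", "ror", "ror_lo", "ror_hi", "prr", "chi2",
            "ic", "ic025", "ebgm", "ebgm05", "is_signal", "corrected"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
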