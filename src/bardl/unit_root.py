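"""Unit-root battery: ADF, Phillips-Perron and KPSS, plus an I(d) classifier.

The bounds test tolerates any mixture of I(0) and I(1) regressors but breaks
down with I(2) inputs, so every variable is screened at level and first
difference before estimation.  ADF and KPSS are delegated to statsmodels
(ADF lag order selected by the Schwarz criterion, MacKinnon response-surface
critical values); the Phillips-Perron Z-t statistic with Bartlett-kernel
long-run variance is implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tools.sm_exceptions import InterpolationWarning
from statsmodels.tsa.adfvalues import mackinnoncrit
from statsmodels.tsa.stattools import adfuller, kpss

from .data_model import AnnualSeries, first_difference
from .exceptions import DegenerateDataError, SizeError, SpecificationError

__all__ = [
    "UnitRootResult",
    "IntegrationClassification",
    "adf_test",
    "pp_test",
    "kpss_test",
    "classify_integration",
    "classify_series",
    "default_bandwidth",
    "default_max_lag",
    "simulate_adf_critical_value",
]

_DETERMINISTIC = {"constant": "c", "constant+trend": "ct", "c": "c", "ct": "ct"}
_ALPHAS = (0.01, 0.05, 0.10)

# KPSS upper-tail critical values (level-stationarity and trend-stationarity nulls)
_KPSS_CRIT = {
    "c": {0.10: 0.347, 0.05: 0.463, 0.01: 0.739},
    "ct": {0.10: 0.119, 0.05: 0.146, 0.01: 0.216},
}


@dataclass(frozen=True)
class UnitRootResult:
    """Outcome of one unit-root (or stationarity) test.

    ``null_meaning`` records what the null hypothesis asserts: a unit root for
    ADF/PP, stationarity for KPSS — so ``reject_null`` must be read against it.
    """

    test: str                  # "ADF" | "PP" | "KPSS"
    statistic: float
    lag_or_bandwidth: int
    deterministic: str         # "c" | "ct"
    alpha: float
    critical_value: float
    reject_null: bool
    null_meaning: str          # "unit_root" | "stationarity"
    nobs: int

    @property
    def judged_stationary(self) -> bool:
        """Stationarity verdict with KPSS's inverted null folded in."""
        if self.null_meaning == "unit_root":
            return self.reject_null
        return not self.reject_null


@dataclass(frozen=True)
class IntegrationClassification:
    """I(0)/I(1)/I(2+) verdict with the per-test votes behind it."""

    order: str                                  # "I0" | "I1" | "I2plus"
    level_stationary: bool
    diff_stationary: bool
    level_votes: dict
    diff_votes: dict

    @property
    def bounds_eligible(self) -> bool:
        return self.order in ("I0", "I1")


def _values(s) -> np.ndarray:
    return s.values if isinstance(s, AnnualSeries) else np.asarray(s, dtype=float)


def _check(x: np.ndarray, what: str) -> None:
    if np.ptp(x) == 0:
        raise DegenerateDataError(f"constant series passed to {what}")


def _alpha_key(alpha: float) -> str:
    if alpha not in _ALPHAS:
        raise SpecificationError(f"alpha must be one of {_ALPHAS}, got {alpha}")
    return {0.01: "1%", 0.05: "5%", 0.10: "10%"}[alpha]


def default_max_lag(n: int) -> int:
    """Schwert-style cap 12*(n/100)^(1/4) within which SIC selects."""
    return int(np.floor(12.0 * (n / 100.0) ** 0.25))


def default_bandwidth(n: int) -> int:
    """Newey-West short truncation 4*(n/100)^(1/4) for the Bartlett kernel."""
    return int(np.floor(4.0 * (n / 100.0) ** 0.25))


def adf_test(
    s,
    deterministic: str = "constant",
    max_lag: int | None = None,
    alpha: float = 0.05,
) -> UnitRootResult:
    """Augmented Dickey-Fuller test, lag order chosen by SIC within 0..max_lag.

    Null: the series has a unit root. Rejection (statistic below the MacKinnon
    critical value) means the series is judged stationary.
    """
    x = _values(s)
    _check(x, "adf_test")
    reg = _DETERMINISTIC[deterministic]
    n = len(x)
    if max_lag is None:
        max_lag = min(default_max_lag(n), (n - 7) // 2)
    if n - max_lag - 2 < 5:
        raise SizeError(f"series too short (n={n}) for max_lag={max_lag}")
    stat, _pval, usedlag, nobs, crit, _ = adfuller(
        x, maxlag=max_lag, regression=reg, autolag="BIC"
    )
    cv = float(crit[_alpha_key(alpha)])
    return UnitRootResult(
        test="ADF", statistic=float(stat), lag_or_bandwidth=int(usedlag),
        deterministic=reg, alpha=alpha, critical_value=cv,
        reject_null=bool(stat < cv), null_meaning="unit_root", nobs=int(nobs),
    )


def _bartlett_lrv(e: np.ndarray, bandwidth: int) -> tuple[float, float]:
    """(gamma0, lambda^2): residual variance and Bartlett long-run variance, divisor T."""
    T = len(e)
    gamma0 = float(e @ e) / T
    lam2 = gamma0
    for j in range(1, bandwidth + 1):
        w = 1.0 - j / (bandwidth + 1.0)
        lam2 += 2.0 * w * float(e[j:] @ e[:-j]) / T
    return gamma0, max(lam2, 1e-300)


def pp_test(
    s,
    deterministic: str = "constant",
    bandwidth: int | None = None,
    alpha: float = 0.05,
) -> UnitRootResult:
    """Phillips-Perron Z-t test.

    The Dickey-Fuller regression with zero augmentation lags is corrected
    nonparametrically for serial correlation through the Bartlett-kernel
    long-run variance of its residuals:

        Z_t = sqrt(g0/l2) * t_rho - T * se(rho) * (l2 - g0) / (2 * sqrt(l2) * s)

    With ``bandwidth == 0`` the correction vanishes and Z_t equals the ADF(0)
    statistic exactly.
    """
    x = _values(s)
    _check(x, "pp_test")
    reg = _DETERMINISTIC[deterministic]
    n = len(x)
    if n < 10:
        raise SizeError(f"series too short for pp_test (n={n})")
    if bandwidth is None:
        bandwidth = default_bandwidth(n)
    if bandwidth < 0 or bandwidth >= n - 2:
        raise SpecificationError(f"bandwidth {bandwidth} out of range for n={n}")

    dy = np.diff(x)
    ylag = x[:-1]
    T = len(dy)
    cols = [np.ones(T), ylag]
    if reg == "ct":
        cols.insert(1, np.arange(1, T + 1, dtype=float))
    X = np.column_stack(cols)
    beta, _, rank, _ = np.linalg.lstsq(X, dy, rcond=None)
    if rank < X.shape[1]:
        raise DegenerateDataError("rank-deficient Dickey-Fuller regression")
    e = dy - X @ beta
    k = X.shape[1]
    s2 = float(e @ e) / (T - k)
    XtX_inv = np.linalg.inv(X.T @ X)
    se_rho = np.sqrt(s2 * XtX_inv[-1, -1])
    t_rho = beta[-1] / se_rho

    gamma0, lam2 = _bartlett_lrv(e, bandwidth)
    zt = np.sqrt(gamma0 / lam2) * t_rho - T * se_rho * (lam2 - gamma0) / (
        2.0 * np.sqrt(lam2) * np.sqrt(s2)
    )
    cv = float(mackinnoncrit(N=1, regression=reg, nobs=T)[{0.01: 0, 0.05: 1, 0.10: 2}[
        alpha if alpha in _ALPHAS else _ALPHAS[1]]])
    _alpha_key(alpha)  # validates
    return UnitRootResult(
        test="PP", statistic=float(zt), lag_or_bandwidth=int(bandwidth),
        deterministic=reg, alpha=alpha, critical_value=cv,
        reject_null=bool(zt < cv), null_meaning="unit_root", nobs=T,
    )


def kpss_test(
    s,
    deterministic: str = "constant",
    bandwidth: int | None = None,
    alpha: float = 0.05,
) -> UnitRootResult:
    """KPSS test. Null: (trend-)stationarity; large statistics reject it."""
    x = _values(s)
    _check(x, "kpss_test")
    reg = _DETERMINISTIC[deterministic]
    if bandwidth is None:
        bandwidth = default_bandwidth(len(x))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", InterpolationWarning)
        stat, _pval, nlags, _crit = kpss(x, regression=reg, nlags=bandwidth)
    cv = _KPSS_CRIT[reg][alpha if alpha in _ALPHAS else 0.05]
    _alpha_key(alpha)
    return UnitRootResult(
        test="KPSS", statistic=float(stat), lag_or_bandwidth=int(nlags),
        deterministic=reg, alpha=alpha, critical_value=cv,
        reject_null=bool(stat > cv), null_meaning="stationarity", nobs=len(x),
    )


def classify_integration(
    level_results: list[UnitRootResult],
    diff_results: list[UnitRootResult],
    rule: str = "majority",
) -> IntegrationClassification:
    """Vote the battery into an I(0)/I(1)/I(2+) verdict.

    Majority rule over the stationarity verdicts of the supplied tests, with
    KPSS's inverted null already folded in; ties are resolved toward
    non-stationarity (conservative toward I(1), and toward I(2+) exclusion at
    the difference stage).
    """
    if rule != "majority":
        raise SpecificationError(f"unknown voting rule {rule!r}")
    if not level_results or not diff_results:
        raise SpecificationError("need at least one test at level and at difference")
    dets = {r.deterministic for r in level_results} | {r.deterministic for r in diff_results}
    if len(dets) > 1:
        raise SpecificationError(f"mixed deterministic specs across tests: {sorted(dets)}")

    def vote(results: list[UnitRootResult]) -> tuple[bool, dict]:
        votes = {r.test: r.judged_stationary for r in results}
        n_stat = sum(votes.values())
        return 2 * n_stat > len(votes), votes  # tie -> non-stationary

    lvl_stat, lvl_votes = vote(level_results)
    dif_stat, dif_votes = vote(diff_results)
    if lvl_stat:
        order = "I0"
    elif dif_stat:
        order = "I1"
    else:
        order = "I2plus"
    return IntegrationClassification(
        order=order, level_stationary=lvl_stat, diff_stationary=dif_stat,
        level_votes=lvl_votes, diff_votes=dif_votes,
    )


def classify_series(
    s: AnnualSeries,
    deterministic: str = "constant",
    alpha: float = 0.05,
) -> IntegrationClassification:
    """Run the full ADF/PP/KPSS battery at level and first difference and vote."""
    d = first_difference(s)
    level = [adf_test(s, deterministic, alpha=alpha),
             pp_test(s, deterministic, alpha=alpha),
             kpss_test(s, deterministic, alpha=alpha)]
    diff = [adf_test(d, deterministic, alpha=alpha),
            pp_test(d, deterministic, alpha=alpha),
            kpss_test(d, deterministic, alpha=alpha)]
    return classify_integration(level, diff)


def simulate_adf_critical_value(
    n: int,
    deterministic: str = "constant",
    alpha: float = 0.05,
    reps: int = 20000,
    seed: int = 0,
) -> float:
    """Monte-Carlo Dickey-Fuller critical value for sample size ``n``.

    Fallback for sample sizes where the response-surface approximation is not
    trusted: simulates driftless random walks, computes the DF t-ratio with
    zero lags, and returns the ``alpha`` quantile.
    """
    rng = np.random.default_rng(seed)
    reg = _DETERMINISTIC[deterministic]
    stats = np.empty(reps)
    t_idx = np.arange(1, n, dtype=float)
    for r in range(reps):
        x = np.cumsum(rng.standard_normal(n))
        dy = np.diff(x)
        cols = [np.ones(n - 1), x[:-1]]
        if reg == "ct":
            cols.insert(1, t_idx)
        X = np.column_stack(cols)
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ (X.T @ dy)
        e = dy - X @ beta
        s2 = (e @ e) / (len(dy) - X.shape[1])
        stats[r] = beta[-1] / np.sqrt(s2 * XtX_inv[-1, -1])
    return float(np.quantile(stats, alpha))
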