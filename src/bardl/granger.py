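"""Short-run and long-run Granger causality within the conditional ECM.

Short-run causality from x to y is a Wald F test of the joint nullity of
every lagged-difference coefficient of x in the y equation.  Long-run
causality is the significance of x's lagged-level coefficient, and is only
defined when the bounds test classified the equation as cointegrated — a
lagged level in a non-cointegrated equation is an unbalanced regressor.

Every result carries the sign of the summed relevant coefficients, reported
separately from significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .ardl_bounds import (
    ARDLSpec,
    BoundsOutcome,
    ECMFit,
    bounds_test,
    estimate_ecm,
    wald_f,
)
from .data_model import Dataset
from .exceptions import BardlError, GatingError, SpecificationError

__all__ = [
    "CausalityResult",
    "CausalityMatrix",
    "test_short_run_causality",
    "test_long_run_causality",
    "causality_matrix",
]


@dataclass(frozen=True)
class CausalityResult:
    """One directed causality test (cause -> effect) at one horizon."""

    cause: str
    effect: str
    horizon: str               # "short_run" | "long_run"
    statistic: float           # Wald F form
    t_statistic: float | None  # t form when a single coefficient is tested
    p_value: float
    sign: str                  # "+" | "-"
    significant: bool
    alpha: float
    df_num: int
    df_den: int


@dataclass(frozen=True)
class CausalityMatrix:
    """All directed pairs for one country, short run always, long run where defined."""

    country: str
    results: tuple[CausalityResult, ...]
    outcomes: dict              # dependent name -> BoundsOutcome (or None)
    alpha: float

    def get(self, cause: str, effect: str, horizon: str) -> CausalityResult | None:
        for r in self.results:
            if (r.cause, r.effect, r.horizon) == (cause, effect, horizon):
                return r
        return None

    @property
    def digest(self) -> dict:
        """Machine-readable summary of detected directed links."""
        links = sorted(
            f"{r.cause}->{r.effect}" for r in self.results
            if r.horizon == "short_run" and r.significant
        )
        pairs = {tuple(sorted(l.split("->"))) for l in links}
        bidir = sorted(
            f"{a}<->{b}" for a, b in pairs
            if f"{a}->{b}" in links and f"{b}->{a}" in links
        )
        unidir = sorted(
            l for l in links if tuple(sorted(l.split("->"))) not in
            {tuple(s.split("<->")) for s in bidir}
        )
        long_run = sorted(
            f"{r.cause}->{r.effect}" for r in self.results
            if r.horizon == "long_run" and r.significant
        )
        return {
            "country": self.country,
            "short_run_unidirectional": unidir,
            "short_run_bidirectional": bidir,
            "long_run": long_run,
        }


def _result(fit: ECMFit, cause: str, horizon: str, cols, alpha: float) -> CausalityResult:
    F, m, dfd = wald_f(fit, cols)
    coef_sum = float(np.sum(fit.params[cols]))
    t_stat = None
    if m == 1:
        i = cols[0]
        t_stat = float(fit.params[i] / np.sqrt(fit.cov_params[i, i]))
    p = float(sps.f.sf(F, m, dfd))
    return CausalityResult(
        cause=cause, effect=fit.spec.dependent, horizon=horizon,
        statistic=F, t_statistic=t_stat, p_value=p,
        sign="+" if coef_sum >= 0 else "-",
        significant=bool(p < alpha), alpha=alpha, df_num=m, df_den=dfd,
    )


def test_short_run_causality(fit: ECMFit, cause: str, alpha: float = 0.05) -> CausalityResult:
    """Wald F on all lagged-difference coefficients of ``cause`` in the fit."""
    if cause not in fit.spec.independents:
        raise SpecificationError(f"{cause!r} is not an independent of this equation")
    cols = fit.groups.get(f"dlags_{cause}", [])
    if not cols:
        raise SpecificationError(
            f"no lagged differences of {cause!r} in the design (q=1); "
            "nothing to test at the short-run horizon"
        )
    return _result(fit, cause, "short_run", cols, alpha)


def test_long_run_causality(
    fit: ECMFit, cause: str, outcome: BoundsOutcome, alpha: float = 0.05
) -> CausalityResult:
    """t/F test on the lagged level of ``cause``; requires cointegration.

    The statistic is reported in F form; when a single coefficient is tested
    the t form (its signed square root) is attached as ``t_statistic``.
    """
    if outcome.label != "COINTEGRATION":
        raise GatingError(
            "long-run causality is defined only under cointegration; the bounds "
            f"outcome for this equation is {outcome.label}"
        )
    if cause not in fit.spec.independents:
        raise SpecificationError(f"{cause!r} is not an independent of this equation")
    j = fit.spec.independents.index(cause)
    cols = [fit.groups["level_indep"][j]]
    return _result(fit, cause, "long_run", cols, alpha)


def causality_matrix(
    data: Dataset,
    specs: dict[str, ARDLSpec],
    alpha: float = 0.05,
    B: int = 0,
    seed: int = 0,
    outcomes: dict[str, BoundsOutcome] | None = None,
) -> CausalityMatrix:
    """Causality tests for every ordered pair of variables.

    ``specs`` maps each dependent variable to its equation spec.  Long-run
    entries are produced only for equations whose bounds outcome is
    COINTEGRATION; outcomes are taken from ``outcomes`` if given, computed by
    the bootstrap bounds test when ``B > 0``, and skipped otherwise.
    """
    results: list[CausalityResult] = []
    out: dict[str, BoundsOutcome | None] = {}
    failures: list[str] = []
    for i, (dep, spec) in enumerate(specs.items()):
        if spec.dependent != dep:
            raise SpecificationError(f"spec for {dep!r} has dependent {spec.dependent!r}")
        try:
            if outcomes is not None and dep in outcomes:
                outcome = outcomes[dep]
                fit = estimate_ecm(data, spec)
            elif B > 0:
                res = bounds_test(data, spec, B=B, alpha=alpha, seed=seed + i)
                fit, outcome = res.fit, res.outcome
            else:
                fit, outcome = estimate_ecm(data, spec), None
            out[dep] = outcome
            for cause in spec.independents:
                results.append(test_short_run_causality(fit, cause, alpha))
                if outcome is not None and outcome.label == "COINTEGRATION":
                    results.append(test_long_run_causality(fit, cause, outcome, alpha))
        except BardlError as e:
            failures.append(f"{dep}: {e}")
    if failures:
        raise BardlError("causality matrix estimation failed for: " + "; ".join(failures))
    return CausalityMatrix(
        country=data.country, results=tuple(results), outcomes=out, alpha=alpha
    )
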