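"""Synthetic trivariate annual systems for exercising the whole pipeline.

The generator emulates the statistical shape of short macro-health panels:
log GDP (``gdp``), life expectancy at birth in years (``le``) and per-capita
alcohol consumption in litres (``alc``), observed annually.  The independents
evolve as random walks with drift (weak exogeneity); the dependent follows a
conditional error-correction equation whose settings define six named
scenarios:

* ``no_cointegration``  — three unrelated random walks (the bounds-test null),
* ``cointegration``     — y error-corrects toward theta_x*x + theta_z*z,
* ``degenerate_1``      — lagged independent levels matter but there is no
                          error correction (no usable long-run relation),
* ``degenerate_2``      — y mean-reverts on its own; x, z carry no long-run
                          information,
* ``one_way_short_run`` — lagged differences of x drive y, nothing back,
* ``bidirectional``     — short-run feedback in both directions between x and y.

Level calibration (initial values and drifts) mimics the published ranges of
the study variables — log GDP around 9-11, life expectancy in the 60s-70s,
alcohol at a few litres — so demo output looks like real data; the test
statistics themselves are invariant to these scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ardl_bounds import ARDLSpec, bounds_test, estimate_ecm
from .data_model import AnnualSeries, Dataset
from .exceptions import ConfigError, ReplicationError
from .granger import test_short_run_causality

__all__ = ["DGPConfig", "simulate_trivariate", "size_power_experiment", "ExperimentReport"]

SCENARIOS = (
    "no_cointegration",
    "cointegration",
    "degenerate_1",
    "degenerate_2",
    "one_way_short_run",
    "bidirectional",
)

#: calibrated to the published level ranges (log GDP, years, litres)
_DEFAULT_INITIAL = (9.0, 61.0, 2.9)
_DEFAULT_DRIFTS = (0.09, 0.28, 0.12)
#: annual innovation standard deviations on the same scales
_DEFAULT_SDS = (0.03, 0.25, 0.15)


@dataclass(frozen=True)
class DGPConfig:
    """Full description of one synthetic scenario.

    ``error_correction`` is the speed coefficient on the equilibrium error
    y - theta_x*x - theta_z*z (0 = none, -1 = full adjustment each year);
    ``level_coefs`` are *direct* lagged-level coefficients of x and z in the
    y equation, used only by ``degenerate_1``; ``short_run`` holds the lagged
    difference coefficients (lambda on dy, delta on dx, pi on dz) in the y
    equation and ``feedback`` the coefficient of dy_{t-1} in the x equation.
    """

    scenario: str = "no_cointegration"
    n: int = 24
    burn_in: int = 100
    error_correction: float = 0.0
    theta: tuple[float, float] = (0.0, 0.0)
    level_coefs: tuple[float, float] = (0.0, 0.0)
    short_run: dict = field(default_factory=lambda: {
        "lambda": 0.0, "delta": 0.0, "pi": 0.0, "feedback": 0.0,
    })
    drifts: tuple[float, float, float] = _DEFAULT_DRIFTS
    innovation_cov: np.ndarray = field(
        default_factory=lambda: np.diag(np.asarray(_DEFAULT_SDS) ** 2)
    )
    initial: tuple[float, float, float] = _DEFAULT_INITIAL
    dummy_years: tuple[int, ...] = ()
    dummy_effects: tuple[float, ...] = ()
    start_year: int = 1992
    names: tuple[str, str, str] = ("gdp", "le", "alc")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n < 10:
            raise ConfigError(f"n={self.n} too short (need >= 10)")
        if self.burn_in < 50:
            raise ConfigError(f"burn_in={self.burn_in} < 50")
        cov = np.asarray(self.innovation_cov, dtype=float)
        object.__setattr__(self, "innovation_cov", cov)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ConfigError("innovation_cov must be a symmetric 3x3 matrix")
        if np.any(np.linalg.eigvalsh(cov) < -1e-12 * max(1.0, np.abs(cov).max())):
            raise ConfigError("innovation_cov must be positive semi-definite")
        ec = self.error_correction
        if not -1.0 <= ec <= 0.0:
            raise ConfigError(f"error_correction {ec} outside [-1, 0]")
        if abs(self.short_run.get("lambda", 0.0)) >= 1.0:
            raise ConfigError("|lambda| >= 1 gives an explosive difference equation")
        if len(self.dummy_years) != len(self.dummy_effects):
            raise ConfigError("dummy_years and dummy_effects lengths differ")
        if self.scenario == "no_cointegration" and (
            ec != 0.0 or any(self.theta) or any(self.level_coefs)
        ):
            raise ConfigError("no_cointegration requires zero level terms")
        if self.scenario == "cointegration" and ec == 0.0:
            raise ConfigError("cointegration scenario needs error_correction < 0")
        if self.scenario == "degenerate_2" and (ec == 0.0 or any(self.theta)):
            raise ConfigError("degenerate_2 needs error_correction < 0 and theta = 0")
        if self.scenario == "degenerate_1" and (ec != 0.0 or not any(self.level_coefs)):
            raise ConfigError("degenerate_1 needs error_correction = 0 and level_coefs != 0")

    @classmethod
    def for_scenario(cls, scenario: str, n: int = 24, seed: int = 0, **overrides) -> "DGPConfig":
        """Preset coefficient sets for the named scenarios."""
        presets: dict[str, dict] = {
            "no_cointegration": {},
            "cointegration": {"error_correction": -0.5, "theta": (1.0, 0.5)},
            "degenerate_1": {
                "level_coefs": (0.1, -0.1),
                "drifts": (0.0, 0.0, 0.0),
            },
            "degenerate_2": {"error_correction": -0.5},
            "one_way_short_run": {
                "short_run": {"lambda": 0.0, "delta": 0.8, "pi": 0.0, "feedback": 0.0},
            },
            "bidirectional": {
                "short_run": {"lambda": 0.0, "delta": 0.8, "pi": 0.0, "feedback": 0.8},
            },
        }
        kwargs = {**presets[scenario], **overrides}
        return cls(scenario=scenario, n=n, seed=seed, **kwargs)

    def with_seed(self, seed: int) -> "DGPConfig":
        return replace(self, seed=seed)


def simulate_trivariate(config: DGPConfig) -> Dataset:
    """Generate one trivariate annual Dataset from ``config``.

    The system is run for ``burn_in + n`` years from the configured initial
    levels and the burn-in is discarded; dummy shocks are added to the
    dependent equation in the configured calendar years of the returned
    window only.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    total = c.burn_in + c.n
    # PSD square root via eigendecomposition so a zero matrix stays exactly zero
    w, V = np.linalg.eigh(c.innovation_cov)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    eps = rng.standard_normal((total, 3)) @ L.T

    a_y, a_x, a_z = c.drifts
    th_x, th_z = c.theta
    g_x, g_z = c.level_coefs
    lam = c.short_run.get("lambda", 0.0)
    delta = c.short_run.get("delta", 0.0)
    pi_ = c.short_run.get("pi", 0.0)
    fb = c.short_run.get("feedback", 0.0)
    ec = c.error_correction
    y0, x0, z0 = c.initial
    mu = y0 - th_x * x0 - th_z * z0

    # map dummy calendar years to recursion indices (post burn-in window)
    shock = np.zeros(total + 1)
    for yr, eff in zip(c.dummy_years, c.dummy_effects):
        k = yr - c.start_year
        if not 0 <= k < c.n:
            raise ConfigError(f"dummy year {yr} outside the returned window")
        shock[c.burn_in + k + 1] = eff

    y = np.empty(total + 1)
    x = np.empty(total + 1)
    z = np.empty(total + 1)
    y[0], x[0], z[0] = y0, x0, z0
    dy_prev = dx_prev = dz_prev = 0.0
    for t in range(1, total + 1):
        e_y, e_x, e_z = eps[t - 1]
        dx = a_x + fb * dy_prev + e_x
        dz = a_z + e_z
        dy = (
            a_y
            + ec * (y[t - 1] - th_x * x[t - 1] - th_z * z[t - 1] - mu)
            + g_x * (x[t - 1] - x0)
            + g_z * (z[t - 1] - z0)
            + lam * dy_prev
            + delta * dx_prev
            + pi_ * dz_prev
            + shock[t]
            + e_y
        )
        x[t] = x[t - 1] + dx
        z[t] = z[t - 1] + dz
        y[t] = y[t - 1] + dy
        dy_prev, dx_prev, dz_prev = dy, dx, dz

    if not (np.all(np.isfinite(y)) and np.abs(y).max() < 1e12):
        raise ConfigError("explosive parameter combination: simulated series overflow")

    years = np.arange(c.start_year, c.start_year + c.n)
    sl = slice(c.burn_in + 1, total + 1)
    ny, nx, nz = c.names
    return Dataset(
        (
            AnnualSeries(ny, years, y[sl], transform="log" if ny == "gdp" else "level"),
            AnnualSeries(nx, years, x[sl]),
            AnnualSeries(nz, years, z[sl]),
        ),
        country=f"synthetic[{c.scenario}]",
    )


@dataclass(frozen=True)
class ExperimentReport:
    """Outcome frequencies (and causality rejection rates) per scenario."""

    scenarios: tuple[str, ...]
    n: int
    n_mc: int
    B: int
    alpha: float
    seed: int
    outcome_freq: dict          # scenario -> {label: frequency}
    test_rejection: dict        # scenario -> {"F_overall"/"t_dep"/"F_indep": rate}
    causality_rates: dict       # scenario -> {"cause->effect": rejection rate}

    def to_json(self) -> dict:
        return {
            "n": self.n, "n_mc": self.n_mc, "B": self.B,
            "alpha": self.alpha, "seed": self.seed,
            "outcome_freq": self.outcome_freq,
            "test_rejection": self.test_rejection,
            "causality_rates": self.causality_rates,
        }

    def outcome_frame(self):
        import pandas as pd

        return pd.DataFrame(self.outcome_freq).T.fillna(0.0)


def _default_spec(names: tuple[str, str, str]) -> ARDLSpec:
    return ARDLSpec(dependent=names[0], independents=(names[1], names[2]), p=2, q=(2, 2))


def size_power_experiment(
    scenarios,
    n_mc: int = 500,
    B: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
    n: int = 50,
    spec: ARDLSpec | None = None,
    causality: bool = False,
    config_overrides: dict | None = None,
) -> ExperimentReport:
    """Monte-Carlo calibration harness over the named scenarios.

    Per replicate: simulate, run the full bootstrap bounds test with the given
    equation spec, tally the outcome label; optionally also run the six
    short-run causality tests (asymptotic F) across all three equations.
    Fully deterministic given ``seed``.
    """
    scenarios = tuple(scenarios)
    if n_mc < 100:
        raise ReplicationError(f"n_mc={n_mc} < 100")
    if B < 199:
        raise ReplicationError(f"B={B} < 199")
    overrides = dict(config_overrides or {})
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=(len(scenarios), n_mc, 2))

    outcome_freq: dict = {}
    test_rejection: dict = {}
    causality_rates: dict = {}
    for i, scn in enumerate(scenarios):
        base = DGPConfig.for_scenario(scn, n=n, seed=0, **overrides)
        eq_spec = spec or _default_spec(base.names)
        counts: dict[str, int] = {}
        rej = {"F_overall": 0, "t_dep": 0, "F_indep": 0}
        cause_counts: dict[str, int] = {}
        for r in range(n_mc):
            data = simulate_trivariate(base.with_seed(int(seeds[i, r, 0])))
            res = bounds_test(data, eq_spec, B=B, alpha=alpha, seed=int(seeds[i, r, 1]))
            counts[res.outcome.label] = counts.get(res.outcome.label, 0) + 1
            rej["F_overall"] += int(res.outcome.sig_F)
            rej["t_dep"] += int(res.outcome.sig_t)
            rej["F_indep"] += int(res.outcome.sig_F_indep)
            if causality:
                for dep in base.names:
                    others = tuple(v for v in base.names if v != dep)
                    fit = estimate_ecm(data, ARDLSpec(dep, others, p=2, q=(2, 2)))
                    for cause in others:
                        cr = test_short_run_causality(fit, cause, alpha)
                        key = f"{cause}->{dep}"
                        cause_counts[key] = cause_counts.get(key, 0) + int(cr.significant)
        outcome_freq[scn] = {k: v / n_mc for k, v in sorted(counts.items())}
        test_rejection[scn] = {k: v / n_mc for k, v in rej.items()}
        if causality:
            causality_rates[scn] = {k: v / n_mc for k, v in sorted(cause_counts.items())}
    return ExperimentReport(
        scenarios=scenarios, n=n, n_mc=n_mc, B=B, alpha=alpha, seed=seed,
        outcome_freq=outcome_freq, test_rejection=test_rejection,
        causality_rates=causality_rates,
    )
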