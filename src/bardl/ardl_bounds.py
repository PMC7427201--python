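"""Conditional error-correction ARDL estimation and the bootstrap bounds test.

The model for dependent variable y with independents x (and optionally z) is
the conditional error-correction form

    dy_t = c + a*y_{t-1} + b_x*x_{t-1} + b_z*z_{t-1}
           + sum_{i=1}^{p-1} l_i dy_{t-i} + sum_{j=1}^{q-1} d_j dx_{t-j}
           + sum_{k=1}^{r-1} g_k dz_{t-k} + sum_l w_l D_{t,l} + e_t

estimated by OLS.  Cointegration is decided by three tests evaluated jointly:

* F_overall — Wald F on the joint nullity of all lagged-level coefficients,
* t_dep     — t-ratio on the lagged dependent level (error-correction speed),
* F_indep   — Wald F on the lagged independent levels only.

Critical values come from a residual bootstrap under the no-cointegration
null: the dependent equation is re-estimated without any lagged levels, the
independents get marginal difference equations, residual rows are resampled
jointly (preserving contemporaneous innovation correlation), the trivariate
system is regenerated recursively from the observed pre-sample values, and the
full model is re-estimated on every replicate.  An outcome is classified as

* COINTEGRATION   — all three tests significant,
* DEGENERATE_1    — F_overall and F_indep significant, t_dep not
                    (no usable error correction: the lagged dependent level
                    does not matter),
* DEGENERATE_2    — F_overall and t_dep significant, F_indep not
                    (the dependent is mean-reverting on its own; the lagged
                    independents carry no long-run information),
* NO_COINTEGRATION otherwise.

t_dep is one-sided lower-tail: error correction requires a negative
coefficient.  Ties at a critical value count as not significant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data_model import AnnualSeries, Dataset, DummySpec, build_dummies
from .exceptions import (
    CollinearityError,
    ComparisonError,
    RegenerationError,
    ReplicationError,
    SizeError,
    SpecificationError,
)

__all__ = [
    "ARDLSpec",
    "ECMFit",
    "BoundsStatistics",
    "BootstrapCriticalValues",
    "BoundsOutcome",
    "BoundsTestResult",
    "build_ecm_design",
    "estimate_ecm",
    "select_lags",
    "compute_bounds_statistics",
    "wald_f",
    "bootstrap_critical_values",
    "classify_outcome",
    "bounds_test",
]

_LABELS = ("COINTEGRATION", "NO_COINTEGRATION", "DEGENERATE_1", "DEGENERATE_2")


@dataclass(frozen=True)
class ARDLSpec:
    """Specification of one conditional ECM equation.

    ``p`` is the lag order of the dependent variable (p-1 lagged differences
    enter the equation); ``q`` holds one order per independent, same
    convention.  ``p = q = 1`` therefore means levels-only plus constant.
    """

    dependent: str
    independents: tuple[str, ...]
    p: int = 1
    q: tuple[int, ...] = (1,)
    dummies: DummySpec | None = None
    include_constant: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "independents", tuple(self.independents))
        q = self.q if isinstance(self.q, tuple) else tuple(self.q) if hasattr(self.q, "__iter__") else (self.q,)
        object.__setattr__(self, "q", tuple(int(v) for v in q))
        if not 1 <= len(self.independents) <= 2:
            raise SpecificationError("need 1 or 2 independent variables")
        if len(set(self.independents) | {self.dependent}) != len(self.independents) + 1:
            raise SpecificationError("dependent/independent names must be distinct")
        if len(self.q) != len(self.independents):
            raise SpecificationError("one q per independent variable required")
        if self.p < 1 or any(v < 1 for v in self.q):
            raise SpecificationError("lag orders must be >= 1")

    @property
    def max_lag(self) -> int:
        return max(self.p, *self.q)

    @property
    def n_params(self) -> int:
        s = len(self.dummies.years) if self.dummies else 0
        return (
            int(self.include_constant)
            + 1 + len(self.independents)
            + (self.p - 1) + sum(v - 1 for v in self.q)
            + s
        )


@dataclass
class ECMFit:
    """OLS fit of a conditional ECM with everything Wald tests need."""

    spec: ARDLSpec
    params: np.ndarray
    colnames: tuple[str, ...]
    groups: dict                       # column-group name -> list of indices
    resid: np.ndarray
    rss: float
    sigma2: float                      # rss / (T - k)
    cov_params: np.ndarray             # sigma2 * (X'X)^{-1}
    sic: float
    effective_n: int
    X: np.ndarray
    y: np.ndarray                      # the response dy_t

    @property
    def df_resid(self) -> int:
        return self.effective_n - len(self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.colnames.index(name)])

    def se(self, name: str) -> float:
        i = self.colnames.index(name)
        return float(np.sqrt(self.cov_params[i, i]))

    @property
    def long_run_multipliers(self) -> dict[str, float]:
        """-b_x/a per independent: the level relationship implied by the ECM."""
        a = self.params[self.groups["level_dep"][0]]
        if abs(a) <= 1e-10:
            return {}
        out = {}
        for name, i in zip(self.spec.independents, self.groups["level_indep"]):
            out[name] = float(-self.params[i] / a)
        return out


@dataclass(frozen=True)
class BoundsStatistics:
    """The three bounds-test statistics of one estimated equation."""

    F_overall: float
    t_dep: float
    F_indep: float
    df_num_overall: int
    df_num_indep: int
    df_den: int


@dataclass(frozen=True)
class BootstrapCriticalValues:
    """Empirical bootstrap quantiles for the three statistics at one alpha."""

    alpha: float
    B: int
    f_star: float
    t_star: float
    f_indep_star: float
    seed: int
    scheme: str
    replicates: dict = field(repr=False, default_factory=dict)


@dataclass(frozen=True)
class BoundsOutcome:
    """Four-way classification with the three significance flags behind it."""

    label: str
    sig_F: bool
    sig_t: bool
    sig_F_indep: bool
    alpha: float
    warning: str | None = None

    def __post_init__(self) -> None:
        assert self.label in _LABELS


@dataclass(frozen=True)
class BoundsTestResult:
    fit: ECMFit
    statistics: BoundsStatistics
    critical_values: BootstrapCriticalValues
    outcome: BoundsOutcome


# ---------------------------------------------------------------------------
# design construction (array core; supports a leading batch axis)
# ---------------------------------------------------------------------------

def _design_core(
    y: np.ndarray,
    xs: list[np.ndarray],
    p: int,
    qs: tuple[int, ...],
    dummy_mat: np.ndarray | None,
    include_constant: bool,
    trim_to: int | None = None,
):
    """Stack the ECM design. ``y``/``xs`` are level arrays of shape (..., n).

    Rows cover t = m+1 .. n-1 (0-based) where m = trim_to or max(p, q).
    Returns (X of shape (..., T, k_wo_dummies+s), dy of shape (..., T)).
    Dummy columns are appended last and are shared across the batch axis.
    """
    m = max(p, *qs) if trim_to is None else trim_to
    n = y.shape[-1]
    T = n - m - 1
    if T < 1:
        raise SizeError(f"no usable observations: n={n}, max lag={m}")
    t0 = m + 1
    dy_full = np.diff(y, axis=-1)                 # dy_full[..., t-1] = y_t - y_{t-1}
    dxs_full = [np.diff(x, axis=-1) for x in xs]

    cols = []
    if include_constant:
        cols.append(np.broadcast_to(np.ones(T), y.shape[:-1] + (T,)))
    cols.append(y[..., t0 - 1 : n - 1])           # y_{t-1}
    for x in xs:
        cols.append(x[..., t0 - 1 : n - 1])       # x_{t-1}
    for i in range(1, p):
        cols.append(dy_full[..., t0 - 1 - i : n - 1 - i])
    for dx, q in zip(dxs_full, qs):
        for j in range(1, q):
            cols.append(dx[..., t0 - 1 - j : n - 1 - j])
    X = np.stack(cols, axis=-1)
    if dummy_mat is not None and dummy_mat.shape[1] > 0:
        D = dummy_mat[t0:n, :]
        D = np.broadcast_to(D, y.shape[:-1] + D.shape)
        X = np.concatenate([X, D], axis=-1)
    dy = dy_full[..., t0 - 1 :]
    return X, dy


def _column_names_and_groups(spec: ARDLSpec):
    dep, indeps = spec.dependent, spec.independents
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    if spec.include_constant:
        groups["const"] = [len(names)]
        names.append("const")
    groups["level_dep"] = [len(names)]
    names.append(f"{dep}.L1")
    groups["level_indep"] = []
    for x in indeps:
        groups["level_indep"].append(len(names))
        names.append(f"{x}.L1")
    groups["dlags_dep"] = []
    for i in range(1, spec.p):
        groups["dlags_dep"].append(len(names))
        names.append(f"d{dep}.L{i}")
    for x, q in zip(indeps, spec.q):
        groups[f"dlags_{x}"] = []
        for j in range(1, q):
            groups[f"dlags_{x}"].append(len(names))
            names.append(f"d{x}.L{j}")
    groups["dummies"] = []
    if spec.dummies:
        for yr in spec.dummies.years:
            groups["dummies"].append(len(names))
            names.append(f"D{yr}")
    groups["levels"] = groups["level_dep"] + groups["level_indep"]
    return tuple(names), groups


def _extract_arrays(data: Dataset, spec: ARDLSpec):
    try:
        y = data[spec.dependent].values
        xs = [data[x].values for x in spec.independents]
    except KeyError as e:
        raise SpecificationError(f"series {e.args[0]!r} not in dataset {data.names}") from e
    dummy_mat = None
    if spec.dummies and spec.dummies.years:
        dummy_mat = build_dummies(spec.dummies, data.years, as_frame=False)
    return y, xs, dummy_mat


def build_ecm_design(data: Dataset, spec: ARDLSpec):
    """Design matrix and response (dy_t) for the conditional ECM.

    Columns are ordered constant, lagged levels (dependent first), lagged
    differences of the dependent, lagged differences of each independent,
    impulse dummies.  Row count is n - max(p, q) - 1.
    """
    y, xs, dummy_mat = _extract_arrays(data, spec)
    names, groups = _column_names_and_groups(spec)
    X, dy = _design_core(y, xs, spec.p, spec.q, dummy_mat, spec.include_constant)
    k = X.shape[-1]
    if data.n - spec.max_lag < k + 5:
        raise SizeError(
            f"effective sample {data.n - spec.max_lag} < {k} regressors + 5"
        )
    _check_rank(X, names)
    return X, dy, names, groups


def _check_rank(X: np.ndarray, names: tuple[str, ...]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[-1]:
        # name the columns involved in the deficiency via QR pivoting
        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [names[j] for j in piv[len(diag):]]
        raise CollinearityError(
            f"rank-deficient design (rank {rank} < {X.shape[-1]}); "
            f"offending columns: {bad}", columns=tuple(bad)
        )


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _sic(rss: float, T: int, k: int) -> float:
    """Schwarz criterion ln(rss/T) + k ln(T)/T (Gaussian concentrated form)."""
    return float(np.log(rss / T) + k * np.log(T) / T)


def estimate_ecm(data: Dataset, spec: ARDLSpec) -> ECMFit:
    """OLS estimate of the conditional ECM defined by ``spec``."""
    X, dy, names, groups = build_ecm_design(data, spec)
    beta, _, rank, _ = np.linalg.lstsq(X, dy, rcond=None)
    resid = dy - X @ beta
    T, k = X.shape
    rss = float(resid @ resid)
    sigma2 = rss / (T - k)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return ECMFit(
        spec=spec, params=beta, colnames=names, groups=groups,
        resid=resid, rss=rss, sigma2=sigma2, cov_params=cov,
        sic=_sic(rss, T, k), effective_n=T, X=X, y=dy,
    )


def select_lags(
    data: Dataset,
    dependent: str,
    independents: tuple[str, ...],
    p_grid=range(1, 4),
    q_grid=range(1, 4),
    dummies: DummySpec | None = None,
    include_constant: bool = True,
) -> ARDLSpec:
    """Pick (p, q, ...) minimizing SIC on a common estimation sample.

    All candidates are estimated on the rows implied by the largest candidate
    max-lag so their SICs are comparable.  Ties go to the candidate with fewer
    parameters, then to the lexicographically smallest lag tuple.
    """
    independents = tuple(independents)
    k_ind = len(independents)
    cands = [
        (p,) + qs
        for p in p_grid
        for qs in itertools.product(q_grid, repeat=k_ind)
    ]
    if not cands:
        raise SpecificationError("empty lag grid")
    trim = max(max(c) for c in cands)
    y, xs, dummy_mat = _extract_arrays(
        data, ARDLSpec(dependent, independents, 1, (1,) * k_ind, dummies, include_constant)
    )
    best = None
    for c in cands:
        p, qs = c[0], c[1:]
        spec = ARDLSpec(dependent, independents, p, qs, dummies, include_constant)
        X, dy = _design_core(y, xs, p, qs, dummy_mat, include_constant, trim_to=trim)
        T, k = X.shape
        if T < k + 5:
            continue
        beta, _, rank, _ = np.linalg.lstsq(X, dy, rcond=None)
        if rank < k:
            continue
        resid = dy - X @ beta
        sic = _sic(float(resid @ resid), T, k)
        key = (round(sic, 12), k, c)
        if best is None or key < best[0]:
            best = (key, spec)
    if best is None:
        raise SpecificationError("no feasible candidate in the lag grid")
    return best[1]


# ---------------------------------------------------------------------------
# test statistics
# ---------------------------------------------------------------------------

def wald_f(fit: ECMFit, cols) -> tuple[float, int, int]:
    """Homoskedastic Wald F of H0: beta[cols] = 0; returns (F, df_num, df_den)."""
    cols = list(cols)
    if not cols:
        raise SpecificationError("no restrictions to test")
    b = fit.params[cols]
    V = fit.cov_params[np.ix_(cols, cols)]
    m = len(cols)
    F = float(b @ np.linalg.solve(V, b)) / m
    return F, m, fit.df_resid


def compute_bounds_statistics(fit: ECMFit) -> BoundsStatistics:
    """F on all lagged levels, t on the dependent level, F on independent levels."""
    F_all, m_all, dfd = wald_f(fit, fit.groups["levels"])
    F_ind, m_ind, _ = wald_f(fit, fit.groups["level_indep"])
    i_dep = fit.groups["level_dep"][0]
    t_dep = float(fit.params[i_dep] / np.sqrt(fit.cov_params[i_dep, i_dep]))
    return BoundsStatistics(
        F_overall=F_all, t_dep=t_dep, F_indep=F_ind,
        df_num_overall=m_all, df_num_indep=m_ind, df_den=dfd,
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _batched_ols(X: np.ndarray, y: np.ndarray):
    """OLS over a leading batch axis. X: (B,T,k), y: (B,T) -> beta, rss, Ginv."""
    G = np.einsum("bti,btj->bij", X, X)
    c = np.einsum("bti,bt->bi", X, y)
    Ginv = np.linalg.inv(G)
    beta = np.einsum("bij,bj->bi", Ginv, c)
    resid = y - np.einsum("bti,bi->bt", X, beta)
    rss = np.einsum("bt,bt->b", resid, resid)
    return beta, rss, Ginv


def bootstrap_critical_values(
    data: Dataset,
    spec: ARDLSpec,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCriticalValues:
    """Residual-bootstrap critical values for the three bounds statistics.

    Under the null all lagged-level terms are removed from the dependent
    equation; each independent gets a marginal equation of its differences on
    its own lagged differences.  Residual rows are resampled jointly and the
    system is regenerated recursively from the observed pre-sample values,
    dummies held at their observed positions.
    """
    if B < 199:
        raise ReplicationError(f"B={B} < 199")
    if not 0 < alpha < 0.5:
        raise SpecificationError(f"alpha {alpha} outside (0, 0.5)")
    y, xs, dummy_mat = _extract_arrays(data, spec)
    names, groups = _column_names_and_groups(spec)
    X, dy = _design_core(y, xs, spec.p, spec.q, dummy_mat, spec.include_constant)
    _check_rank(X, names)
    T = X.shape[0]
    m = spec.max_lag
    n = data.n

    # null-restricted dependent equation: drop all lagged levels
    keep = [i for i in range(X.shape[1]) if i not in groups["levels"]]
    X0 = X[:, keep]
    b0, _, _, _ = np.linalg.lstsq(X0, dy, rcond=None)
    e0 = dy - X0 @ b0
    e0 = e0 - e0.mean()

    # marginal equations: dx_t on const + own lagged differences
    marg = []
    for x, q in zip(xs, spec.q):
        dx = np.diff(x)
        rows = np.column_stack(
            [np.ones(T)] + [dx[m - j : n - 1 - j] for j in range(1, q)]
        )
        resp = dx[m:]
        bj, _, _, _ = np.linalg.lstsq(rows, resp, rcond=None)
        ej = resp - rows @ bj
        marg.append((bj, ej - ej.mean()))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, T, size=(B, T))
    eY = e0[idx]
    eXs = [e[idx] for _, e in marg]

    # recursive regeneration, batch axis first
    ystar = np.empty((B, n))
    ystar[:, : m + 1] = y[: m + 1]
    xstars = []
    for x in xs:
        xa = np.empty((B, n))
        xa[:, : m + 1] = x[: m + 1]
        xstars.append(xa)
    dys = np.zeros((B, n))          # dys[:, t] = y*_t - y*_{t-1}
    dxs = [np.zeros((B, n)) for _ in xs]
    dys[:, 1 : m + 1] = np.diff(y[: m + 1])
    for xa, x in zip(dxs, xs):
        xa[:, 1 : m + 1] = np.diff(x[: m + 1])

    # coefficient layout of the null dependent equation mirrors keep-order:
    # const, dep d-lags, indep d-lags, dummies
    c0 = 0.0
    pos = 0
    if spec.include_constant:
        c0 = b0[0]
        pos = 1
    lam = b0[pos : pos + spec.p - 1]
    pos += spec.p - 1
    dcoefs = []
    for q in spec.q:
        dcoefs.append(b0[pos : pos + q - 1])
        pos += q - 1
    wcoefs = b0[pos:]

    for t in range(m + 1, n):
        for xa, dxa, (bj, _), q, ex in zip(xstars, dxs, marg, spec.q, eXs):
            val = bj[0] + ex[:, t - m - 1]
            for j in range(1, q):
                val = val + bj[j] * dxa[:, t - j]
            dxa[:, t] = val
            xa[:, t] = xa[:, t - 1] + val
        val = c0 + eY[:, t - m - 1]
        for i in range(1, spec.p):
            val = val + lam[i - 1] * dys[:, t - i]
        for dxa, dc, q in zip(dxs, dcoefs, spec.q):
            for j in range(1, q):
                val = val + dc[j - 1] * dxa[:, t - j]
        if dummy_mat is not None and len(wcoefs):
            val = val + dummy_mat[t, :] @ wcoefs
        dys[:, t] = val
        ystar[:, t] = ystar[:, t - 1] + val

    scale = 1e9 * (1.0 + max(np.abs(y).max(), *(np.abs(x).max() for x in xs)))
    if not np.all(np.isfinite(ystar)) or np.abs(ystar).max() > scale:
        raise RegenerationError(
            "bootstrap regeneration produced explosive series "
            f"(max |y*| = {np.abs(ystar).max():.3g}); check the null-model fit"
        )

    Xb, dyb = _design_core(ystar, xstars, spec.p, spec.q, dummy_mat, spec.include_constant)
    k = Xb.shape[-1]
    beta_u, rss_u, Ginv = _batched_ols(Xb, dyb)
    sigma2 = rss_u / (T - k)
    i_dep = groups["level_dep"][0]
    t_b = beta_u[:, i_dep] / np.sqrt(sigma2 * Ginv[:, i_dep, i_dep])

    def _f_from_restriction(drop: list[int]) -> np.ndarray:
        keep_r = [i for i in range(k) if i not in drop]
        _, rss_r, _ = _batched_ols(Xb[:, :, keep_r], dyb)
        return ((rss_r - rss_u) / len(drop)) / (rss_u / (T - k))

    f_b = _f_from_restriction(groups["levels"])
    find_b = _f_from_restriction(groups["level_indep"])

    return BootstrapCriticalValues(
        alpha=alpha, B=B,
        f_star=float(np.quantile(f_b, 1.0 - alpha)),
        t_star=float(np.quantile(t_b, alpha)),
        f_indep_star=float(np.quantile(find_b, 1.0 - alpha)),
        seed=seed,
        scheme="iid joint residual resampling; recursive regeneration under the null",
        replicates={"F_overall": f_b, "t_dep": t_b, "F_indep": find_b},
    )


def classify_outcome(
    stats: BoundsStatistics, cvs: BootstrapCriticalValues, alpha: float | None = None
) -> BoundsOutcome:
    """Map the three significance flags to the four-way outcome label.

    Significance is strict (a statistic exactly at its critical value does not
    reject).  t_dep rejects in the lower tail only.
    """
    if alpha is not None and abs(alpha - cvs.alpha) > 1e-12:
        raise ComparisonError(f"alpha mismatch: {alpha} vs critical values at {cvs.alpha}")
    sig_F = stats.F_overall > cvs.f_star
    sig_t = stats.t_dep < cvs.t_star
    sig_Find = stats.F_indep > cvs.f_indep_star
    warning = None
    if sig_F and sig_t and sig_Find:
        label = "COINTEGRATION"
    elif sig_F and sig_Find and not sig_t:
        label = "DEGENERATE_1"
    elif sig_F and sig_t and not sig_Find:
        label = "DEGENERATE_2"
    else:
        label = "NO_COINTEGRATION"
        if sig_F and not sig_t and not sig_Find:
            warning = (
                "overall F significant but neither component test is; "
                "treated as no cointegration"
            )
    return BoundsOutcome(
        label=label, sig_F=sig_F, sig_t=sig_t, sig_F_indep=sig_Find,
        alpha=cvs.alpha, warning=warning,
    )


def bounds_test(
    data: Dataset,
    spec: ARDLSpec,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BoundsTestResult:
    """End-to-end bounds test: estimate, bootstrap, classify."""
    fit = estimate_ecm(data, spec)
    stats = compute_bounds_statistics(fit)
    cvs = bootstrap_critical_values(data, spec, B=B, alpha=alpha, seed=seed)
    outcome = classify_outcome(stats, cvs)
    return BoundsTestResult(fit=fit, statistics=stats, critical_values=cvs, outcome=outcome)


def f_pvalue(F: float, df_num: int, df_den: int) -> float:
    """Upper-tail p-value of an F statistic."""
    return float(sps.f.sf(F, df_num, df_den))
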