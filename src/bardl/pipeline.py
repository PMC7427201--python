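"""End-to-end orchestration: descriptives -> unit roots -> bounds -> causality.

One declarative config drives the whole per-country analysis and every random
step is seeded, so a run is a pure function of (input file, config, seed).
The bundle mirrors the four standard tables of this kind of study: a
descriptives block, a unit-root grid with lag/bandwidth annotations, a bounds
grid with one row per candidate dependent variable, and a causality grid.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ardl_bounds import ARDLSpec, BoundsTestResult, bounds_test, select_lags
from .data_model import (
    Dataset,
    DummySpec,
    descriptives_table,
    first_difference,
    load_dataset,
)
from .exceptions import ConfigError, FormatError, GatingError
from .granger import causality_matrix
from .unit_root import adf_test, classify_series, kpss_test, pp_test

__all__ = ["AnalysisConfig", "ReportBundle", "run_country_analysis", "render_tables",
           "unit_root_table", "bounds_table"]

log = logging.getLogger("bardl")


@dataclass(frozen=True)
class AnalysisConfig:
    """Validated configuration of one country analysis."""

    input: str
    country: str = ""
    transforms: dict = field(default_factory=dict)
    dummies: dict = field(default_factory=dict)     # dependent -> list of years or "d03d07" label
    lags: dict = field(default_factory=dict)        # {"mode": "fixed"|"sic", "p":..,"q":..,"max":..}
    deterministic: str = "constant"
    B: int = 2000
    alpha: float = 0.05
    seed: int = 0
    outdir: str = "bardl_out"

    def __post_init__(self) -> None:
        if not Path(self.input).exists():
            raise ConfigError(f"input file not found: {self.input}")
        if not 0.0 < self.alpha < 0.5:
            raise ConfigError(f"alpha must lie in (0, 0.5), got {self.alpha}")
        if self.B > 0 and self.seed is None:
            raise ConfigError("a seed is required whenever B > 0")
        if self.B != 0 and self.B < 199:
            raise ConfigError(f"B must be 0 (skip bootstrap) or >= 199, got {self.B}")
        mode = self.lags.get("mode", "fixed")
        if mode not in ("fixed", "sic"):
            raise ConfigError(f"lags.mode must be 'fixed' or 'sic', got {mode!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load YAML or JSON; unknown keys are a validation error."""
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        raw.update(overrides)
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def dummy_spec(self, dependent: str) -> DummySpec:
        val = self.dummies.get(dependent, ())
        if isinstance(val, str):
            return DummySpec.from_label(val)
        return DummySpec(tuple(int(v) for v in val))


@dataclass
class ReportBundle:
    """Everything one run produces, renderable to CSV/text."""

    config: AnalysisConfig
    descriptives: pd.DataFrame
    unit_root: pd.DataFrame
    integration: dict
    bounds: pd.DataFrame
    bounds_results: dict            # dependent -> BoundsTestResult
    causality: pd.DataFrame
    digest: dict
    stages: list = field(default_factory=list)


def unit_root_table(data: Dataset, deterministic: str = "constant", alpha: float = 0.05) -> pd.DataFrame:
    """ADF/PP/KPSS grid at level and first difference with [lag]/(bandwidth)."""
    rows = []
    for s in data.series:
        d = first_difference(s)
        row: dict = {"variable": s.name}
        for label, ser in (("level", s), ("diff", d)):
            a = adf_test(ser, deterministic, alpha=alpha)
            p = pp_test(ser, deterministic, alpha=alpha)
            k = kpss_test(ser, deterministic, alpha=alpha)
            row[f"ADF_{label}"] = f"{a.statistic:.3f}{'*' if a.reject_null else ''} [{a.lag_or_bandwidth}]"
            row[f"PP_{label}"] = f"{p.statistic:.3f}{'*' if p.reject_null else ''} ({p.lag_or_bandwidth})"
            row[f"KPSS_{label}"] = f"{k.statistic:.3f}{'*' if k.reject_null else ''} ({k.lag_or_bandwidth})"
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


def bounds_table(results: dict[str, BoundsTestResult], dummies: dict | None = None) -> pd.DataFrame:
    """One row per dependent variable, columns in the conventional order."""
    rows = []
    for dep, res in results.items():
        st, cv = res.statistics, res.critical_values
        ivs = ",".join(res.fit.spec.independents)
        dspec = res.fit.spec.dummies
        dlabel = "".join(f"d{y % 100:02d}" for y in (dspec.years if dspec else ()))
        rows.append({
            "DV|IV": f"{dep}|{ivs}",
            "Dummy variable": dlabel,
            "F": round(st.F_overall, 3), "F*": round(cv.f_star, 3),
            "T_dep": round(st.t_dep, 3), "T*_dep": round(cv.t_star, 3),
            "F_indep": round(st.F_indep, 3), "F*_indep": round(cv.f_indep_star, 3),
            "Result": res.outcome.label,
        })
    return pd.DataFrame(rows)


def _stage(stages: list, name: str, t0: float, **info) -> None:
    rec = {"stage": name, "seconds": round(time.perf_counter() - t0, 3), **info}
    stages.append(rec)
    log.info("stage %s done in %.2fs %s", name, rec["seconds"], info)


def run_country_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full four-table analysis described by ``config``.

    Refuses to proceed if any variable classifies as I(2+): the bounds test
    is valid for mixtures of I(0) and I(1) series only.
    """
    stages: list = []
    t0 = time.perf_counter()
    data = load_dataset(config.input, config.transforms, country=config.country)
    _stage(stages, "load", t0, n=data.n, variables=list(data.names))

    t0 = time.perf_counter()
    desc = descriptives_table(data)
    _stage(stages, "descriptives", t0)

    t0 = time.perf_counter()
    ur = unit_root_table(data, config.deterministic, config.alpha)
    integration = {s.name: classify_series(s, config.deterministic, config.alpha)
                   for s in data.series}
    bad = [name for name, c in integration.items() if not c.bounds_eligible]
    if bad:
        raise GatingError(
            f"variables {bad} classify as I(2+); the bounds test requires all "
            "series to be I(0) or I(1) — without I(2) variables"
        )
    _stage(stages, "unit_root", t0,
           orders={k: v.order for k, v in integration.items()})

    t0 = time.perf_counter()
    results: dict[str, BoundsTestResult] = {}
    rng = np.random.default_rng(config.seed)
    eq_seeds = rng.integers(0, 2**31 - 1, size=len(data.names))
    for i, dep in enumerate(data.names):
        others = tuple(v for v in data.names if v != dep)
        dspec = config.dummy_spec(dep)
        if config.lags.get("mode", "fixed") == "sic":
            mx = int(config.lags.get("max", 3))
            spec = select_lags(data, dep, others, range(1, mx + 1), range(1, mx + 1),
                               dummies=dspec)
        else:
            p = int(config.lags.get("p", 2))
            q = int(config.lags.get("q", 2))
            spec = ARDLSpec(dep, others, p=p, q=(q,) * len(others), dummies=dspec)
        results[dep] = bounds_test(data, spec, B=config.B, alpha=config.alpha,
                                   seed=int(eq_seeds[i]))
    bnd = bounds_table(results, config.dummies)
    _stage(stages, "bounds", t0, B=config.B,
           outcomes={k: v.outcome.label for k, v in results.items()})

    t0 = time.perf_counter()
    specs = {dep: res.fit.spec for dep, res in results.items()}
    outcomes = {dep: res.outcome for dep, res in results.items()}
    matrix = causality_matrix(data, specs, alpha=config.alpha, outcomes=outcomes)
    caus = pd.DataFrame([{
        "country": data.country, "equation": r.effect, "cause": r.cause,
        "horizon": r.horizon, "statistic": round(r.statistic, 4),
        "p_value": round(r.p_value, 4), "sign": r.sign, "significant": r.significant,
    } for r in matrix.results])
    digest = matrix.digest
    digest["bounds_outcomes"] = {k: v.outcome.label for k, v in results.items()}
    digest["integration_orders"] = {k: v.order for k, v in integration.items()}
    _stage(stages, "causality", t0, digest=digest)

    return ReportBundle(
        config=config, descriptives=desc, unit_root=ur, integration=integration,
        bounds=bnd, bounds_results=results, causality=caus, digest=digest,
        stages=stages,
    )


def render_tables(bundle: ReportBundle, outdir: str | Path | None = None,
                  fmt: str = "csv") -> list[Path]:
    """Write the four tables plus the digest. ``fmt``: 'csv' or 'text'."""
    if fmt not in ("csv", "text"):
        raise FormatError(f"unknown format {fmt!r}; use 'csv' or 'text'")
    out = Path(outdir or bundle.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "descriptives": bundle.descriptives,
        "unit_root": bundle.unit_root,
        "bounds": bundle.bounds,
        "causality": bundle.causality,
    }
    for name, df in tables.items():
        if fmt == "csv":
            p = out / f"{name}.csv"
            df.to_csv(p, index=name in ("descriptives", "unit_root"))
        else:
            p = out / f"{name}.txt"
            p.write_text(df.to_string() + "\n")
        written.append(p)
    p = out / "digest.json"
    p.write_text(json.dumps(bundle.digest, indent=2, sort_keys=True) + "\n")
    written.append(p)
    p = out / "stages.json"
    p.write_text(json.dumps(bundle.stages, indent=2) + "\n")
    written.append(p)
    return written
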