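"""Data containers, CSV I/O, transforms and descriptive statistics.

The package analyses short annual macro-health series (log GDP, life
expectancy at birth, per-capita alcohol consumption).  Everything downstream
operates on :class:`AnnualSeries` objects aligned into a :class:`Dataset`.

Descriptive statistics follow the econometric-software convention used in the
source tables: skewness and kurtosis are moment-based with divisor ``n``
(population central moments) and kurtosis is *non-excess*, so a normal sample
has kurtosis near 3 and the Jarque-Bera statistic is

    JB = n/6 * (S^2 + (K - 3)^2 / 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateDataError,
    DomainError,
    SizeError,
    SpecificationError,
)

__all__ = [
    "AnnualSeries",
    "Dataset",
    "DummySpec",
    "DescriptiveStats",
    "load_dataset",
    "first_difference",
    "descriptive_stats",
    "descriptives_table",
    "jarque_bera",
    "build_dummies",
]

#: minimum length accepted when a dataset enters the analysis pipeline
MIN_ANALYSIS_LENGTH = 10


@dataclass(frozen=True)
class AnnualSeries:
    """One annual time series on a level or natural-log scale.

    Parameters
    ----------
    name : str
        Variable identifier (e.g. ``"gdp"``).
    years : array-like of int
        Strictly consecutive calendar years.
    values : array-like of float
        Observations, finite; on log scale when ``transform == "log"``.
    transform : {"level", "log"}
        Provenance of the values.
    """

    name: str
    years: np.ndarray
    values: np.ndarray
    transform: str = "level"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.ndim != 1 or values.ndim != 1 or len(years) != len(values):
            raise SpecificationError("years and values must be 1-d and equally long")
        if len(years) < 2:
            raise SizeError(f"series {self.name!r} needs >= 2 observations, got {len(years)}")
        if np.any(np.diff(years) != 1):
            raise AlignmentError(f"series {self.name!r} has non-consecutive years")
        if not np.all(np.isfinite(values)):
            raise DomainError(f"series {self.name!r} contains non-finite values")
        if self.transform not in ("level", "log"):
            raise SpecificationError(f"unknown transform {self.transform!r}")

    def __len__(self) -> int:
        return len(self.years)

    def log(self) -> "AnnualSeries":
        """Natural log of a strictly positive level series."""
        if self.transform == "log":
            raise DomainError(f"series {self.name!r} is already on log scale")
        if np.any(self.values <= 0):
            raise DomainError(f"cannot log-transform non-positive values in {self.name!r}")
        return AnnualSeries(self.name, self.years, np.log(self.values), transform="log")

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.years, name="year"), name=self.name)


@dataclass(frozen=True)
class Dataset:
    """Aligned collection of :class:`AnnualSeries` for one country."""

    series: tuple[AnnualSeries, ...]
    country: str = ""

    def __post_init__(self) -> None:
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        if len(series) < 2:
            raise SpecificationError("a Dataset needs >= 2 series")
        ref = series[0].years
        for s in series[1:]:
            if len(s.years) != len(ref) or np.any(s.years != ref):
                raise AlignmentError(
                    f"series {s.name!r} window differs from {series[0].name!r}"
                )
        names = [s.name for s in series]
        if len(set(names)) != len(names):
            raise SpecificationError(f"duplicate series names: {names}")

    @property
    def years(self) -> np.ndarray:
        return self.series[0].years

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.series)

    @property
    def n(self) -> int:
        return len(self.series[0])

    def __getitem__(self, name: str) -> AnnualSeries:
        for s in self.series:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({s.name: s.values for s in self.series})
        df.insert(0, "year", self.years)
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class DummySpec:
    """Impulse dummies: an indicator equal to 1 in each named year, 0 elsewhere."""

    years: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        if len(set(years)) != len(years):
            raise SpecificationError(f"duplicate dummy years: {years}")
        object.__setattr__(self, "years", tuple(sorted(years)))

    @classmethod
    def from_label(cls, label: str, century_pivot: int = 50) -> "DummySpec":
        """Parse compact labels like ``"d03d07d11"`` into calendar years.

        Two-digit years are mapped to 19xx above ``century_pivot`` and 20xx
        at or below it (so ``d95`` -> 1995, ``d03`` -> 2003).
        """
        label = label.strip().lower()
        if not label:
            return cls(())
        parts = [p for p in label.split("d") if p]
        years = []
        for p in parts:
            v = int(p)
            if v < 100:
                v += 1900 if v > century_pivot else 2000
            years.append(v)
        return cls(tuple(years))


@dataclass(frozen=True)
class DescriptiveStats:
    """Summary row block mirroring the descriptives table of the analysis."""

    n: int
    mean: float
    median: float
    maximum: float
    minimum: float
    skewness: float
    kurtosis: float
    jarque_bera: float


def jarque_bera(skewness: float, kurtosis: float, n: int) -> float:
    """Jarque-Bera statistic from moment-based skewness S, non-excess kurtosis K.

    JB = n/6 * (S^2 + (K-3)^2/4), always >= 0.
    """
    return n / 6.0 * (skewness**2 + (kurtosis - 3.0) ** 2 / 4.0)


def descriptive_stats(s: AnnualSeries) -> DescriptiveStats:
    """Descriptive statistics with population-moment S and K (divisor ``n``)."""
    v = s.values
    n = len(v)
    if n < 4:
        raise SizeError(f"need >= 4 observations for moments, got {n}")
    m = v.mean()
    c = v - m
    m2 = np.mean(c**2)
    if m2 <= 0 or not np.isfinite(m2):
        raise DegenerateDataError(f"series {s.name!r} has zero variance")
    skew = float(np.mean(c**3) / m2**1.5)
    kurt = float(np.mean(c**4) / m2**2)
    return DescriptiveStats(
        n=n,
        mean=float(m),
        median=float(np.median(v)),
        maximum=float(v.max()),
        minimum=float(v.min()),
        skewness=skew,
        kurtosis=kurt,
        jarque_bera=jarque_bera(skew, kurt, n),
    )


def descriptives_table(data: Dataset) -> pd.DataFrame:
    """Descriptives for every series, rows labelled like the published table."""
    rows = ["Mean", "Median", "Maximum", "Minimum", "Skewness", "Kurtosis", "Jarque-Bera"]
    out = {}
    for s in data.series:
        d = descriptive_stats(s)
        out[s.name] = [d.mean, d.median, d.maximum, d.minimum, d.skewness, d.kurtosis, d.jarque_bera]
    return pd.DataFrame(out, index=pd.Index(rows, name="statistic"))


def first_difference(s: AnnualSeries) -> AnnualSeries:
    """First difference; output drops the first year."""
    if len(s) < 2:
        raise SizeError("need >= 2 observations to difference")
    return AnnualSeries(
        name=f"d_{s.name}",
        years=s.years[1:],
        values=np.diff(s.values),
        transform=s.transform,
    )


def load_dataset(
    path: str | Path,
    transforms: Mapping[str, str] | None = None,
    country: str = "",
    min_length: int = MIN_ANALYSIS_LENGTH,
) -> Dataset:
    """Load a tidy annual CSV (``year,<var1>,<var2>,...``) into a Dataset.

    Parameters
    ----------
    transforms : mapping variable -> {"level", "log"}
        Variables not named are kept on level scale.
    """
    transforms = dict(transforms or {})
    df = pd.read_csv(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "year" not in cols:
        raise SpecificationError(f"{path}: no 'year' column (found {cols})")
    value_cols = [c for c in cols if c != "year"]
    if len(value_cols) < 2:
        raise SpecificationError(f"{path}: need >= 2 value columns")
    unknown = set(transforms) - set(value_cols)
    if unknown:
        raise SpecificationError(f"transforms name unknown columns: {sorted(unknown)}")
    years = df["year"].to_numpy()
    if len(years) < min_length:
        raise SizeError(f"{path}: {len(years)} rows < minimum {min_length}")
    if np.any(np.diff(years) != 1):
        raise AlignmentError(f"{path}: year column has gaps or is unsorted")
    if df[value_cols].isna().any().any():
        raise AlignmentError(f"{path}: missing cells inside the year window")
    series = []
    for c in value_cols:
        s = AnnualSeries(c, years, df[c].to_numpy(dtype=float))
        if transforms.get(c, "level") == "log":
            s = s.log()
        series.append(s)
    return Dataset(tuple(series), country=country)


def build_dummies(
    d: DummySpec, window: Iterable[int], as_frame: bool = True
) -> pd.DataFrame | np.ndarray:
    """Impulse-dummy indicator matrix over ``window`` (one column per year).

    Every column sums to exactly 1; a year outside the window is a
    specification error.
    """
    years = np.asarray(list(window), dtype=np.int64)
    outside = [y for y in d.years if y not in years]
    if outside:
        raise SpecificationError(f"dummy years outside estimation window: {outside}")
    mat = np.zeros((len(years), len(d.years)))
    for j, y in enumerate(d.years):
        mat[years == y, j] = 1.0
    if as_frame:
        return pd.DataFrame(mat, index=pd.Index(years, name="year"),
                            columns=[f"D{y}" for y in d.years])
    return mat
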