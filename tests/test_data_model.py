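import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from bardl import (
    AnnualSeries,
    Dataset,
    DummySpec,
    build_dummies,
    descriptive_stats,
    first_difference,
    jarque_bera,
    load_dataset,
)
from bardl.exceptions import (
    AlignmentError,
    DegenerateDataError,
    DomainError,
    SizeError,
    SpecificationError,
)
from conftest import TABLE1, TABLE1_N


@pytest.mark.parametrize("column", sorted(TABLE1))
def test_jarque_bera_matches_published_cells(column):
    """JB = n/6 (S^2 + (K-3)^2/4) reproduces every printed cell at n=19."""
    s, k, jb = TABLE1[column]
    assert jarque_bera(s, k, TABLE1_N) == pytest.approx(jb, abs=1e-5)


def test_jarque_bera_zero_for_exact_normal_moments():
    assert jarque_bera(0.0, 3.0, 19) == 0.0


def test_descriptive_stats_population_moment_convention(rng):
    """Skewness/kurtosis use divisor-n central moments, kurtosis non-excess."""
    v = rng.gamma(2.0, size=40)
    s = AnnualSeries("x", np.arange(1980, 2020), v)
    d = descriptive_stats(s)
    assert d.skewness == pytest.approx(scipy.stats.skew(v, bias=True), rel=1e-12)
    assert d.kurtosis == pytest.approx(
        scipy.stats.kurtosis(v, fisher=False, bias=True), rel=1e-12
    )
    assert d.minimum <= d.median <= d.maximum
    assert d.jarque_bera == pytest.approx(
        jarque_bera(d.skewness, d.kurtosis, d.n), rel=1e-12
    )


def test_descriptive_stats_rejects_constant_series():
    s = AnnualSeries("c", np.arange(2000, 2012), np.full(12, 3.0))
    with pytest.raises(DegenerateDataError):
        descriptive_stats(s)


def test_first_difference_basic():
    s = AnnualSeries("x", [2000, 2001, 2002], [1.0, 3.0, 6.0])
    d = first_difference(s)
    assert d.values.tolist() == [2.0, 3.0]
    assert d.years.tolist() == [2001, 2002]


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=40))
def test_first_difference_inverts_cumulative_sum(increments):
    """Differencing the cumulative sum recovers the increments exactly."""
    inc = np.asarray(increments)
    levels = np.concatenate([[0.0], np.cumsum(inc)])
    s = AnnualSeries("x", np.arange(1900, 1900 + len(levels)), levels)
    d = first_difference(s)
    np.testing.assert_allclose(d.values, inc, rtol=0, atol=1e-6 * (1 + np.abs(inc).max()))


def test_annual_series_invariants():
    with pytest.raises(AlignmentError):
        AnnualSeries("x", [2000, 2002, 2003], [1.0, 2.0, 3.0])
    with pytest.raises(DomainError):
        AnnualSeries("x", [2000, 2001], [1.0, np.nan])
    with pytest.raises(SizeError):
        AnnualSeries("x", [2000], [1.0])
    with pytest.raises(DomainError):
        AnnualSeries("x", [2000, 2001], [0.0, 1.0]).log()


def test_dataset_requires_common_window():
    a = AnnualSeries("a", np.arange(2000, 2012), np.arange(12.0))
    b = AnnualSeries("b", np.arange(2001, 2013), np.arange(12.0))
    with pytest.raises(AlignmentError):
        Dataset((a, b))


def _write_csv(path, years, cols):
    import pandas as pd

    df = pd.DataFrame({"year": years, **cols})
    df.to_csv(path, index=False)


def test_load_dataset_applies_transforms(tmp_path):
    p = tmp_path / "c.csv"
    years = np.arange(1992, 2016)
    gdp = np.exp(np.linspace(9.0, 11.1, 24))
    _write_csv(p, years, {"gdp": gdp, "le": np.linspace(70.6, 76.0, 24),
                          "alc": np.linspace(2.9, 5.8, 24)})
    d = load_dataset(p, {"gdp": "log"}, country="china")
    assert d["gdp"].transform == "log"
    np.testing.assert_allclose(d["gdp"].values, np.log(gdp))
    assert d["le"].transform == "level"
    assert d.n == 24 and d.country == "china"


def test_load_dataset_errors(tmp_path):
    years = np.concatenate([np.arange(1992, 2004), np.arange(2005, 2017)])  # 2004 missing
    p = tmp_path / "gap.csv"
    _write_csv(p, years, {"a": np.arange(24.0), "b": np.arange(24.0) + 1})
    with pytest.raises(AlignmentError):
        load_dataset(p)
    p2 = tmp_path / "neg.csv"
    _write_csv(p2, np.arange(1992, 2016), {"a": np.linspace(-1, 1, 24), "b": np.ones(24)})
    with pytest.raises(DomainError):
        load_dataset(p2, {"a": "log"})
    # constant column loads fine; rejection happens downstream
    p3 = tmp_path / "const.csv"
    _write_csv(p3, np.arange(1992, 2016), {"a": np.ones(24), "b": np.arange(24.0)})
    assert load_dataset(p3).n == 24


def test_build_dummies_columns_sum_to_one():
    spec = DummySpec((2003, 2007, 2011))
    m = build_dummies(spec, range(1992, 2016))
    assert m.shape == (24, 3)
    np.testing.assert_array_equal(m.sum(axis=0).to_numpy(), [1.0, 1.0, 1.0])


def test_build_dummies_empty_and_errors():
    assert build_dummies(DummySpec(()), range(1992, 2016)).shape == (24, 0)
    with pytest.raises(SpecificationError):
        build_dummies(DummySpec((1980,)), range(1992, 2016))
    with pytest.raises(SpecificationError):
        DummySpec((2003, 2003))


def test_dummy_label_parsing():
    assert DummySpec.from_label("d03d07d11").years == (2003, 2007, 2011)
    assert DummySpec.from_label("d95d00d06").years == (1995, 2000, 2006)
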