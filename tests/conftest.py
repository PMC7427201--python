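import numpy as np
import pytest

from bardl import AnnualSeries, Dataset


# Published descriptives block (n = 19 annual observations per column):
# skewness, non-excess kurtosis, Jarque-Bera as printed.
TABLE1 = {
    "GDP_CHINA": (0.060023, 1.550272, 1.675264),
    "GDP_INDIA": (0.154473, 1.694879, 1.424040),
    "LE_CHINA": (-0.448266, 1.936737, 1.531319),
    "LE_INDIA": (-0.008901, 1.801810, 1.136814),
    "ALC_CHINA": (-0.133630, 1.325313, 2.276837),
    "ALC_INDIA": (0.177633, 1.504744, 1.869921),
}
TABLE1_N = 19

# Published bounds-test grid: (F, t_dep, F_indep), their bootstrap critical
# values (F*, t*, F_indep*), and the printed verdict.
TABLE3 = [
    ("GDP_CHINA", (6.730, -4.223, 10.020), (2.917, -1.203, 3.228), "COINTEGRATION"),
    ("LE_CHINA", (4.278, -1.490, 1.014), (3.058, -1.003, 3.412), "DEGENERATE_2"),
    ("ALC_CHINA", (2.977, -0.439, 2.963), (3.083, -1.809, 3.365), "NO_COINTEGRATION"),
    ("GDP_INDIA", (8.267, -4.795, 12.186), (4.278, -2.651, 4.603), "COINTEGRATION"),
    ("LE_INDIA", (3.264, -1.020, 1.795), (3.772, -1.678, 3.980), "NO_COINTEGRATION"),
    ("ALC_INDIA", (2.977, -0.439, 2.963), (3.083, -1.809, 3.365), "NO_COINTEGRATION"),
]


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_walk_dataset(rng):
    """Three independent random walks, n=60 — a no-cointegration system."""
    n = 60
    years = np.arange(1960, 1960 + n)
    vals = np.cumsum(rng.standard_normal((3, n)), axis=1)
    return Dataset(
        tuple(AnnualSeries(name, years, 10.0 + v)
              for name, v in zip(("gdp", "le", "alc"), vals)),
        country="testland",
    )
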