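import numpy as np
import pandas as pd
import pytest

from iprp.cohort_io import ClinicalTable, Cohort, ExpressionMatrix


@pytest.fixture
def tiny_expr() -> ExpressionMatrix:
    """3 genes x 4 samples with known orderings."""
    data = pd.DataFrame(
        {
            "s1": [5.0, 3.0, 1.0],
            "s2": [2.0, 2.0, 4.0],
            "s3": [1.0, 6.0, 2.0],
            "s4": [3.0, 3.0, 3.0],
        },
        index=["GA", "GB", "GC"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_clinical() -> ClinicalTable:
    data = pd.DataFrame(
        {
            "os_time": [100.0, 250.0, 400.0, 30.0],
            "os_event": [1, 0, 1, 1],
            "age": [55.0, 60.0, 70.0, 48.0],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return ClinicalTable(data)


@pytest.fixture
def tiny_cohort(tiny_expr, tiny_clinical) -> Cohort:
    return Cohort("tiny", tiny_expr, tiny_clinical)


def make_survival(rng: np.random.Generator, lp: np.ndarray, censor_frac: float = 0.3,
                  scale: float = 1000.0, shape: float = 1.2):
    """Weibull proportional-hazards survival draw used by several tests."""
    n = len(lp)
    u = rng.uniform(size=n)
    T = scale * (-np.log(u) / np.exp(lp)) ** (1.0 / shape)
    if censor_frac > 0:
        C = rng.exponential(np.quantile(T, 1 - censor_frac / 2), size=n)
    else:
        C = np.full(n, np.inf)
    return np.minimum(T, C), (T <= C).astype(int)
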