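import numpy as np
import pandas as pd
import pytest

from candeqtl import (
    CovariateTable,
    ExpressionMatrix,
    GenotypeTable,
    SimulationConfig,
    simulate_cohort,
)
from candeqtl.qcnorm import SCALE_LOG2


@pytest.fixture
def small_cohort():
    """74+47 synthetic cohort, 40 probes, one planted effect on probe 0."""
    config = SimulationConfig(
        n_probes=40,
        planted_effects=[("rs10098821", 0, 0.3)],
        detection_miss_rate=0.02,
        seed=42,
    )
    expr, geno, cov = simulate_cohort(config)
    return config, expr, geno, cov


@pytest.fixture
def log2_matrix():
    """Tiny hand-checkable log2-scale expression matrix with detection Ps."""
    intensities = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2"],
    )
    detection = pd.DataFrame(
        0.01, index=intensities.index, columns=intensities.columns
    )
    return ExpressionMatrix(
        intensities=intensities, detection_p=detection, scale_flag=SCALE_LOG2
    )


@pytest.fixture
def toy_genotypes():
    codes = pd.DataFrame(
        {"snpA": [0.0, 0, 1, 1, 2, 2], "snpB": [1.0, 1, 1, 1, 1, 1]},
        index=[f"s{i}" for i in range(6)],
    )
    return GenotypeTable(codes=codes)


@pytest.fixture
def toy_covariates():
    table = pd.DataFrame(
        {
            "age": [30.0, 40, 50, 60, 70, 80],
            "status": ["case", "case", "case", "control", "control", "control"],
        },
        index=[f"s{i}" for i in range(6)],
    )
    return CovariateTable(table=table)
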