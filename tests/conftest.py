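import numpy as np
import pandas as pd
import pytest

from bmsr import (
    ExpressionMatrix,
    LogLogisticFit,
    SimConfig,
    simulate_multisource,
)
from bmsr.preprocess import harmonize_sources


@pytest.fixture(scope="session")
def small_multisource():
    """Two harmonized sources with 4 active genes out of 80 (fast fits)."""
    cfg = SimConfig(
        n_sources=2,
        n_samples_per_source=(60, 40),
        n_genes=80,
        n_active=4,
        effect_sd=1.0,
        target_r2=0.5,
        seed=3,
    )
    sources, truth = simulate_multisource(cfg)
    harm = harmonize_sources(
        [ExpressionMatrix(s.X.T, dataset_id=s.source_id) for s in sources],
        [s.y for s in sources],
    )
    return harm, truth


@pytest.fixture
def ll4_params():
    """A well-behaved inhibition curve: 0 -> 100 %, inflection 0.1 uM."""
    return LogLogisticFit(
        model="LL4", b=-1.0, c=0.0, d=100.0, e=0.1, rss=0.0, converged=True
    )


@pytest.fixture
def seven_doses():
    """Seven half-log doses spanning 1e-3..1 uM."""
    return list(10.0 ** np.linspace(-3, 0, 7))


@pytest.fixture
def toy_expression():
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(10)]
    samples = [f"s{j}" for j in range(6)]
    return ExpressionMatrix(
        pd.DataFrame(
            rng.normal(size=(10, 6)), index=genes, columns=samples
        ),
        dataset_id="toy",
    )
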