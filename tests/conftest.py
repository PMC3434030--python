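import numpy as np
import pandas as pd
import pytest

from strainarray.io import ExpressionMatrix, SampleInfo
from strainarray.simulate import SimulationConfig, generate_probe_level_dataset


@pytest.fixture(scope="session")
def samples16() -> list[SampleInfo]:
    """The 4-strain x 2-sex x 2-pool study design (16 samples)."""
    from strainarray.simulate import _make_samples

    return _make_samples(SimulationConfig())


@pytest.fixture(scope="session")
def small_dataset():
    """A 120-probe-set synthetic dataset plus its planted truth."""
    return generate_probe_level_dataset(SimulationConfig(n_probesets=120, seed=11))


def make_expression(values: np.ndarray, sample_ids=None, prefix: str = "g") -> ExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(values.shape[0])],
            columns=list(sample_ids),
        )
    )
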