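import numpy as np
import pandas as pd
import pytest

from diffcornet import SimulationConfig, generate_study
from diffcornet.tables import MISSING, QUANTIFIED, SampleTable


def make_table(values, groups, statuses=None, covariates=None):
    """Assemble a SampleTable from plain arrays for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    index = pd.Index([f"S{k:03d}" for k in range(n)], name="sample_id")
    names = [f"M{k:03d}" for k in range(m)]
    rng = np.random.default_rng(0)
    meta = pd.DataFrame(
        {
            "group": groups,
            "age": covariates["age"] if covariates else rng.normal(50, 10, n),
            "bmi": covariates["bmi"] if covariates else rng.normal(29, 5, n),
            "activity": covariates["activity"] if covariates else rng.normal(8, 1.5, n),
            "menarche_age": covariates["menarche_age"] if covariates else rng.normal(13, 2, n),
        },
        index=index,
    )
    vals = pd.DataFrame(values, index=index, columns=names)
    if statuses is None:
        status = pd.DataFrame(QUANTIFIED, index=index, columns=names)
        status = status.where(~vals.isna(), MISSING)
    else:
        status = pd.DataFrame(np.asarray(statuses), index=index, columns=names)
    vals = vals.where(status == QUANTIFIED)
    return SampleTable(meta, vals, status)


@pytest.fixture(scope="session")
def small_study():
    """A 20-metabolite planted study at the default cohort sizes."""
    config = SimulationConfig(
        n_metabolites=20,
        shared_blocks=[(5, 0.5)],
        differential_pairs=[(14, 15, 0.7, 0.0), (16, 17, 0.0, 0.7)],
        seed=42,
    )
    return generate_study(config)


@pytest.fixture(scope="session")
def toy_table():
    """4 metabolites x 8 samples of continuous data, no degeneracies."""
    rng = np.random.default_rng(7)
    return make_table(
        np.exp(rng.normal(1.0, 0.5, size=(8, 4))),
        groups=["pre"] * 4 + ["post"] * 4,
    )
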