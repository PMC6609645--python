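import numpy as np
import pandas as pd
import pytest

from metmap import preprocess, synthdata
from metmap.synthdata import CohortSpec, EffectSpec, MissingnessSpec


@pytest.fixture(scope="session")
def cohort():
    """Default 17/13/13 donor cohort."""
    return synthdata.generate_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def small_annotation():
    """Compact two-platform annotation (30 + 30 metabolites)."""
    return synthdata.generate_annotation(n_gc=30, n_lc=30, seed=7)


@pytest.fixture(scope="session")
def null_dataset(cohort, small_annotation):
    """No planted effects, default left-censored missingness, one tissue."""
    return synthdata.generate_intensities(
        cohort, small_annotation, effects=EffectSpec(),
        missing=MissingnessSpec(0.15, 0.8), seed=7, tissues=("muscle",))


@pytest.fixture(scope="session")
def muscle_scaled(null_dataset):
    gc = null_dataset.intensity_tables[("muscle", "GC-MS")]
    lc = null_dataset.intensity_tables[("muscle", "LC-MS")]
    return preprocess.preprocess_tissue(gc, lc)


def make_intensity_frame(values, metabolites=None, samples=None):
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return pd.DataFrame(
        values,
        index=metabolites or [f"M{i}" for i in range(m)],
        columns=samples or [f"S{j}" for j in range(n)],
    )
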