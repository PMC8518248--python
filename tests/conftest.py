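import numpy as np
import pandas as pd
import pytest

from triomics.containers import ExpressionMatrix
from triomics.simulate import SyntheticConfig, generate_cohort, generate_multiomic


@pytest.fixture(scope="session")
def tiny_config():
    """Down-scaled cohort for fast unit tests."""
    return SyntheticConfig(
        n_disease=20,
        n_control=12,
        n_serum_dropout_disease=1,
        n_serum_dropout_control=1,
        n_proteins=120,
        n_censored_proteins=10,
        n_transcripts_pbc=150,
        n_transcripts_skin=150,
        frac_mapped_pbc=0.4,
        frac_mapped_skin=0.5,
        n_de_serum=20,
        n_de_pbc=15,
        n_de_skin=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config):
    subjects = generate_cohort(tiny_config)
    serum, llod, pbc, pbc_det, skin, skin_det, fmap, truth = generate_multiomic(
        subjects, tiny_config
    )
    return {
        "subjects": subjects,
        "serum": serum,
        "llod": llod,
        "pbc": pbc,
        "pbc_det": pbc_det,
        "skin": skin,
        "skin_det": skin_det,
        "fmap": fmap,
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, layer="serum", features=None, samples=None):
    values = np.asarray(values, float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), layer)
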