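import numpy as np
import pandas as pd
import pytest

from algalipid.catalog import (
    build_theoretical_catalog,
    load_class_catalog,
    load_reference_species,
)


@pytest.fixture(scope="session")
def class_defs():
    return load_class_catalog()


@pytest.fixture(scope="session")
def reference_rows():
    return load_reference_species()


@pytest.fixture(scope="session")
def theoretical_catalog(class_defs):
    return build_theoretical_catalog(class_defs)


@pytest.fixture(scope="session")
def fa_reference_profile():
    """Packaged seasonal total-FA weight-percent profile (fa x columns)."""
    from importlib import resources
    from pathlib import Path

    path = Path(resources.files("algalipid.data") / "fa_seasonal_profile.tsv")
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
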