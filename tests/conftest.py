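import warnings

import numpy as np
import pandas as pd
import pytest

from omixplain.simulate import simulate_cohort
from omixplain.tables import FeatureTable, PhenotypeTable


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-animal four-layer cohort with the default planted fractions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(11)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose phenotype carries no omics signal (all fractions zero)."""
    fractions = {k: 0.0 for k in ("taxa", "function", "rumen_metabolome", "serum_metabolome")}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(12, true_fractions=fractions)


def make_feature_table(values, layer_kind="taxa", value_kind="count", meta=None,
                       sample_prefix="s", feature_prefix="f"):
    values = np.asarray(values, dtype=float)
    n, q = values.shape
    df = pd.DataFrame(
        values,
        index=[f"{sample_prefix}{i + 1}" for i in range(n)],
        columns=[f"{feature_prefix}{j + 1}" for j in range(q)],
    )
    return FeatureTable(df, layer_kind, value_kind, meta)


def make_phenotype(mpy, parity=None, dim=None, group=None):
    mpy = np.asarray(mpy, dtype=float)
    n = mpy.size
    data = {
        "mpy": mpy,
        "parity": parity if parity is not None else np.ones(n, dtype=int),
        "dim": dim if dim is not None else np.full(n, 100),
    }
    if group is not None:
        data["group"] = group
    return PhenotypeTable(pd.DataFrame(data, index=[f"s{i + 1}" for i in range(n)]))
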