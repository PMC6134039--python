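import numpy as np
import pandas as pd
import pytest

from metaboflow.core import AbundanceTable
from metaboflow.differential import classify_table, differential_table
from metaboflow.synthetic import default_paper_config, generate


def make_table(
    values,
    metabolites=None,
    mode="cation",
    compartment="intestine",
    standards=None,
    replicates=None,
):
    """Small AbundanceTable helper: ``values`` is metabolites x samples
    (3 control then 3 probiotic columns unless ``replicates`` given)."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    reps = replicates or n_cols // 2
    cols = [
        f"{compartment}_{g}_{r + 1}"
        for g in ("control", "probiotic")
        for r in range(reps)
    ]
    if metabolites is None:
        metabolites = [f"met_{i + 1:02d}" for i in range(n_rows)]
    if standards is None:
        standards = np.ones(n_cols)
    data = pd.DataFrame(values, index=pd.Index(metabolites, name="metabolite"),
                        columns=cols)
    return AbundanceTable(mode, compartment, data,
                          pd.Series(standards, index=cols))


@pytest.fixture(scope="session")
def default_study():
    """The default planted fixture at seed 42, with separability verified."""
    config = default_paper_config(seed=42)
    bundle, truth = generate(config, verify_separability=True)
    return config, bundle, truth


@pytest.fixture(scope="session")
def default_diffs(default_study):
    """Classified differential tables for intestine and serum."""
    _, bundle, _ = default_study
    normalized = bundle.normalized()
    out = {}
    for compartment in ("intestine", "serum"):
        diff = differential_table(normalized, compartment)
        out[compartment], _ = classify_table(diff)
    return normalized, out
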