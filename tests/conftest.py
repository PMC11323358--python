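import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import branchtf as bt

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_branch():
    """A 600-cell, 80-gene branch with 3 planted linear regulons and 3 outlier cells."""
    spec = bt.SyntheticSpec(
        n_cells=600, n_genes=80, n_tfs=3, targets_per_tf=8,
        relation="linear", effect=0.9, outlier_cells=3, seed=1,
    )
    branch, regulons, metadata, truth = bt.generate_branch(spec)
    return spec, branch, regulons, metadata, truth


@pytest.fixture(scope="session")
def smoothed_small(small_branch):
    """Smoothed gene-by-bin profiles for the small planted branch."""
    _, branch, regulons, _, _ = small_branch
    focused, _ = bt.focus_branch(branch)
    qc = bt.BranchQC(branch.branch_id, 16, 0.5, 0.0, 0.05, True)
    values = bt.smooth_branch(focused, qc)
    return pd.DataFrame(values, index=focused.gene_ids), regulons


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
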