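"""Shared fixtures: one small synthetic study reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from acetylstoich import StudyConfig, make_study, quantify_study


@pytest.fixture(scope="session")
def small_study():
    """A 50-site, 3-group study at the default noise settings."""
    cfg = StudyConfig(n_proteins=20, n_sites=50, seed=7)
    return make_study(cfg)


@pytest.fixture(scope="session")
def small_quantified(small_study):
    return quantify_study(small_study.quant, small_study.sequences)


@pytest.fixture(scope="session")
def noise_free_study():
    """Perfect chemistry: CV=0, full labeling, no missingness."""
    cfg = StudyConfig(
        n_proteins=15,
        n_sites=40,
        cv=0.0,
        labeling_efficiency=1.0,
        missing_rate=0.0,
        seed=11,
    )
    return make_study(cfg)


def truth_long(truth: pd.DataFrame, groups) -> pd.DataFrame:
    """Truth table melted to (protein_id, site_position, group, s_true)."""
    long = truth.melt(
        id_vars=["protein_id", "site_position", "effect_flag"],
        value_vars=[f"s_{g}" for g in groups],
        var_name="sg",
        value_name="s_true",
    )
    long["group"] = long["sg"].str.slice(2)
    return long[["protein_id", "site_position", "group", "s_true"]]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230909)
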