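import warnings

import numpy as np
import pandas as pd
import pytest

from blastoderm_atlas import (
    CohortConfig,
    EmbryoProfile,
    make_cohort,
    make_pattern_model,
)
from blastoderm_atlas.synthetic import evaluate_pattern


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Pipeline stages warn on benign conditions; keep test output clean."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def t8_config():
    return CohortConfig(classes=("T8",), n_embryos_per_class=4, seed=101)


@pytest.fixture(scope="session")
def t8_cohort(t8_config):
    return make_cohort(t8_config)


@pytest.fixture(scope="session")
def clean_t8_profile():
    """One noiseless, jitter-free, background-free T8 embryo."""
    cfg = CohortConfig(
        classes=("T8",), n_embryos_per_class=1, seed=7,
        noise_sigma=0.0, jitter_scale=0.0, jitter_offset=0.0,
        position_jitter=0.0, background=(0.0, 0.0, 0.0),
    )
    cohort, ledger = make_cohort(cfg)
    return cohort[0]


def synthetic_profile(x, y=None, intensities=None, embryo_id="e0", **meta) -> EmbryoProfile:
    """Hand-built per-nucleus profile for operator-level tests."""
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, 50.0) if y is None else np.asarray(y, dtype=float)
    data = {"nucleus_id": np.arange(len(x)), "x": x, "y": y}
    for ch, vals in (intensities or {}).items():
        data[f"I_{ch}"] = np.asarray(vals, dtype=float)
    return EmbryoProfile(embryo_id=embryo_id, data=pd.DataFrame(data), meta=meta)


def truth_positions(gene, time_class, species="clogmia"):
    """Analytic feature table of a preset pattern."""
    return make_pattern_model(gene, time_class, species).truth


def pattern_values(gene, time_class, x, species="clogmia"):
    return evaluate_pattern(make_pattern_model(gene, time_class, species), x)
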