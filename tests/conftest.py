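import warnings

import numpy as np
import pandas as pd
import pytest

from adipogrs.simulate import Locus, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Three-locus config with one real WCR effect and no noise."""
    loci = [
        Locus("rs0001", ("A", "G"), 0.3),
        Locus("rs0002", ("C", "T"), 0.2),
        Locus("rs0003", ("A", "C"), 0.4),
    ]
    return SimConfig(n_subjects=60, loci=loci, noise_sd={"WCR": 0.0, "TFATL": 0.0}, seed=7)


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Small simulated groups routinely trip the n<2 ANOVA drop warning."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="anova_screen: dropped", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message="build_design: dropped", category=UserWarning
        )
        yield


def make_cohort(n=60, seed=0, arm="MHP"):
    """Minimal analysis-ready cohort frame with nuisance covariates."""
    r = np.random.default_rng(seed)
    idx = pd.Index([f"S{i:04d}" for i in range(1, n + 1)], name="subject_id")
    return pd.DataFrame(
        {
            "sex": r.integers(0, 2, n),
            "age": r.uniform(25, 65, n),
            "weight": r.uniform(70, 110, n),
            "height": r.uniform(1.5, 1.9, n),
            "baseline_wc": r.uniform(85, 120, n),
            "baseline_tfat": r.uniform(30, 52, n),
            "mets": r.uniform(5, 60, n),
            "energy": r.uniform(1800, 4200, n),
            "adherence": r.integers(1, 4, n),
            "arm": arm,
        },
        index=idx,
    )
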