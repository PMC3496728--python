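import numpy as np
import pandas as pd
import pytest

from antclock import DEFAULT_ZT_GRID, generate_qpcr_dataset, study_config


@pytest.fixture(scope="session")
def zt_grid() -> np.ndarray:
    return np.asarray(DEFAULT_ZT_GRID, float)


@pytest.fixture(scope="session")
def study_ct() -> pd.DataFrame:
    """One simulated study-design dataset (3 colonies x 7 ZT x triplicates)."""
    return generate_qpcr_dataset(study_config(seed=11))


@pytest.fixture(scope="session")
def noiseless_ct() -> pd.DataFrame:
    """Same design with every noise source switched off."""
    return generate_qpcr_dataset(
        study_config(seed=0, colony_offset_sd=0.0, replicate_noise_sd=0.0)
    )


def tiny_ct_frame(rows):
    """Helper: build a Ct table from (gene, colony, zt, replicate, ct) tuples."""
    return pd.DataFrame(rows, columns=["gene", "colony", "zt", "replicate", "ct"])
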