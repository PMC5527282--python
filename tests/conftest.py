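import numpy as np
import pandas as pd
import pytest

from polarspec import synthetic
from polarspec.polarization import StrainPanel


def make_panel(baseline: dict, lps: dict, strains: list[str]) -> StrainPanel:
    """Build a one-replicate StrainPanel from per-gene value dicts."""
    base_cols = [f"{s}_b" for s in strains]
    lps_cols = [f"{s}_l" for s in strains]
    return StrainPanel(
        baseline=pd.DataFrame(baseline, index=base_cols).T,
        lps=pd.DataFrame(lps, index=lps_cols).T,
        baseline_cols={s: [c] for s, c in zip(strains, base_cols)},
        lps_cols={s: [c] for s, c in zip(strains, lps_cols)},
    )


@pytest.fixture(scope="session")
def default_panel():
    """One default-configuration synthetic panel with its ground truth."""
    return synthetic.generate_strain_panel(synthetic.PanelConfig(seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
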