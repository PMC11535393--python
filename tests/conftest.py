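import numpy as np
import pytest

import invivokinetics as ivk

MEDIUM_PANEL_S = np.geomspace(0.12, 20.78, 8)  # substrate levels of the medium-expression panel
TRUTH_VMAX = 849.0
TRUTH_K = 19.0


@pytest.fixture
def noiseless_dataset() -> ivk.KineticDataset:
    """Exact Michaelis-Menten data at the medium-expression design point."""
    s = np.repeat(MEDIUM_PANEL_S, 3)
    return ivk.KineticDataset(s, ivk.michaelis_menten(s, TRUTH_VMAX, TRUTH_K))


@pytest.fixture
def noisy_dataset() -> ivk.KineticDataset:
    """Seeded noisy panel at the same design point (additive rate noise)."""
    rng = np.random.default_rng(123)
    s = np.repeat(MEDIUM_PANEL_S, 3)
    v = np.clip(ivk.michaelis_menten(s, TRUTH_VMAX, TRUTH_K) + rng.normal(0, 40, s.size), 0, None)
    return ivk.KineticDataset(s, v)


@pytest.fixture
def crtb_panel_records():
    cfg = ivk.reference_presets()["crtB_medium"]
    return ivk.generate_strain_panel(cfg)
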