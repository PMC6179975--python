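import numpy as np
import pandas as pd
import pytest

import ricotype as rt

NOISELESS = rt.CurveConfig(smoothing_window=1)


@pytest.fixture(scope="session")
def noiseless_config():
    return NOISELESS


@pytest.fixture(scope="session")
def default_panel():
    """One synthetic study panel (19 retained variables) with true labels."""
    return rt.gen_feature_panel(rt.PanelSpec(), seed=7)


@pytest.fixture(scope="session")
def full_panel():
    """A 25-variable synthetic panel including the redundant block."""
    return rt.gen_feature_panel(rt.PanelSpec(include_redundant=True), seed=7)


@pytest.fixture(scope="session")
def ward_result(default_panel):
    panel, _ = default_panel
    return rt.ward_cluster(panel, k=3)


@pytest.fixture(scope="session")
def selected_model(default_panel, ward_result):
    """Forward-AIC multinomial logit fitted to the Ward labels."""
    panel, _ = default_panel
    return rt.forward_aic_select(panel, ward_result.labels)
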