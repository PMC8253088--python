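import logging
import warnings

import numpy as np
import pandas as pd
import pytest

import migexpress as mx

logging.getLogger("migexpress").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_screen():
    """One default synthetic screen, shared read-only across tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mx.simulate_screen(mx.SimulationSpec(seed=1))


@pytest.fixture(scope="session")
def default_analysis(default_screen):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mx.analyze_screen(default_screen)


def make_matrix(values, layer="rna", scale="linear", features=None, lines=None,
                detected=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"F{i}" for i in range(values.shape[0])]
    lines = lines or [f"L{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=features, columns=lines)
    det = None
    if detected is not None:
        det = pd.DataFrame(np.asarray(detected, dtype=bool), index=features,
                           columns=lines)
    return mx.OmicsMatrix(values=df, layer=layer, scale=scale, detected=det)
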