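import numpy as np
import pandas as pd
import pytest

from clpnet.panel import SymptomPanel
from clpnet.synthetic import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default-conditions synthetic panel (n=2000) with its ground truth."""
    return generate_panel(GeneratorConfig(n_participants=2000, seed=42))


@pytest.fixture(scope="session")
def small_panel():
    """Small 6-item panel for fast estimator-level tests."""
    return generate_panel(
        GeneratorConfig(n_participants=800, n_items=6, seed=7)
    )


def make_panel(wave1: np.ndarray, wave2: np.ndarray, scr1=None, scr2=None, **kw) -> SymptomPanel:
    """Assemble a SymptomPanel from raw item matrices."""
    n, p = np.asarray(wave1).shape
    labels = [f"iat{j + 1}" for j in range(p)]
    return SymptomPanel(
        ids=np.arange(1, n + 1),
        age=np.full(n, 14.0),
        gender=np.tile([0, 1], n)[:n],
        wave1_items=pd.DataFrame(np.asarray(wave1), columns=labels),
        wave2_items=pd.DataFrame(np.asarray(wave2), columns=labels),
        wave1_screener_total=np.zeros(n, dtype=int) if scr1 is None else scr1,
        wave2_screener_total=np.zeros(n, dtype=int) if scr2 is None else scr2,
        **kw,
    )
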