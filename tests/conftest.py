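import numpy as np
import pytest

from hcrquant.simulate import (CurveShape, FlowSimConfig, QpcrSimConfig,
                               simulate_flow_events, simulate_qpcr_plate)
from hcrquant.variants import example_reference


@pytest.fixture(scope="session")
def reference():
    return example_reference()


@pytest.fixture(scope="session")
def clean_plate():
    """Noiseless 6-well plate (RFP + GFP), efficiency 2, with ground truth."""
    cfg = QpcrSimConfig(
        wells=(("R1", "RFP", 1.0), ("R2", "RFP", 0.5), ("R3", "RFP", 0.125),
               ("G1", "GFP", 2.0), ("G2", "GFP", 1.0), ("G3", "GFP", 0.25)),
        true_efficiency=2.0, noise_sd=0.0, n_cycles=45, seed=0,
    )
    return simulate_qpcr_plate(cfg)


@pytest.fixture(scope="session")
def spillover_10pct():
    """10% GFP->RFP and 5% RFP->GFP cross-detection."""
    return np.array([[1.0, 0.05, 0.0],
                     [0.10, 1.0, 0.0],
                     [0.0, 0.0, 1.0]])


@pytest.fixture(scope="session")
def flow_events_mixed(spillover_10pct):
    cfg = FlowSimConfig(n_events=10_000, induced_fraction=0.7,
                        spillover=spillover_10pct, seed=42)
    events, labels = simulate_flow_events(cfg)
    return cfg, events, labels
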