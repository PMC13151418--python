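import numpy as np
import pytest

from nirsblock.core import ProbeLayout
from nirsblock.synthcohort import (
    DesignParams,
    NoiseParams,
    SimulationConfig,
)

# noise settings reused across tests ---------------------------------------

#: strictly silent forward model (no physiology, no artifacts, no instrument noise)
SILENT = NoiseParams(
    drift_amplitude=0.0,
    oscillations=(),
    white_noise_sd=0.0,
    motion_spike_rate=0.0,
    baseline_shift_rate=0.0,
    measurement_noise_sd=0.0,
)

#: silent physiology with a vanishing instrument-noise floor, so the
#: adaptive motion-detection threshold is well defined (see docs/methods.md)
NEAR_SILENT = NoiseParams(
    drift_amplitude=0.0,
    oscillations=(),
    white_noise_sd=0.0,
    motion_spike_rate=0.0,
    baseline_shift_rate=0.0,
    measurement_noise_sd=1e-4,
)


@pytest.fixture
def roi_layout() -> ProbeLayout:
    return ProbeLayout.standard(roi_only=True)


@pytest.fixture
def full_layout() -> ProbeLayout:
    return ProbeLayout.standard()


@pytest.fixture
def fast_config(roi_layout) -> SimulationConfig:
    """Small, deterministic simulation: 6 ROI channels, default design."""
    return SimulationConfig(n_participants=2, layout=roi_layout, seed=7)


@pytest.fixture
def fixed_design_params() -> DesignParams:
    """Deterministic schedule: fixed first condition, single baseline choice."""
    return DesignParams(first_condition_policy="fixed_HL", baseline_choices=(20.0,))
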