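"""Shared fixtures: the patient scenario and small Womersley ensembles."""

import numpy as np
import pytest

from haemokit.synthdata import (
    TubeSpec,
    patient_scenario,
    plane_field_ensemble,
    womersley_velocity,
)
from haemokit.waveforms import (
    WaveformSpec,
    adjust_period_to_frame_rate,
    synthesise_inlet_waveform,
)


@pytest.fixture(scope="session")
def scenario():
    return patient_scenario()


@pytest.fixture(scope="session")
def patient_waveform(scenario):
    """Inlet flow wave at the clinical parameters (T = 0.8 s)."""
    return scenario.inlet_waveform()


@pytest.fixture(scope="session")
def acquisition_waveform(scenario):
    """Inlet wave with the period stretched to the 22 Hz frame grid."""
    adj = adjust_period_to_frame_rate(scenario.waveform_spec.period, scenario.piv_frame_rate)
    spec = WaveformSpec(
        period=adj.t_exact, stroke_volume=scenario.waveform_spec.stroke_volume
    )
    return synthesise_inlet_waveform(spec)


@pytest.fixture(scope="session")
def inlet_tube(scenario):
    return TubeSpec(radius=scenario.inlet_diameter / 2.0, length=0.05)


@pytest.fixture(scope="session")
def womersley_evaluator(acquisition_waveform, inlet_tube, scenario):
    return womersley_velocity(acquisition_waveform, inlet_tube, scenario.fluid, n_harmonics=10)


@pytest.fixture(scope="session")
def clean_ensemble(womersley_evaluator, inlet_tube):
    """Noise-free 10-cycle ensemble; default transverse resolution (150 rows,
    which resolves the near-wall Womersley boundary layer), trimmed axially."""
    return plane_field_ensemble(
        womersley_evaluator, inlet_tube, grid_shape=(150, 40), n_cycles=10
    )


@pytest.fixture(scope="session")
def central_region(clean_ensemble):
    """5x5 block at the lumen centre, the convergence-evaluation region."""
    ny = len(clean_ensemble.frames[0].y)
    nx = len(clean_ensemble.frames[0].x)
    rr, cc = np.meshgrid(
        np.arange(ny // 2 - 2, ny // 2 + 3),
        np.arange(nx // 2 - 2, nx // 2 + 3),
        indexing="ij",
    )
    return rr.ravel(), cc.ravel()
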