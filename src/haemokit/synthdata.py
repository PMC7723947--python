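"""Seeded synthetic inputs: Womersley fields, ringing pressures, the patient fixture.

The stand-in geometry for all field generation is a straight rigid circular
tube, where the pulsatile Navier-Stokes solution is known in closed form
(Womersley). The evaluator decomposes the prescribed flow wave into Fourier
harmonics; the steady part carries a Poiseuille profile and each harmonic k
is the annular solution built from order-zero Bessel functions of complex
argument, normalised so its cross-section-integrated flow equals the
waveform's k-th Fourier coefficient exactly. The generated planar ensembles
(axial slice through the tube axis, sampled at a fixed frame rate) therefore
come with an exact analytical oracle: no-slip at the wall, and flow-rate
round trips limited only by the waveform's spectral content.

Measurement emulation adds i.i.d. Gaussian noise, spurious-vector outliers
with ground-truth labels, and per-cycle multiplicative gain variability; all
generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.special import jv

from .flowfield import CycleEnsemble, VelocityField2D
from .personalise import FluidProperties, TargetSet
from .waveforms import FlowWaveform, PressureWaveform, WaveformSpec, synthesise_inlet_waveform
from .windkessel import AorticNetwork, BranchSpec, WindkesselParams

__all__ = [
    "TubeSpec",
    "NoiseSpec",
    "ValveRingSpec",
    "NoisyEnsemble",
    "WomersleyEvaluator",
    "womersley_velocity",
    "plane_field_ensemble",
    "add_measurement_noise",
    "synth_pressure_with_ringing",
    "PatientScenario",
    "patient_scenario",
]


@dataclass(frozen=True)
class TubeSpec:
    """Straight circular tube standing in for the imaged vessel segment."""

    radius: float  # m
    length: float  # m
    axis_angle: float = 0.0  # rad, tube axis orientation in the imaging plane

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("radius and length must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic PIV-like ensembles.

    sigma: i.i.d. Gaussian noise SD per component (m/s). outlier_fraction of
    valid vectors are replaced by spurious vectors of magnitude
    outlier_amplitude x the ensemble peak speed, in a random direction.
    gain_sd is the SD of a per-cycle multiplicative gain (inter-cycle
    variability).
    """

    sigma: float = 0.03  # m/s
    outlier_fraction: float = 0.0
    outlier_amplitude: float = 5.0  # multiples of max speed
    gain_sd: float = 0.01  # relative
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or not 0 <= self.outlier_fraction < 1 or self.gain_sd < 0:
            raise ValueError("invalid noise specification")


@dataclass(frozen=True)
class ValveRingSpec:
    """Damped mechanical-valve ringing superimposed on pressure signals."""

    frequency: float = 20.0  # Hz
    decay: float = 0.05  # s
    amplitude: float = 8.0  # mmHg at the inlet station
    attenuation: float = 0.6  # per downstream station, in (0, 1]
    sampling_rate: float = 200.0  # Hz, acquisition rate of the pressure chain

    def __post_init__(self) -> None:
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation must be in (0, 1]")
        if self.frequency >= self.sampling_rate / 2:
            raise ValueError("ringing frequency must be below the Nyquist rate")


@dataclass(frozen=True)
class NoisyEnsemble:
    """Noisy ensemble plus ground-truth outlier labels per frame."""

    ensemble: CycleEnsemble
    outlier_masks: List[np.ndarray]


class WomersleyEvaluator:
    """Analytical pulsatile velocity u(r, t) in a rigid circular tube.

    Built from the first ``n_harmonics`` Fourier harmonics of the flow wave.
    ``alpha`` is the Womersley number of the fundamental harmonic.
    """

    def __init__(
        self,
        waveform: FlowWaveform,
        tube: TubeSpec,
        fluid: FluidProperties,
        n_harmonics: int = 10,
    ):
        if n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if n_harmonics >= waveform.n_samples // 2:
            raise ValueError("n_harmonics exceeds the waveform Nyquist limit")
        self.waveform = waveform
        self.tube = tube
        self.fluid = fluid
        self.n_harmonics = n_harmonics
        n = waveform.n_samples
        coeff = np.fft.rfft(waveform.flow) / n
        self.q0 = float(coeff[0].real) * 1e-6  # m^3/s
        self.qk = 2.0 * coeff[1 : n_harmonics + 1] * 1e-6  # complex, m^3/s
        self.omega = 2.0 * math.pi / waveform.period
        nu = fluid.viscosity / fluid.density
        self.alpha = tube.radius * math.sqrt(self.omega / nu)

    def _harmonic_profile(self, k: int, r: np.ndarray) -> np.ndarray:
        """Complex spatial profile of harmonic k with unit flow amplitude."""
        R = self.tube.radius
        alpha_k = self.alpha * math.sqrt(k)
        lam = 1j**1.5 * alpha_k
        j0_wall = jv(0, lam)
        shape = 1.0 - jv(0, lam * r / R) / j0_wall
        flow_factor = math.pi * R**2 * (1.0 - 2.0 * jv(1, lam) / (lam * j0_wall))
        return shape / flow_factor

    def __call__(self, r, t) -> np.ndarray:
        """Axial velocity (m/s) at radii ``r`` (m) and scalar time ``t`` (s)."""
        r = np.asarray(r, dtype=float)
        R = self.tube.radius
        u = 2.0 * self.q0 / (math.pi * R**2) * (1.0 - (r / R) ** 2)
        for k in range(1, self.n_harmonics + 1):
            phase = np.exp(1j * k * self.omega * t)
            u = u + (self.qk[k - 1] * self._harmonic_profile(k, r) * phase).real
        return np.where(np.abs(r) <= R, u, 0.0)

    def flow_rate(self, t) -> np.ndarray:
        """Prescribed flow (mL/s) carried by the truncated harmonic series."""
        t = np.asarray(t, dtype=float)
        q = np.full_like(t, self.q0, dtype=float)
        for k in range(1, self.n_harmonics + 1):
            q = q + (self.qk[k - 1] * np.exp(1j * k * self.omega * t)).real
        return q * 1e6

    def peak_speed(self, n_time: int = 64, n_radial: int = 200) -> float:
        """Max |u| over a dense (r, t) grid, used to scale outlier amplitudes."""
        r = np.linspace(0.0, self.tube.radius, n_radial)
        ts = np.linspace(0.0, self.waveform.period, n_time, endpoint=False)
        return float(max(np.abs(self(r, t)).max() for t in ts))


def womersley_velocity(
    waveform: FlowWaveform,
    tube: TubeSpec,
    fluid: FluidProperties,
    n_harmonics: int = 10,
) -> WomersleyEvaluator:
    """Build the analytical Womersley velocity evaluator for a flow wave."""
    return WomersleyEvaluator(waveform, tube, fluid, n_harmonics)


def plane_field_ensemble(
    evaluator: WomersleyEvaluator,
    tube: TubeSpec,
    grid_shape: Tuple[int, int] = (150, 200),
    frame_rate: float = 22.0,
    n_cycles: int = 10,
    margin: float = 0.1,
) -> CycleEnsemble:
    """Deterministic multi-cycle ensemble of axial-plane velocity frames.

    The imaging plane contains the tube axis: axial coordinate x in
    [0, length], transverse coordinate y in [-(1+margin) R, (1+margin) R];
    points with |y| > R are outside the lumen and masked invalid. Velocity
    is axial (u component), v = 0. Frame k is sampled at t = k / frame_rate.
    """
    ny, nx = grid_shape
    if ny < 4 or nx < 2:
        raise ValueError("degenerate grid")
    T = evaluator.waveform.period
    fpc = int(round(T * frame_rate))
    if fpc < 4:
        raise ValueError("fewer than 4 phases per cycle")
    R = tube.radius
    x = np.linspace(0.0, tube.length, nx)
    y = np.linspace(-(1.0 + margin) * R, (1.0 + margin) * R, ny)
    valid = np.abs(y)[:, None] <= R
    valid = np.broadcast_to(valid, (ny, nx)).copy()
    frames = []
    for c in range(n_cycles):
        for p in range(fpc):
            t = (c * fpc + p) / frame_rate
            u_col = evaluator(np.abs(y), t % T)
            u = np.repeat(u_col[:, None], nx, axis=1)
            frames.append(
                VelocityField2D(
                    x=x, y=y, u=u, v=np.zeros_like(u), valid=valid, phase=p, cycle=c
                )
            )
    return CycleEnsemble(frames=frames, frame_rate=frame_rate, period=fpc / frame_rate, n_cycles=n_cycles)


def add_measurement_noise(ensemble: CycleEnsemble, spec: NoiseSpec) -> NoisyEnsemble:
    """Add Gaussian noise, labelled outliers and inter-cycle gain to an ensemble.

    Pure function of (ensemble, spec): a fixed seed reproduces the output
    bit for bit. Masks and grid geometry are preserved exactly.
    """
    rng = np.random.default_rng(spec.seed)
    peak = max(float(np.abs(f.u).max()) for f in ensemble.frames) or 1.0
    peak = max(peak, max(float(np.abs(f.v).max()) for f in ensemble.frames))
    fpc = ensemble.frames_per_cycle
    gains = 1.0 + spec.gain_sd * rng.standard_normal(ensemble.n_cycles)
    frames = []
    masks = []
    for i, fr in enumerate(ensemble.frames):
        cyc = i // fpc
        u = fr.u * gains[cyc]
        v = fr.v * gains[cyc]
        if spec.sigma > 0:
            u = u + spec.sigma * rng.standard_normal(fr.u.shape)
            v = v + spec.sigma * rng.standard_normal(fr.v.shape)
        out_mask = np.zeros(fr.u.shape, dtype=bool)
        if spec.outlier_fraction > 0:
            cand = np.flatnonzero(fr.valid.ravel())
            n_out = int(round(spec.outlier_fraction * cand.size))
            if n_out:
                idx = rng.choice(cand, size=n_out, replace=False)
                out_mask.ravel()[idx] = True
                amp = spec.outlier_amplitude * peak
                theta = rng.uniform(0.0, 2.0 * math.pi, n_out)
                u = u.copy()
                v = v.copy()
                u.ravel()[idx] = amp * np.cos(theta)
                v.ravel()[idx] = amp * np.sin(theta)
        frames.append(replace(fr, u=u, v=v))
        masks.append(out_mask)
    noisy = CycleEnsemble(
        frames=frames,
        frame_rate=ensemble.frame_rate,
        period=ensemble.period,
        n_cycles=ensemble.n_cycles,
    )
    return NoisyEnsemble(ensemble=noisy, outlier_masks=masks)


def synth_pressure_with_ringing(
    base: PressureWaveform,
    spec: ValveRingSpec,
    systole_onset: float,
    systole_offset: float,
    station: int = 0,
) -> PressureWaveform:
    """Superimpose valve opening/closing ringing bursts on a pressure wave.

    Two exponentially damped sinusoids start at ``systole_onset`` (valve
    opening) and ``systole_offset`` (closing); the burst amplitude is
    attenuated by ``spec.attenuation ** station`` for downstream measurement
    stations, mimicking the decay of the oscillations along the flow
    direction.
    """
    T = base.period
    if not (0 <= systole_onset < T and 0 < systole_offset <= T):
        raise ValueError("onset/offset must lie inside the cycle")
    amp = spec.amplitude * spec.attenuation**station
    p = base.pressure.astype(float).copy()
    if amp > 0:
        t = base.time
        for t0 in (systole_onset, systole_offset):
            dt_ = t - t0
            burst = np.where(
                dt_ >= 0,
                amp * np.exp(-np.clip(dt_, 0, None) / spec.decay)
                * np.sin(2.0 * math.pi * spec.frequency * dt_),
                0.0,
            )
            p = p + burst
    return PressureWaveform(time=base.time, period=T, pressure=p)


@dataclass(frozen=True)
class PatientScenario:
    """The in-study patient fixture: targets, 3WK table, waveform and rig specs."""

    targets: TargetSet
    network: AorticNetwork
    waveform_spec: WaveformSpec
    fluid: FluidProperties
    piv_frame_rate: float  # Hz
    pressure_sampling_rate: float  # Hz
    inlet_diameter: float  # m, implied by the reported mean Reynolds number

    def inlet_waveform(self, dt: float = 1e-3) -> FlowWaveform:
        return synthesise_inlet_waveform(self.waveform_spec, dt=dt)


def patient_scenario() -> PatientScenario:
    """Byte-stable patient fixture used across tests and worked examples.

    Clinical targets: 150/80 mmHg, inlet mean flow 134.5 mL/s split
    BT 22.5 / LCC 8.9 / LSA 9.8 / DA 93.3 mL/s; cycle 0.8 s, stroke volume
    107.6 mL. Outlet 3WK reference parameters as used by the 3D model. The
    working fluid is the refractive-index-matched KSCN solution (rho = 1310
    kg/m^3, mu = 2.2 mPa s); the inlet diameter is backed out of the reported
    mean Reynolds number 3472 at the mean flow.
    """
    targets = TargetSet(
        p_sys=150.0,
        p_dia=80.0,
        branch_flows={"BT": 22.5, "LCC": 8.9, "LSA": 9.8, "DA": 93.3},
        q_inlet=134.5,
    )
    network = AorticNetwork(
        branches=[
            BranchSpec("BT", WindkesselParams(r1=0.25, r2=6.00, c=0.30)),
            BranchSpec("LCC", WindkesselParams(r1=0.63, r2=10.00, c=0.07)),
            BranchSpec("LSA", WindkesselParams(r1=0.57, r2=10.00, c=0.07)),
            BranchSpec("DA", WindkesselParams(r1=0.01, r2=1.15, c=0.30)),
        ]
    )
    fluid = FluidProperties(density=1310.0, viscosity=2.2e-3)
    re_mean = 3472.0
    q_mean_si = 134.5e-6
    diameter = 4.0 * fluid.density * q_mean_si / (math.pi * fluid.viscosity * re_mean)
    return PatientScenario(
        targets=targets,
        network=network,
        waveform_spec=WaveformSpec(period=0.8, mean_flow=134.5, stroke_volume=107.6),
        fluid=fluid,
        piv_frame_rate=22.0,
        pressure_sampling_rate=200.0,
        inlet_diameter=diameter,
    )
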