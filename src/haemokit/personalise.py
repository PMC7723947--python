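"""Patient-specific calibration of Windkessel outlets and flow-regime numbers.

Calibration tunes per-branch 3WK parameters so that the 0D network, driven by
the patient's inlet flow wave, reproduces the clinical systolic/diastolic
pressures and the measured division of cardiac output among the branches.

The procedure is a damped multiplicative fixed point:

* each branch total resistance is scaled by (achieved mean flow / target),
  which corrects the flow split;
* all resistances are scaled by (target MAP / achieved MAP), which sets the
  pressure level without disturbing the split;
* the total compliance is scaled by (achieved pulse pressure / target),
  which sets the pressure swing.

MAP is estimated as P_dia + PP/3 throughout. The loop is deterministic; it
terminates when pressures are within ``tol_p`` (mmHg) and every branch mean
flow within ``tol_q`` (relative), or after ``max_iterations``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .waveforms import FlowWaveform, waveform_stats
from .windkessel import AorticNetwork, BranchSpec, WindkesselParams, simulate_network

__all__ = [
    "TargetSet",
    "CalibrationConfig",
    "CalibrationResult",
    "FluidProperties",
    "FlowRegime",
    "initial_guess",
    "calibrate",
    "flow_regime",
]


@dataclass(frozen=True)
class TargetSet:
    """Clinical calibration targets: pressure extrema and branch mean flows."""

    p_sys: float  # mmHg
    p_dia: float  # mmHg
    branch_flows: Dict[str, float]  # mL/s by branch label
    q_inlet: float  # mL/s

    def __post_init__(self) -> None:
        if not self.p_sys > self.p_dia > 0:
            raise ValueError("require P_sys > P_dia > 0")
        if not self.branch_flows:
            raise ValueError("at least one branch target required")
        for lab, q in self.branch_flows.items():
            if q <= 0:
                raise ValueError(f"target flow for branch {lab!r} must be positive")
        total = sum(self.branch_flows.values())
        if abs(total - self.q_inlet) > 0.005 * self.q_inlet:
            raise ValueError(
                f"branch flows sum to {total} mL/s, inconsistent with inlet {self.q_inlet}"
            )

    @property
    def pulse_pressure(self) -> float:
        return self.p_sys - self.p_dia

    @property
    def map(self) -> float:
        return self.p_dia + self.pulse_pressure / 3.0


@dataclass(frozen=True)
class CalibrationConfig:
    r1_fraction: float = 0.05  # kappa: proximal share of total resistance
    venous_pressure: float = 0.0  # mmHg
    tol_p: float = 0.5  # mmHg on P_sys and P_dia
    tol_q: float = 0.005  # relative, per-branch mean flow
    max_iterations: int = 50
    dt: float = 1e-3  # s
    relaxation: float = 1.0  # update damping exponent in (0, 1]

    def __post_init__(self) -> None:
        if not 0 < self.r1_fraction < 0.5:
            raise ValueError("r1_fraction must lie in (0, 0.5)")
        if self.tol_p <= 0 or self.tol_q <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 < self.relaxation <= 1:
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class CalibrationResult:
    network: AorticNetwork
    achieved_p_sys: float
    achieved_p_dia: float
    achieved_flows: Dict[str, float]
    iterations: int
    converged: bool
    history: List[Dict[str, float]] = field(default_factory=list, repr=False)


@dataclass(frozen=True)
class FluidProperties:
    """Working-fluid properties (blood analogue): SI units."""

    density: float  # kg/m^3
    viscosity: float  # Pa·s (dynamic)

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


@dataclass(frozen=True)
class FlowRegime:
    re_mean: float
    re_peak: float
    womersley: float
    re_critical: float
    transitional: bool


def _build_network(
    labels: List[str],
    r_tot: np.ndarray,
    c_each: np.ndarray,
    kappa: float,
    p_v: float,
) -> AorticNetwork:
    branches = [
        BranchSpec(
            label=lab,
            wk=WindkesselParams(
                r1=kappa * rt, r2=(1.0 - kappa) * rt, c=float(ci)
            ),
        )
        for lab, rt, ci in zip(labels, r_tot, c_each)
    ]
    return AorticNetwork(branches=branches, venous_pressure=p_v)


def initial_guess(
    targets: TargetSet,
    waveform: FlowWaveform,
    config: CalibrationConfig = CalibrationConfig(),
) -> AorticNetwork:
    """Closed-form starting point for the calibration loop.

    Per branch, R_tot = (MAP - P_v)/Q-bar; total compliance SV/PP distributed
    proportionally to the target flows (higher-flow beds are more compliant).
    """
    labels = list(targets.branch_flows)
    q = np.array([targets.branch_flows[lab] for lab in labels])
    r_tot = (targets.map - config.venous_pressure) / q
    sv = waveform_stats(waveform).net_volume
    c_tot = sv / targets.pulse_pressure
    c_each = c_tot * q / q.sum()
    return _build_network(labels, r_tot, c_each, config.r1_fraction, config.venous_pressure)


def calibrate(
    targets: TargetSet,
    waveform: FlowWaveform,
    config: CalibrationConfig = CalibrationConfig(),
    network0: Optional[AorticNetwork] = None,
) -> CalibrationResult:
    """Tune the outlet Windkessels to the clinical target set.

    Deterministic multiplicative fixed-point iteration; each iteration runs
    the network to periodic steady state (warm-started from the previous
    iteration's capacitor states) and measures final-cycle haemodynamics.
    Non-convergence is reported via ``converged=False`` with the full error
    history attached.
    """
    labels = list(targets.branch_flows)
    net = network0 if network0 is not None else initial_guess(targets, waveform, config)
    if sorted(net.labels) != sorted(labels):
        raise ValueError("network0 branch labels do not match the target set")
    kappa = config.r1_fraction
    p_v = config.venous_pressure
    q_tgt = np.array([targets.branch_flows[lab] for lab in labels])
    lam = config.relaxation

    states = None
    history: List[Dict[str, float]] = []
    achieved: Dict[str, float] = {}
    p_sys = p_dia = math.nan
    converged = False
    iterations = 0
    for it in range(1, config.max_iterations + 1):
        iterations = it
        sim = simulate_network(
            net, waveform, dt=config.dt, max_cycles=60, tol=1e-4, initial_states=states
        )
        states = np.array([sim.capacitor_states[lab][-1] for lab in net.labels])
        p = sim.inlet_pressure.pressure
        p_sys, p_dia = float(p.max()), float(p.min())
        pp = p_sys - p_dia
        map_ach = p_dia + pp / 3.0
        q_ach = np.array([sim.branch_flows[lab].mean() for lab in net.labels])
        achieved = dict(zip(net.labels, map(float, q_ach)))

        err_p = max(abs(p_sys - targets.p_sys), abs(p_dia - targets.p_dia))
        err_q = float(np.abs(q_ach / q_tgt - 1.0).max())
        history.append(
            {
                "iteration": it,
                "p_sys": p_sys,
                "p_dia": p_dia,
                "err_p": err_p,
                "err_q": err_q,
            }
        )
        if err_p <= config.tol_p and err_q <= config.tol_q:
            converged = True
            break

        r_tot = np.array([b.wk.r_total + b.r_series for b in net.branches])
        c_each = np.array([b.wk.c for b in net.branches])
        flow_fac = (q_ach / q_tgt) ** lam
        level_fac = (targets.map / map_ach) ** lam
        pp_fac = (pp / targets.pulse_pressure) ** lam
        r_tot = r_tot * flow_fac * level_fac
        c_tot = c_each.sum() * pp_fac
        c_each = c_tot * q_tgt / q_tgt.sum()
        net = _build_network(list(net.labels), r_tot, c_each, kappa, p_v)

    return CalibrationResult(
        network=net,
        achieved_p_sys=p_sys,
        achieved_p_dia=p_dia,
        achieved_flows=achieved,
        iterations=iterations,
        converged=converged,
        history=history,
    )


def flow_regime(
    waveform: FlowWaveform,
    diameter: float,
    fluid: FluidProperties,
    transition_coefficient: float = 250.0,
) -> FlowRegime:
    """Reynolds and Womersley numbers of a pulsatile flow in a round vessel.

    Re = 4 rho Q / (pi mu D) at the mean and peak flow; Wo = (D/2)
    sqrt(2 pi rho / (T mu)); the transition threshold is Re_c = 250 Wo and
    the flow is flagged transitional when Re_peak exceeds it.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    stats = waveform_stats(waveform)
    q_mean = stats.mean * 1e-6  # mL/s -> m^3/s
    q_peak = stats.peak * 1e-6
    re = lambda q: 4.0 * fluid.density * q / (math.pi * fluid.viscosity * diameter)  # noqa: E731
    omega = 2.0 * math.pi / waveform.period
    wo = (diameter / 2.0) * math.sqrt(omega * fluid.density / fluid.viscosity)
    re_c = transition_coefficient * wo
    re_p = re(q_peak)
    return FlowRegime(
        re_mean=re(q_mean),
        re_peak=re_p,
        womersley=wo,
        re_critical=re_c,
        transitional=re_p > re_c,
    )
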