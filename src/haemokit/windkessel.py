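"""0D pulsatile simulation of a branched arterial network with 3WK outlets.

The network is a single zero-volume junction node fed by a prescribed inflow
Q_in(t); each branch carries an optional series connector resistance R_s and
terminates in a three-element Windkessel (proximal resistance R1, distal
resistance R2, compliance C) referenced to a venous pressure P_v.

State variables are the capacitor pressures P_c,i. At every instant the node
pressure solves the algebraic balance

    sum_i (P_ao - P_c,i) / (R1_i + R_s,i) = Q_in(t),

which makes the system linear time-invariant with input Q_in:

    C_i dP_c,i/dt = q_i - (P_c,i - P_v)/R2_i,   q_i = (P_ao - P_c,i)/(R1_i + R_s,i).

Time integration is classical fixed-step 4th-order Runge-Kutta. Because the
system is LTI, one RK4 step is an affine map x -> M x + r(t); M and the input
response matrices are precomputed once, so a cycle costs one small mat-vec
per step. Cycles are repeated until the inlet pressure trace is periodic.

Units follow the clinical convention used across the package: pressure mmHg,
flow mL/s, resistance mmHg·s/mL, compliance mL/mmHg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .exceptions import SolverError
from .waveforms import FlowWaveform, PressureWaveform

__all__ = [
    "WindkesselParams",
    "BranchSpec",
    "AorticNetwork",
    "SimulationResult",
    "PeriodicityCheck",
    "wk3_response",
    "simulate_network",
    "periodic_steady_state",
]


@dataclass(frozen=True)
class WindkesselParams:
    """Three-element Windkessel: R1 (proximal), R2 (distal), C (compliance)."""

    r1: float  # mmHg·s/mL
    r2: float  # mmHg·s/mL
    c: float  # mL/mmHg

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r2 <= 0 or self.c <= 0:
            raise ValueError("R1, R2 and C must all be positive")

    @property
    def tau(self) -> float:
        """Diastolic decay time constant R2*C in seconds."""
        return self.r2 * self.c

    @property
    def r_total(self) -> float:
        return self.r1 + self.r2


@dataclass(frozen=True)
class BranchSpec:
    label: str
    wk: WindkesselParams
    r_series: float = 0.0  # connector/tubing resistance, mmHg·s/mL

    def __post_init__(self) -> None:
        if self.r_series < 0:
            raise ValueError("series resistance must be non-negative")


@dataclass(frozen=True)
class AorticNetwork:
    branches: Sequence[BranchSpec]
    venous_pressure: float = 0.0  # mmHg

    def __post_init__(self) -> None:
        labels = [b.label for b in self.branches]
        if not labels:
            raise ValueError("network needs at least one branch")
        if len(set(labels)) != len(labels):
            raise ValueError("branch labels must be unique")

    @property
    def labels(self) -> List[str]:
        return [b.label for b in self.branches]


@dataclass
class SimulationResult:
    """Final-cycle series of a network simulation plus convergence history."""

    time: np.ndarray  # s, one cycle grid [0, T)
    period: float
    inlet_pressure: PressureWaveform
    inlet_flow: np.ndarray  # mL/s at the stored instants
    branch_flows: Dict[str, np.ndarray]  # mL/s
    branch_pressures: Dict[str, np.ndarray]  # mmHg, at the 3WK inlet
    capacitor_states: Dict[str, np.ndarray]  # mmHg
    cycles_run: int
    periodic: bool
    converged_at_cycle: Optional[int]
    cycle_history: List[np.ndarray] = field(default_factory=list, repr=False)

    def mean_branch_flows(self) -> Dict[str, float]:
        return {k: float(v.mean()) for k, v in self.branch_flows.items()}


@dataclass(frozen=True)
class PeriodicityCheck:
    converged: bool
    at_cycle: Optional[int]


def _rk4_matrices(A: np.ndarray, h: float):
    """Exact RK4 one-step operator for x' = A x + u(t).

    Returns (M, G0, Gm, G1) with x_{n+1} = M x_n + G0 u(t_n)
    + Gm u(t_n + h/2) + G1 u(t_n + h).
    """
    eye = np.eye(A.shape[0])
    hA = h * A
    hA2 = hA @ hA
    hA3 = hA2 @ hA
    hA4 = hA3 @ hA
    M = eye + hA + hA2 / 2.0 + hA3 / 6.0 + hA4 / 24.0
    B0 = eye + hA + hA2 / 2.0 + hA3 / 4.0
    Bm = 4.0 * eye + 2.0 * hA + hA2 / 2.0
    return M, (h / 6.0) * B0, (h / 6.0) * Bm, (h / 6.0) * eye


class _NetworkOperator:
    """Precomputed LTI step operator for a network at a fixed dt."""

    def __init__(self, network: AorticNetwork, dt: float):
        wk = [b.wk for b in network.branches]
        self.a = np.array([1.0 / (b.wk.r1 + b.r_series) for b in network.branches])
        self.S = self.a.sum()
        c = np.array([w.c for w in wk])
        r2 = np.array([w.r2 for w in wk])
        self.pv = network.venous_pressure
        m = len(wk)
        A = (np.outer(self.a, self.a) / self.S) / c[:, None]
        A -= np.diag(self.a / c + 1.0 / (r2 * c))
        self.b = self.a / (self.S * c)
        self.const = self.pv / (r2 * c)
        self.M, self.G0, self.Gm, self.G1 = _rk4_matrices(A, dt)
        self.m = m

    def input_terms(self, q0: np.ndarray, qm: np.ndarray, q1: np.ndarray) -> np.ndarray:
        """r_n for every step of a cycle; q* are inflow samples (n,)."""
        u0 = np.outer(q0, self.b) + self.const
        um = np.outer(qm, self.b) + self.const
        u1 = np.outer(q1, self.b) + self.const
        return u0 @ self.G0.T + um @ self.Gm.T + u1 @ self.G1.T

    def node_pressure(self, x: np.ndarray, q_in: np.ndarray) -> np.ndarray:
        return (q_in + x @ self.a) / self.S


def simulate_network(
    network: AorticNetwork,
    inlet: FlowWaveform,
    dt: float = 1e-3,
    max_cycles: int = 50,
    tol: float = 1e-3,
    initial_states: Optional[np.ndarray] = None,
) -> SimulationResult:
    """Run the 0D network to periodic steady state (or ``max_cycles``).

    The result carries the final simulated cycle; ``periodic`` is False when
    the cycle-to-cycle inlet pressure change never fell below ``tol``
    (relative to the cycle pressure range). Non-convergence is reported, not
    raised.
    """
    T = inlet.period
    n = int(round(T / dt))
    if n < 8:
        raise ValueError("dt too coarse for the cycle length")
    h = T / n
    if dt > inlet.dt * (1 + 1e-9):
        raise ValueError("dt must not exceed the inlet sampling interval")
    op = _NetworkOperator(network, h)
    t = np.arange(n) * h
    q0 = inlet.sample(t)
    qm = inlet.sample(t + h / 2.0)
    q1 = inlet.sample(t + h)
    r = op.input_terms(q0, qm, q1)

    x = (
        np.full(op.m, network.venous_pressure, dtype=float)
        if initial_states is None
        else np.asarray(initial_states, dtype=float).copy()
    )
    traj = np.empty((n, op.m))
    prev_inlet_p: Optional[np.ndarray] = None
    history: List[np.ndarray] = []
    converged_at = None
    cycles = 0
    M = op.M
    for cycle in range(1, max_cycles + 1):
        for k in range(n):
            traj[k] = x
            x = M @ x + r[k]
        if not np.isfinite(x).all():
            raise SolverError(f"non-finite state at cycle {cycle}")
        cycles = cycle
        p_ao = op.node_pressure(traj, q0)
        history.append(p_ao.copy())
        if prev_inlet_p is not None:
            rng = p_ao.max() - p_ao.min()
            if rng <= 0:
                rng = max(abs(p_ao).max(), 1.0)
            if np.abs(p_ao - prev_inlet_p).max() / rng < tol:
                converged_at = cycle
                break
        prev_inlet_p = p_ao.copy()

    p_ao = op.node_pressure(traj, q0)
    flows = (p_ao[:, None] - traj) * op.a[None, :]
    labels = network.labels
    branch_p = {
        lab: flows[:, i] * network.branches[i].wk.r1 + traj[:, i]
        for i, lab in enumerate(labels)
    }
    return SimulationResult(
        time=t,
        period=T,
        inlet_pressure=PressureWaveform(time=t, period=T, pressure=p_ao),
        inlet_flow=q0,
        branch_flows={lab: flows[:, i] for i, lab in enumerate(labels)},
        branch_pressures=branch_p,
        capacitor_states={lab: traj[:, i] for i, lab in enumerate(labels)},
        cycles_run=cycles,
        periodic=converged_at is not None,
        converged_at_cycle=converged_at,
        cycle_history=history,
    )


def wk3_response(
    params: WindkesselParams,
    inflow: FlowWaveform,
    dt: float = 1e-3,
    p_c0: float = 0.0,
    p_v: float = 0.0,
) -> PressureWaveform:
    """Proximal pressure of a single 3WK driven by a prescribed inflow.

    Integrates C dP_c/dt = Q - (P_c - P_v)/R2 over one period of ``inflow``
    from initial capacitor pressure ``p_c0``; returns P = Q R1 + P_c.
    """
    T = inflow.period
    n = int(round(T / dt))
    if n < 4:
        raise ValueError("dt too coarse for the waveform")
    h = T / n
    t = np.arange(n) * h
    q0 = inflow.sample(t)
    qm = inflow.sample(t + h / 2.0)
    q1 = inflow.sample(t + h)

    k = 1.0 / (params.r2 * params.c)
    A = np.array([[-k]])
    M, G0, Gm, G1 = _rk4_matrices(A, h)
    m, g0, gm, g1 = M[0, 0], G0[0, 0], Gm[0, 0], G1[0, 0]
    u0 = q0 / params.c + p_v * k
    um = qm / params.c + p_v * k
    u1 = q1 / params.c + p_v * k
    r = g0 * u0 + gm * um + g1 * u1

    pc = np.empty(n)
    x = float(p_c0)
    for i in range(n):
        pc[i] = x
        x = m * x + r[i]
    if not np.isfinite(x):
        raise SolverError("non-finite capacitor pressure during integration")
    return PressureWaveform(time=t, period=T, pressure=q0 * params.r1 + pc)


def periodic_steady_state(result: SimulationResult, tol: float = 1e-3) -> PeriodicityCheck:
    """Locate the first cycle at which the inlet pressure became periodic.

    Convergence at cycle k means max |P_k - P_{k-1}| over the cycle, divided
    by the cycle-k pressure range, fell below ``tol``.
    """
    hist = result.cycle_history
    if len(hist) < 2:
        raise ValueError("need at least two simulated cycles")
    for k in range(1, len(hist)):
        rng = hist[k].max() - hist[k].min()
        if rng <= 0:
            rng = max(abs(hist[k]).max(), 1.0)
        if np.abs(hist[k] - hist[k - 1]).max() / rng < tol:
            return PeriodicityCheck(converged=True, at_cycle=k + 1)
    return PeriodicityCheck(converged=False, at_cycle=None)
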