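"""Pulsatile flow and pressure waveforms: synthesis, statistics, filtering.

The central object is a uniformly sampled periodic time series over one
cardiac cycle (time grid on ``[0, T)``). Flow is carried in mL/s, pressure in
mmHg, time in seconds throughout the package.

The inlet-waveform synthesiser builds an analytical aortic flow wave from a
small set of physiological parameters (cycle length, mean flow / stroke
volume, optional peak flow). The template is a raised-cosine systolic lobe
over a configurable fraction of the cycle followed by a low-amplitude
diastolic lobe; the template is projected onto a finite Fourier basis and
then shifted/rescaled so the result is non-negative, band-limited, and
carries the requested stroke volume exactly. Band-limitation matters
downstream: the Womersley field generator represents the waveform by its
first ``K`` harmonics, and a band-limited inlet wave makes that
representation exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter as _scipy_savgol

from .exceptions import InfeasibleSpecError

__all__ = [
    "FlowWaveform",
    "PressureWaveform",
    "WaveformSpec",
    "WaveformStats",
    "PressureIndices",
    "PeriodAdjustment",
    "DecayFit",
    "synthesise_inlet_waveform",
    "adjust_period_to_frame_rate",
    "heart_rate_bpm",
    "waveform_stats",
    "extract_pressure_indices",
    "fit_decay_time",
    "savitzky_golay_filter",
]


def _validate_series(time: np.ndarray, values: np.ndarray, period: float) -> None:
    if time.ndim != 1 or values.shape != time.shape:
        raise ValueError("time and values must be 1-D arrays of equal length")
    if time.size < 2:
        raise ValueError("waveform needs at least two samples")
    if not (np.isfinite(time).all() and np.isfinite(values).all()):
        raise ValueError("waveform contains non-finite values")
    if period <= 0:
        raise ValueError("period must be positive")
    dt = np.diff(time)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("waveform must be uniformly sampled")
    if abs(time[0]) > 1e-12:
        raise ValueError("time grid must start at 0")
    if time[-1] >= period - 1e-12:
        raise ValueError("time grid must end strictly before one period")


@dataclass(frozen=True)
class _PeriodicSeries:
    time: np.ndarray
    period: float

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def n_samples(self) -> int:
        return int(self.time.size)


@dataclass(frozen=True)
class FlowWaveform(_PeriodicSeries):
    """One period of a volumetric flow wave. time: s, flow: mL/s."""

    flow: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "flow", np.asarray(self.flow, dtype=float))
        _validate_series(self.time, self.flow, self.period)

    def sample(self, t) -> np.ndarray:
        """Periodic linear interpolation of the flow at arbitrary times."""
        tw = np.asarray(t, dtype=float) % self.period
        tt = np.concatenate([self.time, [self.period]])
        qq = np.concatenate([self.flow, [self.flow[0]]])
        return np.interp(tw, tt, qq)


@dataclass(frozen=True)
class PressureWaveform(_PeriodicSeries):
    """One or more periods of a pressure signal. time: s, pressure: mmHg."""

    pressure: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "pressure", np.asarray(self.pressure, dtype=float))
        if self.time.ndim != 1 or self.pressure.shape != self.time.shape:
            raise ValueError("time and pressure must be 1-D arrays of equal length")
        if not (np.isfinite(self.time).all() and np.isfinite(self.pressure).all()):
            raise ValueError("pressure waveform contains non-finite values")
        if self.period <= 0:
            raise ValueError("period must be positive")
        dt = np.diff(self.time)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("pressure waveform must be uniformly sampled")


@dataclass(frozen=True)
class WaveformSpec:
    """Physiological parameters defining an inlet flow wave.

    period
        Cycle length T in seconds.
    mean_flow
        Cycle-averaged flow Q-bar in mL/s.
    stroke_volume
        Ejected volume per cycle in mL; for a non-negative wave SV = Q-bar * T.
    peak_flow
        Optional systolic peak in mL/s.
    systolic_fraction
        Fraction of the cycle occupied by the systolic lobe, in (0, 1).
    """

    period: float
    mean_flow: Optional[float] = None
    stroke_volume: Optional[float] = None
    peak_flow: Optional[float] = None
    systolic_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise InfeasibleSpecError("period must be positive")
        if not 0 < self.systolic_fraction < 1:
            raise InfeasibleSpecError("systolic_fraction must be in (0, 1)")
        if self.mean_flow is None and self.stroke_volume is None:
            raise InfeasibleSpecError("provide mean_flow and/or stroke_volume")
        if self.mean_flow is not None and self.mean_flow < 0:
            raise InfeasibleSpecError("mean_flow must be non-negative")
        if self.stroke_volume is not None and self.stroke_volume < 0:
            raise InfeasibleSpecError("stroke_volume must be non-negative")
        if (
            self.mean_flow is not None
            and self.stroke_volume is not None
            and self.stroke_volume > 0
            and abs(self.stroke_volume - self.mean_flow * self.period)
            > 0.005 * self.stroke_volume
        ):
            raise InfeasibleSpecError(
                "stroke_volume and mean_flow*period disagree by more than 0.5%"
            )

    @property
    def resolved_stroke_volume(self) -> float:
        if self.stroke_volume is not None:
            return float(self.stroke_volume)
        return float(self.mean_flow * self.period)

    @property
    def resolved_mean_flow(self) -> float:
        if self.mean_flow is not None:
            return float(self.mean_flow)
        return float(self.stroke_volume / self.period)


@dataclass(frozen=True)
class WaveformStats:
    mean: float  # mL/s
    peak: float  # mL/s
    min: float  # mL/s
    net_volume: float  # mL
    forward_volume: float  # mL


@dataclass(frozen=True)
class PressureIndices:
    p_sys: float  # mmHg
    p_dia: float  # mmHg
    map: float  # mmHg
    pulse_pressure: float  # mmHg


@dataclass(frozen=True)
class PeriodAdjustment:
    t_exact: float
    t_rounded: float
    frames_per_cycle: int


@dataclass(frozen=True)
class DecayFit:
    tau: float  # s
    p0: float  # mmHg, fitted intercept at window start
    residual: float  # RMS of log-domain fit residual


def synthesise_inlet_waveform(
    spec: WaveformSpec,
    dt: float = 1e-3,
    diastolic_ratio: float = 0.1,
    n_harmonics: int = 10,
) -> FlowWaveform:
    """Build an analytical non-negative aortic inflow wave from ``spec``.

    The raised-cosine two-lobe template (systolic lobe of relative width
    ``spec.systolic_fraction``, diastolic lobe scaled by ``diastolic_ratio``)
    is projected onto its first ``n_harmonics`` Fourier harmonics; the
    band-limited shape is then affinely mapped (positive gain + offset) so
    that min flow = 0 (or peak = ``spec.peak_flow`` when given) and the cycle
    mean equals SV/T exactly.
    """
    T = spec.period
    n = int(round(T / dt))
    if n < 4 * n_harmonics:
        raise InfeasibleSpecError("sampling too coarse for the requested harmonics")
    t = np.arange(n) * (T / n)
    qbar = spec.resolved_mean_flow
    sv = spec.resolved_stroke_volume
    if qbar == 0.0:
        return FlowWaveform(time=t, period=T, flow=np.zeros(n))

    ts = spec.systolic_fraction * T
    lobe = lambda ph: 0.5 * (1.0 - np.cos(2.0 * np.pi * ph))  # noqa: E731
    shape = np.where(t < ts, lobe(t / ts), diastolic_ratio * lobe((t - ts) / (T - ts)))

    coeff = np.fft.rfft(shape) / n
    coeff[n_harmonics + 1 :] = 0.0
    shape = np.fft.irfft(coeff * n, n=n)

    s_mean, s_min, s_max = shape.mean(), shape.min(), shape.max()
    if spec.peak_flow is None:
        # gain + offset so min -> 0 and mean -> qbar
        gain = qbar / (s_mean - s_min)
        offset = -gain * s_min
    else:
        qp = spec.peak_flow
        if qp <= qbar:
            raise InfeasibleSpecError(
                f"peak_flow {qp} mL/s must exceed mean flow {qbar} mL/s"
            )
        gain = (qp - qbar) / (s_max - s_mean)
        offset = qbar - gain * s_mean
        if gain * s_min + offset < -1e-9 * qp:
            raise InfeasibleSpecError(
                "peak_flow incompatible with non-negative flow for this template"
            )
    flow = np.maximum(gain * shape + offset, 0.0)
    # touch-up: exact mean after the clip (clip only removes O(1e-12) dips)
    flow *= qbar / flow.mean()
    wave = FlowWaveform(time=t, period=T, flow=flow)
    assert abs(waveform_stats(wave).net_volume - sv) <= 1e-3 * sv
    return wave


def adjust_period_to_frame_rate(period: float, frame_rate: float) -> PeriodAdjustment:
    """Stretch the cycle length to the next multiple of one frame interval.

    Image-based acquisition at ``frame_rate`` f locks the usable cycle length
    to integer multiples of 1/f; the period is never shortened.
    """
    if period <= 0 or frame_rate <= 0:
        raise ValueError("period and frame_rate must be positive")
    n = int(np.ceil(period * frame_rate - 1e-9))
    t_exact = n / frame_rate
    return PeriodAdjustment(
        t_exact=t_exact, t_rounded=round(t_exact, 2), frames_per_cycle=n
    )


def heart_rate_bpm(period: float) -> int:
    """Heart rate in beats per minute, rounded to the nearest integer."""
    if period <= 0:
        raise ValueError("period must be positive")
    return int(round(60.0 / period))


def waveform_stats(w: FlowWaveform) -> WaveformStats:
    """Cycle statistics of a flow wave.

    The mean is the time average over one period (exact for a uniform grid
    covering ``[0, T)``); net volume is mean * T, forward volume integrates
    the positive part only.
    """
    if w.flow.size == 0:
        raise ValueError("empty waveform")
    mean = float(w.flow.mean())
    return WaveformStats(
        mean=mean,
        peak=float(w.flow.max()),
        min=float(w.flow.min()),
        net_volume=mean * w.period,
        forward_volume=float(np.clip(w.flow, 0.0, None).mean()) * w.period,
    )


def extract_pressure_indices(p: PressureWaveform) -> PressureIndices:
    """Systolic/diastolic/MAP indices from the final recorded cycle.

    MAP uses the standard brachial estimate P_dia + PP/3.
    """
    dt = float(p.time[1] - p.time[0])
    n_cycle = int(round(p.period / dt))
    if p.pressure.size < n_cycle:
        raise ValueError("need at least one full cycle of pressure data")
    last = p.pressure[-n_cycle:]
    p_sys = float(last.max())
    p_dia = float(last.min())
    pp = p_sys - p_dia
    return PressureIndices(p_sys=p_sys, p_dia=p_dia, map=p_dia + pp / 3.0, pulse_pressure=pp)


def fit_decay_time(p: PressureWaveform, window: Tuple[float, float]) -> DecayFit:
    """Fit an exponential decay P(t) = P0 exp(-t/tau) over a time window.

    Log-linear least squares; the window is usually placed in diastole where
    a Windkessel predicts a pure RC relaxation with tau = R2*C.
    """
    t0, t1 = window
    sel = (p.time >= t0 - 1e-12) & (p.time <= t1 + 1e-12)
    if sel.sum() < 3:
        raise ValueError("decay window must contain at least 3 samples")
    t = p.time[sel]
    y = p.pressure[sel]
    if (y <= 0).any():
        raise ValueError("pressures in the decay window must be positive")
    logy = np.log(y)
    slope, intercept = np.polyfit(t - t[0], logy, 1)
    if slope >= 0:
        raise ValueError("window does not contain a decaying signal")
    resid = logy - (intercept + slope * (t - t[0]))
    return DecayFit(
        tau=float(-1.0 / slope),
        p0=float(np.exp(intercept)),
        residual=float(np.sqrt(np.mean(resid**2))),
    )


def savitzky_golay_filter(
    p: PressureWaveform, window_samples: int = 31, poly_order: int = 3
) -> PressureWaveform:
    """Savitzky-Golay low-pass filter of a pressure signal.

    Length preserving; polynomials of degree <= ``poly_order`` pass through
    unchanged. Defaults (31 samples at 200 Hz sampling, order 3) attenuate
    valve-ringing frequencies around 20 Hz while keeping the physiological
    waveform intact.
    """
    if window_samples % 2 == 0 or window_samples <= poly_order:
        raise ValueError("window must be odd and greater than poly_order")
    if p.pressure.size < window_samples:
        raise ValueError("signal shorter than the filter window")
    smoothed = _scipy_savgol(p.pressure, window_samples, poly_order)
    return PressureWaveform(time=p.time, period=p.period, pressure=smoothed)
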