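"""Planar velocity-field post-processing and experiment-vs-simulation metrics.

Covers the standard PIV-style analysis chain: phase averaging of multi-cycle
ensembles, cycle-count convergence, the normalized median outlier test,
profile extraction along directed lines, a percent-difference profile metric,
axisymmetric flow-rate integration and a multi-section mass-conservation
error.

Grid convention: fields live on a regular rectangular grid with 1-D
coordinate vectors ``x`` (nx,) and ``y`` (ny,), row-major arrays of shape
(ny, nx), y increasing upward, coordinates in metres, velocities in m/s.
Invalid vectors are carried in an explicit boolean ``valid`` mask; masked
points are excluded from every statistic. Profile lines are directed and the
profile normal is the +90 degree rotation of the line direction, which fixes
the sign of the sampled normal velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "VelocityField2D",
    "CycleEnsemble",
    "PhaseAverage",
    "ProfileLine",
    "VelocityProfile",
    "ComparisonReport",
    "FilterResult",
    "phase_average",
    "convergence_curve",
    "normalized_median_filter",
    "extract_profile",
    "delta_metric",
    "axisymmetric_flow_rate",
    "mass_conservation_error",
]


@dataclass(frozen=True)
class VelocityField2D:
    """One planar velocity frame on a regular grid."""

    x: np.ndarray  # (nx,) m
    y: np.ndarray  # (ny,) m
    u: np.ndarray  # (ny, nx) m/s
    v: np.ndarray  # (ny, nx) m/s
    valid: np.ndarray  # (ny, nx) bool
    phase: int = 0
    cycle: int = 0

    def __post_init__(self) -> None:
        ny, nx = len(self.y), len(self.x)
        for name in ("u", "v", "valid"):
            arr = getattr(self, name)
            if arr.shape != (ny, nx):
                raise ValueError(f"{name} must have shape (ny, nx) = {(ny, nx)}")


@dataclass(frozen=True)
class CycleEnsemble:
    """Ordered frames spanning whole cycles at a fixed frame rate."""

    frames: Sequence[VelocityField2D]
    frame_rate: float  # Hz
    period: float  # s
    n_cycles: int

    def __post_init__(self) -> None:
        fpc = self.frames_per_cycle
        if len(self.frames) != fpc * self.n_cycles:
            raise ValueError(
                f"expected {fpc * self.n_cycles} frames "
                f"({fpc}/cycle x {self.n_cycles}), found {len(self.frames)}"
            )

    @property
    def frames_per_cycle(self) -> int:
        return int(round(self.period * self.frame_rate))


@dataclass(frozen=True)
class PhaseAverage:
    """Per-phase ensemble mean and SD fields with per-point sample counts."""

    mean_u: np.ndarray  # (n_phases, ny, nx)
    mean_v: np.ndarray
    sd_u: np.ndarray
    sd_v: np.ndarray
    count: np.ndarray  # (n_phases, ny, nx) contributing cycles per point
    n_cycles: int


@dataclass(frozen=True)
class ProfileLine:
    """Directed sampling line; normal is the +90 deg rotation of p0 -> p1."""

    p0: Tuple[float, float]  # m
    p1: Tuple[float, float]
    n_samples: int = 1000

    def __post_init__(self) -> None:
        if self.length == 0:
            raise ValueError("profile line must have nonzero length")
        if self.n_samples < 2:
            raise ValueError("need at least two samples")

    @property
    def length(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    @property
    def direction(self) -> Tuple[float, float]:
        L = self.length
        return ((self.p1[0] - self.p0[0]) / L, (self.p1[1] - self.p0[1]) / L)

    @property
    def normal(self) -> Tuple[float, float]:
        dx, dy = self.direction
        return (-dy, dx)


@dataclass(frozen=True)
class VelocityProfile:
    s: np.ndarray  # arc length, m
    u_n: np.ndarray  # normal velocity, m/s
    valid: np.ndarray  # bool


@dataclass(frozen=True)
class ComparisonReport:
    delta_percent: float
    n_used: int
    abs_differences: np.ndarray  # m/s, on the mutually valid points
    normaliser: float  # max_j |u_n,j^c|, m/s


@dataclass(frozen=True)
class FilterResult:
    spurious: np.ndarray  # (ny, nx) bool
    filled: Optional[VelocityField2D]
    unresolved: np.ndarray  # (ny, nx) bool: isolated vectors with no usable neighbours


def _stack(ensemble: CycleEnsemble):
    fpc = ensemble.frames_per_cycle
    nc = ensemble.n_cycles
    f0 = ensemble.frames[0]
    shape = (nc, fpc) + f0.u.shape
    u = np.empty(shape)
    v = np.empty(shape)
    ok = np.empty(shape, dtype=bool)
    for i, fr in enumerate(ensemble.frames):
        c, p = divmod(i, fpc)
        u[c, p] = fr.u
        v[c, p] = fr.v
        ok[c, p] = fr.valid
    return u, v, ok


def phase_average(ensemble: CycleEnsemble) -> PhaseAverage:
    """Ensemble mean and SD per cycle phase, masked points excluded per point.

    SD is the per-point sample standard deviation over contributing cycles
    (ddof=1); points seen in fewer than two cycles report SD 0.
    """
    if ensemble.n_cycles < 1:
        raise ValueError("need at least one complete cycle")
    u, v, ok = _stack(ensemble)
    w = ok.astype(float)
    count = w.sum(axis=0)
    safe = np.maximum(count, 1.0)
    mean_u = (u * w).sum(axis=0) / safe
    mean_v = (v * w).sum(axis=0) / safe
    du = (u - mean_u) * w
    dv = (v - mean_v) * w
    dof = np.maximum(count - 1.0, 1.0)
    sd_u = np.sqrt((du**2).sum(axis=0) / dof)
    sd_v = np.sqrt((dv**2).sum(axis=0) / dof)
    never = count == 0
    for arr in (mean_u, mean_v, sd_u, sd_v):
        arr[never] = np.nan
    return PhaseAverage(
        mean_u=mean_u,
        mean_v=mean_v,
        sd_u=sd_u,
        sd_v=sd_v,
        count=count.astype(int),
        n_cycles=ensemble.n_cycles,
    )


def convergence_curve(
    ensemble: CycleEnsemble, region: Tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Phase-average convergence vs number of cycles, in percent.

    Entry ``k`` (k = 0..n_cycles-2) is the maximum, over the region's points
    and all phases, of the vector magnitude of the change in running mean
    when cycle k+2 is added, normalised by the maximum final mean speed over
    the region, times 100.
    """
    rows, cols = region
    if len(rows) == 0:
        raise ValueError("region must be non-empty")
    u, v, ok = _stack(ensemble)
    u = u[:, :, rows, cols]
    v = v[:, :, rows, cols]
    w = ok[:, :, rows, cols].astype(float)
    nc = ensemble.n_cycles
    csum_u = np.cumsum(u * w, axis=0)
    csum_v = np.cumsum(v * w, axis=0)
    csum_w = np.cumsum(w, axis=0)
    safe = np.maximum(csum_w, 1.0)
    run_u = csum_u / safe
    run_v = csum_v / safe
    final_speed = np.hypot(run_u[-1], run_v[-1])
    norm = np.nanmax(final_speed)
    if norm == 0:
        raise ValueError("region has identically zero mean velocity")
    out = np.empty(nc - 1)
    for n in range(2, nc + 1):
        d = np.hypot(run_u[n - 1] - run_u[n - 2], run_v[n - 1] - run_v[n - 2])
        out[n - 2] = 100.0 * np.nanmax(d) / norm
    return out


def _windows(arr: np.ndarray, hw: int) -> np.ndarray:
    """Sliding (2hw+1)^2 neighbourhood view with NaN padding, centre removed."""
    k = 2 * hw + 1
    pad = np.pad(arr, hw, mode="constant", constant_values=np.nan)
    win = np.lib.stride_tricks.sliding_window_view(pad, (k, k)).copy()
    win[:, :, hw, hw] = np.nan  # exclude the vector itself from its neighbourhood
    return win.reshape(arr.shape + (k * k,))


def normalized_median_filter(
    fieldframe: VelocityField2D,
    half_window: int = 2,
    threshold: float = 2.0,
    eps: float = 0.02,
    fill: bool = False,
) -> FilterResult:
    """Normalized median test for spurious vectors (5x5 neighbourhood default).

    For each component, the residual of a vector against the median of its
    neighbourhood is normalised by the median of the neighbours' own
    residuals plus the noise floor ``eps`` (m/s); the vector is flagged when
    either component's normalised residual exceeds ``threshold``. Masked
    vectors never contribute to neighbourhoods; a vector whose neighbourhood
    is entirely unusable is left unflagged and reported in ``unresolved``.
    """
    spurious = np.zeros_like(fieldframe.valid, dtype=bool)
    unresolved = np.zeros_like(fieldframe.valid, dtype=bool)
    medians = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN neighbourhoods
        for comp in ("u", "v"):
            a = getattr(fieldframe, comp).astype(float).copy()
            a[~fieldframe.valid] = np.nan
            win = _windows(a, half_window)
            med = np.nanmedian(win, axis=-1)
            medians[comp] = med
            no_neigh = np.isnan(med) & fieldframe.valid
            unresolved |= no_neigh
            r0 = np.abs(a - med)
            rm = np.nanmedian(np.abs(win - med[..., None]), axis=-1)
            norm_resid = r0 / (rm + eps)
            spurious |= fieldframe.valid & ~no_neigh & (norm_resid > threshold)
    filled = None
    if fill:
        rep_ok = spurious & np.isfinite(medians["u"]) & np.isfinite(medians["v"])
        filled = replace(
            fieldframe,
            u=np.where(rep_ok, medians["u"], fieldframe.u),
            v=np.where(rep_ok, medians["v"], fieldframe.v),
            valid=fieldframe.valid & (~spurious | rep_ok),
        )
    return FilterResult(spurious=spurious, filled=filled, unresolved=unresolved)


def _bilinear(x: np.ndarray, y: np.ndarray, arr: np.ndarray, px: np.ndarray, py: np.ndarray):
    """Bilinear sampling of ``arr`` at points (px, py); NaN outside the grid."""
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator(
        (y, x), arr, method="linear", bounds_error=False, fill_value=np.nan
    )
    return itp(np.column_stack([py, px]))


def extract_profile(fieldframe: VelocityField2D, line: ProfileLine) -> VelocityProfile:
    """Sample the velocity component normal to a directed line.

    ``line.n_samples`` equally spaced points from p0 to p1 are sampled by
    bilinear interpolation; a sample is valid only when all four surrounding
    grid vectors are valid and the point lies inside the grid.
    """
    N = line.n_samples
    frac = np.linspace(0.0, 1.0, N)
    px = line.p0[0] + frac * (line.p1[0] - line.p0[0])
    py = line.p0[1] + frac * (line.p1[1] - line.p0[1])
    if (
        px.max() < fieldframe.x[0]
        or px.min() > fieldframe.x[-1]
        or py.max() < fieldframe.y[0]
        or py.min() > fieldframe.y[-1]
    ):
        raise ValueError("profile line lies fully outside the grid")
    ui = _bilinear(fieldframe.x, fieldframe.y, fieldframe.u, px, py)
    vi = _bilinear(fieldframe.x, fieldframe.y, fieldframe.v, px, py)
    wi = _bilinear(fieldframe.x, fieldframe.y, fieldframe.valid.astype(float), px, py)
    nx_, ny_ = line.normal
    u_n = ui * nx_ + vi * ny_
    ok = np.isfinite(u_n) & (wi > 1.0 - 1e-9)
    u_n = np.where(ok, u_n, 0.0)
    return VelocityProfile(s=frac * line.length, u_n=u_n, valid=ok)


def delta_metric(
    experimental: VelocityProfile, computational: VelocityProfile
) -> ComparisonReport:
    """Mean absolute profile difference normalised by the computational peak.

    Delta = (1/N) sum_i |u_e,i - u_c,i| / max_j |u_c,j|, in percent, over the
    mutually valid sample points (N reported accordingly). Scale-covariant:
    multiplying both profiles by a constant leaves Delta unchanged.
    """
    if experimental.u_n.size != computational.u_n.size:
        raise ValueError("profiles must share the same number of samples")
    ok = experimental.valid & computational.valid
    n = int(ok.sum())
    if n == 0:
        raise ValueError("profiles share no valid points")
    u_c = computational.u_n[ok]
    norm = float(np.abs(u_c).max())
    if norm == 0.0:
        raise ValueError("computational profile is identically zero; Delta undefined")
    diffs = np.abs(experimental.u_n[ok] - u_c)
    return ComparisonReport(
        delta_percent=float(100.0 * diffs.mean() / norm),
        n_used=n,
        abs_differences=diffs,
        normaliser=norm,
    )


def axisymmetric_flow_rate(profile: VelocityProfile, axis_position: float) -> float:
    """Flow rate (mL/s) from a lumen-spanning profile, assuming axisymmetry.

    The two half-profiles about ``axis_position`` (arc-length coordinate of
    the vessel axis) are averaged onto a common radial grid and integrated as
    Q = 2 pi * int_0^R u(r) r dr by the trapezoid rule.
    """
    s = profile.s[profile.valid]
    u = profile.u_n[profile.valid]
    if s.size < 4:
        raise ValueError("too few valid samples for integration")
    if not s.min() < axis_position < s.max():
        raise ValueError("axis position lies outside the profile span")
    left = s <= axis_position
    right = s >= axis_position
    r_left = axis_position - s[left]
    u_left = u[left]
    r_right = s[right] - axis_position
    u_right = u[right]
    R = min(r_left.max(), r_right.max())
    nr = max(profile.s.size // 2, 16)
    r = np.linspace(0.0, R, nr)
    ul = np.interp(r, r_left[::-1], u_left[::-1])
    ur = np.interp(r, r_right, u_right)
    u_mean = 0.5 * (ul + ur)
    q_si = 2.0 * np.pi * np.trapezoid(u_mean * r, r)
    return float(q_si * 1e6)  # m^3/s -> mL/s


def mass_conservation_error(section_flows: Sequence[float], method: str = "range") -> float:
    """Spread of flow rates across successive sections, in percent of the mean.

    ``method='range'`` gives (max - min)/mean x 100; ``method='sd'`` gives
    SD/mean x 100.
    """
    q = np.asarray(section_flows, dtype=float)
    if q.size < 2:
        raise ValueError("need at least two sections")
    mean = q.mean()
    if mean == 0:
        raise ValueError("mean section flow is zero")
    if method == "range":
        return float(100.0 * (q.max() - q.min()) / abs(mean))
    if method == "sd":
        return float(100.0 * q.std(ddof=1) / abs(mean))
    raise ValueError("method must be 'range' or 'sd'")
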