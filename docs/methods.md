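# Methods

This note documents the models behind `haemokit`, the choices made where the
design was genuinely open, and what the synthetic-data generators do and do
not emulate. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code does
not measure.

## Inlet waveform synthesis

The inlet wave is built from clinical parameters only: cycle length T,
mean flow Q̄ and/or stroke volume SV (consistency |SV − Q̄T| ≤ 0.5 % SV is
enforced), an optional peak flow Q_p, and the systolic fraction of the cycle
(default 1/3). The underlying template is a raised-cosine systolic lobe over
the systolic fraction followed by a low-amplitude raised-cosine diastolic
lobe (tail-to-lobe amplitude ratio 0.1), which reproduces the two-phase
character of an aortic flow wave while staying non-negative (no
regurgitation is modelled).

The template is then projected onto its first K = 10 Fourier harmonics and
affinely rescaled (positive gain + offset) so that the minimum is exactly
zero (or the peak matches Q_p when given) and the cycle mean equals SV/T
exactly. Band-limiting is deliberate: the Womersley field generator
represents the drive waveform by its first K harmonics, and a band-limited
wave makes cross-section-integrated flow reproduce Q(t) to round-off rather
than to a truncation error. Infeasible parameter combinations (Q_p ≤ Q̄, or
a peak unreachable without negative flow) raise an explicit error.

Period adjustment to an imaging frame rate f returns the smallest n/f ≥ T
(never shortening the cycle) and preserves SV, not mean flow: both cannot be
preserved when T changes, and a fixed ejected volume is the physically
conserved quantity for a positive-displacement pump; the mean is recomputed
as SV/T_exact. With T = 0.8 s and f = 22 Hz this gives 18 frames/cycle,
T = 0.8182 s (0.82 s at two decimals) and 73 bpm.

## 0D network and Windkessel solver

* Topology: one zero-volume junction feeding all branches. The 3D vessel
  interior is not modelled; its resistance can be lumped into an optional
  per-branch series resistance R_s (default 0).
* State: capacitor pressures only (no inertance, no valve, no proximal
  compliance by default). The system is linear time-invariant, with the
  junction pressure solved algebraically at every stage — mass conservation
  at the junction is therefore an identity, tested to 1e-6 relative.
* Integrator: classical fixed-step RK4, default dt = 1 ms. Because the
  system is LTI the RK4 step is precomputed as an affine map (truncated
  matrix exponential plus input-response matrices), making a cycle a few
  hundred 4×4 mat-vecs. Halving dt changes final-cycle pressures by < 0.1 %;
  the solver matches closed-form constant-inflow and RC-decay solutions to
  < 0.1 % at dt = 1 ms.
* Periodic steady state: cycles repeat until the maximum cycle-to-cycle
  change of the inlet-pressure trace, relative to the cycle pressure range,
  drops below tol (default 1e-3). Non-convergence within max_cycles is
  reported as a flag, never an exception.
* Venous reference pressure defaults to 0 mmHg; initial capacitor pressures
  default to it, and warm starting from a previous run is supported.

## Calibration

Targets are P_sys, P_dia and per-branch mean flows (their sum must match the
inlet mean within 0.5 %). The initial guess is closed-form: per branch
R_tot = (MAP − P_v)/Q̄ᵢ with MAP = P_dia + PP/3 (a convention the package
uses throughout; none is mandated by the data), C_tot = SV/PP distributed
proportionally to target flows. The R₁:R₂ split is fixed by κ (default
0.05, the order of the proximal share in published aortic 3WK sets); it is
not identifiable from the targets, and the recovery tests assert totals
only.

Each iteration simulates to periodic steady state (warm-started), then
rescales branch resistances by achieved/target flow, the overall resistance
level by target/achieved MAP, and the total compliance by achieved/target
pulse pressure; a relaxation exponent (default 1, i.e. undamped) is
available should a configuration oscillate. On the built-in patient fixture
the loop converges in 4 iterations to 149.7/80.0 mmHg with the exact flow
split; the error history is monotone after the second iteration. Doubling
all target flows at fixed pressures halves calibrated resistances (scale
equivariance), and targets extracted from a known network are recovered to
2 % in R_tot and 5 % in C_tot.

Note that published 3WK tables for a specific 3D model are *not* expected to
be reproduced exactly by a 0D surrogate: such values absorb the 3D domain's
internal pressure losses. A steady resistive-divider analysis of the
reference outlet table gives a brachiocephalic flow share of ~13 % versus
the 16.7 % clinical target, so the calibrated 0D parameters legitimately
differ; the table is used as a simulation fixture and a loose (±30 %)
cross-check only.

## Flow regime

Re = 4ρQ/(πμD) at mean and peak flow; Wo = (D/2)·√(2πρ/(Tμ)); transition
threshold Re_c = 250·Wo, flagged when Re_peak exceeds it. With the KSCN
analogue (ρ = 1310 kg/m³, μ = 2.2 mPa·s), the inlet diameter implied by
Re_m = 3472 at Q̄ = 134.5 mL/s is 29.37 mm, and Wo at T = 0.82 s evaluates
to 31.4 (printed elsewhere rounded to 32; the regime check carries a 3 %
tolerance for this reason).

## Velocity-field analytics

* Grids are regular and rectangular, metres and m/s, row-major (ny, nx),
  y increasing upward; validity is an explicit boolean mask, never NaN, in
  all public interfaces.
* Phase averaging groups frames by index mod frames-per-cycle and computes
  per-point mean and sample SD (ddof = 1) over cycles, excluding masked
  points per point; a single contributing cycle reports SD 0 with the count
  exposed.
* The convergence curve reports, for n = 2…N cycles, the maximum over a
  chosen region and all phases of the vector magnitude of the running-mean
  change, normalised by the maximum final mean speed over the region, in
  percent. The defining region is configurable because the underlying
  criterion ("converged within X % after N cycles in small regions") does
  not pin down a norm; the fixture uses a 5×5 block at the lumen centre.
* The normalized median test uses a 5×5 neighbourhood (half-window 2),
  excludes the vector itself from its neighbourhood, normalises the
  component residual against the median neighbour residual plus a noise
  floor eps (default 0.02 m/s, the velocity-domain analogue of the standard
  0.1 px floor) and flags at threshold 2 in either component. Borders use
  shrunken neighbourhoods; vectors with no usable neighbours are left
  unflagged and reported separately. Flagging never mutates the input, and
  lowering the threshold flags a superset.
* Profiles are sampled at N equally spaced points (default 1000) by
  bilinear interpolation; the profile normal is the +90° rotation of the
  directed line, which fixes the sign convention of uₙ. A sample is valid
  only if all four surrounding vectors are valid.
* The Δ metric normalises by the peak of the *computational* profile (so it
  is undefined for an identically zero computational profile), counts only
  mutually valid points, and is scale-covariant but offset-sensitive.
* Axisymmetric flow rate averages the two half-profiles about the stated
  axis position onto a common radial grid and applies the trapezoid rule to
  2π∫u r dr; convergence is second order in profile resolution. The
  multi-section mass-conservation error defaults to (max − min)/mean × 100,
  with SD/mean available as an option — the underlying figure of merit has
  no canonical formula.

## Synthetic data

The generators emulate the *statistical and kinematic* structure of planar
PIV data of pulsatile tube flow, not its imaging physics:

* Geometry is a straight rigid circular tube; the analytical Womersley
  solution exists there, so every generated frame has an exact oracle.
  Curved, branched or dissected geometries (true/false lumen jets,
  recirculation) are not emulated — passing tests demonstrate correctness
  of the analytics, not fidelity to anatomical flow structures.
* The evaluator carries the steady Poiseuille component plus K = 10 annular
  harmonic solutions built from order-zero complex-argument Bessel
  functions, each normalised so its sectional flow equals the waveform's
  Fourier coefficient exactly. No-slip holds to 1e-12; sectional flow
  reproduces Q(t) to < 0.1 % of peak.
* Default imaging grid 150×200 (a 20× downscale of a 4000×3000 px camera),
  frame rate 22 Hz, 10 cycles. The transverse resolution matters: the
  near-wall Stokes layer at Wo ≈ 31 is ~R/22 thick, and coarser grids
  produce spurious outlier-test flags at the wall.
* Noise defaults: Gaussian σ = 0.03 m/s (~2 % of peak speed), inter-cycle
  gain SD = 0.01, no outliers unless requested (the filter fixtures inject
  5 % labelled outliers at 5× peak speed). These defaults were fixed once so
  that the 10-cycle phase-average convergence criterion (< 1.6 % variation
  in a central region) holds robustly across seeds, which is the documented
  role of the inter-cycle variability term; they are not re-derived from
  any measured data.
* Valve-ringing pressure bursts (default 20 Hz, decay 0.05 s, attenuation
  0.6 per downstream station) are qualitative stand-ins: their placement at
  systole onset/offset and downstream amplitude decay mirror mechanical-
  valve behaviour, but frequency and decay are invented defaults, documented
  as such. The Savitzky–Golay defaults (window 31 at 200 Hz sampling, order
  3) attenuate the 20 Hz line by > 80 % while passing cubic trends exactly.

## Known limitations

* No wave propagation (0D), no valve or inertance elements, no compliant
  walls or intimal-flap mechanics; pressure wave *shapes* inside a 3D domain
  are outside the model class.
* The R₁/R₂ split is a convention (κ), not an identified quantity.
* The calibration assumes a flow-driven inlet; pressure-driven rigs need a
  different formulation.
* Profile validity near masked regions is conservative (all four
  neighbours required), which shortens usable profiles by one cell at each
  boundary.
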