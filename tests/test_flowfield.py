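"""Phase averaging, outlier detection, profiles, Delta metric, flow rates."""

import numpy as np
import pytest

from haemokit.flowfield import (
    CycleEnsemble,
    ProfileLine,
    VelocityField2D,
    VelocityProfile,
    axisymmetric_flow_rate,
    convergence_curve,
    delta_metric,
    extract_profile,
    mass_conservation_error,
    normalized_median_filter,
    phase_average,
)
from haemokit.synthdata import NoiseSpec, add_measurement_noise


def _uniform_field(value=1.0, ny=12, nx=16, v=0.0):
    x = np.linspace(0.0, 0.15, nx)
    y = np.linspace(-0.05, 0.06, ny)
    return VelocityField2D(
        x=x,
        y=y,
        u=np.full((ny, nx), value),
        v=np.full((ny, nx), v),
        valid=np.ones((ny, nx), dtype=bool),
    )


def _repeat_ensemble(frame, fpc=4, n_cycles=5, frame_rate=8.0):
    frames = [
        VelocityField2D(
            x=frame.x, y=frame.y, u=frame.u * (p + 1), v=frame.v,
            valid=frame.valid, phase=p, cycle=c,
        )
        for c in range(n_cycles)
        for p in range(fpc)
    ]
    return CycleEnsemble(
        frames=frames, frame_rate=frame_rate, period=fpc / frame_rate, n_cycles=n_cycles
    )


class TestPhaseAverage:
    def test_identical_cycles_mean_equal_sd_zero(self):
        ens = _repeat_ensemble(_uniform_field())
        pa = phase_average(ens)
        for p in range(4):
            np.testing.assert_allclose(pa.mean_u[p], p + 1.0)
        np.testing.assert_allclose(pa.sd_u, 0.0, atol=1e-12)
        np.testing.assert_allclose(pa.sd_v, 0.0, atol=1e-12)

    def test_single_cycle_degenerate(self):
        ens = _repeat_ensemble(_uniform_field(), n_cycles=1)
        pa = phase_average(ens)
        assert pa.n_cycles == 1
        np.testing.assert_allclose(pa.sd_u, 0.0)
        assert (pa.count == 1).all()

    def test_sd_recovers_injected_noise(self, clean_ensemble):
        sigma = 0.05
        noisy = add_measurement_noise(
            clean_ensemble, NoiseSpec(sigma=sigma, gain_sd=0.0, seed=21)
        )
        pa = phase_average(noisy.ensemble)
        valid = clean_ensemble.frames[0].valid
        # per-point SD has ~24% sampling error at n=10; assert on the mean
        assert np.nanmean(pa.sd_u[:, valid]) == pytest.approx(sigma, rel=0.25)
        assert np.nanmean(pa.sd_v[:, valid]) == pytest.approx(sigma, rel=0.25)

    def test_masked_points_excluded(self):
        f = _uniform_field()
        bad = f.valid.copy()
        bad[3, 4] = False
        f2 = VelocityField2D(x=f.x, y=f.y, u=f.u * 5, v=f.v, valid=bad)
        frames = [f, f2]
        ens = CycleEnsemble(frames=frames, frame_rate=2.0, period=0.5, n_cycles=2)
        pa = phase_average(ens)
        assert pa.count[0, 3, 4] == 1
        assert pa.mean_u[0, 3, 4] == pytest.approx(1.0)  # only the valid cycle counts
        assert pa.mean_u[0, 0, 0] == pytest.approx(3.0)


class TestConvergenceCurve:
    def test_identical_cycles_zero_variation(self):
        ens = _repeat_ensemble(_uniform_field(), n_cycles=6)
        rows, cols = np.nonzero(ens.frames[0].valid)
        var = convergence_curve(ens, (rows, cols))
        np.testing.assert_allclose(var, 0.0, atol=1e-12)

    def test_default_noise_meets_convergence_criterion(
        self, clean_ensemble, central_region
    ):
        noisy = add_measurement_noise(clean_ensemble, NoiseSpec(seed=0))
        var = convergence_curve(noisy.ensemble, central_region)
        assert var[-1] < 1.6  # 10-cycle convergence criterion

    def test_doubling_noise_increases_variation(self, clean_ensemble, central_region):
        v1 = convergence_curve(
            add_measurement_noise(
                clean_ensemble, NoiseSpec(sigma=0.03, gain_sd=0.0, seed=5)
            ).ensemble,
            central_region,
        )
        v2 = convergence_curve(
            add_measurement_noise(
                clean_ensemble, NoiseSpec(sigma=0.06, gain_sd=0.0, seed=5)
            ).ensemble,
            central_region,
        )
        assert (v2 > v1).all()


class TestNormalizedMedianFilter:
    def test_uniform_field_unflagged(self):
        res = normalized_median_filter(_uniform_field())
        assert not res.spurious.any()

    def test_single_spike_flagged_exactly(self):
        f = _uniform_field()
        u = f.u.copy()
        u[5, 7] = 10.0
        spiked = VelocityField2D(x=f.x, y=f.y, u=u, v=f.v, valid=f.valid)
        res = normalized_median_filter(spiked, eps=0.02)
        expected = np.zeros_like(f.valid)
        expected[5, 7] = True
        np.testing.assert_array_equal(res.spurious, expected)

    def test_labelled_outliers_recall_and_fpr(self, clean_ensemble):
        noisy = add_measurement_noise(
            clean_ensemble,
            NoiseSpec(sigma=0.0, gain_sd=0.0, outlier_fraction=0.05, seed=3),
        )
        frame = noisy.ensemble.frames[2]
        truth = noisy.outlier_masks[2]
        res = normalized_median_filter(frame)
        valid = frame.valid
        tp = (res.spurious & truth).sum()
        fp = (res.spurious & ~truth & valid).sum()
        recall = tp / truth.sum()
        fpr = fp / (~truth & valid).sum()
        assert recall >= 0.95
        assert fpr <= 0.02

    def test_masks_monotone_in_threshold(self, clean_ensemble):
        noisy = add_measurement_noise(
            clean_ensemble, NoiseSpec(sigma=0.02, outlier_fraction=0.03, seed=9)
        )
        frame = noisy.ensemble.frames[0]
        loose = normalized_median_filter(frame, threshold=4.0).spurious
        tight = normalized_median_filter(frame, threshold=2.0).spurious
        assert (tight | loose == tight).all()  # lower threshold flags a superset

    def test_does_not_modify_input(self):
        f = _uniform_field()
        u_before = f.u.copy()
        normalized_median_filter(f, fill=True)
        np.testing.assert_array_equal(f.u, u_before)

    def test_fill_replaces_spike_with_median(self):
        f = _uniform_field()
        u = f.u.copy()
        u[5, 7] = 10.0
        spiked = VelocityField2D(x=f.x, y=f.y, u=u, v=f.v, valid=f.valid)
        res = normalized_median_filter(spiked, fill=True)
        assert res.filled.u[5, 7] == pytest.approx(1.0)


class TestExtractProfile:
    def test_uniform_flow_unit_normal(self):
        f = _uniform_field(1.0)
        # upward line: direction (0,1), normal (-1,0) -> u_n = -u
        line = ProfileLine(p0=(0.02, -0.04), p1=(0.02, 0.05), n_samples=100)
        prof = extract_profile(f, line)
        assert prof.valid.all()
        np.testing.assert_allclose(prof.u_n, -1.0, atol=1e-12)

    def test_linear_shear_exact_under_bilinear(self):
        f = _uniform_field()
        a = 7.0
        u = a * f.y[:, None] * np.ones_like(f.u)
        shear = VelocityField2D(x=f.x, y=f.y, u=u, v=f.v, valid=f.valid)
        line = ProfileLine(p0=(0.02, 0.05), p1=(0.02, -0.04), n_samples=64)
        prof = extract_profile(shear, line)
        # direction (0,-1) -> normal (1,0) -> u_n = u = a*y, linear in s
        y_expected = 0.05 - prof.s
        np.testing.assert_allclose(prof.u_n, a * y_expected, atol=1e-12)

    def test_rotated_line_matches_analytic_projection(self):
        f = _uniform_field()
        a = 3.0
        u = a * f.y[:, None] * np.ones_like(f.u)
        shear = VelocityField2D(x=f.x, y=f.y, u=u, v=f.v, valid=f.valid)
        p0, p1 = (0.01, -0.03), (0.10, 0.04)
        line = ProfileLine(p0=p0, p1=p1, n_samples=80)
        prof = extract_profile(shear, line)
        frac = prof.s / line.length
        y_s = p0[1] + frac * (p1[1] - p0[1])
        nx_, _ = line.normal
        np.testing.assert_allclose(prof.u_n, a * y_s * nx_, atol=1e-12)

    def test_line_outside_grid_raises(self):
        with pytest.raises(ValueError):
            extract_profile(
                _uniform_field(), ProfileLine(p0=(1.0, 1.0), p1=(2.0, 2.0))
            )


class TestDeltaMetric:
    def _prof(self, u):
        u = np.asarray(u, dtype=float)
        return VelocityProfile(
            s=np.linspace(0.0, 1.0, u.size), u_n=u, valid=np.ones(u.size, bool)
        )

    def test_identical_profiles_zero(self):
        p = self._prof([0.3, 0.5, 0.9])
        assert delta_metric(p, p).delta_percent == 0.0

    def test_hand_example_one_third(self):
        rep = delta_metric(self._prof([1, 2, 3]), self._prof([2, 2, 2]))
        assert rep.delta_percent == pytest.approx(100.0 / 3.0)
        assert rep.n_used == 3

    def test_hand_example_full_difference(self):
        rep = delta_metric(self._prof([0, 0]), self._prof([1, -1]))
        assert rep.delta_percent == pytest.approx(100.0)

    def test_scale_covariance_and_offset_sensitivity(self):
        e, c = self._prof([1.0, 2.0, 0.5]), self._prof([1.5, 1.8, 0.7])
        base = delta_metric(e, c).delta_percent
        scaled = delta_metric(self._prof([3, 6, 1.5]), self._prof([4.5, 5.4, 2.1]))
        assert scaled.delta_percent == pytest.approx(base, rel=1e-12)
        shifted = delta_metric(
            self._prof([2.0, 3.0, 1.5]), self._prof([2.5, 2.8, 1.7])
        )
        assert shifted.delta_percent != pytest.approx(base, rel=1e-6)

    def test_zero_computational_profile_rejected(self):
        with pytest.raises(ValueError):
            delta_metric(self._prof([1, 2]), self._prof([0, 0]))

    def test_only_mutually_valid_points_counted(self):
        e = VelocityProfile(
            s=np.linspace(0, 1, 4),
            u_n=np.array([1.0, 9.0, 1.0, 1.0]),
            valid=np.array([True, False, True, True]),
        )
        c = self._prof([1.0, 1.0, 1.0, 1.0])
        rep = delta_metric(e, c)
        assert rep.n_used == 3
        assert rep.delta_percent == 0.0


class TestFlowRateIntegration:
    def _chord_profile(self, u_of_r, R=0.015, N=1000):
        s = np.linspace(0.0, 2.2 * R, N)
        r = np.abs(s - 1.1 * R)
        u = np.where(r <= R, u_of_r(r), 0.0)
        return VelocityProfile(s=s, u_n=u, valid=np.ones(N, bool)), 1.1 * R

    def test_uniform_profile_closed_form(self):
        R, U = 0.015, 0.8
        prof, axis = self._chord_profile(lambda r: U, R=R)
        q = axisymmetric_flow_rate(prof, axis)
        assert q == pytest.approx(np.pi * R**2 * U * 1e6, rel=5e-3)

    def test_poiseuille_closed_form(self):
        R, u0 = 0.012, 1.2
        prof, axis = self._chord_profile(lambda r: u0 * (1 - (r / R) ** 2), R=R)
        q = axisymmetric_flow_rate(prof, axis)
        assert q == pytest.approx(np.pi * R**2 * u0 / 2.0 * 1e6, rel=5e-3)

    def test_second_order_convergence_on_poiseuille(self):
        R, u0 = 0.012, 1.0
        exact = np.pi * R**2 * u0 / 2.0 * 1e6

        def err(N):
            prof, axis = self._chord_profile(
                lambda r: u0 * (1 - (r / R) ** 2), R=R, N=N
            )
            return abs(axisymmetric_flow_rate(prof, axis) - exact)

        e1, e2 = err(250), err(1000)  # 4x resolution -> ~16x error drop
        assert e2 < e1 / 8.0

    def test_axis_outside_span_raises(self):
        prof, _ = self._chord_profile(lambda r: 1.0)
        with pytest.raises(ValueError):
            axisymmetric_flow_rate(prof, axis_position=1.0)


class TestMassConservation:
    def test_identical_flows_zero(self):
        assert mass_conservation_error([90.0, 90.0, 90.0]) == 0.0

    def test_hand_example(self):
        assert mass_conservation_error([100.0, 95.0]) == pytest.approx(5.128, abs=1e-3)

    def test_sd_variant(self):
        q = [100.0, 95.0]
        expected = 100.0 * np.std(q, ddof=1) / np.mean(q)
        assert mass_conservation_error(q, method="sd") == pytest.approx(expected)

    def test_womersley_sections_consistent(self, clean_ensemble):
        # 28 chords across the straight tube at one phase: spread < 1%
        frame = clean_ensemble.frames[3]
        y_top, y_bot = frame.y[-1], frame.y[0]
        axis = (y_top - y_bot) / 2.0
        flows = []
        for x_pos in np.linspace(frame.x[2], frame.x[-3], 28):
            line = ProfileLine(p0=(x_pos, y_top), p1=(x_pos, y_bot), n_samples=500)
            prof = extract_profile(frame, line)
            flows.append(axisymmetric_flow_rate(prof, axis))
        assert mass_conservation_error(flows) < 1.0
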