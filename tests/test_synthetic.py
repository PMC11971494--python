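"""Waveform generators, eddy-current simulator, probe layouts, directions."""

import numpy as np
import pytest
from scipy.signal import periodogram

from fieldcomp import (GAMMA_PROTON, EddyGradientScene, EddyMode,
                       GradientWaveform, InfeasibleWaveformError,
                       ProbeArray, ProbeLayoutSpec, build_probe_array,
                       evaluate_basis, fit_k, generate_monitoring_data,
                       make_waveform, repulsion_energy, simulate_k_true,
                       uniform_directions)
from fieldcomp.synthetic import (DEFAULT_GMAX, DEFAULT_SMAX, b_value,
                                 _effective_diffusion)


class TestWaveforms:
    @pytest.mark.parametrize("kind,params", [
        ("pgse", dict(b=1000.0)),
        ("ogse", dict(frequency=40.0, n_periods=2)),
        ("spiral", dict(duration=5e-3)),
        ("epi", dict(n_lines=8)),
        ("chirp", dict(duration=10e-3)),
    ])
    def test_hardware_limits_respected(self, kind, params):
        wf = make_waveform(kind, **params)
        assert np.max(np.abs(wf.g)) <= DEFAULT_GMAX * (1 + 1e-9)
        slew = np.max(np.abs(np.diff(wf.g, axis=1))) / wf.dt
        assert slew <= DEFAULT_SMAX * (1 + 1e-9)

    def test_pgse_b0_is_silent(self):
        wf = make_waveform("pgse", b=0.0)
        assert np.all(wf.g == 0)

    def test_pgse_hits_requested_b_value(self):
        """Numerical ∫(γ∫G dt')² dt of the effective waveform matches the
        request within 1%."""
        for b in (300.0, 1000.0):
            wf = make_waveform("pgse", b=b, direction=(1, 0, 0))
            b_num = b_value(_effective_diffusion(wf.g[0], wf.dt), wf.dt)
            assert b_num == pytest.approx(b, rel=0.01)

    def test_pgse_infeasible_b_raises(self):
        with pytest.raises(InfeasibleWaveformError):
            make_waveform("pgse", b=20000.0, delta=5e-3, Delta=8e-3)

    def test_ogse_spectral_peak_at_requested_frequency(self):
        wf = make_waveform("ogse", frequency=40.0, n_periods=4)
        # spectrum of one diffusion pulse (the second lobe interferes only
        # in fine fringes under the same 40 Hz envelope)
        n_lobe = int(round(4 / 40.0 / wf.dt))
        f, pxx = periodogram(wf.g[0, :n_lobe], fs=1.0 / wf.dt, nfft=1 << 18)
        assert abs(f[np.argmax(pxx)] - 40.0) <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_waveform("zigzag")

    def test_waveform_validates_limits(self):
        with pytest.raises(InfeasibleWaveformError):
            GradientWaveform(np.full((3, 4), 0.2), 1e-5)  # 200 mT/m


class TestEddySimulator:
    def test_no_modes_leaves_only_nominal_terms(self):
        wf = make_waveform("epi", n_lines=4)
        k = simulate_k_true(EddyGradientScene(wf, modes=()), 3)
        lin = k.indexing.linear_indices
        for ax, name in enumerate(("x", "y", "z")):
            expected = GAMMA_PROTON * np.cumsum(wf.g[ax]) * wf.dt
            np.testing.assert_allclose(k.k[lin[name]], expected, atol=1e-9)
        high = np.delete(np.arange(16), [0, lin["x"], lin["y"], lin["z"]])
        assert np.all(k.k[high] == 0)

    def test_step_response_matches_closed_form(self):
        """Single exponential mode, rectangular gradient step: the package's
        convention gives k(t) = −γAΔg·τ(1 − e^{−t/τ}) after the step."""
        dt, tau, A, dg = 2e-5, 1e-3, 2.5, 0.02
        g = np.zeros((3, 300))
        g[0, 50:] = dg
        wf = GradientWaveform(g, dt, smax=1e5)
        k = simulate_k_true(EddyGradientScene(wf, modes=(EddyMode(6, 0, A, tau),)), 2)
        t = np.arange(250) * dt
        expected = -GAMMA_PROTON * A * dg * tau * (1.0 - np.exp(-t / tau))
        err = np.max(np.abs(k.k[6, 50:] - expected)) / np.max(np.abs(expected))
        assert err < 1e-6

    def test_modes_superpose(self):
        wf = make_waveform("epi", n_lines=4)
        m1 = EddyMode(6, 0, 1.0, 1e-3)
        m2 = EddyMode(6, 0, 0.5, 5e-3)
        k1 = simulate_k_true(EddyGradientScene(wf, modes=(m1,)), 2).k[6]
        k2 = simulate_k_true(EddyGradientScene(wf, modes=(m2,)), 2).k[6]
        k12 = simulate_k_true(EddyGradientScene(wf, modes=(m1, m2)), 2).k[6]
        np.testing.assert_allclose(k12, k1 + k2, rtol=1e-12, atol=1e-9)

    def test_rotation_about_z_permutes_axes_and_modes(self):
        """Rotating gradients by 90° about z while relabelling the driven
        axis leaves the high-order k time-course unchanged."""
        wf = make_waveform("epi", n_lines=4)           # drive on x (+ blips y)
        g_rot = np.zeros_like(wf.g)                    # x -> y, y -> -x
        g_rot[1] = wf.g[0]
        g_rot[0] = -wf.g[1]
        wf_rot = GradientWaveform(g_rot, wf.dt)
        k = simulate_k_true(EddyGradientScene(wf, modes=(EddyMode(6, 0, 1.0, 1e-3),)), 2)
        k_rot = simulate_k_true(
            EddyGradientScene(wf_rot, modes=(EddyMode(6, 1, 1.0, 1e-3),)), 2)
        np.testing.assert_allclose(k_rot.k[6], k.k[6], rtol=1e-12, atol=1e-9)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            EddyMode(6, 0, 1.0, -1e-3)
        with pytest.raises(ValueError):
            EddyMode(6, 5, 1.0, 1e-3)


class TestProbeLayout:
    def test_single_orientation_no_filter_is_base(self):
        spec = ProbeLayoutSpec(n_z_shifts=1, n_rotations=1, r_max=10.0, axis_max=10.0)
        cal, base = build_probe_array(spec)
        np.testing.assert_allclose(cal.positions, base.positions)

    def test_default_candidate_count_before_filter(self):
        spec = ProbeLayoutSpec(r_max=10.0, axis_max=10.0)
        cal, base = build_probe_array(spec)
        assert base.n_probes == 16
        assert cal.n_probes == 16 * 9

    def test_filter_matches_brute_force(self):
        spec = ProbeLayoutSpec()
        unfiltered, _ = build_probe_array(
            ProbeLayoutSpec(r_max=10.0, axis_max=10.0))
        cal, _ = build_probe_array(spec)
        keep = ((np.linalg.norm(unfiltered.positions, axis=1) <= spec.r_max)
                & np.all(np.abs(unfiltered.positions) <= spec.axis_max, axis=1))
        assert cal.n_probes == int(keep.sum())
        np.testing.assert_allclose(cal.positions, unfiltered.positions[keep])

    def test_default_layout_near_100_probes(self):
        cal, base = build_probe_array()
        assert 90 <= cal.n_probes <= 110
        r = base.radii
        assert r.min() >= 0.119 - 1e-9 and r.max() <= 0.149 + 1e-9
        assert abs(r.mean() - 0.135) < 0.005

    def test_everything_filtered_raises(self):
        with pytest.raises(ValueError):
            build_probe_array(ProbeLayoutSpec(r_max=1e-6))


class TestMonitoringData:
    def test_noiseless_fit_recovers_truth(self):
        cal, base = build_probe_array()
        wf = make_waveform("epi", n_lines=4)
        scene = EddyGradientScene(wf, modes=(EddyMode(10, 0, 1e-4, 1e-3),),
                                  noise_sd=0.0)
        phase, k_true, P = generate_monitoring_data(scene, cal, 3, seed=0)
        k_est = fit_k(phase, P)
        np.testing.assert_allclose(k_est.k, k_true.k, atol=1e-8 * max(1, np.abs(k_true.k).max()))

    def test_fixed_seed_is_bit_reproducible(self):
        _, base = build_probe_array()
        wf = make_waveform("epi", n_lines=4)
        scene = EddyGradientScene(wf, modes=(), noise_sd=0.05)
        p1, _, _ = generate_monitoring_data(scene, base, 2, seed=42)
        p2, _, _ = generate_monitoring_data(scene, base, 2, seed=42)
        np.testing.assert_array_equal(p1.phi, p2.phi)
        p3, _, _ = generate_monitoring_data(scene, base, 2, seed=43)
        assert not np.array_equal(p1.phi, p3.phi)

    def test_residual_variance_matches_ls_theory(self, rng):
        """Overdetermined fit residual variance ≈ σ²(Np−Nb)/Np across seeds."""
        probes = ProbeArray(rng.uniform(-0.12, 0.12, (30, 3)))
        P = evaluate_basis(probes, 2)
        wf = make_waveform("epi", n_lines=2)
        scene = EddyGradientScene(wf, modes=(), noise_sd=0.05)
        ratios = []
        for seed in range(50):
            phase, _, _ = generate_monitoring_data(scene, probes, 2, seed=seed)
            k_est = fit_k(phase, P)
            resid = phase.phi - P.values @ k_est.k
            ratios.append(np.var(resid))
        expected = 0.05**2 * (30 - 9) / 30
        assert np.mean(ratios) == pytest.approx(expected, rel=0.10)


class TestDirections:
    def test_repulsion_near_best_of_random_restarts(self):
        """Optimized 12-direction set beats (within 5%) the best of 100
        random restarts by repulsion energy."""
        opt = uniform_directions(12, seed=7)
        e_opt = repulsion_energy(opt)
        rng = np.random.default_rng(0)
        best = np.inf
        for _ in range(100):
            pts = rng.normal(size=(12, 3))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            best = min(best, repulsion_energy(pts))
        assert e_opt <= best * 1.05

    def test_directions_are_unit_and_deterministic(self):
        d1 = uniform_directions(6, seed=3)
        d2 = uniform_directions(6, seed=3)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_allclose(np.linalg.norm(d1, axis=1), 1.0, atol=1e-12)
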