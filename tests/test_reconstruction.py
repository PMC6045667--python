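"""Deconvolution, length selection, center correction and gridding."""

import numpy as np
import pytest

from ceamri import rf_pulses
from ceamri.analog_frontend import SignalTrace
from ceamri.reconstruction import (
    build_convolution_matrix,
    center_shift_correction,
    deconvolve,
    deconvolve_batch,
    grid_reconstruct,
    select_length,
)
from ceamri.spin_sim import (
    GradientWaveform,
    ImpulseResponse,
    Phantom,
    Protocol,
    acquire_dataset,
    fid_response,
    spoke_directions,
)
from ceamri.pipeline import reconstruct_spokes


class TestConvolutionMatrix:
    def test_small_example(self):
        p = rf_pulses.RFPulse(np.array([1.0, 2.0, 3.0], dtype=complex), 1e-6, 3e-6)
        U = build_convolution_matrix(p, 3, 2).U
        assert np.allclose(U, [[1, 0], [2, 1], [3, 2]])

    def test_delta_pulse_identity(self):
        p = rf_pulses.RFPulse(np.array([1.0, 0, 0, 0], dtype=complex), 1e-6, 4e-6)
        U = build_convolution_matrix(p, 4, 3).U
        assert np.allclose(U, np.eye(4, 3))

    def test_matches_direct_convolution(self, chirp_pulse):
        rng = np.random.default_rng(0)
        h = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        n = 200
        U = build_convolution_matrix(chirp_pulse, n, 32).U
        direct = np.convolve(chirp_pulse.samples, h)[:n]
        assert np.allclose(U @ h, direct, rtol=1e-12)

    def test_invalid_length(self, chirp_pulse):
        with pytest.raises(ValueError):
            build_convolution_matrix(chirp_pulse, 16, 32)


class TestDeconvolve:
    def test_noise_free_round_trip(self, chirp_pulse):
        rng = np.random.default_rng(1)
        h = rng.standard_normal(64) + 1j * rng.standard_normal(64)
        n = 400
        U = build_convolution_matrix(chirp_pulse, n, 64).U
        s = SignalTrace(U @ h, chirp_pulse.dt)
        hr = deconvolve(s, chirp_pulse, 64)
        assert np.linalg.norm(hr.h - h) / np.linalg.norm(h) < 1e-6

    def test_delta_pulse_returns_prefix(self):
        p = rf_pulses.RFPulse(
            np.concatenate([[1.0], np.zeros(63)]).astype(complex), 1e-6, 64e-6
        )
        s = SignalTrace(np.arange(64, dtype=complex), 1e-6)
        hr = deconvolve(s, p, 16)
        assert np.allclose(hr.h, np.arange(16))

    def test_ridge_shrinkage_limit(self, chirp_pulse):
        s = SignalTrace(chirp_pulse.samples[:256], chirp_pulse.dt)
        h = deconvolve(s, chirp_pulse, 32, lam=1e12)
        assert np.max(np.abs(h.h)) < 1e-6

    def test_batch_matches_single(self, chirp_pulse):
        rng = np.random.default_rng(2)
        sigs = [rng.standard_normal(300) + 1j * rng.standard_normal(300) for _ in range(3)]
        batch = deconvolve_batch(sigs, chirp_pulse, 300, 48)
        for s, hb in zip(sigs, batch):
            hs = deconvolve(SignalTrace(s, chirp_pulse.dt), chirp_pulse, 48)
            assert np.allclose(hb.h, hs.h, atol=1e-8)


class TestSelectLength:
    def test_recovers_true_support(self, chirp_pulse):
        rng = np.random.default_rng(3)
        h = np.zeros(32, dtype=complex)
        h[:32] = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        n = 2048
        U = build_convolution_matrix(chirp_pulse, n, 32).U
        s = SignalTrace(U @ h, chirp_pulse.dt)
        assert select_length(s, chirp_pulse, [8, 16, 32, 64]) == 32

    def test_pure_noise_picks_smallest(self, chirp_pulse):
        rng = np.random.default_rng(4)
        s = SignalTrace(
            rng.standard_normal(2048) + 1j * rng.standard_normal(2048), chirp_pulse.dt
        )
        assert select_length(s, chirp_pulse, [8, 16, 32, 64]) == 8

    def test_single_candidate(self, chirp_pulse):
        s = SignalTrace(chirp_pulse.samples[:256], chirp_pulse.dt)
        assert select_length(s, chirp_pulse, [24]) == 24

    def test_empty_candidates(self, chirp_pulse):
        s = SignalTrace(chirp_pulse.samples[:256], chirp_pulse.dt)
        with pytest.raises(ValueError):
            select_length(s, chirp_pulse, [])


def gaussian_fid(n, center, width, shift=0.0):
    m = np.arange(n)
    return np.exp(-0.5 * ((m - center - shift) / width) ** 2).astype(complex)


class TestCenterShift:
    def test_identical_pair_zero_shift(self):
        h = ImpulseResponse(gaussian_fid(64, 10, 4), 1e-6)
        _, shifts = center_shift_correction([(h, h)])
        assert shifts[0] == pytest.approx(0.0, abs=1e-9)

    def test_injected_subsample_shift_recovered(self):
        ha = ImpulseResponse(gaussian_fid(64, 10, 4, shift=+0.2), 1e-6)
        hb = ImpulseResponse(gaussian_fid(64, 10, 4, shift=-0.2), 1e-6)
        corrected, shifts = center_shift_correction([(ha, hb)])
        assert shifts[0] == pytest.approx(0.4, abs=0.05)
        # after correction the pair magnitudes align
        ca, cb = corrected[0]
        assert np.allclose(np.abs(ca.h), np.abs(cb.h), atol=0.01)

    def test_antisymmetric_under_swap(self):
        ha = ImpulseResponse(gaussian_fid(64, 10, 4, shift=+0.3), 1e-6)
        hb = ImpulseResponse(gaussian_fid(64, 10, 4, shift=-0.3), 1e-6)
        _, s_ab = center_shift_correction([(ha, hb)])
        _, s_ba = center_shift_correction([(hb, ha)])
        assert s_ab[0] == pytest.approx(-s_ba[0], abs=1e-6)

    def test_unequal_lengths_rejected(self):
        ha = ImpulseResponse(gaussian_fid(64, 10, 4), 1e-6)
        hb = ImpulseResponse(gaussian_fid(32, 10, 4), 1e-6)
        with pytest.raises(ValueError):
            center_shift_correction([(ha, hb)])


class TestGridding:
    def _protocol(self, n_spokes=64):
        pulse = rf_pulses.make_chirp(4.1e-3, 16e3, 1.0, 8e-6, 0.1)
        return Protocol(
            n_spokes=n_spokes, n_samples=512, pulse=pulse, grad_amplitude=2.35,
            ramp_time=50e-6, dims=2, fov=0.24, max_gradient=10.0,
        )

    def _point(self, offset):
        return Phantom(
            positions=np.array([offset]), m0=np.array([1.0]),
            t2star=np.array([100e-6]), chem_shift=np.array([0.0]),
        )

    def _grid_point(self, offset, t2s=250e-6, L=128, matrix=48):
        """Grid analytic point-source FIDs (pure gridding, no deconvolution)."""
        proto = self._protocol()
        dirs = spoke_directions(proto.n_spokes, 2)
        t_k = (np.arange(L) + 0.5) * proto.pulse.dt
        ph = self._point(offset)
        ph = Phantom(ph.positions, ph.m0, np.array([t2s]), ph.chem_shift)
        resp, traj = [], []
        for d in dirs:
            g = GradientWaveform(d, proto.grad_amplitude, proto.ramp_time, 10.0)
            resp.append(fid_response(ph, g, proto.pulse.dt, L))
            traj.append(g.k_radius(t_k)[:, None] * d[None, :2])
        return grid_reconstruct(resp, traj, matrix, proto.fov, dims=2).data

    def test_centered_point_psf(self):
        img = self._grid_point((0.0, 0.0, 0.0))
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert peak == (24, 24)
        yy, xx = np.meshgrid(np.arange(48), np.arange(48), indexing="ij")
        side = img[(yy - 24) ** 2 + (xx - 24) ** 2 > 9].max()
        assert img.max() / side > 10.0

    def test_displaced_point_localizes(self):
        vox = 0.24 / 48
        img = self._grid_point((5 * vox, -3 * vox, 0.0))
        peak = np.unravel_index(np.argmax(img), img.shape)
        assert abs(peak[0] - 29) <= 1 and abs(peak[1] - 21) <= 1

    def test_zero_responses_zero_image(self):
        zeros = [ImpulseResponse(np.zeros(32, dtype=complex), 1e-6) for _ in range(4)]
        traj = [np.stack([np.linspace(0, 50, 32), np.zeros(32)], axis=1)] * 4
        img = grid_reconstruct(zeros, traj, 32, 0.24, dims=2)
        assert np.all(img.data == 0)

    def test_antipodal_fids_conjugate_for_real_object(self):
        """Real magnetization density: the antipodal spoke's FID is the
        complex conjugate of the spoke's own (Hermitian k-space symmetry)."""
        proto = self._protocol(8)
        ph = Phantom(
            positions=np.array([[0.02, 0.01, 0.0], [-0.03, 0.0, 0.0]]),
            m0=np.array([1.0, 0.5]),
            t2star=np.array([100e-6, 150e-6]),
            chem_shift=np.array([0.0, 0.0]),
        )
        dirs_spokes = acquire_dataset(ph, proto)
        for i in range(4):
            grad_a = GradientWaveform(dirs_spokes[i].direction, 2.35, 50e-6, 10.0)
            grad_b = GradientWaveform(dirs_spokes[i + 4].direction, 2.35, 50e-6, 10.0)
            ha = fid_response(ph, grad_a, proto.pulse.dt, 64).h
            hb = fid_response(ph, grad_b, proto.pulse.dt, 64).h
            assert np.allclose(hb, np.conj(ha), rtol=1e-10)

    def test_nyquist_clipping_warns(self):
        h = [ImpulseResponse(np.ones(16, dtype=complex), 1e-6)]
        traj = [np.stack([np.linspace(0, 500, 16), np.zeros(16)], axis=1)]
        with pytest.warns(UserWarning, match="Nyquist"):
            grid_reconstruct(h, traj, 32, 0.24, dims=2)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            grid_reconstruct([], [], 8, 0.24)
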