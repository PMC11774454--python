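"""Forward-model tests: coil maps, Cartesian masks, DFT/adjoint, noise."""

import numpy as np
import pytest

from iobound import (CoilEnsemble, KspaceData, LumpyParams, NoiseModel,
                     add_noise, adjoint, forward, make_cartesian_mask,
                     sample_lumpy_background, simulate_coil_maps)
from iobound.sense import _coil_profile, fft2c, ifft2c


class TestCoilMaps:
    def test_single_coil_normalized_is_unit_magnitude(self):
        ens = simulate_coil_maps(1, (32, 32), normalize=True)
        np.testing.assert_allclose(np.abs(ens.maps[0]), 1.0, atol=1e-12)

    def test_sum_of_squares_normalization(self, coils8):
        sos = np.sum(np.abs(coils8.maps) ** 2, axis=0)
        assert np.max(np.abs(sos - 1.0)) < 1e-6

    def test_rotation_by_coil_angle_permutes_maps(self):
        # evaluate raw coil profiles on a circularly symmetric point set
        # rotated by 2 pi / C about the grid center
        C, H = 8, 33
        cy = cx = (H - 1) / 2
        radius = np.hypot(H / 2, H / 2)
        sigma, phase = 0.7 * np.hypot(H, H), 0.05
        theta_pts = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts_y = cy + 10.0 * np.sin(theta_pts)
        pts_x = cx + 10.0 * np.cos(theta_pts)
        dtheta = 2 * np.pi / C
        rot_y = cy + 10.0 * np.sin(theta_pts + dtheta)
        rot_x = cx + 10.0 * np.cos(theta_pts + dtheta)
        for i in range(C):
            ci = (cy + radius * np.sin(2 * np.pi * i / C),
                  cx + radius * np.cos(2 * np.pi * i / C))
            cj = (cy + radius * np.sin(2 * np.pi * (i + 1) / C),
                  cx + radius * np.cos(2 * np.pi * (i + 1) / C))
            a = _coil_profile(rot_y, rot_x, cj, sigma, phase)
            b = _coil_profile(pts_y, pts_x, ci, sigma, phase)
            assert np.max(np.abs(a - b)) < 1e-6

    def test_normalized_flag_validated(self):
        with pytest.raises(ValueError):
            CoilEnsemble(np.ones((2, 4, 4), dtype=complex), normalized=True)


class TestCartesianMask:
    def test_full_sampling_selects_all(self):
        assert make_cartesian_mask(64, 1).n_selected == 64

    def test_r4_selects_every_fourth_line(self):
        mask = make_cartesian_mask(64, 4, offset=0, center_fraction=0.0)
        assert mask.n_selected == 16
        assert np.array_equal(np.flatnonzero(mask.line_selector),
                              np.arange(0, 64, 4))

    def test_masks_nest_for_divisible_accelerations(self):
        sel = {R: make_cartesian_mask(64, R).line_selector for R in (2, 4, 8)}
        assert np.all(sel[8] <= sel[4])
        assert np.all(sel[4] <= sel[2])

    def test_center_fraction_adds_central_lines(self):
        mask = make_cartesian_mask(64, 8, center_fraction=0.1)
        n_center = int(np.ceil(0.1 * 64))  # 7 central lines
        lo = 32 - n_center // 2
        assert mask.line_selector[lo:lo + n_center].all()
        assert mask.n_selected > make_cartesian_mask(64, 8).n_selected

    def test_achieved_acceleration_close_to_nominal(self):
        for R in (2, 4, 6, 8, 12):
            mask = make_cartesian_mask(64, R)
            assert abs(mask.n_selected - 64 / R) <= 1

    def test_r_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_cartesian_mask(64, 65)
        with pytest.raises(ValueError):
            make_cartesian_mask(64, 0)


class TestForwardAdjoint:
    def test_parseval_single_uniform_coil(self, uniform_coil):
        rng = np.random.default_rng(0)
        f = rng.normal(size=(64, 64))
        g = forward(f, uniform_coil, make_cartesian_mask(64, 1))
        assert abs(np.linalg.norm(g.samples) - np.linalg.norm(f)) < 1e-9

    def test_unselected_lines_exactly_zero(self, coils8):
        mask = make_cartesian_mask(64, 4)
        f = sample_lumpy_background(LumpyParams(), seed=1)
        g = forward(f, coils8, mask, NoiseModel(1.5), seed=2)
        assert np.all(g.samples[:, ~mask.line_selector, :] == 0)

    @pytest.mark.parametrize("n_coils,R", [(1, 1), (8, 1), (8, 4), (4, 8)])
    def test_randomized_adjoint_identity(self, n_coils, R):
        rng = np.random.default_rng(42)
        coils = simulate_coil_maps(n_coils, (64, 64), normalize=True)
        mask = make_cartesian_mask(64, R)
        for _ in range(20):
            x = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
            y = rng.normal(size=(n_coils, 64, 64)) \
                + 1j * rng.normal(size=(n_coils, 64, 64))
            y[:, ~mask.line_selector, :] = 0
            Ax = fft2c(coils.maps * x[None])
            Ax[:, ~mask.line_selector, :] = 0
            lhs = np.vdot(y, Ax)
            rhs = np.vdot(adjoint(y, coils, mask), x)
            denom = np.linalg.norm(x) * np.linalg.norm(y)
            assert abs(lhs - rhs) / denom < 1e-10

    def test_linearity(self, coils8):
        rng = np.random.default_rng(3)
        mask = make_cartesian_mask(64, 2)
        f1 = rng.normal(size=(64, 64))
        f2 = rng.normal(size=(64, 64))
        a, b = 2.3, -0.7
        g = forward(a * f1 + b * f2, coils8, mask).samples
        g_lin = (a * forward(f1, coils8, mask).samples
                 + b * forward(f2, coils8, mask).samples)
        assert (np.linalg.norm(g - g_lin)
                / np.linalg.norm(g) < 1e-10)

    def test_energy_monotone_under_nested_masks(self, coils8):
        f = sample_lumpy_background(LumpyParams(), seed=7)
        norms = {R: np.linalg.norm(
            forward(f, coils8, make_cartesian_mask(64, R)).samples)
            for R in (1, 2, 4, 8)}
        assert norms[8] <= norms[4] <= norms[2] <= norms[1]

    def test_adjoint_of_zero_is_zero(self, coils8):
        mask = make_cartesian_mask(64, 4)
        out = adjoint(np.zeros((8, 64, 64), complex), coils8, mask)
        assert np.all(out == 0)

    def test_adjoint_single_uniform_coil_full_mask_is_ifft(self, uniform_coil):
        rng = np.random.default_rng(5)
        g = rng.normal(size=(1, 64, 64)) + 1j * rng.normal(size=(1, 64, 64))
        mask = make_cartesian_mask(64, 1)
        out = adjoint(g, uniform_coil, mask)
        ref = np.conj(uniform_coil.maps[0]) * ifft2c(g[0])
        np.testing.assert_allclose(out, ref, atol=1e-12)


class TestNoise:
    def test_component_noise_std_recovered(self):
        # the default noise level: std 15 per real/imaginary component
        mask = make_cartesian_mask(8, 1)
        k = np.zeros((1, 8, 8), complex)
        reals = []
        for seed in range(1600):  # 1600 * 64 = 102400 samples
            out = add_noise(k, NoiseModel(15.0), mask, seed=seed)
            reals.append(out.real.ravel())
        std = np.concatenate(reals).std()
        assert 14.85 < std < 15.15

    def test_zero_sigma_identity(self):
        rng = np.random.default_rng(0)
        k = rng.normal(size=(2, 16, 16)) + 1j * rng.normal(size=(2, 16, 16))
        out = add_noise(k, NoiseModel(0.0), make_cartesian_mask(16, 2), seed=0)
        assert np.array_equal(out, k)

    def test_seeded_noise_reproducible(self):
        k = np.zeros((2, 16, 16), complex)
        mask = make_cartesian_mask(16, 2)
        a = add_noise(k, NoiseModel(1.0), mask, seed=9)
        b = add_noise(k, NoiseModel(1.0), mask, seed=9)
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(-1.0)


class TestKspaceDataInvariants:
    def test_nonzero_unselected_line_rejected(self):
        mask = make_cartesian_mask(16, 2)
        k = np.ones((1, 16, 16), complex)
        with pytest.raises(ValueError):
            KspaceData(k, mask=mask)

    def test_label_validated(self):
        mask = make_cartesian_mask(16, 1)
        with pytest.raises(ValueError):
            KspaceData(np.zeros((1, 16, 16), complex), mask=mask,
                       hypothesis_label="H2")
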