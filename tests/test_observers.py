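"""Observer tests: analytic SKE/SKS ideal observers, Hotelling, CNN-IO."""

import numpy as np
import pytest

from iobound import (AnalyticDetectability, CnnIdealObserver, CnnIoConfig,
                     HotellingObserver, SignalModel, SkeObserver, SksObserver,
                     apply_observer, as_real_vector, estimate_auc,
                     render_gaussian_signal, simulate_coil_maps,
                     ske_bke_analytic_auc, ske_bke_statistic,
                     sks_bke_statistic)
from iobound.sense import fft2c

from conftest import draw_ske_kspace


@pytest.fixture(scope="module")
def small_task():
    """16x16 single-coil SKE/BKE task: b = 0, centered Gaussian signal."""
    H, sigma = 16, 1.0
    img = render_gaussian_signal(SignalModel(0.7, 2.0, (8.0, 8.0)),
                                 1.0, (H, H)).pixels
    s = fft2c(img[None].astype(complex))
    b = np.zeros((1, H, H), complex)
    return b, s, sigma


class TestSkeStatistic:
    def test_zero_signal_gives_zero_statistic(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(0)
        g = draw_ske_kspace(b, s, sigma, 10, False, rng)
        t = ske_bke_statistic(g, b, np.zeros_like(s), sigma)
        assert np.all(t == 0)

    def test_matches_direct_formula(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(1)
        g = draw_ske_kspace(b, s, sigma, 1, True, rng)[0]
        t = ske_bke_statistic(g, b, s, sigma)
        direct = (np.sum(np.conj(s) * (g - b)).real / sigma**2
                  - np.sum(np.abs(s) ** 2) / (2 * sigma**2))
        assert t == pytest.approx(direct, rel=1e-12)

    def test_mc_mean_separation_matches_theory(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(2)
        t0 = ske_bke_statistic(draw_ske_kspace(b, s, sigma, 10_000, False, rng),
                               b, s, sigma)
        t1 = ske_bke_statistic(draw_ske_kspace(b, s, sigma, 10_000, True, rng),
                               b, s, sigma)
        expected = np.sum(np.abs(s) ** 2) / sigma**2
        se = np.sqrt(t0.var() / t0.size + t1.var() / t1.size)
        assert abs((t1.mean() - t0.mean()) - expected) < 3 * se

    def test_invariant_to_orthogonal_perturbation(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(3)
        g = draw_ske_kspace(b, s, sigma, 1, True, rng)[0]
        t_ref = ske_bke_statistic(g, b, s, sigma)
        # build a complex perturbation orthogonal to s under Re<s, .>
        v = rng.normal(size=s.shape) + 1j * rng.normal(size=s.shape)
        v -= s * (np.vdot(s, v).real / np.sum(np.abs(s) ** 2))
        assert abs(np.vdot(s, v).real) < 1e-9
        t_pert = ske_bke_statistic(g + v, b, s, sigma)
        assert t_pert == pytest.approx(t_ref, abs=1e-9)

    def test_zero_sigma_rejected(self, small_task):
        b, s, _ = small_task
        with pytest.raises(ValueError):
            ske_bke_statistic(b, b, s, 0.0)


class TestAnalyticAuc:
    def test_zero_signal_is_chance(self):
        det = ske_bke_analytic_auc(np.zeros((1, 8, 8), complex), None, 1.0)
        assert det.d_prime == 0.0
        assert det.auc == 0.5

    def test_dprime_two_gives_standard_value(self, small_task):
        b, s, _ = small_task
        # scale sigma so d' = 2 exactly: d' = sqrt(2 E) / sigma
        sigma = np.sqrt(2 * np.sum(np.abs(s) ** 2)) / 2.0
        det = ske_bke_analytic_auc(s, None, sigma)
        assert det.d_prime == pytest.approx(2.0, rel=1e-12)
        assert det.auc == pytest.approx(0.8413447460685429, abs=1e-10)

    def test_invariant_enforced(self):
        with pytest.raises(ValueError):
            AnalyticDetectability(d_prime=2.0, auc=0.9)

    def test_empirical_auc_matches_analytic(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(4)
        t0 = ske_bke_statistic(draw_ske_kspace(b, s, sigma, 10_000, False, rng),
                               b, s, sigma)
        t1 = ske_bke_statistic(draw_ske_kspace(b, s, sigma, 10_000, True, rng),
                               b, s, sigma)
        emp = estimate_auc(t0, t1)
        ana = ske_bke_analytic_auc(s, None, sigma)
        assert abs(emp.auc - ana.auc) < 0.01


class TestSksStatistic:
    def test_single_component_equals_ske(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(5)
        g = draw_ske_kspace(b, s, sigma, 20, True, rng)
        t_sks = sks_bke_statistic(g, b, [s], [1.0], sigma)
        t_ske = ske_bke_statistic(g, b, s, sigma)
        np.testing.assert_allclose(t_sks, t_ske, rtol=1e-12)

    def test_identical_components_equal_ske(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(6)
        g = draw_ske_kspace(b, s, sigma, 20, True, rng)
        t_sks = sks_bke_statistic(g, b, [s, s, s], None, sigma)
        t_ske = ske_bke_statistic(g, b, s, sigma)
        np.testing.assert_allclose(t_sks, t_ske, rtol=1e-12)

    def test_invalid_prior_rejected(self, small_task):
        b, s, sigma = small_task
        with pytest.raises(ValueError):
            sks_bke_statistic(b, b, [s], [0.5], sigma)
        with pytest.raises(ValueError):
            sks_bke_statistic(b, b, [], None, sigma)

    def test_location_uncertainty_degrades_auc(self):
        # 4 disjoint candidate locations on a 32x32 grid, equal energy
        H, sigma = 32, 1.0
        b = np.zeros((1, H, H), complex)
        centers = [(8, 8), (8, 24), (24, 8), (24, 24)]
        sigs = [fft2c(render_gaussian_signal(
            SignalModel(0.7, 2.0, (float(r), float(c))), 1.0,
            (H, H)).pixels[None].astype(complex)) for r, c in centers]
        rng = np.random.default_rng(7)
        n = 4000
        noise = lambda: (rng.normal(0, sigma, (n, 1, H, H))
                         + 1j * rng.normal(0, sigma, (n, 1, H, H)))
        g0 = b[None] + noise()
        which = rng.integers(4, size=n)
        g1 = b[None] + np.stack([sigs[k] for k in which]) + noise()
        sks0 = sks_bke_statistic(g0, b, sigs, None, sigma)
        sks1 = sks_bke_statistic(g1, b, sigs, None, sigma)
        auc_sks = estimate_auc(sks0, sks1)
        # matched SKE reference: known location per draw
        ske0 = ske_bke_statistic(g0, b, sigs[0], sigma)
        ske1 = np.array([ske_bke_statistic(g1[i], b, sigs[k], sigma)
                         for i, k in enumerate(which[:1000])])
        auc_ske = estimate_auc(ske0[:1000], ske1)
        gap_se = np.hypot(auc_ske.se, auc_sks.se)
        assert auc_sks.auc < auc_ske.auc - 3 * gap_se


class TestHotelling:
    def test_template_aligns_with_matched_filter(self):
        # strong signal, heavy shrinkage toward the (white) diagonal
        H, sigma = 16, 0.5
        img = render_gaussian_signal(SignalModel(1.4, 2.0, (8.0, 8.0)),
                                     1.0, (H, H)).pixels
        s = fft2c(img[None].astype(complex))
        b = np.zeros((1, H, H), complex)
        rng = np.random.default_rng(3)
        x0 = draw_ske_kspace(b, s, sigma, 4000, False, rng)
        x1 = draw_ske_kspace(b, s, sigma, 4000, True, rng)
        assert as_real_vector(x0).shape[1] == 512
        fit = HotellingObserver(x0, x1, shrinkage=0.8).fit()
        w_opt = as_real_vector(s).ravel()
        cos = (fit.template @ w_opt
               / np.linalg.norm(fit.template) / np.linalg.norm(w_opt))
        assert np.degrees(np.arccos(cos)) < 5.0

    def test_auc_matches_analytic_io_for_gaussian_data(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(3)
        fit = HotellingObserver(
            draw_ske_kspace(b, s, sigma, 4000, False, rng),
            draw_ske_kspace(b, s, sigma, 4000, True, rng),
            shrinkage=0.01).fit()
        res = fit.auc(draw_ske_kspace(b, s, sigma, 2000, False, rng),
                      draw_ske_kspace(b, s, sigma, 2000, True, rng))
        ana = ske_bke_analytic_auc(s, None, sigma)
        assert abs(res.auc - ana.auc) < 2 * res.se

    def test_auc_invariant_to_input_scaling(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(8)
        x0 = draw_ske_kspace(b, s, sigma, 500, False, rng)
        x1 = draw_ske_kspace(b, s, sigma, 500, True, rng)
        t0 = draw_ske_kspace(b, s, sigma, 500, False, rng)
        t1 = draw_ske_kspace(b, s, sigma, 500, True, rng)
        auc_a = HotellingObserver(x0, x1).fit().auc(t0, t1).auc
        auc_b = HotellingObserver(10 * x0, 10 * x1).fit().auc(
            10 * t0, 10 * t1).auc
        assert auc_a == pytest.approx(auc_b, abs=1e-9)

    def test_singular_covariance_flagged(self):
        rng = np.random.default_rng(9)
        x0 = rng.normal(size=(5, 64))  # n << dim: rank-deficient covariance
        x1 = rng.normal(size=(5, 64)) + 0.5
        fit = HotellingObserver(x0, x1, shrinkage=0.0).fit()
        assert fit.singular

    def test_summary_mentions_shrinkage(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(10)
        fit = HotellingObserver(
            draw_ske_kspace(b, s, sigma, 50, False, rng),
            draw_ske_kspace(b, s, sigma, 50, True, rng),
            shrinkage=0.25).fit()
        assert "0.25" in fit.summary()


@pytest.fixture(scope="module")
def trained(small_task):
    b, s, sigma = small_task
    rng = np.random.default_rng(11)
    cfg = CnnIoConfig(max_stages=1, epochs_per_stage=6, channels=8, seed=0)
    model = CnnIdealObserver(
        draw_ske_kspace(b, s, sigma, 800, False, rng, np.complex64),
        draw_ske_kspace(b, s, sigma, 800, True, rng, np.complex64),
        draw_ske_kspace(b, s, sigma, 400, False, rng, np.complex64),
        draw_ske_kspace(b, s, sigma, 400, True, rng, np.complex64),
        config=cfg)
    return model.fit(), small_task


class TestCnnIo:
    def test_learns_detectable_signal(self, trained):
        res, (b, s, sigma) = trained
        ana = ske_bke_analytic_auc(s, None, sigma)
        assert res.val_auc > 0.5 + 0.6 * (ana.auc - 0.5)

    def test_trace_contract(self, trained):
        res, _ = trained
        assert len(res.auc_trace) >= 1
        assert res.val_auc == max(r["val_auc"] for r in res.auc_trace)

    def test_statistic_deterministic(self, trained, small_task):
        res, _ = trained
        b, s, sigma = small_task
        rng = np.random.default_rng(12)
        g = draw_ske_kspace(b, s, sigma, 8, True, rng, np.complex64)
        assert np.array_equal(res.statistic(g), res.statistic(g))

    def test_monotone_transform_preserves_auc(self, trained, small_task):
        res, _ = trained
        b, s, sigma = small_task
        rng = np.random.default_rng(13)
        g0 = draw_ske_kspace(b, s, sigma, 200, False, rng, np.complex64)
        g1 = draw_ske_kspace(b, s, sigma, 200, True, rng, np.complex64)
        t0, t1 = res.statistic(g0), res.statistic(g1)
        a = estimate_auc(t0, t1).auc
        b_ = estimate_auc(np.tanh(t0), np.tanh(t1)).auc
        assert a == pytest.approx(b_, abs=1e-12)

    def test_degenerate_labels_rejected(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(14)
        x = draw_ske_kspace(b, s, sigma, 4, False, rng)
        with pytest.raises(ValueError):
            CnnIdealObserver(x, np.empty((0, *b.shape)), x, x)


class TestSerialization:
    def test_hotelling_round_trip(self, small_task, tmp_path):
        from iobound import load_observer, save_observer

        b, s, sigma = small_task
        rng = np.random.default_rng(21)
        fit = HotellingObserver(
            draw_ske_kspace(b, s, sigma, 100, False, rng),
            draw_ske_kspace(b, s, sigma, 100, True, rng),
            shrinkage=0.2).fit()
        path = str(tmp_path / "hot.npz")
        save_observer(fit, path)
        loaded = load_observer(path)
        g = draw_ske_kspace(b, s, sigma, 10, True, rng)
        np.testing.assert_array_equal(fit.statistic(g), loaded.statistic(g))
        assert loaded.shrinkage == 0.2

    def test_cnn_round_trip(self, trained, small_task, tmp_path):
        from iobound import load_observer, save_observer

        res, _ = trained
        b, s, sigma = small_task
        path = str(tmp_path / "cnn.npz")
        save_observer(res, path)
        loaded = load_observer(path)
        rng = np.random.default_rng(22)
        g = draw_ske_kspace(b, s, sigma, 12, True, rng, np.complex64)
        np.testing.assert_allclose(res.statistic(g), loaded.statistic(g),
                                   rtol=1e-6)
        assert loaded.depth == res.depth
        assert loaded.auc_trace == res.auc_trace


class TestApplyObserver:
    def test_analytic_delegation_exact(self, small_task):
        b, s, sigma = small_task
        obs = SkeObserver(b, s, sigma)
        rng = np.random.default_rng(15)
        g = draw_ske_kspace(b, s, sigma, 6, True, rng)
        ts = apply_observer(obs, g)
        np.testing.assert_array_equal(ts.value,
                                      ske_bke_statistic(g, b, s, sigma))
        assert ts.observer_tag == "analytic_ske"

    def test_sks_delegation(self, small_task):
        b, s, sigma = small_task
        obs = SksObserver(b, [s], [1.0], sigma)
        rng = np.random.default_rng(16)
        g = draw_ske_kspace(b, s, sigma, 6, False, rng)
        ts = apply_observer(obs, g)
        np.testing.assert_array_equal(
            ts.value, sks_bke_statistic(g, b, [s], [1.0], sigma))

    def test_space_mismatch_rejected(self, small_task):
        b, s, sigma = small_task
        rng = np.random.default_rng(17)
        x0 = rng.normal(size=(20, 8, 8))
        x1 = x0 + 0.5
        fit = HotellingObserver(x0, x1, shrinkage=0.5).fit()
        complex_input = draw_ske_kspace(b, s, sigma, 2, False, rng)
        with pytest.raises(ValueError):
            apply_observer(fit, complex_input)

    def test_unknown_observer_type_rejected(self):
        with pytest.raises(TypeError):
            apply_observer(object(), np.zeros((1, 4, 4)))
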