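"""Parameter-map computations: smoothing, normalization, IAUC, ADC, nCBV."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, quad

from gbmalt import (AcquisitionConfig, DiffusionPair, DynamicSeries,
                    compute_adc, compute_iauc, compute_iauc_map, compute_ncbv,
                    detect_arrival, generate_dwi_pair, normalize_baseline,
                    smooth_lowpass)
from gbmalt.errors import (ConfigurationError, NilVoxelError, ParameterError,
                           TruncationError)
from gbmalt.synthetic import DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK, gamma_variate


class TestSmoothLowpass:
    def test_constant_curve_unchanged(self):
        c = np.full(50, 7.0)
        assert np.allclose(smooth_lowpass(c, 3), c)

    def test_spike_reduced_to_third(self):
        c = np.zeros(21)
        c[10] = 9.0
        out = smooth_lowpass(c, 3)
        assert out[10] == pytest.approx(3.0)
        assert out[9] == out[11] == pytest.approx(3.0)

    def test_mass_conserved_at_default_window(self, rng):
        for _ in range(20):
            c = rng.normal(size=rng.integers(5, 60))
            assert smooth_lowpass(c, 3).mean() == pytest.approx(
                c.mean(), abs=1e-9)

    def test_noise_reduction_on_gamma_variate(self, rng):
        t = np.arange(120) * 3.22
        clean = gamma_variate(t, 29.0, DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK)
        residuals_in, residuals_out = [], []
        for _ in range(100):
            noisy = clean + rng.normal(0, 0.05, clean.shape)
            residuals_in.append(np.std(noisy - clean))
            residuals_out.append(np.std(smooth_lowpass(noisy, 3) - clean))
        assert np.mean(residuals_out) < np.mean(residuals_in)

    @pytest.mark.parametrize("window", [0, 2, 4, -1])
    def test_rejects_even_or_nonpositive_window(self, window):
        with pytest.raises(ParameterError):
            smooth_lowpass(np.zeros(10), window)


class TestNormalizeBaseline:
    def test_constant_maps_to_zero(self):
        assert np.allclose(normalize_baseline(np.full(20, 42.0), 5), 0.0)

    def test_plateau_enhancement_fraction(self):
        c = np.r_[np.full(10, 100.0), np.full(20, 150.0)]
        out = normalize_baseline(c, 10)
        assert out[:10] == pytest.approx(0.0, abs=1e-12)
        assert out[10:] == pytest.approx(0.5)

    def test_zero_baseline_flags_nil_voxel(self):
        with pytest.raises(NilVoxelError):
            normalize_baseline(np.zeros(20), 5)

    def test_commutes_with_smoothing_on_flat_baseline(self):
        # both operations are linear, so the order must not matter as long
        # as the smoothing window does not leak enhancement into baseline
        c = np.r_[np.full(12, 80.0), 80.0 * (1 + np.linspace(0, 1, 18))]
        a = smooth_lowpass(normalize_baseline(c, 10), 3)
        b = normalize_baseline(smooth_lowpass(c, 3), 10)
        assert np.allclose(a, b, atol=1e-9)


class TestDetectArrival:
    def test_clean_step(self):
        c = np.r_[np.zeros(12), np.ones(20)]
        assert detect_arrival(c, 1.0, 10) == 12

    def test_flat_curve_falls_back_to_baseline_end(self):
        assert detect_arrival(np.zeros(30), 1.0, 10) == 10

    def test_gamma_variate_onset(self):
        t = np.arange(120) * 3.22
        g = gamma_variate(t, 32.2, DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK)
        assert detect_arrival(g, 3.22, 10) in (10, 11)


class TestComputeIauc:
    def test_zero_curve(self):
        assert compute_iauc(np.zeros(60), 10, 3.22) == 0.0

    def test_constant_after_arrival_integrates_to_window(self):
        c = np.r_[np.zeros(10), np.ones(50)]
        assert compute_iauc(c, 10, 3.22, window_s=30.0) == pytest.approx(30.0)

    def test_ramp_triangle_area_exact_for_trapezoid(self):
        # f(t) = t/30 over the 30 s window: trapezoids are exact on lines
        dt = 3.22
        c = np.r_[np.zeros(10), np.arange(50) * dt / 30.0]
        assert compute_iauc(c, 10, dt, 30.0) == pytest.approx(15.0, rel=1e-9)

    def test_trapezoid_matches_adaptive_quadrature_within_1pct(self):
        dt, n_baseline = 3.22, 10
        t = np.arange(120) * dt
        t0 = (n_baseline - 1) * dt
        g = gamma_variate(t, t0, DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK)
        arrival = detect_arrival(g, dt, n_baseline)
        iauc = compute_iauc(g, arrival, dt, 30.0)
        start = arrival * dt
        oracle, _ = quad(lambda x: gamma_variate(
            np.array([x]), t0, DCE_GAMMA_ALPHA, DCE_GAMMA_TPEAK)[0],
            start, start + 30.0)
        assert iauc == pytest.approx(oracle, rel=0.01)

    def test_window_beyond_acquisition_reports_truncation(self):
        with pytest.raises(TruncationError):
            compute_iauc(np.ones(15), 10, 3.22, window_s=30.0)

    def test_linear_in_amplitude(self):
        c = np.r_[np.zeros(10), np.random.default_rng(0).random(50)]
        one = compute_iauc(c, 10, 3.22)
        assert compute_iauc(3.5 * c, 10, 3.22) == pytest.approx(3.5 * one)


class TestComputeAdc:
    def test_known_decay(self):
        pair = DiffusionPair(np.full((4, 4, 2), 1000.0),
                             np.full((4, 4, 2), 367.8794411714423), b=1000.0)
        out = compute_adc(pair)
        assert out.values == pytest.approx(1.0)
        assert not out.nil_mask.any()

    def test_equal_signals_give_zero(self):
        pair = DiffusionPair(np.full((2, 2, 2), 500.0),
                             np.full((2, 2, 2), 500.0), b=1000.0)
        assert np.all(compute_adc(pair).values == 0.0)

    def test_zero_s0_is_nil(self):
        s0 = np.full((3, 3, 1), 800.0)
        s0[1, 1, 0] = 0.0
        pair = DiffusionPair(s0, np.full((3, 3, 1), 300.0), b=1000.0)
        out = compute_adc(pair)
        assert out.nil_mask[1, 1, 0]
        assert out.nil_mask.sum() == 1

    def test_noiseless_roundtrip_identity(self, rng):
        field = rng.uniform(0.3, 2.5, (8, 8, 4))
        pair = generate_dwi_pair(field, s0=1000.0, b=1000.0, noise_sd=0.0)
        out = compute_adc(pair)
        assert np.abs(out.values - field).max() < 1e-9

    def test_rmse_under_5pct_at_snr_50(self, rng):
        # SNR quoted on the diffusion-weighted volume, same receiver noise
        # on both volumes
        field = np.full((16, 16, 8), 1.0)
        sb_mean = 1000.0 * np.exp(-1.0)
        pair = generate_dwi_pair(field, s0=1000.0, b=1000.0,
                                 noise_sd=sb_mean / 50.0, seed=4)
        out = compute_adc(pair)
        ok = ~out.nil_mask
        rmse = np.sqrt(np.mean((out.values[ok] - field[ok]) ** 2))
        assert rmse < 0.05 * 1.0


class TestComputeIaucMap:
    def test_recovers_amplitude_field(self, acq):
        from gbmalt import generate_dce_volume
        field = np.zeros((6, 6, 3))
        field[2:4, 2:4, 1] = 8.64
        series = generate_dce_volume(field, acq, noise_sd=0.0)
        out = compute_iauc_map(series, smooth_window=1)
        assert out.values[2, 2, 1] == pytest.approx(8.64, abs=1e-6)
        assert out.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_signal_loss_voxels_flagged_nil(self, acq):
        from gbmalt import generate_dce_volume
        field = np.full((6, 6, 3), 4.0)
        series = generate_dce_volume(field, acq, noise_sd=0.0)
        series.si[0, 0, 0, :] = 0.5     # below 5% of the median baseline
        out = compute_iauc_map(series)
        assert out.nil_mask[0, 0, 0]
        assert out.nil_mask.sum() == 1
        assert out.values[0, 0, 0] == 0.0


def _leakage_phantom(k1, k2, te=0.040, dt=1.808, n_dyn=60, n_base=10,
                     baseline=600.0, noise_sd=0.0, seed=0):
    """DSC stack whose voxels follow dR2*(t) = k1·r(t) − k2·∫r exactly."""
    from gbmalt.synthetic import _dsc_shape
    acq = AcquisitionConfig(n_dynamics_dsc=n_dyn, n_baseline_dsc=n_base,
                            dt_dsc=dt, te_dsc=te,
                            grid_shape=k1.shape)
    shape = 10.0 * _dsc_shape(acq, recirculation=False)
    cum = cumulative_trapezoid(shape, dx=dt, initial=0.0)
    dr2 = k1[..., None] * shape - k2[..., None] * cum
    si = baseline * np.exp(-te * dr2)
    if noise_sd:
        si += np.random.default_rng(seed).normal(0, noise_sd, si.shape)
    return DynamicSeries(np.maximum(si, 0.0), dt=dt, n_baseline=n_base, te=te)


class TestComputeNcbv:
    def _nawm(self, grid):
        m = np.zeros(grid, dtype=bool)
        m[0:2] = True
        return m

    def test_scale_ratio_recovered_without_leakage(self):
        k1 = np.ones((6, 6, 2))
        k1[3:, 3:, :] = 2.5
        dsc = _leakage_phantom(k1, np.zeros_like(k1))
        out = compute_ncbv(dsc, self._nawm(k1.shape))
        assert out.values[4, 4, 0] == pytest.approx(2.5, rel=1e-6)

    def test_nawm_self_normalizes_to_one(self):
        k1 = np.ones((6, 6, 2)) * 1.7
        dsc = _leakage_phantom(k1, np.zeros_like(k1))
        nawm = self._nawm(k1.shape)
        out = compute_ncbv(dsc, nawm)
        assert out.values[nawm].mean() == pytest.approx(1.0, abs=1e-9)

    def test_dead_voxel_is_nil(self):
        k1 = np.ones((6, 6, 2))
        dsc = _leakage_phantom(k1, np.zeros_like(k1))
        dsc.si[5, 5, 1, :] = 0.0
        out = compute_ncbv(dsc, self._nawm(k1.shape))
        assert out.nil_mask[5, 5, 1]
        assert out.values[5, 5, 1] == 0.0

    def test_scale_invariance(self):
        k1 = np.ones((6, 6, 2))
        k1[3, 3, 0] = 2.0
        dsc = _leakage_phantom(k1, np.full_like(k1, 0.05))
        a = compute_ncbv(dsc, self._nawm(k1.shape)).values
        dsc2 = DynamicSeries(dsc.si * 3.7, dt=dsc.dt,
                             n_baseline=dsc.n_baseline, te=dsc.te)
        b = compute_ncbv(dsc2, self._nawm(k1.shape)).values
        assert np.allclose(a, b, atol=1e-9)

    def test_leakage_correction_reduces_bias(self, rng):
        # a small tumor leaks (k2 > 0) on top of a monotone T1-driven ramp;
        # the surrounding brain and the NAWM do not. Truth is k1 itself.
        grid = (12, 12, 4)
        k1 = np.ones(grid)
        k2 = np.zeros(grid)
        lesion = np.zeros(grid, dtype=bool)
        lesion[5:9, 5:9, 1:3] = True
        k1[lesion] = rng.uniform(1.0, 3.0, int(lesion.sum()))
        k2[lesion] = 0.15
        nawm = self._nawm(grid)
        dsc = _leakage_phantom(k1, k2, noise_sd=1.0, seed=11)
        corr = compute_ncbv(dsc, nawm, leakage_correction=True).values
        unc = compute_ncbv(dsc, nawm, leakage_correction=False).values
        better = (np.abs(corr - k1) < np.abs(unc - k1))[lesion]
        assert better.mean() >= 0.95

    def test_empty_nawm_is_configuration_error(self):
        k1 = np.ones((4, 4, 2))
        dsc = _leakage_phantom(k1, np.zeros_like(k1))
        with pytest.raises(ConfigurationError):
            compute_ncbv(dsc, np.zeros(k1.shape, dtype=bool))
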