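"""DICS beamformer: CSD, spatial filters, pseudo-t maps, virtual sensors."""

import numpy as np
import pytest
from scipy import signal as sps

from visent.beamform import (
    CrossSpectralDensity,
    compute_csd,
    dics_filters,
    find_peak_voxel,
    source_power_map,
    virtual_sensor,
)
from visent.preprocess import SensorEpochs
from visent.synth import SyntheticConfig, simulate_subject
from visent.tfr import DEFAULT_NUMTAPS

FS = 1000.0


def _epochs(data):
    return SensorEpochs(data=data, fs=FS, t0_index=600, window_ms=(-600.0, 3200.0))


def _sine_epochs(n_trials=4, n_sensors=6, amp_per_sensor=None, f=15.0, seed=0):
    t = -0.6 + np.arange(3800) / FS
    rng = np.random.default_rng(seed)
    if amp_per_sensor is None:
        amp_per_sensor = rng.uniform(0.5, 2.0, n_sensors)
    data = np.zeros((n_trials, n_sensors, 3800))
    for i in range(n_trials):
        phase = rng.uniform(0, 2 * np.pi)
        data[i] = amp_per_sensor[:, None] * np.sin(2 * np.pi * f * t + phase)
    return _epochs(data)


class TestCSD:
    def test_common_sinusoid_gives_rank_one_csd(self):
        csd = compute_csd(_sine_epochs())
        ev = np.sort(np.linalg.eigvalsh(csd.matrix).real)[::-1]
        assert ev[1] < 1e-8 * ev[0]

    def test_hermitian_on_random_data(self):
        rng = np.random.default_rng(1)
        csd = compute_csd(_epochs(rng.standard_normal((6, 5, 3800))))
        assert np.abs(csd.matrix - csd.matrix.conj().T).max() < 1e-10
        assert np.all(np.diag(csd.matrix).real >= 0)
        assert np.abs(np.diag(csd.matrix).imag).max() < 1e-12

    def test_white_noise_diagonal_matches_welch_oracle(self):
        """FFT/Welch cross-spectrum oracle, scaled by the demodulation
        kernel's noise bandwidth."""
        rng = np.random.default_rng(2)
        data = rng.standard_normal((40, 4, 3800))
        csd = compute_csd(_epochs(data), band=(14.5, 15.5), window_ms=(200, 2000))
        h = sps.firwin(DEFAULT_NUMTAPS, 1.0, fs=FS, window="hamming")
        h /= h.sum()
        enbw = np.sum(h**2)
        diag = np.diag(csd.matrix).real
        for s in range(4):
            f, p1 = sps.welch(data[:, s, :], fs=FS, nperseg=1900)
            psd_band = p1.mean(axis=0)[(f >= 13) & (f <= 17)].mean()
            expected = 2.0 * psd_band * FS * enbw
            assert abs(diag[s] - expected) < 0.05 * expected

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            compute_csd(_sine_epochs(), band=(16.0, 15.0))

    def test_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            compute_csd(_sine_epochs(), window_ms=(3000, 4000))


class TestFilters:
    def test_unit_gain_identity(self, leadfield):
        csd = compute_csd(_sine_epochs(n_sensors=leadfield.n_sensors, seed=3))
        filt = dics_filters(csd, leadfield)
        gains = np.einsum("vs,vs->v", filt.weights, leadfield.gains)
        assert np.allclose(gains, 1.0, atol=1e-8)

    def test_identity_covariance_closed_form(self, leadfield):
        csd = CrossSpectralDensity(
            np.eye(leadfield.n_sensors, dtype=complex), (14.5, 15.5), (200, 2000), 1
        )
        filt = dics_filters(csd, leadfield, lambda_frac=0.0)
        L = leadfield.gains
        expected = L / np.sum(L**2, axis=1, keepdims=True)
        assert np.allclose(filt.weights, expected, atol=1e-10)

    def test_noise_free_single_source_localizes_exactly(self, leadfield, quiet_config):
        from dataclasses import replace

        true_voxel = 37
        # noise-free baseline power would be exactly zero, so add a
        # whisper of sensor noise for a finite denominator
        cfg = replace(quiet_config, sensor_noise_sd=1e-4)
        rec = simulate_subject(cfg, "HC", 21, leadfield, source_voxel=true_voxel)
        act = compute_csd(rec.epochs, window_ms=(200, 2000))
        base = compute_csd(rec.epochs, window_ms=(-600, 0))
        filt = dics_filters(act, leadfield)
        m = source_power_map(filt, act, base)
        assert int(np.argmax(m.pseudo_t)) == true_voxel


class TestSourcePowerMap:
    def test_equal_csds_give_zero_map(self, leadfield):
        csd = compute_csd(_sine_epochs(n_sensors=leadfield.n_sensors, seed=4))
        filt = dics_filters(csd, leadfield)
        m = source_power_map(filt, csd, csd)
        assert np.allclose(m.pseudo_t, 0.0, atol=1e-12)

    def test_scale_invariance(self, leadfield):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((8, leadfield.n_sensors, 3800))
        data[:, :, 800:2000] *= 3.0
        for c, ref in ((1.0, None), (7.3, None)):
            ep = _epochs(c * data)
            act = compute_csd(ep, window_ms=(200, 2000))
            base = compute_csd(ep, window_ms=(-600, 0))
            filt = dics_filters(act, leadfield)
            m = source_power_map(filt, act, base).pseudo_t
            if c == 1.0:
                m_ref = m
        assert np.allclose(m, m_ref, rtol=1e-9)

    def test_sqrt2_amplitude_ratio_gives_pseudo_t_one(self, leadfield):
        """Active amplitude sqrt(2) x baseline -> power ratio 2 -> pseudo-t 1."""
        t = -0.6 + np.arange(3800) / FS
        v = 21
        rng = np.random.default_rng(6)
        data = np.zeros((6, leadfield.n_sensors, 3800))
        for i in range(6):
            amp = np.where((t >= 0.2) & (t <= 2.0), np.sqrt(2.0), 1.0)
            src = amp * np.sin(2 * np.pi * 15.0 * t + rng.uniform(0, 2 * np.pi))
            data[i] = leadfield.gains[v][:, None] * src[None, :]
        ep = _epochs(data)
        act = compute_csd(ep, window_ms=(400, 1800))
        base = compute_csd(ep, window_ms=(-500, -100))
        filt = dics_filters(act, leadfield)
        m = source_power_map(filt, act, base)
        assert abs(m.pseudo_t[v] - 1.0) < 0.05

    def test_band_mismatch_rejected(self, leadfield):
        a = compute_csd(_sine_epochs(n_sensors=leadfield.n_sensors), band=(14.5, 15.5))
        b = compute_csd(_sine_epochs(n_sensors=leadfield.n_sensors), band=(29.5, 30.5))
        filt = dics_filters(a, leadfield)
        with pytest.raises(ValueError, match="band"):
            source_power_map(filt, a, b)


class TestPeakVoxel:
    def _map(self, values):
        from visent.beamform import SourcePowerMap

        v = np.asarray(values, dtype=float)
        return SourcePowerMap(v, v + 1, np.ones_like(v), np.zeros((len(v), 3)))

    def test_single_map_unique_max(self):
        idx, grand = find_peak_voxel([self._map([0.1, 3.0, 0.2])])
        assert idx == 1

    def test_grand_average_argmax_by_brute_force(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        idx, grand = find_peak_voxel([self._map(a), self._map(b)])
        best = max(range(50), key=lambda i: (a[i] + b[i]) / 2)  # exhaustive scan
        assert idx == best
        assert np.allclose(grand, (a + b) / 2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            find_peak_voxel([self._map([1, 2]), self._map([1, 2, 3])])


class TestVirtualSensor:
    def test_exact_recovery_under_unit_gain(self, leadfield):
        rng = np.random.default_rng(8)
        v = 12
        s = rng.standard_normal((5, 3800))
        data = leadfield.gains[v][None, :, None] * s[:, None, :]
        ep = _epochs(data)
        csd = compute_csd(ep)
        filt = dics_filters(csd, leadfield)
        vs = virtual_sensor(filt, v, ep)
        assert np.allclose(vs, s, atol=1e-8)

    def test_linearity(self, leadfield):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((3, leadfield.n_sensors, 3800))
        y = rng.standard_normal((3, leadfield.n_sensors, 3800))
        csd = compute_csd(_epochs(x + y))
        filt = dics_filters(csd, leadfield)
        vs = virtual_sensor(filt, 5, _epochs(2 * x + 3 * y))
        vx = virtual_sensor(filt, 5, _epochs(x))
        vy = virtual_sensor(filt, 5, _epochs(y))
        assert np.allclose(vs, 2 * vx + 3 * vy, rtol=1e-10)

    def test_noisy_single_source_correlation_above_0p9(self, leadfield):
        from dataclasses import replace

        cfg = SyntheticConfig(n_trials=20)
        rec = simulate_subject(cfg, "HC", 33, leadfield, source_voxel=42)
        act = compute_csd(rec.epochs, window_ms=(200, 2000))
        filt = dics_filters(act, leadfield)
        vs = virtual_sensor(filt, 42, rec.epochs)
        # exact ground-truth source series: rerun the same subject seed
        # without sensor noise (the source draws are unchanged)
        clean = simulate_subject(
            replace(cfg, sensor_noise_sd=0.0), "HC", 33, leadfield, source_voxel=42
        )
        sensor_best = int(np.argmax(np.abs(leadfield.gains[42])))
        true_series = (
            clean.epochs.data[:, sensor_best, :] / leadfield.gains[42, sensor_best]
        )
        sel = slice(800, 2600)
        r = np.corrcoef(vs[:, sel].ravel(), true_series[:, sel].ravel())[0, 1]
        assert r > 0.9

    def test_sensor_count_mismatch_rejected(self, leadfield):
        csd = compute_csd(_sine_epochs(n_sensors=leadfield.n_sensors))
        filt = dics_filters(csd, leadfield)
        with pytest.raises(ValueError, match="sensor"):
            virtual_sensor(filt, 0, _sine_epochs(n_sensors=4))
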