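"""Ambiguity function, RID-Rihaczek distribution and phase extraction."""

import numpy as np
import pytest

from dynfc.tfd import (
    SignalEpoch,
    ambiguity,
    choi_williams_kernel,
    phase,
    rid_rihaczek,
)


def brute_force_ambiguity(x):
    """Direct double-loop evaluation of A[m, l] = sum_n R[n, l] e^{-j2pi mn/L}."""
    L = x.size
    A = np.zeros((L, L), dtype=complex)
    for m in range(L):
        for l in range(L):
            for n in range(L):
                A[m, l] += x[n] * np.conj(x[(n - l) % L]) * np.exp(-2j * np.pi * m * n / L)
    return A


def direct_rihaczek(x):
    """(1/2pi) x[n] X*[k] e^{-j2pi nk/L} evaluated term by term."""
    L = x.size
    X = np.fft.fft(x)
    n, k = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    return x[:, None] * np.conj(X)[None, :] * np.exp(-2j * np.pi * n * k / L) / (2 * np.pi)


class TestAmbiguity:
    def test_impulse_support_is_zero_lag_only(self):
        x = np.zeros(8, dtype=complex)
        x[0] = 1.0
        A = ambiguity(x)
        # single-sample signal: R[n, l] nonzero only at n = 0, l = 0
        assert A[0, 0] == pytest.approx(1.0)
        assert np.allclose(np.abs(A[:, 1:]), 0.0)
        # constant over Doppler at zero lag
        assert np.allclose(A[:, 0], A[0, 0])

    def test_complex_exponential_energy_at_origin(self):
        L = 16
        x = np.exp(2j * np.pi * 3 * np.arange(L) / L)
        A = ambiguity(x)
        assert A[0, 0] == pytest.approx(L)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.normal(size=16) + 1j * rng.normal(size=16)
        A = ambiguity(x)
        assert np.allclose(A, brute_force_ambiguity(x), atol=1e-10)
        assert A[0, 0] == pytest.approx(np.sum(np.abs(x) ** 2))

    def test_zero_signal_warns(self):
        with pytest.warns(UserWarning):
            A = ambiguity(np.zeros(8))
        assert np.allclose(A, 0.0)

    def test_real_input_converted_to_analytic(self):
        x = np.cos(2 * np.pi * 4 * np.arange(32) / 32)
        A = ambiguity(x)
        # analytic signal of a unit cosine has energy L/... > 0 at origin
        assert np.abs(A[0, 0]) > 0


class TestRidRihaczek:
    @pytest.mark.parametrize("L", [8, 32, 64])
    def test_sigma_inf_equals_direct_product_form(self, rng, L):
        x = rng.normal(size=L) + 1j * rng.normal(size=L)
        C = rid_rihaczek(x, sigma=np.inf).values
        assert np.abs(C - direct_rihaczek(x)).max() < 1e-8

    def test_finite_sigma_path_with_huge_sigma_approaches_product_form(self, rng):
        # the ambiguity-domain round trip itself (not the sigma=inf shortcut)
        x = rng.normal(size=16) + 1j * rng.normal(size=16)
        C = rid_rihaczek(x, sigma=1e12).values
        assert np.abs(C - direct_rihaczek(x)).max() < 1e-6

    def test_monochromatic_energy_concentrated_at_carrier_bin(self):
        L, k0 = 64, 7
        x = np.exp(2j * np.pi * k0 * np.arange(L) / L + 0.5j)
        C = rid_rihaczek(x, sigma=np.inf).values
        mag = np.abs(C)
        assert np.argmax(mag.sum(axis=0)) == k0
        assert np.abs(np.delete(mag, k0, axis=1)).max() < 1e-10

    def test_monochromatic_phase_constant_along_time_at_carrier(self):
        L, k0 = 64, 7
        x = np.exp(2j * np.pi * k0 * np.arange(L) / L + 0.3j)
        C = rid_rihaczek(x, sigma=np.inf).values
        ph = np.angle(C[:, k0])
        assert np.allclose(ph, ph[0], atol=1e-10)

    def test_cross_term_beating_suppressed_by_kernel(self):
        # Rihaczek cross-terms of a two-tone signal beat in time on the
        # auto columns; the Choi-Williams kernel removes the beating.
        L = 64
        t = np.arange(L)
        x = np.exp(2j * np.pi * 8 * t / L) + np.exp(2j * np.pi * 24 * t / L)
        std_inf = np.std(np.abs(rid_rihaczek(x, sigma=np.inf).values[:, 8]))
        std_fin = np.std(np.abs(rid_rihaczek(x, sigma=0.01).values[:, 8]))
        assert std_fin < 0.1 * std_inf

    def test_offaxis_ambiguity_energy_monotone_in_sigma(self):
        L = 64
        t = np.arange(L)
        x = np.exp(2j * np.pi * 8 * t / L) + np.exp(2j * np.pi * 24 * t / L)
        A = ambiguity(x)
        offaxis = np.ones((L, L), dtype=bool)
        offaxis[0, :] = False
        offaxis[:, 0] = False
        energies = [
            np.sum(np.abs(A * choi_williams_kernel(L, s))[offaxis])
            for s in [np.inf, 1.0, 0.1, 0.01, 0.001]
        ]
        assert all(a >= b - 1e-9 for a, b in zip(energies, energies[1:]))

    def test_one_sided_grid_for_real_input(self):
        ep = SignalEpoch(np.sin(2 * np.pi * 5 * np.arange(128) / 128), fs=128.0, t0=-500.0)
        tf = rid_rihaczek(ep, sigma=np.inf)
        assert tf.freq_axis[0] == 0.0
        assert tf.freq_axis[-1] == pytest.approx(64.0)
        assert tf.values.shape == (128, 65)
        assert tf.time_axis[0] == pytest.approx(-500.0)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            rid_rihaczek(np.ones(8), sigma=0.0)
        with pytest.raises(ValueError):
            rid_rihaczek(np.ones(8), sigma=-1.0)


class TestPhase:
    def test_unit_distribution_has_zero_phase(self):
        from dynfc.tfd import TFDMatrix

        tf = TFDMatrix(np.ones((4, 4), complex), np.arange(4), np.arange(4))
        pm = phase(tf)
        assert np.all(pm.valid_mask)
        assert np.allclose(pm.values, 0.0)

    def test_negative_real_maps_to_plus_pi(self):
        from dynfc.tfd import TFDMatrix

        tf = TFDMatrix(np.full((2, 2), -1 + 0j), np.arange(2), np.arange(2))
        pm = phase(tf)
        assert np.allclose(pm.values, np.pi)

    def test_zero_entries_masked_even_with_zero_floor(self):
        from dynfc.tfd import TFDMatrix

        vals = np.ones((2, 2), complex)
        vals[0, 0] = 0.0
        tf = TFDMatrix(vals, np.arange(2), np.arange(2))
        pm = phase(tf, magnitude_floor=0.0)
        assert not pm.valid_mask[0, 0]
        assert pm.valid_mask[1, 1]

    def test_wrapped_range(self, rng):
        from dynfc.tfd import TFDMatrix

        vals = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        pm = phase(TFDMatrix(vals, np.arange(8), np.arange(8)))
        v = pm.values[pm.valid_mask]
        assert np.all(v > -np.pi) and np.all(v <= np.pi)


class TestSignalEpoch:
    def test_validation(self):
        with pytest.raises(ValueError):
            SignalEpoch(np.array([1.0]), fs=128.0)
        with pytest.raises(ValueError):
            SignalEpoch(np.array([1.0, np.nan]), fs=128.0)
        with pytest.raises(ValueError):
            SignalEpoch(np.ones(4), fs=0.0)

    def test_time_axis_convention(self):
        ep = SignalEpoch(np.zeros(256), fs=128.0, t0=-1000.0)
        assert ep.time_axis[0] == -1000.0
        assert ep.time_axis[1] - ep.time_axis[0] == pytest.approx(1000.0 / 128.0)
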