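"""Morlet CWT, coherence, semblance: localisation, ranges, phase fidelity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirscoupling.coupling import (
    CouplingMap,
    WaveletConfig,
    band_average,
    coherence_map,
    couple_recording,
    cwt_morlet,
    semblance_map,
)
from nirscoupling.errors import ConfigurationError, DegenerateSignalError, GridMismatchError
from nirscoupling.preprocess import make_signal_set
from nirscoupling.synthetic import CouplingScenario, generate_chromophore_series

FS = 0.5
NO_SMOOTH = WaveletConfig(smoothing_time_scalefactor=0.0, smoothing_scale_octaves=0.0)


def _sin(f, t, phase=0.0):
    return np.sin(2 * np.pi * f * t - phase)


class TestCwt:
    def test_linearity_in_amplitude(self, time_vector, wcfg):
        x = _sin(0.04, time_vector)
        Wa = cwt_morlet(x, FS, wcfg)
        Wb = cwt_morlet(3.5 * x, FS, wcfg)
        np.testing.assert_allclose(Wb.W, 3.5 * Wa.W, atol=1e-9)

    def test_scalogram_peaks_at_oscillation_frequency(self, time_vector, wcfg):
        W = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        mid = time_vector.size // 2
        peak_freq = W.freqs[np.argmax(np.abs(W.W[:, mid]))]
        nearest = W.freqs[np.argmin(np.abs(W.freqs - 0.04))]
        assert peak_freq == nearest

    def test_two_tones_give_two_local_maxima(self, time_vector, wcfg):
        x = _sin(0.03, time_vector) + _sin(0.10, time_vector)
        W = cwt_morlet(x, FS, wcfg)
        mag = np.abs(W.W[:, time_vector.size // 2])
        local_max = np.flatnonzero((mag[1:-1] > mag[:-2]) & (mag[1:-1] > mag[2:])) + 1
        top_two = local_max[np.argsort(mag[local_max])][-2:]
        found = sorted(W.freqs[top_two])
        for f_expected, f_found in zip([0.03, 0.10], found):
            nearest = W.freqs[np.argmin(np.abs(W.freqs - f_expected))]
            assert f_found == nearest

    def test_degenerate_signal_raises(self, wcfg):
        with pytest.raises(DegenerateSignalError, match="degenerate"):
            cwt_morlet(np.full(900, 3.0), FS, wcfg)

    def test_frequency_span_covers_band_and_nyquist(self, time_vector, wcfg):
        W = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        assert W.freqs.max() == pytest.approx(FS / 2)
        assert W.freqs.min() <= wcfg.band_low / 2 * 1.0001

    def test_coi_excludes_edges(self, time_vector, wcfg):
        W = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        assert np.isinf(W.coi[0]) and np.isinf(W.coi[-1])
        assert W.coi[time_vector.size // 2] < 0.02  # mid-record reliable in band


class TestCoherence:
    def test_self_coherence_is_one(self, time_vector, wcfg):
        # broadband signal: auto-power is well above rounding noise at every
        # cell, so the identity |S(WW*)|^2 = S(|W|^2)^2 holds numerically
        x = np.random.default_rng(1).normal(size=time_vector.size)
        W = cwt_morlet(x, FS, wcfg)
        cmap = coherence_map(W, W, wcfg)
        interior = cmap.coherence[:, 100:-100]
        assert np.all(np.abs(interior - 1.0) < 1e-6)

    def test_self_coherence_narrowband_in_band_cells(self, time_vector, wcfg):
        # for a tonal signal the identity is checked where the signal has
        # power: all cells inside the analysis band
        x = _sin(0.04, time_vector) + 0.3 * _sin(0.11, time_vector)
        W = cwt_morlet(x, FS, wcfg)
        cmap = coherence_map(W, W, wcfg)
        rows = (W.freqs >= wcfg.band_low) & (W.freqs <= wcfg.band_high)
        assert np.all(np.abs(cmap.coherence[rows, 100:-100] - 1.0) < 1e-6)

    def test_no_smoothing_degeneracy(self, time_vector):
        # |ab*|^2 = |a|^2 |b|^2: without smoothing coherence is 1 for ANY pair,
        # which proves the default smoothing is what makes the estimator work
        rng = np.random.default_rng(0)
        Wx = cwt_morlet(rng.normal(size=900), FS, NO_SMOOTH)
        Wy = cwt_morlet(rng.normal(size=900), FS, NO_SMOOTH)
        cmap = coherence_map(Wx, Wy, NO_SMOOTH)
        assert np.all(np.abs(cmap.coherence - 1.0) < 1e-6)

    def test_independent_noise_low_band_coherence(self, wcfg):
        rng = np.random.default_rng(42)
        below = 0
        for _ in range(30):
            Wx = cwt_morlet(rng.normal(size=900), FS, wcfg)
            Wy = cwt_morlet(rng.normal(size=900), FS, wcfg)
            s = band_average(coherence_map(Wx, Wy, wcfg), wcfg)
            below += s.band_coherence < 0.5
        assert below >= 29

    def test_grid_mismatch(self, time_vector, wcfg):
        Wx = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        Wy = cwt_morlet(_sin(0.04, time_vector[:800]), FS, wcfg)
        with pytest.raises(GridMismatchError):
            coherence_map(Wx, Wy, wcfg)


class TestSemblance:
    def test_identical_signals_plus_one(self, time_vector, wcfg):
        W = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        s = band_average(semblance_map(W, W), wcfg)
        assert s.band_semblance == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_minus_one(self, time_vector, wcfg):
        x = _sin(0.04, time_vector)
        Wx = cwt_morlet(x, FS, wcfg)
        Wy = cwt_morlet(-x, FS, wcfg)
        s = band_average(semblance_map(Wx, Wy), wcfg)
        assert s.band_semblance == pytest.approx(-1.0, abs=1e-9)

    def test_quadrature_near_zero(self, time_vector, wcfg):
        Wx = cwt_morlet(np.sin(2 * np.pi * 0.04 * time_vector), FS, wcfg)
        Wy = cwt_morlet(np.cos(2 * np.pi * 0.04 * time_vector), FS, wcfg)
        s = band_average(semblance_map(Wx, Wy), wcfg)
        assert abs(s.band_semblance) <= 0.05

    @pytest.mark.parametrize("lag", [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4, np.pi])
    def test_phase_fidelity(self, time_vector, wcfg, lag):
        Wx = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        Wy = cwt_morlet(_sin(0.04, time_vector, phase=lag), FS, wcfg)
        s = band_average(semblance_map(Wx, Wy), wcfg)
        assert s.band_semblance == pytest.approx(np.cos(lag), abs=0.05)

    def test_semblance_equals_cos_phase(self, time_vector, wcfg):
        Wx = cwt_morlet(_sin(0.04, time_vector), FS, wcfg)
        Wy = cwt_morlet(_sin(0.035, time_vector), FS, wcfg)
        smap = semblance_map(Wx, Wy)
        np.testing.assert_allclose(smap.semblance, np.cos(smap.phase), atol=1e-12)


class TestBandAverage:
    def _constant_map(self, value_phase, n_f=20, n_t=100):
        freqs = 0.25 * 2.0 ** (-np.arange(n_f) / 4.0)
        t = np.arange(n_t) * 2.0
        phase = np.full((n_f, n_t), value_phase)
        return CouplingMap(
            freqs=freqs, t=t, phase=phase, semblance=np.cos(phase),
            coi=np.zeros(n_t), coherence=np.ones((n_f, n_t)),
        )

    def test_mean_of_constant_coherence(self, wcfg):
        s = band_average(self._constant_map(0.0), wcfg)
        assert s.band_coherence == pytest.approx(1.0)

    def test_mean_of_constant_semblance(self, wcfg):
        s = band_average(self._constant_map(np.pi / 3), wcfg)
        assert s.band_semblance == pytest.approx(0.5, abs=1e-12)

    def test_identical_sinusoid_pair_high_coherence(self, time_vector, wcfg):
        x = _sin(0.04, time_vector)
        W = cwt_morlet(x, FS, wcfg)
        s = band_average(coherence_map(W, W, wcfg), wcfg)
        assert s.band_coherence >= 0.99

    def test_short_record_coi_exhaustion(self):
        # a band so slow that no cell of a 128 s record escapes edge effects
        cfg = WaveletConfig(band_low=0.002, band_high=0.003)
        t = np.arange(64) / FS
        W = cwt_morlet(_sin(0.04, t), FS, cfg)
        with pytest.raises(ConfigurationError, match="cone of influence"):
            band_average(coherence_map(W, W, cfg), cfg)

    def test_coi_include_policy_uses_all_band_cells(self, time_vector):
        cfg_inc = WaveletConfig(coi_policy="include")
        W = cwt_morlet(_sin(0.04, time_vector), FS, cfg_inc)
        s_inc = band_average(coherence_map(W, W, cfg_inc), cfg_inc)
        cfg_exc = WaveletConfig()
        s_exc = band_average(coherence_map(W, W, cfg_exc), cfg_exc)
        assert s_inc.n_cells > s_exc.n_cells


class TestProperties:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_ranges_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        cfg = WaveletConfig()
        Wx = cwt_morlet(rng.normal(size=300), FS, cfg)
        Wy = cwt_morlet(rng.normal(size=300), FS, cfg)
        cmap = coherence_map(Wx, Wy, cfg)
        smap = semblance_map(Wx, Wy)
        assert np.all((cmap.coherence >= 0) & (cmap.coherence <= 1))
        assert np.all((smap.semblance >= -1) & (smap.semblance <= 1))

    def test_symmetry(self, time_vector, wcfg):
        rng = np.random.default_rng(3)
        Wx = cwt_morlet(rng.normal(size=900), FS, wcfg)
        Wy = cwt_morlet(rng.normal(size=900), FS, wcfg)
        np.testing.assert_allclose(
            coherence_map(Wx, Wy, wcfg).coherence,
            coherence_map(Wy, Wx, wcfg).coherence, atol=1e-12,
        )
        np.testing.assert_allclose(
            semblance_map(Wx, Wy).semblance,
            semblance_map(Wy, Wx).semblance, atol=1e-12,
        )

    def test_amplitude_invariance(self, time_vector, wcfg):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=900), rng.normal(size=900)
        base_c = coherence_map(cwt_morlet(x, FS, wcfg), cwt_morlet(y, FS, wcfg), wcfg)
        scaled_c = coherence_map(
            cwt_morlet(7.3 * x, FS, wcfg), cwt_morlet(0.002 * y, FS, wcfg), wcfg
        )
        assert np.max(np.abs(base_c.coherence - scaled_c.coherence)) <= 1e-9
        assert np.max(np.abs(base_c.semblance - scaled_c.semblance)) <= 1e-9


class TestCoupleRecording:
    def test_sign_pattern_matches_construction(self, wcfg):
        sc = CouplingScenario(coupling=1.0, phase_lag=0.0, noise_sd=0.05,
                              hhb_gain=0.6, seed=21)
        sset = make_signal_set(generate_chromophore_series(sc))
        res = couple_recording(sset, wcfg)
        assert res["oxCCO-HbO2"].band_semblance > 0
        assert res["oxCCO-HHb"].band_semblance < 0
        assert res["oxCCO-HbT"].band_semblance > 0
        assert res["oxCCO-HbDiff"].band_semblance > 0

    def test_uncoupled_scenario_lower_coherence(self, wcfg):
        # paired seeds: rho=0 must lose band coherence relative to rho=1
        for seed in (31, 32, 33):
            res = {}
            for rho in (1.0, 0.0):
                sc = CouplingScenario(coupling=rho, noise_sd=0.3, hhb_gain=0.6, seed=seed)
                sset = make_signal_set(generate_chromophore_series(sc))
                res[rho] = couple_recording(sset, wcfg)
            for pair in res[1.0]:
                assert res[1.0][pair].band_coherence > res[0.0][pair].band_coherence

    def test_degenerate_oxcco_raises(self, wcfg, scenario):
        sset = make_signal_set(generate_chromophore_series(scenario), denoise=False)
        sset.signals["oxcco"][:] = 0.0
        with pytest.raises(DegenerateSignalError):
            couple_recording(sset, wcfg)

    def test_all_pairs_share_config(self, wcfg):
        sc = CouplingScenario(duration=600.0, noise_sd=0.2, hhb_gain=0.6, seed=42)
        sset = make_signal_set(generate_chromophore_series(sc))
        res = couple_recording(sset, wcfg)
        assert len({s.config_hash for s in res.values()}) == 1


def test_config_invariants():
    with pytest.raises(ConfigurationError, match="omega0"):
        WaveletConfig(omega0=3.0)
    with pytest.raises(ConfigurationError, match="voices"):
        WaveletConfig(voices_per_octave=2)
    with pytest.raises(ConfigurationError, match="coi_policy"):
        WaveletConfig(coi_policy="sometimes")
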