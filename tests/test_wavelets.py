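"""Wavelet construction, calibration, and spectral-diagnostic tests."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import skewnorm

from pcwa import (
    CalibrationError,
    InvalidParameterError,
    ResolutionError,
    build_msg,
    msg_spec,
    morlet_spec,
    ricker_spec,
    sample_morlet,
    sample_msg,
    sample_ricker,
    skew_normal_mode,
    wavelet_spectrum,
)
from pcwa.detector import _row_maxima_indices


def _random_scales(rng, n=20, lo=1e-4, hi=1e-1):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def _sample(family, scale, dt):
    if family == "ricker":
        return sample_ricker(scale, dt)
    if family == "morlet":
        return sample_morlet(scale, dt)
    p = build_msg(7)
    return sample_msg(p, scale, dt)


@pytest.mark.parametrize("family", ["ricker", "morlet", "msg"])
def test_admissibility_and_unit_norm(family, rng):
    """Every sampled wavelet is zero-mean and unit-square-norm at any scale."""
    for scale in _random_scales(rng):
        w = _sample(family, scale, dt=scale / 40)
        assert abs(w.values.mean()) <= 1e-10 * np.abs(w.values).max()
        assert abs(np.sum(w.values**2) * w.dt - 1.0) <= 1e-6


@pytest.mark.parametrize("family", ["ricker", "morlet", "msg"])
def test_dilation_covariance(family):
    """Doubling the scale stretches time by 2 and divides amplitude by sqrt(2)."""
    s, dt = 1e-3, 1e-5
    w1 = _sample(family, s, dt)
    w2 = _sample(family, 2 * s, 2 * dt)
    assert len(w1.values) == len(w2.values)
    np.testing.assert_allclose(w2.values, w1.values / np.sqrt(2), rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(w2.t_grid, 2 * w1.t_grid)


class TestRicker:
    def test_center_is_global_maximum_and_zeros_at_unit_x(self):
        w = sample_ricker(1.0, 1e-3)
        center = len(w.values) // 2
        assert np.argmax(w.values) == center
        # the raw shape (1-x^2)exp(-x^2/2) vanishes at x=±1; calibration
        # only shifts it by the truncated tail mass (~4e-6 of the peak)
        for x in (-1.0, 1.0):
            i = center + int(round(x / 1e-3))
            assert abs(w.values[i]) < 1e-4 * w.values[center]

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            sample_ricker(-1.0, 1e-3)
        with pytest.raises(InvalidParameterError):
            sample_ricker(1.0, 0.0)
        with pytest.raises(InvalidParameterError):
            sample_ricker(1e-4, 1e-3)  # dt >= scale


class TestMorlet:
    @pytest.mark.parametrize("scale", [1e-3, 1 / 4500, 0.02])
    def test_dominant_frequency_is_one_over_scale(self, scale):
        w = sample_morlet(scale, scale / 80)
        freqs, mags = wavelet_spectrum(w, pad_factor=32)
        f_peak = freqs[np.argmax(mags)]
        assert abs(f_peak - 1.0 / scale) < 0.02 / scale

    def test_dominant_frequency_invariant_under_finer_sampling(self):
        scale = 1e-3
        f_peaks = []
        for dt in (scale / 40, scale / 80):
            w = sample_morlet(scale, dt)
            freqs, mags = wavelet_spectrum(w, pad_factor=32)
            f_peaks.append(freqs[np.argmax(mags)])
        assert abs(f_peaks[0] - f_peaks[1]) < 0.02 / scale

    def test_single_dominant_band(self):
        """The Morlet spectrum is a single band: no comparable second lobe."""
        w = sample_morlet(1e-3, 1e-5)
        freqs, mags = wavelet_spectrum(w, pad_factor=32)
        peaks = _row_maxima_indices(mags)
        peaks = peaks[np.argsort(mags[peaks])[::-1]]
        if len(peaks) > 1:
            assert mags[peaks[1]] < 0.2 * mags[peaks[0]]


class TestMSG:
    def test_mode_offset_matches_skew_normal(self):
        """m0 equals the numerically located mode of the skew-normal pdf."""
        for alpha in (0.5, 3.0, 8.0):
            m0 = skew_normal_mode(alpha)
            ref = minimize_scalar(
                lambda x: -skewnorm.pdf(x, alpha), bounds=(-2, 2), method="bounded"
            ).x
            assert abs(m0 - ref) < 1e-6

    @pytest.mark.parametrize("n", [1, 6, 7, 8])
    def test_peak_train_structure(self, n):
        """N positive maxima spaced by Δt; side-lobe minima Δt outside the train."""
        scale, dt = 1e-3, 1e-5
        p = build_msg(n)
        w = sample_msg(p, scale, dt)
        idx = _row_maxima_indices(w.values)
        idx = idx[w.values[idx] > 0.05 * w.values.max()]
        assert len(idx) == n
        if n > 2:
            # interior spacings are exactly Δt; the outermost peaks are
            # pulled slightly inward by the adjacent negative lobe
            np.testing.assert_allclose(np.diff(w.t_grid[idx[1:-1]]), scale, atol=dt)
            np.testing.assert_allclose(np.diff(w.t_grid[idx]), scale, atol=0.06 * scale)
        # most negative samples sit at the side-lobe modes,
        # ±((N−1)/2 + 0.75)·Δt by default
        expected = ((n - 1) / 2 + 0.75) * scale
        neg_order = np.argsort(w.values)
        lobe_pos = np.sort(np.abs(w.t_grid[neg_order[:2]]))
        np.testing.assert_allclose(lobe_pos, expected, atol=2 * dt)

    def test_degenerate_single_peak_low_skew(self):
        """N=1, alpha→0 gives a difference-of-Gaussians band-pass shape."""
        p = build_msg(1, alpha=1e-6)
        w = sample_msg(p, 1e-3, 1e-5)
        center = len(w.values) // 2
        assert np.argmax(w.values) == center
        assert abs(w.values.mean()) <= 1e-10 * w.values.max()

    def test_zero_mean_solve_value(self):
        """The solved lobe amplitude matches the closed-form N·sqrt(2π)·σ₊/2."""
        for n in (1, 7):
            p = build_msg(n, sigma_plus=0.18)
            assert abs(p.a - n * np.sqrt(2 * np.pi) * 0.18 / 2) < 1e-4 * p.a

    def test_spectrum_has_first_and_second_harmonic(self):
        """MSG N=7 spectrum is comb-like with energy at 1/Δt and 2/Δt."""
        scale = 1e-3
        w = sample_msg(build_msg(7), scale, 1e-5)
        freqs, mags = wavelet_spectrum(w, pad_factor=16)
        peaks = _row_maxima_indices(mags)
        peaks = peaks[mags[peaks] > 0.03 * mags.max()]
        peak_freqs = freqs[peaks]
        assert np.any(np.abs(peak_freqs - 1 / scale) < 0.05 / scale)
        assert np.any(np.abs(peak_freqs - 2 / scale) < 0.06 / scale)

    def test_resolution_error_for_coarse_sampling(self):
        with pytest.raises(ResolutionError):
            sample_msg(build_msg(7), 1e-4, 2e-5)  # < 4 samples per peak FWHM

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            build_msg(0)
        with pytest.raises(InvalidParameterError):
            build_msg(7, sigma_plus=-0.1)


def test_fit_sigma_plus_recovers_generator_width():
    """The σ₊ fit helper recovers the spot-width/pitch ratio from events."""
    from pcwa import Event, SimConfig, simulate_trace
    from pcwa.wavelets import fit_sigma_plus

    cfg = SimConfig(
        duration=1.0, dt=1e-5, bg_rate=0.0, event_rate=3.0, n_spots=7,
        spot_pitch_um=6.0, spot_sigma_um=1.08, velocity_mean=20.0,
        amp_median=200.0, amp_sigma=0.0, poisson_noise=False, seed=12,
    )
    trace, truth = simulate_trace(cfg)
    events = [
        Event(t=float(t), scale=float(s), coeff=1.0, n_members=3,
              t_adjusted=float(t), n_peaks=7)
        for t, s in zip(truth.t_true, truth.dt_true)
    ]
    est = fit_sigma_plus(trace.counts, cfg.dt, events)
    assert abs(est - 0.18) < 0.04  # sigma/pitch of the generator


def test_spectrum_zero_at_dc():
    """Zero mean implies zero DC component for every family."""
    for spec in (ricker_spec(), morlet_spec(), msg_spec(7)):
        w = spec.sample(1e-3, 1e-5)
        freqs, mags = wavelet_spectrum(w)
        assert mags[0] < 1e-8 * mags.max()
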