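"""Mother wavelets for cluster-based CWT event detection.

Three families are provided:

* **Ricker** (Mexican hat): the standard single-peak detector kernel,
  ``(1 - x^2) exp(-x^2/2)`` with ``x = t/scale``.
* **Morlet** (real): a cosine under a Gaussian window, a single-frequency
  band-pass kernel whose dominant frequency at scale ``s`` is ``1/s``.
* **MSG** (Multi-Spot Gaussian): a custom kernel matched to the signal of a
  particle crossing an N-spot excitation pattern — N unit Gaussians spaced
  one scale unit apart, flanked by two negative skew-Gaussian lobes that
  enforce the zero-mean (admissibility) condition.

Every sampled wavelet is calibrated to zero mean and unit square norm
(``sum(psi^2) * dt == 1``), so that the dilation family ``psi_s(t) =
s^{-1/2} psi(t/s)`` of the transform is realised automatically: sampling at
scale ``2s`` equals the sample at ``s`` stretched by two in time and scaled
by ``1/sqrt(2)`` in amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .errors import CalibrationError, InvalidParameterError, ResolutionError

__all__ = [
    "SampledWavelet",
    "MSGParams",
    "WaveletSpec",
    "sample_ricker",
    "sample_morlet",
    "build_msg",
    "sample_msg",
    "wavelet_spectrum",
    "skew_normal_mode",
    "ricker_spec",
    "morlet_spec",
    "msg_spec",
]

#: default truncation half-width of the Ricker wavelet, in units of scale
RICKER_SUPPORT_RADIUS = 5.0

#: default number of oscillation cycles inside the Morlet envelope FWHM
MORLET_CENTER_CYCLES = 2.0


@dataclass(frozen=True)
class SampledWavelet:
    """A mother wavelet evaluated on a uniform, symmetric time grid.

    Attributes
    ----------
    values : ndarray
        Amplitudes, zero-mean and unit square norm (``sum(values**2)*dt == 1``).
    t_grid : ndarray
        Sample times in seconds, uniform with step ``dt``, symmetric about 0.
    scale : float
        The dilation parameter Δt (seconds) this sample realises.
    dt : float
        Sampling interval (seconds).
    """

    values: np.ndarray
    t_grid: np.ndarray
    scale: float
    dt: float

    @property
    def half_width(self) -> float:
        """Truncation half-width in seconds."""
        return float(self.t_grid[-1])


def _check_scale_dt(scale: float, dt: float) -> None:
    if not (scale > 0):
        raise InvalidParameterError(f"scale must be > 0, got {scale}")
    if not (dt > 0):
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    if not (dt < scale):
        raise InvalidParameterError(f"dt ({dt}) must be smaller than scale ({scale})")


def _symmetric_grid(half_width: float, dt: float) -> np.ndarray:
    n = max(int(np.floor(half_width / dt)), 1)
    return np.arange(-n, n + 1) * dt


def _calibrate(values: np.ndarray, dt: float) -> np.ndarray:
    """Enforce zero mean, then unit square norm, on a sampled wavelet."""
    v = values - values.mean()
    norm_sq = float(np.sum(v * v) * dt)
    if norm_sq <= 0:
        raise CalibrationError("wavelet has zero energy after mean removal", residual=norm_sq)
    return v / np.sqrt(norm_sq)


def sample_ricker(
    scale: float, dt: float, support_radius: float = RICKER_SUPPORT_RADIUS
) -> SampledWavelet:
    """Sample the Ricker (Mexican hat) wavelet at a given scale.

    Parameters
    ----------
    scale : float
        Dilation Δt in seconds; the wavelet's central lobe has this width.
    dt : float
        Sampling interval in seconds; must satisfy ``dt < scale``.
    support_radius : float
        Truncation half-width in units of scale.
    """
    _check_scale_dt(scale, dt)
    t = _symmetric_grid(support_radius * scale, dt)
    x = t / scale
    values = (1.0 - x * x) * np.exp(-0.5 * x * x)
    return SampledWavelet(_calibrate(values, dt), t, scale, dt)


def sample_morlet(
    scale: float, dt: float, center_cycles: float = MORLET_CENTER_CYCLES
) -> SampledWavelet:
    """Sample the real Morlet wavelet (cosine under a Gaussian window).

    The carrier has period ``scale``, so the dominant frequency at scale
    Δt is ``1/Δt`` regardless of ``center_cycles``; ``center_cycles`` sets
    the envelope FWHM to roughly that many oscillation cycles, which
    controls the frequency selectivity of the band-pass.
    """
    _check_scale_dt(scale, dt)
    if not (center_cycles > 0):
        raise InvalidParameterError(f"center_cycles must be > 0, got {center_cycles}")
    sigma_x = center_cycles / 2.355  # envelope FWHM = center_cycles carrier periods
    t = _symmetric_grid(5.0 * sigma_x * scale, dt)
    x = t / scale
    values = np.cos(2.0 * np.pi * x) * np.exp(-0.5 * (x / sigma_x) ** 2)
    return SampledWavelet(_calibrate(values, dt), t, scale, dt)


def skew_normal_mode(alpha: float) -> float:
    """Mode of the standard skew-normal density ``2 φ(x) Φ(αx)``, numerically.

    No closed form exists; the mode is the maximiser of the density, found
    by bounded scalar optimisation (the mode always lies in ``(-1, 1)``
    standard units for any shape ``alpha``, approaching ±sqrt(2/π)... the
    bound ``|x| < 2`` is safe for all finite alpha).
    """
    if alpha == 0:
        return 0.0

    def neg_pdf(x: float) -> float:
        return -2.0 * norm.pdf(x) * norm.cdf(alpha * x)

    res = optimize.minimize_scalar(neg_pdf, bounds=(-2.0, 2.0), method="bounded")
    if not res.success:  # pragma: no cover - bounded Brent essentially always converges
        raise CalibrationError("skew-normal mode search failed", residual=float(res.fun))
    return float(res.x)


@dataclass(frozen=True)
class MSGParams:
    """Parameters of the Multi-Spot Gaussian wavelet.

    All widths are dimensionless, normalised to the scale Δt (i.e. the
    spot-to-spot peak spacing of the matched signal).

    Attributes
    ----------
    n_peaks : int
        Number of positive peaks N (excitation spots), ≥ 1.
    sigma_plus : float
        Width of each positive peak (σ₊).
    sigma_minus : float
        Width of the two negative side lobes (σ₋).
    a : float
        Side-lobe amplitude, solved so the wavelet integrates to zero.
    alpha : float
        Skewness shape of the side lobes (tails point away from the train).
    m0 : float
        Standardised mode of the skew-normal with shape ``alpha``.
    lobe_offset : float
        Distance (in Δt units) of each side-lobe maximum outside the
        outermost positive peak.
    """

    n_peaks: int
    sigma_plus: float
    sigma_minus: float
    a: float
    alpha: float
    m0: float
    lobe_offset: float = 0.75

    @property
    def lobe_mode_position(self) -> float:
        """Position of the side-lobe minima, in Δt units (positive side)."""
        return (self.n_peaks - 1) / 2.0 + self.lobe_offset

    def support_radius(self) -> float:
        """Default truncation half-width in Δt units (side lobes contained)."""
        return self.lobe_mode_position + 5.0 * self.sigma_minus


def _msg_positive(tau: np.ndarray, p: MSGParams) -> np.ndarray:
    centers = np.arange(p.n_peaks) - (p.n_peaks - 1) / 2.0
    return np.exp(
        -((tau[:, None] - centers[None, :]) ** 2) / (2.0 * p.sigma_plus**2)
    ).sum(axis=1)


def _msg_lobes_unit(tau: np.ndarray, p: MSGParams) -> np.ndarray:
    """The two skew-Gaussian side lobes for unit amplitude ``a = 1``.

    Each lobe is ``(2/σ₋) φ(x_k) Φ(kα x_k)`` with
    ``x_k = (τ + k(σ₋ m₀ − q))/σ₋``; the shift ``q`` places the lobe mode
    at ±q = ±((N−1)/2 + lobe_offset), i.e. ``lobe_offset`` scale units
    outside the outermost positive peak.
    """
    q = p.lobe_mode_position
    out = np.zeros_like(tau, dtype=float)
    for k in (1.0, -1.0):
        x = (tau + k * (p.sigma_minus * p.m0 - q)) / p.sigma_minus
        out += (2.0 / p.sigma_minus) * norm.pdf(x) * norm.cdf(k * p.alpha * x)
    return out


def msg_shape(tau: np.ndarray, p: MSGParams) -> np.ndarray:
    """Evaluate the (uncalibrated) continuous MSG shape on ``tau = t/Δt``."""
    return _msg_positive(tau, p) - p.a * _msg_lobes_unit(tau, p)


def build_msg(
    n_peaks: int,
    sigma_plus: float = 0.18,
    alpha: float = 3.0,
    sigma_minus: float | None = None,
    lobe_offset: float = 0.75,
) -> MSGParams:
    """Construct MSG parameters with the zero-mean condition solved for ``a``.

    ``sigma_minus`` defaults to ``sigma_plus * sqrt(n_peaks)`` so the side
    lobes span a width comparable to the whole positive train. The lobe
    amplitude ``a`` is solved numerically on the continuous form so the
    integral of the wavelet vanishes: the lobes enter linearly, so
    ``a = ∫(positive part) / ∫(unit lobes)`` evaluated on a fine grid over
    the truncated support.

    Raises
    ------
    CalibrationError
        If the zero-mean solve is degenerate (vanishing lobe mass).
    """
    if n_peaks < 1:
        raise InvalidParameterError(f"n_peaks must be >= 1, got {n_peaks}")
    if not (sigma_plus > 0):
        raise InvalidParameterError(f"sigma_plus must be > 0, got {sigma_plus}")
    if sigma_minus is None:
        sigma_minus = sigma_plus * np.sqrt(n_peaks)
    if not (sigma_minus > 0):
        raise InvalidParameterError(f"sigma_minus must be > 0, got {sigma_minus}")
    m0 = skew_normal_mode(alpha)
    p = MSGParams(
        n_peaks=n_peaks,
        sigma_plus=float(sigma_plus),
        sigma_minus=float(sigma_minus),
        a=1.0,
        alpha=float(alpha),
        m0=m0,
        lobe_offset=float(lobe_offset),
    )
    radius = p.support_radius()
    tau = np.linspace(-radius, radius, 20001)
    step = tau[1] - tau[0]
    pos_mass = float(np.trapezoid(_msg_positive(tau, p), dx=step))
    lobe_mass = float(np.trapezoid(_msg_lobes_unit(tau, p), dx=step))
    if lobe_mass <= 1e-12:
        raise CalibrationError(
            "zero-mean solve degenerate: side lobes carry no mass", residual=pos_mass
        )
    a = pos_mass / lobe_mass  # ≈ N sqrt(2π) σ₊ / 2 for untruncated support
    p = replace(p, a=a)
    residual = float(np.trapezoid(msg_shape(tau, p), dx=step))
    if abs(residual) > 1e-8 * pos_mass:
        raise CalibrationError("zero-mean solve did not converge", residual=residual)
    return p


def sample_msg(
    params: MSGParams,
    scale: float,
    dt: float,
    support_radius: float | None = None,
) -> SampledWavelet:
    """Sample the MSG wavelet at scale Δt.

    Raises
    ------
    ResolutionError
        If ``dt`` is too coarse to resolve the positive peaks (fewer than
        4 samples per peak FWHM).
    """
    _check_scale_dt(scale, dt)
    fwhm = 2.355 * params.sigma_plus * scale
    if fwhm < 4.0 * dt:
        raise ResolutionError(
            f"scale {scale:g}s gives positive-peak FWHM {fwhm:g}s < 4 samples at dt={dt:g}s"
        )
    if support_radius is None:
        support_radius = params.support_radius()
    t = _symmetric_grid(support_radius * scale, dt)
    values = msg_shape(t / scale, params)
    return SampledWavelet(_calibrate(values, dt), t, scale, dt)


def wavelet_spectrum(
    w: SampledWavelet, pad_factor: int = 16
) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of a sampled wavelet (zero-padded for resolution).

    Returns ``(freqs, magnitudes)`` on the positive-frequency grid. Used as
    the matched-design diagnostic: the MSG spectrum is comb-like with
    energy at the first and second harmonic of ``1/Δt``, while the Morlet
    shows a single band there.
    """
    if len(w.values) == 0:
        raise InvalidParameterError("empty wavelet")
    n = int(pad_factor * len(w.values))
    mags = np.abs(np.fft.rfft(w.values, n=n)) * w.dt
    freqs = np.fft.rfftfreq(n, d=w.dt)
    return freqs, mags


@dataclass(frozen=True)
class WaveletSpec:
    """A mother-wavelet family plus its parameters; samples itself at any scale.

    ``family`` is one of ``"ricker"``, ``"morlet"``, ``"msg"``. For MSG,
    ``msg_params`` must be set; ``n_peaks`` reports the peak count used for
    detection geometry (1 for Ricker; the envelope cycle count's nearest
    integer for Morlet, since an N-cycle Morlet is the single-band
    approximation to an N-peak train).
    """

    family: Literal["ricker", "morlet", "msg"]
    msg_params: MSGParams | None = None
    center_cycles: float = MORLET_CENTER_CYCLES
    support_radius: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def n_peaks(self) -> int:
        if self.family == "msg":
            assert self.msg_params is not None
            return self.msg_params.n_peaks
        if self.family == "morlet":
            return max(1, round(self.center_cycles))
        return 1

    def sample(self, scale: float, dt: float) -> SampledWavelet:
        if self.family == "ricker":
            radius = self.support_radius or RICKER_SUPPORT_RADIUS
            return sample_ricker(scale, dt, support_radius=radius)
        if self.family == "morlet":
            return sample_morlet(scale, dt, center_cycles=self.center_cycles)
        if self.family == "msg":
            if self.msg_params is None:
                raise InvalidParameterError("msg family requires msg_params")
            return sample_msg(self.msg_params, scale, dt, support_radius=self.support_radius)
        raise InvalidParameterError(f"unknown wavelet family {self.family!r}")

    def half_width(self, scale: float) -> float:
        """Truncation half-width in seconds at a given scale."""
        if self.family == "ricker":
            return (self.support_radius or RICKER_SUPPORT_RADIUS) * scale
        if self.family == "morlet":
            return 5.0 * (self.center_cycles / 2.355) * scale
        assert self.msg_params is not None
        return (self.support_radius or self.msg_params.support_radius()) * scale


def ricker_spec(support_radius: float = RICKER_SUPPORT_RADIUS) -> WaveletSpec:
    return WaveletSpec(family="ricker", support_radius=support_radius)


def morlet_spec(center_cycles: float = MORLET_CENTER_CYCLES) -> WaveletSpec:
    return WaveletSpec(family="morlet", center_cycles=center_cycles)


def msg_spec(
    n_peaks: int,
    sigma_plus: float = 0.18,
    alpha: float = 3.0,
    sigma_minus: float | None = None,
    lobe_offset: float = 0.75,
) -> WaveletSpec:
    params = build_msg(
        n_peaks, sigma_plus=sigma_plus, alpha=alpha,
        sigma_minus=sigma_minus, lobe_offset=lobe_offset,
    )
    return WaveletSpec(family="msg", msg_params=params)


def fit_sigma_plus(trace_counts: np.ndarray, dt: float, events, default: float = 0.18) -> float:
    """Estimate σ₊ from detected multi-peak events (median peak width / Δt).

    For each event, individual peaks inside the event window are located
    with a conventional peak finder and their half-maximum widths measured;
    σ₊ is the median Gaussian-equivalent width normalised to the event's
    scale. Falls back to ``default`` when no peaks are measurable.
    """
    from scipy.signal import find_peaks, peak_widths

    ratios: list[float] = []
    n = len(trace_counts)
    for ev in events:
        half = ev.n_peaks * ev.scale / 2.0 + ev.scale
        lo = max(int((ev.t - half) / dt), 0)
        hi = min(int((ev.t + half) / dt) + 1, n)
        seg = np.asarray(trace_counts[lo:hi], dtype=float)
        if len(seg) < 5:
            continue
        min_dist = max(int(0.5 * ev.scale / dt), 1)
        peaks, props = find_peaks(seg, prominence=0.25 * seg.max(), distance=min_dist)
        if len(peaks) == 0:
            continue
        widths = peak_widths(seg, peaks, rel_height=0.5)[0] * dt
        ratios.extend(widths / (2.355 * ev.scale))  # FWHM -> Gaussian sigma, / Δt
    if not ratios:
        return default
    return float(np.median(ratios))
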