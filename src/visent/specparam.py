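"""Baseline PSD construction and periodic/aperiodic parameterization.

A power spectrum is modeled in log10 space as the sum of an aperiodic
component and Gaussian oscillatory peaks:

    log10 P(f) = b - chi * log10 f + sum_k PW_k * exp(-(f - CF_k)^2 / (2 sigma_k^2))

with offset ``b``, exponent ``chi`` (fixed mode, no knee), peak center
``CF`` (Hz), height ``PW`` (log10 power units above the aperiodic fit)
and bandwidth ``BW = 2 sigma`` constrained to 1-15 Hz.  The fit is
iterative: a robust aperiodic line fit (discarding top-quartile positive
residuals, which exclude the peaks), peak extraction from the flattened
spectrum until no residual exceeds the 2-SD relative threshold, joint
least-squares refinement of all peaks, and a final aperiodic refit on
the peak-subtracted spectrum.

Baseline PSDs are derived from the virtual-sensor time-frequency data by
averaging squared amplitudes over the pre-stimulus frames, i.e. from the
same data as the entrainment metrics rather than a separate spectral
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .tfr import TFRTensor

__all__ = [
    "BaselinePSD",
    "SpecparamSettings",
    "SpectrumFit",
    "baseline_psd",
    "fit_spectrum",
    "component_band_value",
]


@dataclass
class BaselinePSD:
    freqs: np.ndarray
    power: np.ndarray  # amplitude^2 units

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SpecparamSettings:
    """Fit settings; defaults mirror standard spectral parameterization
    with peak width limits 1-15 Hz, no minimum height, 2-SD threshold."""

    peak_width_limits: tuple = (1.0, 15.0)
    max_n_peaks: int = 12  # safety cap on the peak-extraction loop
    min_peak_height: float = 0.0
    peak_threshold_sd: float = 2.0


@dataclass
class SpectrumFit:
    """Aperiodic + Gaussian-peak model of a log10 power spectrum."""

    offset: float
    exponent: float
    peaks: list  # of (CF, PW, BW) tuples
    r_squared: float
    freqs: np.ndarray
    log_power: np.ndarray  # log10 of the input PSD
    settings: SpecparamSettings = field(default_factory=SpecparamSettings)
    converged: bool = True

    def aperiodic(self, freqs=None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        return self.offset - self.exponent * np.log10(f)

    def periodic(self, freqs=None) -> np.ndarray:
        f = self.freqs if freqs is None else np.asarray(freqs, dtype=float)
        out = np.zeros_like(f, dtype=float)
        for cf, pw, bw in self.peaks:
            sigma = bw / 2.0
            out += pw * np.exp(-((f - cf) ** 2) / (2.0 * sigma**2))
        return out

    def model(self, freqs=None) -> np.ndarray:
        return self.aperiodic(freqs) + self.periodic(freqs)


def baseline_psd(
    vs_tfr: TFRTensor, window_ms: tuple[float, float] = (-600.0, 0.0)
) -> BaselinePSD:
    """Baseline PSD: mean over trials and pre-stimulus frames of |coeff|^2."""
    ti = vs_tfr.time_indices(window_ms)
    if ti.size < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    p = (np.abs(vs_tfr.coeffs[..., ti]) ** 2).mean(axis=(0, -1))
    return BaselinePSD(vs_tfr.freqs.copy(), p)


def _linfit(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares line y = b - chi*logf; returns (b, chi)."""
    A = np.stack([np.ones_like(logf), -logf], axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def _robust_aperiodic(logf: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Line fit robust to peaks: drop the top quartile of residuals, refit."""
    b, chi = _linfit(logf, y)
    resid = y - (b - chi * logf)
    keep = resid <= np.percentile(resid, 75)
    return _linfit(logf[keep], y[keep])


def _gaussians(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        cf, pw, sigma = params[i : i + 3]
        out = out + pw * np.exp(-((f - cf) ** 2) / (2.0 * sigma**2))
    return out


def _guess_sigma(freqs, flat, i, limits):
    """Half-height width guess around the peak at index ``i``."""
    half = flat[i] / 2.0
    lo = i
    while lo > 0 and flat[lo] > half:
        lo -= 1
    hi = i
    while hi < len(flat) - 1 and flat[hi] > half:
        hi += 1
    fwhm = max(freqs[hi] - freqs[lo], freqs[1] - freqs[0])
    sigma = fwhm / 2.355
    return float(np.clip(sigma, limits[0] / 2.0, limits[1] / 2.0))


def fit_spectrum(
    psd: BaselinePSD, settings: SpecparamSettings | None = None
) -> SpectrumFit:
    """Parameterize a PSD into aperiodic and periodic components.

    Raises on non-positive power (the model lives in log10 space).  If
    the joint peak refinement fails to converge the initial guesses are
    kept and the fit is flagged (``converged=False``) with its R^2
    reported.
    """
    settings = settings or SpecparamSettings()
    freqs = np.asarray(psd.freqs, dtype=float)
    power = np.asarray(psd.power, dtype=float)
    if np.any(power <= 0):
        raise ValueError("power must be strictly positive for log fitting")
    y = np.log10(power)
    logf = np.log10(freqs)
    wlo, whi = settings.peak_width_limits

    b0, chi0 = _robust_aperiodic(logf, y)
    flat = y - (b0 - chi0 * logf)

    guesses = []
    work = flat.copy()
    for _ in range(settings.max_n_peaks):
        i = int(np.argmax(work))
        h = work[i]
        if not (h > settings.peak_threshold_sd * np.std(work) and
                h > settings.min_peak_height and h > 1e-9):
            break
        sigma = _guess_sigma(freqs, work, i, settings.peak_width_limits)
        guesses.append((float(freqs[i]), float(h), sigma))
        work = work - h * np.exp(-((freqs - freqs[i]) ** 2) / (2 * sigma**2))

    converged = True
    if guesses:
        p0 = np.ravel([[cf, pw, sg] for cf, pw, sg in guesses])
        lo = np.ravel([[freqs[0], 0.0, wlo / 2.0] for _ in guesses])
        hi = np.ravel([[freqs[-1], np.inf, whi / 2.0] for _ in guesses])
        try:
            popt, _ = curve_fit(
                _gaussians, freqs, flat, p0=p0, bounds=(lo, hi), maxfev=5000
            )
        except RuntimeError:
            popt, converged = p0, False
        peaks = [
            (float(popt[i]), float(popt[i + 1]), float(2 * popt[i + 2]))
            for i in range(0, len(popt), 3)
            if popt[i + 1] > max(settings.min_peak_height, 1e-9)
        ]
    else:
        peaks = []

    peak_model = _gaussians(freqs, *np.ravel([[cf, pw, bw / 2] for cf, pw, bw in peaks])) \
        if peaks else np.zeros_like(freqs)
    b1, chi1 = _linfit(logf, y - peak_model)

    fit = SpectrumFit(
        offset=b1,
        exponent=chi1,
        peaks=sorted(peaks),
        r_squared=0.0,
        freqs=freqs,
        log_power=y,
        settings=settings,
        converged=converged,
    )
    resid = y - fit.model()
    ss_tot = np.sum((y - y.mean()) ** 2)
    fit.r_squared = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return fit


def component_band_value(
    fit: SpectrumFit,
    band: tuple[float, float] = (14.5, 15.5),
    component: str = "full",
) -> float:
    """Band-averaged value of a spectral component, in log10 power units.

    ``full`` averages the measured log10 PSD over the band bins;
    ``aperiodic`` and ``periodic`` average the corresponding model
    components; ``model`` averages the full fitted model (identically
    aperiodic + periodic).
    """
    sel = (fit.freqs >= band[0] - 1e-9) & (fit.freqs <= band[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band} outside fitted range")
    if component == "full":
        return float(fit.log_power[sel].mean())
    if component == "aperiodic":
        return float(fit.aperiodic()[sel].mean())
    if component == "periodic":
        return float(fit.periodic()[sel].mean())
    if component == "model":
        return float(fit.model()[sel].mean())
    raise ValueError("component must be full, aperiodic, periodic or model")
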