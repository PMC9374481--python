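"""Virtual-sensor entrainment read-outs.

All metrics operate on the trial-resolved time-frequency tensor of the
peak-voxel virtual sensor:

- absolute amplitude: band-averaged envelope (14.5-15.5 Hz) averaged over
  the response window (200-2000 ms), trial amplitudes averaged *after*
  rectification so both evoked and induced activity contribute;
- relative amplitude: the same envelope expressed as percent change from
  the pre-stimulus baseline (-600..0 ms);
- ITPL: inter-trial phase locking, the magnitude of the trial-averaged
  unit phase vector, averaged pointwise over the band x window grid;
- CV: sample SD / mean of the trial-wise window-averaged amplitudes,
  a phase-free index of response-strength consistency;
- per-frequency relative response: the relative change per analysis bin,
  used to check spectral specificity of any group effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .tfr import TFRTensor

__all__ = [
    "EntrainmentSummary",
    "band_envelope",
    "itpl",
    "amplitude_cv",
    "per_frequency_relative",
    "summarize_entrainment",
]

logger = logging.getLogger(__name__)

BAND = (14.5, 15.5)
RESPONSE_WINDOW = (200.0, 2000.0)
BASELINE_WINDOW = (-600.0, 0.0)


@dataclass
class EntrainmentSummary:
    """Per-subject entrainment metrics."""

    abs_amp: float
    rel_amp: float
    base_amp: float
    itpl: float
    cv: float
    per_freq_rel: np.ndarray


def band_envelope(
    vs_tfr: TFRTensor, band: tuple[float, float] = BAND
) -> tuple[np.ndarray, np.ndarray]:
    """Band-averaged amplitude envelope.

    Returns ``(trial_avg, trial_resolved)`` where ``trial_resolved`` has
    shape (n_trials, n_frames) and ``trial_avg`` is its mean over trials
    (amplitude is rectified per trial first, so non-phase-locked power
    survives the average).
    """
    if vs_tfr.coeffs.ndim != 3:
        raise ValueError("expected trial-resolved TFR (trial, freq, time)")
    if vs_tfr.coeffs.shape[0] == 0:
        raise ValueError("no trials in TFR")
    fi = vs_tfr.freq_indices(band)
    amp = np.abs(vs_tfr.coeffs[:, fi, :]).mean(axis=1)
    return amp.mean(axis=0), amp


def itpl(
    vs_tfr: TFRTensor,
    band: tuple[float, float] = BAND,
    window_ms: tuple[float, float] = RESPONSE_WINDOW,
) -> float:
    """Inter-trial phase locking averaged over the band x window grid.

    At each (f, t) bin, ``R = |mean_trials coeff/|coeff||``; trials with
    an exactly zero coefficient are excluded at that bin (and logged).
    ``R`` is 1 for perfectly phase-locked trials and 0 for uniformly
    spread phases; amplitude scaling of individual trials cannot change
    it.
    """
    C = vs_tfr.coeffs
    if C.ndim != 3 or C.shape[0] < 2:
        raise ValueError("ITPL needs at least 2 trials")
    fi = vs_tfr.freq_indices(band)
    ti = vs_tfr.time_indices(window_ms)
    sub = C[np.ix_(np.arange(C.shape[0]), fi, ti)]
    mag = np.abs(sub)
    ok = mag > 0
    if not ok.all():
        logger.warning("ITPL: %d zero-magnitude coefficients excluded", (~ok).sum())
    unit = np.where(ok, sub / np.where(ok, mag, 1.0), 0.0)
    n_ok = ok.sum(axis=0)
    if np.any(n_ok == 0):
        raise ValueError("a bin lost all trials to zero coefficients")
    R = np.abs(unit.sum(axis=0)) / n_ok
    return float(R.mean())


def amplitude_cv(
    trial_amp: np.ndarray,
    times_ms: np.ndarray,
    window_ms: tuple[float, float] = RESPONSE_WINDOW,
) -> float:
    """Coefficient of variation of trial-wise window-averaged amplitudes.

    ``trial_amp`` is the trial-resolved band envelope (n_trials,
    n_frames); each trial is averaged over ``window_ms`` frames and the
    sample SD / mean of those values is returned.
    """
    trial_amp = np.asarray(trial_amp, dtype=float)
    if trial_amp.ndim != 2 or trial_amp.shape[0] < 2:
        raise ValueError("CV needs at least 2 trials")
    sel = (times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9)
    a = trial_amp[:, sel].mean(axis=1)
    m = a.mean()
    if m <= 0:
        raise ValueError("non-positive mean amplitude")
    return float(a.std(ddof=1) / m)


def per_frequency_relative(
    vs_tfr: TFRTensor,
    window_ms: tuple[float, float] = RESPONSE_WINDOW,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW,
) -> np.ndarray:
    """Baseline-relative amplitude response per frequency bin (percent).

    For each analysis bin, the trial-averaged envelope is normalized by
    its own baseline mean and averaged over the response window.  Bins
    with a zero baseline are flagged NaN and logged.
    """
    amp = np.abs(vs_tfr.coeffs).mean(axis=0)  # (freq, time)
    bi = vs_tfr.time_indices(baseline_ms)
    wi = vs_tfr.time_indices(window_ms)
    base = amp[:, bi].mean(axis=1)
    out = np.full(amp.shape[0], np.nan)
    ok = base > 0
    if not ok.all():
        logger.warning(
            "per-frequency relative: %d bins with zero baseline flagged NaN",
            (~ok).sum(),
        )
    out[ok] = 100.0 * (amp[ok][:, wi].mean(axis=1) - base[ok]) / base[ok]
    return out


def summarize_entrainment(
    vs_tfr: TFRTensor,
    band: tuple[float, float] = BAND,
    window_ms: tuple[float, float] = RESPONSE_WINDOW,
    baseline_ms: tuple[float, float] = BASELINE_WINDOW,
) -> EntrainmentSummary:
    """All entrainment metrics for one subject's virtual-sensor TFR."""
    avg, trial_amp = band_envelope(vs_tfr, band)
    wi = vs_tfr.time_indices(window_ms)
    bi = vs_tfr.time_indices(baseline_ms)
    abs_amp = float(avg[wi].mean())
    base_amp = float(avg[bi].mean())
    if base_amp <= 0:
        raise ValueError("non-positive baseline amplitude")
    rel_amp = 100.0 * (abs_amp - base_amp) / base_amp
    return EntrainmentSummary(
        abs_amp=abs_amp,
        rel_amp=rel_amp,
        base_amp=base_amp,
        itpl=itpl(vs_tfr, band, window_ms),
        cv=amplitude_cv(trial_amp, vs_tfr.times_ms, window_ms),
        per_freq_rel=per_frequency_relative(vs_tfr, window_ms, baseline_ms),
    )
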