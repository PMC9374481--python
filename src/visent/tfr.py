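"""Complex-demodulation time-frequency analysis and sensor-level window selection.

Complex demodulation shifts each analysis frequency ``f`` to 0 Hz by
multiplying the signal with ``exp(-i 2 pi f t)`` and lowpass filtering,
which yields a complex coefficient whose magnitude is the instantaneous
envelope and whose angle is the instantaneous phase at ``f``.  Here the
lowpass is a symmetric Hamming windowed-sinc FIR applied as a centered
(and therefore zero-phase) convolution, evaluated only on the decimated
output grid (100 ms frames), which turns the whole transform into one
matrix product per block of frequencies.  Kernels are renormalized to
unit DC gain where they overhang the epoch edges, so a constant envelope
stays unbiased at the first and last frames.

Calibration: a pure sinusoid of amplitude ``A`` at a bin center returns
an envelope of ``A`` on interior frames.

The sensor-level statistics locate the entrainment response in the
freq x time plane: a one-sample t-map of baseline-relative power across
participants is thresholded, supra-threshold bins are clustered, and
cluster mass is compared against a max-cluster null distribution built
by random per-participant sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

__all__ = [
    "DEFAULT_FREQS",
    "DEFAULT_TIMES_MS",
    "TFRTensor",
    "SignificanceMask",
    "complex_demodulate",
    "baseline_normalize",
    "select_entrainment_window",
]

#: Analysis frequencies: 4.0-50.0 Hz in 0.5 Hz steps (93 bins).
DEFAULT_FREQS = np.round(np.arange(4.0, 50.0 + 0.25, 0.5), 1)
#: Output frames: -600..3200 ms in 100 ms steps (39 frames).
DEFAULT_TIMES_MS = np.arange(-600.0, 3200.0 + 50.0, 100.0)
#: Lowpass FIR length (samples at 1 kHz).  501 taps give a transition of
#: ~6.6 Hz around the 1 Hz cutoff and a temporal half-width of 250 ms.
DEFAULT_NUMTAPS = 501


@dataclass
class TFRTensor:
    """Complex time-frequency coefficients, trial-resolved.

    ``coeffs`` has shape (..., n_freqs, n_times); leading axes are
    whatever the caller demodulated (trials, or trials x sensors).
    Coefficients are calibrated so that ``abs(coeffs)`` is an amplitude
    envelope in the input units.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    times_ms: np.ndarray

    def amplitude(self) -> np.ndarray:
        return np.abs(self.coeffs)

    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    def freq_indices(self, band: tuple[float, float]) -> np.ndarray:
        idx = np.nonzero((self.freqs >= band[0] - 1e-9) & (self.freqs <= band[1] + 1e-9))[0]
        if idx.size == 0:
            raise ValueError(f"band {band} outside TFR frequency grid")
        return idx

    def time_indices(self, window: tuple[float, float]) -> np.ndarray:
        idx = np.nonzero(
            (self.times_ms >= window[0] - 1e-9) & (self.times_ms <= window[1] + 1e-9)
        )[0]
        if idx.size == 0:
            raise ValueError(f"window {window} outside TFR time grid")
        return idx


def _demod_kernel(
    n_times: int,
    fs: float,
    times_ms: np.ndarray,
    epoch_start_ms: float,
    lowpass_hz: float,
    numtaps: int,
    freqs: np.ndarray,
) -> np.ndarray:
    """Complex demodulation kernels, one (frame x sample) matrix per frequency.

    Each row is the lowpass FIR centered on the frame, multiplied by the
    demodulation phase ``exp(-i 2 pi f t)`` and the amplitude-calibration
    factor 2.  Kernels that would overhang the epoch edges wrap around
    circularly, with the phase attached to the *unwrapped* kernel offset
    (i.e. the transform is a circular convolution with a complex bandpass
    kernel).  This keeps the envelope gain, the noise bandwidth and the
    phase response identical at every frame for any circularly stationary
    input, so edge frames carry no power bias; the wrapped-in samples
    come from the opposite, temporally distant end of the epoch.
    """
    if numtaps >= n_times:
        raise ValueError("FIR longer than the epoch")
    h = signal.firwin(numtaps, lowpass_hz, fs=fs, window="hamming")
    h = h / h.sum()
    half = (numtaps - 1) // 2
    frame_idx = np.round((times_ms - epoch_start_ms) * fs / 1000.0).astype(int)
    frame_idx = np.clip(frame_idx, 0, n_times - 1)
    offsets = np.arange(-half, numtaps - half)
    idx = (frame_idx[:, None] - offsets[None, :]) % n_times  # (frames, taps)
    t_frame_sec = epoch_start_ms / 1000.0 + frame_idx / fs
    K = np.zeros((len(freqs), len(times_ms), n_times), dtype=complex)
    for a, f in enumerate(freqs):
        taps = h * np.exp(2j * np.pi * f * offsets / fs)
        rows = 2.0 * np.exp(-2j * np.pi * f * t_frame_sec)
        for j in range(len(frame_idx)):
            K[a, j, idx[j]] = rows[j] * taps
    return K


def complex_demodulate(
    signals: np.ndarray,
    fs: float = 1000.0,
    freqs: np.ndarray | None = None,
    lowpass_hz: float = 1.0,
    time_step_ms: float = 100.0,
    epoch_start_ms: float = -600.0,
    times_ms: np.ndarray | None = None,
    numtaps: int = DEFAULT_NUMTAPS,
    freq_chunk: int = 8,
) -> TFRTensor:
    """Complex demodulation of one or many signals.

    Parameters
    ----------
    signals : ndarray, shape (..., n_times)
        Real-valued epochs.  Arbitrary leading axes (e.g. trial, or
        trial x sensor) are preserved.
    freqs : array of float, optional
        Analysis frequencies in Hz; default 4-50 Hz in 0.5 Hz steps.
    times_ms : array of float, optional
        Output frame times in ms relative to ``epoch_start_ms`` origin
        convention (epoch starts at ``epoch_start_ms``); by default a
        ``time_step_ms`` grid spanning the epoch.

    Returns
    -------
    TFRTensor
        Calibrated complex coefficients of shape
        ``signals.shape[:-1] + (n_freqs, n_frames)``.
    """
    x = np.asarray(signals, dtype=float)
    n_times = x.shape[-1]
    if freqs is None:
        freqs = DEFAULT_FREQS
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= fs / 2):
        raise ValueError("analysis frequency at or above Nyquist")
    if n_times < numtaps // 2:
        raise ValueError("signal shorter than half the FIR length")
    if times_ms is None:
        # Frames cover the epoch end-inclusively: a 3800-sample epoch at
        # -600 ms start yields the -600..3200 ms grid (39 frames), the
        # last frame anchored at the final sample.
        stop = epoch_start_ms + n_times * 1000.0 / fs
        times_ms = np.arange(epoch_start_ms, stop + 1e-6, time_step_ms)
    times_ms = np.asarray(times_ms, dtype=float)

    lead_shape = x.shape[:-1]
    X = x.reshape(-1, n_times)
    n_frames = len(times_ms)
    out = np.empty((X.shape[0], len(freqs), n_frames), dtype=complex)
    # The calibration factor 2 inside the kernels recovers full amplitude
    # (the negative-frequency half of a real sinusoid is rejected by the
    # lowpass).
    for a in range(0, len(freqs), freq_chunk):
        fc = freqs[a : a + freq_chunk]
        K = _demod_kernel(
            n_times, fs, times_ms, epoch_start_ms, lowpass_hz, numtaps, fc
        )
        Kf = K.reshape(-1, n_times)
        block = X @ Kf.real.T + 1j * (X @ Kf.imag.T)
        out[:, a : a + len(fc), :] = block.reshape(X.shape[0], len(fc), n_frames)
    return TFRTensor(out.reshape(lead_shape + (len(freqs), n_frames)), freqs, times_ms)


def baseline_normalize(
    power: np.ndarray,
    times_ms: np.ndarray,
    baseline_window: tuple[float, float] = (-600.0, 0.0),
) -> np.ndarray:
    """Percent power change relative to the mean baseline power.

    ``out[f, t] = 100 * (P[f, t] - Pbar_base[f]) / Pbar_base[f]`` with
    the baseline mean taken over frames inside ``baseline_window``
    (inclusive).  Works on any array whose last axis is time.
    """
    power = np.asarray(power, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)
    sel = (times_ms >= baseline_window[0] - 1e-9) & (times_ms <= baseline_window[1] + 1e-9)
    if sel.sum() < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    base = power[..., sel].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero or negative mean baseline power at some frequency")
    return 100.0 * (power - base) / base


@dataclass
class SignificanceMask:
    """Cluster-corrected significance mask over the freq x time grid."""

    mask: np.ndarray  # bool, (n_freqs, n_times)
    clusters: list  # dicts: {"mass", "p", "n_bins"}
    t_map: np.ndarray
    n_permutations: int
    alpha_corrected: float
    seed: int
    freqs: np.ndarray = None  # type: ignore[assignment]
    times_ms: np.ndarray = None  # type: ignore[assignment]


def _cluster_masses(t_map: np.ndarray, t_crit: float) -> tuple[np.ndarray, np.ndarray]:
    """Label 4-connected supra-threshold clusters of |t|; return labels, masses."""
    labels, n = ndimage.label(np.abs(t_map) > t_crit)
    if n == 0:
        return labels, np.empty(0)
    masses = ndimage.sum_labels(np.abs(t_map), labels, index=np.arange(1, n + 1))
    return labels, masses


def _t_maps(maps: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """One-sample t-maps for each row of the sign-flip matrix.

    Sign flips change only the mean: the per-participant squared values,
    and hence the second moment, are invariant.
    """
    n, F, T = maps.shape
    X = maps.reshape(n, -1)
    m = signs @ X / n
    msq = np.mean(X**2, axis=0)
    var = (msq - m**2) * n / (n - 1)
    var = np.maximum(var, np.finfo(float).tiny)
    t = m / np.sqrt(var / n)
    return t.reshape(signs.shape[0], F, T)


def select_entrainment_window(
    maps: np.ndarray,
    alpha: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    cluster_alpha: float = 0.05,
    freqs: np.ndarray | None = None,
    times_ms: np.ndarray | None = None,
) -> SignificanceMask:
    """Cluster-based sign-flip permutation test on participant spectrograms.

    Parameters
    ----------
    maps : ndarray, shape (n_participants, n_freqs, n_times)
        Per-participant baseline-relative power maps (sensor-averaged).
    alpha : float
        Corrected (family-wise) significance level for clusters.
    cluster_alpha : float
        Uncorrected two-sided p-value forming cluster candidates.

    Notes
    -----
    The null hypothesis is a symmetric-about-zero baseline-relative
    change, so random per-participant sign flips generate exchangeable
    null datasets; the max-cluster-mass statistic controls the
    family-wise error over the whole grid.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3:
        raise ValueError("maps must be (n_participants, n_freqs, n_times)")
    n = maps.shape[0]
    if n < 6:
        raise ValueError("need at least 6 participants")
    if n_perm < 200:
        raise ValueError("need at least 200 permutations")
    if 1.0 / (n_perm + 1) > alpha:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve corrected p < {alpha}; "
            f"smallest achievable p is {1.0 / (n_perm + 1):.2e}"
        )

    t_crit = stats.t.ppf(1 - cluster_alpha / 2, df=n - 1)
    t_obs = _t_maps(maps, np.ones((1, n)))[0]
    labels, masses = _cluster_masses(t_obs, t_crit)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    null_max = np.zeros(n_perm)
    chunk = 64
    for a in range(0, n_perm, chunk):
        t_null = _t_maps(maps, signs[a : a + chunk])
        for j in range(t_null.shape[0]):
            _, m = _cluster_masses(t_null[j], t_crit)
            null_max[a + j] = m.max() if m.size else 0.0

    mask = np.zeros(maps.shape[1:], dtype=bool)
    clusters = []
    for i, mass in enumerate(masses, start=1):
        p = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        sig = p < alpha
        clusters.append({"mass": float(mass), "p": float(p), "n_bins": int((labels == i).sum())})
        if sig:
            mask |= labels == i
    return SignificanceMask(
        mask=mask,
        clusters=clusters,
        t_map=t_obs,
        n_permutations=n_perm,
        alpha_corrected=alpha,
        seed=seed,
        freqs=freqs,
        times_ms=times_ms,
    )
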