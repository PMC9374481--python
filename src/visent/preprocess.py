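"""Epoch bookkeeping and individualized-threshold artifact rejection.

MEG epoch amplitudes vary strongly across participants because magnetic
field strength falls off sharply with the distance between the cortex and
the sensor array.  Fixed absolute artifact cutoffs are therefore a poor
fit; instead each participant receives thresholds derived from their own
distribution of per-trial peak amplitude and peak gradient (first
temporal difference).  A trial is rejected when either peak strictly
exceeds ``mean + k * SD`` of the corresponding per-trial peak
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SensorEpochs", "RejectionReport", "reject_artifacts"]


@dataclass
class SensorEpochs:
    """Epoched multi-sensor recording for one subject.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_times)
        Sensor amplitudes in arbitrary units (stand-in for fT).
    fs : float
        Sampling rate in Hz.
    t0_index : int
        Sample index of stimulus onset (0 ms).  With the default
        -600..3200 ms epoch at 1 kHz this is 600.
    window_ms : tuple of float
        Epoch extent ``(start, stop)`` in ms relative to stimulus onset.
    kept_mask : ndarray of bool, shape (n_trials,)
        Trials surviving artifact rejection.  All-true on construction.
    """

    data: np.ndarray
    fs: float = 1000.0
    t0_index: int = 600
    window_ms: tuple = (-600.0, 3200.0)
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_times)")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.n_trials, dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
            if self.kept_mask.shape != (self.n_trials,):
                raise ValueError("kept_mask length must equal trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset."""
        return (np.arange(self.n_times) - self.t0_index) * 1000.0 / self.fs

    def kept(self) -> np.ndarray:
        """Data restricted to kept trials."""
        return self.data[self.kept_mask]


@dataclass
class RejectionReport:
    """Per-subject artifact-rejection thresholds and counts."""

    amp_threshold: float
    grad_threshold: float
    n_kept: int
    n_rejected: int

    def as_dict(self) -> dict:
        return {
            "amp_threshold": self.amp_threshold,
            "grad_threshold": self.grad_threshold,
            "n_kept": self.n_kept,
            "n_rejected": self.n_rejected,
        }


def trial_peaks(epochs: SensorEpochs) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial peak |amplitude| and peak |gradient| (amplitude/s).

    The gradient is the first temporal difference scaled by the sampling
    rate, i.e. an amplitude-per-second slope, taken over all sensors.
    """
    x = epochs.data
    peak_amp = np.abs(x).max(axis=(1, 2))
    peak_grad = (np.abs(np.diff(x, axis=2)) * epochs.fs).max(axis=(1, 2))
    return peak_amp, peak_grad


def reject_artifacts(
    epochs: SensorEpochs, k_amp: float = 3.0, k_grad: float = 3.0
) -> tuple[SensorEpochs, RejectionReport]:
    """Individualized-threshold artifact rejection.

    Thresholds are ``mean + k * SD`` (sample SD) of the per-trial peak
    amplitude and peak gradient distributions; a trial is rejected iff
    either peak *strictly* exceeds its threshold.  With identical trials
    the SD is zero, the threshold equals the common peak, and nothing is
    rejected.

    Returns a copy of ``epochs`` with the updated ``kept_mask`` (combined
    with any pre-existing mask) and a :class:`RejectionReport`.

    Raises
    ------
    ValueError
        If fewer than 2 trials, non-positive ``k``, or every trial ends
        up rejected (threshold review advised).
    """
    if epochs.n_trials < 2:
        raise ValueError("artifact rejection needs at least 2 trials")
    if k_amp <= 0 or k_grad <= 0:
        raise ValueError("k_amp and k_grad must be positive")

    peak_amp, peak_grad = trial_peaks(epochs)
    amp_thr = peak_amp.mean() + k_amp * peak_amp.std(ddof=1)
    grad_thr = peak_grad.mean() + k_grad * peak_grad.std(ddof=1)

    bad = (peak_amp > amp_thr) | (peak_grad > grad_thr)
    kept = epochs.kept_mask & ~bad
    if not kept.any():
        raise ValueError(
            "all trials rejected; review thresholds (k_amp=%g, k_grad=%g)"
            % (k_amp, k_grad)
        )
    report = RejectionReport(
        amp_threshold=float(amp_thr),
        grad_threshold=float(grad_thr),
        n_kept=int(kept.sum()),
        n_rejected=int(epochs.n_trials - kept.sum()),
    )
    return replace(epochs, data=epochs.data, kept_mask=kept), report
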