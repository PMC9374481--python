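"""Frequency-domain (DICS-style) beamforming and virtual sensors.

The dynamic-imaging-of-coherent-sources beamformer builds, for every
voxel, a spatial filter from a band-limited sensor cross-spectral density
(CSD) matrix and the voxel's forward gain pattern.  The filter is the
minimum-variance unit-gain solution

    w(v) = (C_r + lambda I)^-1 l(v) / (l(v)^T (C_r + lambda I)^-1 l(v))

where ``C_r`` is the real part of the CSD (power mapping) and ``lambda``
a diagonal-loading regularizer.  Source power in an active window is
normalized per voxel by power in a pre-stimulus baseline window of equal
bandwidth, giving a dimensionless, scale-invariant "pseudo-t" map whose
peak defines the virtual-sensor location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import SensorEpochs
from .synth import LeadFieldModel
from .tfr import complex_demodulate

__all__ = [
    "CrossSpectralDensity",
    "SpatialFilterSet",
    "SourcePowerMap",
    "compute_csd",
    "dics_filters",
    "source_power_map",
    "find_peak_voxel",
    "virtual_sensor",
]


@dataclass
class CrossSpectralDensity:
    """Trial-averaged sensor x sensor CSD for one band and window."""

    matrix: np.ndarray  # complex Hermitian (n_sensors, n_sensors)
    band: tuple
    window_ms: tuple
    n_trials: int

    def __post_init__(self):
        m = self.matrix
        if np.abs(m - m.conj().T).max() > 1e-10:
            raise ValueError("CSD not Hermitian")


@dataclass
class SpatialFilterSet:
    """Unit-gain beamformer weights per voxel."""

    weights: np.ndarray  # (n_voxels, n_sensors) real
    regularization: float
    leadfield: LeadFieldModel


@dataclass
class SourcePowerMap:
    """Baseline-normalized source power per voxel."""

    pseudo_t: np.ndarray
    power_active: np.ndarray
    power_baseline: np.ndarray
    grid_coords: np.ndarray


def compute_csd(
    epochs: SensorEpochs,
    band: tuple[float, float] = (14.5, 15.5),
    window_ms: tuple[float, float] = (200.0, 2000.0),
    freq_step: float = 0.5,
) -> CrossSpectralDensity:
    """Band-limited CSD from complex-demodulation coefficients.

    Coefficients are computed at ``freq_step`` spacing inside ``band``
    for every kept trial and sensor; the CSD is the average over trials,
    band bins and window frames of the sensor outer products, Hermitian
    by construction.
    """
    if band[1] < band[0]:
        raise ValueError("empty band")
    t0, t1 = epochs.window_ms
    if window_ms[0] < t0 or window_ms[1] > t1:
        raise ValueError("window outside epoch")
    freqs = np.round(np.arange(band[0], band[1] + freq_step / 2, freq_step), 3)
    data = epochs.kept()
    if data.shape[0] == 0:
        raise ValueError("no kept trials")
    frames = np.arange(window_ms[0], window_ms[1] + 1e-6, 100.0)
    tfr = complex_demodulate(
        data, fs=epochs.fs, freqs=freqs, epoch_start_ms=t0, times_ms=frames
    )
    V = tfr.coeffs  # (trial, sensor, freq, frame)
    C = np.einsum("tsfr,tzfr->sz", V, V.conj())
    count = V.shape[0] * V.shape[2] * V.shape[3]
    C = C / count
    C = 0.5 * (C + C.conj().T)
    return CrossSpectralDensity(C, tuple(band), tuple(window_ms), int(data.shape[0]))


def dics_filters(
    csd: CrossSpectralDensity,
    leadfield: LeadFieldModel,
    lambda_frac: float = 0.05,
) -> SpatialFilterSet:
    """Unit-gain DICS spatial filters from the real part of the CSD.

    ``lambda = lambda_frac * mean(diag(C_r))`` diagonal loading.  Raises
    if the regularized matrix is numerically singular.
    """
    Cr = np.real(csd.matrix)
    lam = lambda_frac * float(np.mean(np.diag(Cr)))
    A = Cr + lam * np.eye(Cr.shape[0])
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("regularized CSD is numerically singular")
    L = leadfield.gains  # (n_voxels, n_sensors)
    AL = np.linalg.solve(A, L.T)  # (n_sensors, n_voxels)
    denom = np.einsum("vs,sv->v", L, AL)
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("non-positive filter denominator")
    W = (AL / denom[None, :]).T
    return SpatialFilterSet(W, lam, leadfield)


def source_power_map(
    filters: SpatialFilterSet,
    csd_active: CrossSpectralDensity,
    csd_baseline: CrossSpectralDensity,
) -> SourcePowerMap:
    """Per-voxel active power normalized by baseline power.

    ``pseudo_t(v) = (P_act(v) - P_base(v)) / P_base(v)`` with
    ``P(v) = w(v)^T C_r w(v)``.  Both CSDs must share the band; the map
    is invariant under global rescaling of the data.
    """
    if tuple(csd_active.band) != tuple(csd_baseline.band):
        raise ValueError("active and baseline CSDs must share the band")
    W = filters.weights
    Pa = np.einsum("vs,sz,vz->v", W, np.real(csd_active.matrix), W)
    Pb = np.einsum("vs,sz,vz->v", W, np.real(csd_baseline.matrix), W)
    if np.any(Pb <= 0):
        raise ValueError("non-positive baseline power at some voxel")
    return SourcePowerMap(
        pseudo_t=(Pa - Pb) / Pb,
        power_active=Pa,
        power_baseline=Pb,
        grid_coords=filters.leadfield.grid_coords,
    )


def find_peak_voxel(maps: list[SourcePowerMap]) -> tuple[int, np.ndarray]:
    """Grand-average pseudo-t map across subjects and its argmax voxel.

    Ties break toward the lowest linear voxel index (numpy argmax).
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    shape = maps[0].pseudo_t.shape
    for m in maps:
        if m.pseudo_t.shape != shape:
            raise ValueError("source grids do not match across maps")
    grand = np.mean([m.pseudo_t for m in maps], axis=0)
    return int(np.argmax(grand)), grand


def virtual_sensor(
    filters: SpatialFilterSet, voxel: int, epochs: SensorEpochs
) -> np.ndarray:
    """Source-space time series: weights(voxel) applied per sample.

    Returns a (n_kept_trials, n_times) array.
    """
    if filters.weights.shape[1] != epochs.n_sensors:
        raise ValueError("filter/epoch sensor count mismatch")
    w = filters.weights[voxel]
    return np.einsum("s,tsn->tn", w, epochs.kept())
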