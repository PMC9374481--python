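"""Synthetic two-group MEG cohorts with known ground truth.

The generator emulates the signal structure of a 15 Hz visual flicker
(steady-state) experiment: each subject has a single cortical source that
entrains to the stimulus at 15 Hz with 30/45 Hz harmonics during the
response window, a non-phase-locked 15 Hz baseline rhythm sustained
through the whole epoch, 1/f (aperiodic) source background, lognormal
cross-trial amplitude variability, white sensor noise and occasional
high-amplitude transient artifacts.  Group differences are injected
through the configuration: by default the patient-like group ("ADS") has
lower baseline 15 Hz periodic amplitude and lower cross-trial amplitude
CV than the control group ("HC"), with matched absolute entrainment
amplitude, and a cognitive (MMSE-like) score linearly coupled to each
ADS subject's mean absolute source amplitude.

The forward model is a parametric lead field: sensors on a spherical cap
above a cubic voxel grid, with smooth Gaussian distance falloff of
sensitivity plus a small seeded gain perturbation so that neighboring
voxels have correlated but non-identical sensor patterns.  Beamformer
algebra only requires a consistent generator/estimator pair, so no
gradiometer physics is modeled.

Every quantity the downstream pipeline estimates (source voxel, per-trial
amplitudes, baseline amplitude, aperiodic parameters, cognitive score) is
stored as ground truth, and the whole cohort is a pure function of the
configuration (bit-identical regeneration from the same master seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .preprocess import SensorEpochs

__all__ = [
    "LeadFieldModel",
    "SyntheticConfig",
    "SubjectRecord",
    "make_grid",
    "build_leadfield",
    "simulate_subject",
    "simulate_cohort",
    "save_subject",
    "load_subject",
]

GROUPS = ("ADS", "HC")


# ---------------------------------------------------------------------------
# Lead field
# ---------------------------------------------------------------------------

@dataclass
class LeadFieldModel:
    """Parametric forward model: per-voxel sensor gain patterns.

    ``gains`` is voxel x sensor (unitless); ``grid_coords`` holds voxel
    positions in mm in an arbitrary head frame.
    """

    grid_coords: np.ndarray
    gains: np.ndarray
    sensor_coords: np.ndarray
    seed: int

    @property
    def n_voxels(self) -> int:
        return self.gains.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.gains.shape[1]


def make_grid(shape: tuple[int, int, int] = (4, 4, 4), spacing_mm: float = 10.0) -> np.ndarray:
    """Cubic voxel grid centered at the origin; coordinates in mm."""
    axes = [spacing_mm * (np.arange(n) - (n - 1) / 2.0) for n in shape]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    return g.reshape(-1, 3)


def build_leadfield(
    grid_spec,
    n_sensors: int = 24,
    seed: int = 0,
    falloff_mm: float = 40.0,
    sensor_radius_mm: float = 80.0,
    gain_jitter: float = 0.05,
) -> LeadFieldModel:
    """Build a smooth parametric lead field over a voxel grid.

    Parameters
    ----------
    grid_spec : tuple or ndarray
        Either a ``(nx, ny, nz)`` shape (10 mm spacing) or an explicit
        (n_voxels, 3) coordinate array in mm.
    n_sensors : int
        Number of virtual sensors, placed quasi-uniformly on a spherical
        cap of radius ``sensor_radius_mm`` above the grid.
    falloff_mm : float
        Gaussian length scale of the sensitivity falloff with
        voxel-sensor distance.
    gain_jitter : float
        SD of the multiplicative seeded perturbation making voxel
        patterns non-identical beyond pure geometry.
    """
    if isinstance(grid_spec, tuple):
        coords = make_grid(grid_spec)
    else:
        coords = np.asarray(grid_spec, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("grid coordinates must be (n_voxels, 3)")
    if coords.shape[0] < 8:
        raise ValueError("grid must have at least 8 voxels")
    if len(np.unique(coords.round(6), axis=0)) != len(coords):
        raise ValueError("degenerate grid: duplicate voxel coordinates")
    if n_sensors < 8:
        raise ValueError("need at least 8 sensors")

    # Fibonacci spiral on the upper cap -> quasi-uniform sensor layout.
    k = np.arange(n_sensors)
    z = 0.35 + 0.65 * (k + 0.5) / n_sensors  # cap: z in (0.35, 1]
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1 - z**2)
    sensors = sensor_radius_mm * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)

    d = np.linalg.norm(coords[:, None, :] - sensors[None, :, :], axis=2)
    gains = np.exp(-(d**2) / (2.0 * falloff_mm**2))
    rng = np.random.default_rng(seed)
    gains = gains * (1.0 + gain_jitter * rng.standard_normal(gains.shape))
    if np.any(np.all(gains == 0, axis=1)) or not np.all(np.isfinite(gains)):
        raise ValueError("invalid lead field: zero or non-finite gain row")
    return LeadFieldModel(coords, gains, sensors, int(seed))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_n_group():
    return {"ADS": 38, "HC": 20}


def _default_A_abs():
    return {"ADS": (1.0, 0.25), "HC": (1.0, 0.25)}


def _default_cv():
    return {"ADS": 0.25, "HC": 0.40}


def _default_B_base():
    return {"ADS": (0.20, 0.05), "HC": (0.30, 0.05)}


@dataclass
class SyntheticConfig:
    """Cohort generation parameters (the study conditions).

    Amplitudes are in arbitrary source units; the lead field maps them to
    sensor units.  ``aperiodic`` gives (offset, exponent) of the source
    1/f background as ``log10 PSD = offset - exponent * log10 f``.
    ``mmse_link`` is (intercept, slope, noise SD) of the MMSE-like score
    on the subject's mean per-trial source amplitude (ADS group).
    """

    n_group: dict = field(default_factory=_default_n_group)
    n_trials: int = 120
    fs: float = 1000.0
    epoch_window_ms: tuple = (-600.0, 3200.0)
    stim_window_ms: tuple = (0.0, 1500.0)
    response_window_ms: tuple = (200.0, 2000.0)
    f0: float = 15.0
    harmonic_gains: tuple = (0.4, 0.2)  # at 2*f0, 3*f0 relative to f0
    A_abs: dict = field(default_factory=_default_A_abs)  # group -> (mean, sd)
    cv_trial: dict = field(default_factory=_default_cv)  # group -> CV
    B_base: dict = field(default_factory=_default_B_base)  # group -> (mean, sd)
    aperiodic: tuple = (-1.6, 1.0)  # (offset, exponent)
    sensor_noise_sd: float = 0.05
    artifact_rate: float = 0.0
    artifact_gain: float = 10.0
    mmse_link: tuple = (18.0, 6.0, 3.0)  # (alpha, beta, noise sd)
    source_voxel: int | None = None  # None -> voxel nearest grid centroid
    master_seed: int = 0

    def __post_init__(self):
        for g in self.n_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}; expected {GROUPS}")
        for name in ("A_abs", "B_base"):
            for g, (m, s) in getattr(self, name).items():
                if m < 0 or s < 0:
                    raise ValueError(f"{name}[{g}] must be non-negative")
        if any(cv < 0 for cv in self.cv_trial.values()):
            raise ValueError("cv_trial must be non-negative")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be non-negative")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must be in [0, 1]")

    @property
    def n_times(self) -> int:
        t0, t1 = self.epoch_window_ms
        return int(round((t1 - t0) * self.fs / 1000.0))

    def times_sec(self) -> np.ndarray:
        return self.epoch_window_ms[0] / 1000.0 + np.arange(self.n_times) / self.fs


@dataclass
class SubjectRecord:
    """One synthetic subject: epochs plus generating ground truth."""

    subject_id: str
    group: str
    epochs: SensorEpochs
    ground_truth: dict
    score: float


# ---------------------------------------------------------------------------
# Signal building blocks
# ---------------------------------------------------------------------------

def response_envelope(t_sec: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Entrainment envelope: ramp 150-250 ms, plateau to stimulus offset,
    linear decay completing 500 ms after offset (2000 ms by default)."""
    t = t_sec * 1000.0
    on0, on1 = 150.0, 250.0
    plateau_end = config.stim_window_ms[1]
    decay_end = config.response_window_ms[1]
    w = np.zeros_like(t)
    w = np.where((t >= on0) & (t < on1), (t - on0) / (on1 - on0), w)
    w = np.where((t >= on1) & (t <= plateau_end), 1.0, w)
    dec = (decay_end - t) / (decay_end - plateau_end)
    w = np.where((t > plateau_end) & (t < decay_end), dec, w)
    return w


def aperiodic_noise(
    rng: np.random.Generator,
    n_trials: int,
    n_times: int,
    fs: float,
    offset: float,
    exponent: float,
) -> np.ndarray:
    """1/f noise by spectral shaping of white noise.

    The two-sided amplitude spectral density follows
    ``10**(offset/2) * f**(-exponent/2)`` so the PSD of the result is a
    power law with the configured offset and exponent (offset in
    log10(power/Hz) units at 1 Hz).
    """
    n_f = n_times // 2 + 1
    f = np.fft.rfftfreq(n_times, d=1.0 / fs)
    shape = np.zeros(n_f)
    shape[1:] = 10.0 ** (offset / 2.0) * f[1:] ** (-exponent / 2.0)
    white = rng.standard_normal((n_trials, n_times))
    X = np.fft.rfft(white, axis=1)
    # rfft of unit white noise has E|X_k|^2 = n; normalize so the output
    # PSD (two-sided, power per Hz) equals shape**2.
    X *= shape[None, :] * np.sqrt(fs / n_times) * np.sqrt(n_times)
    return np.fft.irfft(X, n=n_times, axis=1)


def _lognormal_amplitudes(
    rng: np.random.Generator, mean: float, cv: float, n: int
) -> np.ndarray:
    """Lognormal draws with exact mean ``mean`` and CV ``cv``."""
    if cv == 0:
        return np.full(n, mean)
    s2 = np.log1p(cv**2)
    return mean * np.exp(rng.standard_normal(n) * np.sqrt(s2) - s2 / 2.0)


# ---------------------------------------------------------------------------
# Subject / cohort simulation
# ---------------------------------------------------------------------------

def simulate_subject(
    config: SyntheticConfig,
    group: str,
    subject_seed: int,
    leadfield: LeadFieldModel,
    source_voxel: int | None = None,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Simulate one subject's epoched sensor recording.

    Per trial the source time course is::

        A_i * w(t) * [sin(2 pi f0 t + phi) + sum_h g_h sin(2 pi h f0 t + phi_h)]
        + B * sin(2 pi f0 t + phi_b_i) + aperiodic noise

    with the entrainment phase ``phi`` fixed across trials (phase-locked)
    and the baseline-rhythm phase ``phi_b_i`` random per trial (non
    phase-locked).  The source is projected through the true voxel's gain
    row, then white sensor noise and (optionally) half-sine transient
    artifacts are added.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = np.random.default_rng(subject_seed)
    t = config.times_sec()
    n_tr, n_t = config.n_trials, config.n_times

    if source_voxel is None:
        source_voxel = config.source_voxel
    if source_voxel is None:
        centroid = leadfield.grid_coords.mean(axis=0)
        source_voxel = int(
            np.argmin(np.linalg.norm(leadfield.grid_coords - centroid, axis=1))
        )

    a_mean, a_sd = config.A_abs[group]
    A_subj = max(a_mean + a_sd * rng.standard_normal(), 0.05 * a_mean if a_mean else 0.0)
    A_trial = _lognormal_amplitudes(rng, A_subj, config.cv_trial[group], n_tr)

    b_mean, b_sd = config.B_base[group]
    B_subj = max(b_mean + b_sd * rng.standard_normal(), 0.0)

    phi = rng.uniform(0, 2 * np.pi)
    phi_h = rng.uniform(0, 2 * np.pi, size=len(config.harmonic_gains))
    phi_b = rng.uniform(0, 2 * np.pi, size=n_tr)

    w = response_envelope(t, config)
    carrier = np.sin(2 * np.pi * config.f0 * t + phi)
    for k, g in enumerate(config.harmonic_gains, start=2):
        carrier = carrier + g * np.sin(2 * np.pi * k * config.f0 * t + phi_h[k - 2])
    entrain = A_trial[:, None] * (w * carrier)[None, :]
    baseline_osc = B_subj * np.sin(
        2 * np.pi * config.f0 * t[None, :] + phi_b[:, None]
    )
    noise_1f = aperiodic_noise(rng, n_tr, n_t, config.fs, *config.aperiodic)
    source = entrain + baseline_osc + noise_1f

    gain = leadfield.gains[source_voxel]
    data = source[:, None, :] * gain[None, :, None]
    if config.sensor_noise_sd > 0:
        data = data + config.sensor_noise_sd * rng.standard_normal(data.shape)

    artifact_trials = []
    if config.artifact_rate > 0:
        hit = rng.random(n_tr) < config.artifact_rate
        width = int(0.1 * config.fs)  # 100 ms half-sine transient
        pulse = np.sin(np.pi * np.arange(width) / width)
        typical = np.sqrt(np.mean(data**2))
        for i in np.nonzero(hit)[0]:
            start = rng.integers(0, n_t - width)
            n_hit = max(1, leadfield.n_sensors // 3)
            sensors = rng.choice(leadfield.n_sensors, size=n_hit, replace=False)
            data[i, sensors, start : start + width] += (
                config.artifact_gain * typical * pulse[None, :]
            )
            artifact_trials.append(int(i))

    alpha, beta, sd = config.mmse_link
    if group == "ADS":
        score = alpha + beta * float(A_trial.mean()) + sd * rng.standard_normal()
    else:
        score = min(30.0, 29.4 + 0.88 * rng.standard_normal())

    epochs = SensorEpochs(
        data=data,
        fs=config.fs,
        t0_index=int(round(-config.epoch_window_ms[0] * config.fs / 1000.0)),
        window_ms=tuple(config.epoch_window_ms),
    )
    gt = {
        "source_voxel": int(source_voxel),
        "A_trial": A_trial,
        "A_mean": float(A_trial.mean()),
        "A_subject": float(A_subj),
        "baseline_amp": float(B_subj),
        "aperiodic_offset": float(config.aperiodic[0]),
        "aperiodic_exponent": float(config.aperiodic[1]),
        "phase": float(phi),
        "artifact_trials": artifact_trials,
        "subject_seed": int(subject_seed),
    }
    return SubjectRecord(
        subject_id=subject_id or f"{group}_{subject_seed}",
        group=group,
        epochs=epochs,
        ground_truth=gt,
        score=float(score),
    )


def simulate_cohort(
    config: SyntheticConfig, leadfield: LeadFieldModel | None = None
) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Simulate the full two-group cohort.

    Per-subject seeds are drawn deterministically from ``master_seed``;
    the returned ground-truth table has one row per subject.
    """
    rng = np.random.default_rng(config.master_seed)
    if leadfield is None:
        leadfield = build_leadfield(
            (4, 4, 4), n_sensors=24, seed=int(rng.integers(2**31 - 1))
        )
    else:
        rng.integers(2**31 - 1)  # keep the seed stream aligned
    records = []
    rows = []
    idx = 0
    for group in GROUPS:
        for _ in range(config.n_group.get(group, 0)):
            seed = int(rng.integers(2**31 - 1))
            rec = simulate_subject(
                config, group, seed, leadfield, subject_id=f"S{idx:03d}_{group}"
            )
            records.append(rec)
            gt = rec.ground_truth
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": group,
                    "subject_seed": seed,
                    "source_voxel": gt["source_voxel"],
                    "A_mean": gt["A_mean"],
                    "A_subject": gt["A_subject"],
                    "cv_trial_config": config.cv_trial[group],
                    "baseline_amp": gt["baseline_amp"],
                    "aperiodic_offset": gt["aperiodic_offset"],
                    "aperiodic_exponent": gt["aperiodic_exponent"],
                    "n_artifact_trials": len(gt["artifact_trials"]),
                    "score": rec.score,
                }
            )
            idx += 1
    return records, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Subject container I/O (HDF5: /epochs + JSON-attribute metadata)
# ---------------------------------------------------------------------------

def save_subject(path, record: SubjectRecord) -> None:
    """Write one subject to an HDF5 container (/epochs + /meta attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=record.epochs.data.astype(np.float32))
        f.create_dataset("kept_mask", data=record.epochs.kept_mask)
        f.create_dataset("A_trial", data=record.ground_truth["A_trial"])
        meta = {
            "subject_id": record.subject_id,
            "group": record.group,
            "fs": record.epochs.fs,
            "t0_index": record.epochs.t0_index,
            "window_ms": list(record.epochs.window_ms),
            "score": record.score,
            "ground_truth": {
                k: v for k, v in record.ground_truth.items() if k != "A_trial"
            },
        }
        f.attrs["meta"] = json.dumps(meta, sort_keys=True)


def load_subject(path) -> SubjectRecord:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["meta"])
        epochs = SensorEpochs(
            data=f["epochs"][()].astype(float),
            fs=meta["fs"],
            t0_index=meta["t0_index"],
            window_ms=tuple(meta["window_ms"]),
            kept_mask=f["kept_mask"][()],
        )
        gt = dict(meta["ground_truth"])
        gt["A_trial"] = f["A_trial"][()]
    return SubjectRecord(
        subject_id=meta["subject_id"],
        group=meta["group"],
        epochs=epochs,
        ground_truth=gt,
        score=meta["score"],
    )
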