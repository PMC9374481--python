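"""End-to-end orchestration of the entrainment analysis.

Stages (each re-runnable from the artifacts of the previous one):

1. ``simulate``   - synthetic cohort -> per-subject HDF5 containers,
                    lead field, ground-truth table.
2. ``preprocess`` - individualized artifact rejection -> kept masks,
                    rejection report CSV.
3. ``tfr``        - sensor-level spectrograms, baseline normalization,
                    permutation selection of the entrainment window.
4. ``beamform``   - per-subject DICS maps, grand-average peak voxel,
                    virtual-sensor extraction.
5. ``metrics``    - virtual-sensor TFR and entrainment metrics CSV.
6. ``specparam``  - baseline PSD parameterization CSV.
7. ``stats``      - group contrasts, Bayes factors, regressions.

A run directory is a flat layout of small text/HDF5 artifacts plus a
JSON manifest echoing the configuration and per-stage wall time.  All
randomness derives from ``master_seed``, so a re-run with the same
configuration reproduces every numeric output bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beamform import (
    compute_csd,
    dics_filters,
    find_peak_voxel,
    source_power_map,
    virtual_sensor,
)
from .metrics import summarize_entrainment
from .preprocess import reject_artifacts
from .specparam import (
    SpecparamSettings,
    baseline_psd,
    component_band_value,
    fit_spectrum,
)
from .stats import cohort_report, write_report
from .synth import (
    LeadFieldModel,
    SyntheticConfig,
    build_leadfield,
    load_subject,
    save_subject,
    simulate_cohort,
)
from .tfr import baseline_normalize, complex_demodulate, select_entrainment_window

__all__ = ["PipelineConfig", "load_config", "validate_config", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

_EPOCH = (-600.0, 3200.0)

DEFAULTS: dict = {
    "master_seed": 0,
    "verbosity": 1,
    "synth": {
        "n_group": {"ADS": 8, "HC": 8},
        "n_trials": 40,
        "fs": 1000.0,
        "f0": 15.0,
        "harmonic_gains": [0.4, 0.2],
        "A_abs": {"ADS": [1.0, 0.25], "HC": [1.0, 0.25]},
        "cv_trial": {"ADS": 0.25, "HC": 0.40},
        "B_base": {"ADS": [0.20, 0.05], "HC": [0.30, 0.05]},
        "aperiodic": [-1.6, 1.0],
        "sensor_noise_sd": 0.05,
        "artifact_rate": 0.03,
        "artifact_gain": 10.0,
        "mmse_link": [18.0, 6.0, 3.0],
    },
    "leadfield": {"shape": [4, 4, 4], "spacing_mm": 10.0, "n_sensors": 24},
    "preprocess": {"k_amp": 3.0, "k_grad": 3.0},
    "window_selection": {"alpha": 0.01, "n_perm": 1000, "cluster_alpha": 0.05},
    "beamform": {
        "band": [14.5, 15.5],
        "active_window": [200.0, 2000.0],
        "baseline_window": [-600.0, 0.0],
        "lambda_frac": 0.05,
    },
    "metrics": {
        "band": [14.5, 15.5],
        "window": [200.0, 2000.0],
        "baseline": [-600.0, 0.0],
    },
    "specparam": {
        "peak_width_limits": [1.0, 15.0],
        "max_n_peaks": 12,
        "min_peak_height": 0.0,
        "peak_threshold_sd": 2.0,
    },
    "stats": {"outlier_k": 2.5},
}


@dataclasses.dataclass
class PipelineConfig:
    """Validated nested configuration; see :data:`DEFAULTS` for keys."""

    sections: dict

    def __getitem__(self, key):
        return self.sections[key]

    @property
    def master_seed(self) -> int:
        return int(self.sections["master_seed"])

    def synthetic_config(self) -> SyntheticConfig:
        s = self.sections["synth"]
        return SyntheticConfig(
            n_group=dict(s["n_group"]),
            n_trials=int(s["n_trials"]),
            fs=float(s["fs"]),
            f0=float(s["f0"]),
            harmonic_gains=tuple(s["harmonic_gains"]),
            A_abs={g: tuple(v) for g, v in s["A_abs"].items()},
            cv_trial=dict(s["cv_trial"]),
            B_base={g: tuple(v) for g, v in s["B_base"].items()},
            aperiodic=tuple(s["aperiodic"]),
            sensor_noise_sd=float(s["sensor_noise_sd"]),
            artifact_rate=float(s["artifact_rate"]),
            artifact_gain=float(s["artifact_gain"]),
            mmse_link=tuple(s["mmse_link"]),
            master_seed=self.master_seed,
        )


def _merge(defaults, user, path, problems):
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict) and key in user and isinstance(user[key], dict):
            out[key] = _merge(dval, user[key], f"{path}{key}.", problems)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    for key in user:
        if key not in defaults:
            problems.append(f"unknown key: {path}{key}")
    return out


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config, merging over defaults; unknown keys raise."""
    user = {}
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
    if overrides:
        user = {**user, **overrides}
    problems: list[str] = []
    merged = _merge(DEFAULTS, user, "", problems)
    problems += _check_values(merged)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    return PipelineConfig(merged)


def _check_values(cfg: dict) -> list[str]:
    problems = []
    s = cfg["synth"]
    if s["n_trials"] <= 0:
        problems.append("synth.n_trials must be positive")
    for g, n in s["n_group"].items():
        if g not in ("ADS", "HC"):
            problems.append(f"synth.n_group has unknown group {g!r}")
        elif n <= 0:
            problems.append(f"synth.n_group[{g}] must be positive")
    if not 0 <= s["artifact_rate"] <= 1:
        problems.append("synth.artifact_rate must be in [0, 1]")
    if s["sensor_noise_sd"] < 0:
        problems.append("synth.sensor_noise_sd must be non-negative")
    for name in ("cv_trial",):
        if any(v < 0 for v in s[name].values()):
            problems.append(f"synth.{name} must be non-negative")
    lf = cfg["leadfield"]
    if int(np.prod(lf["shape"])) < 8:
        problems.append("leadfield.shape must give at least 8 voxels")
    if lf["n_sensors"] < 8:
        problems.append("leadfield.n_sensors must be at least 8")
    for sec in ("beamform", "metrics"):
        band = cfg[sec]["band"]
        if not (4.0 <= band[0] <= band[1] <= 50.0):
            problems.append(f"{sec}.band must lie within 4-50 Hz")
    for sec, key in (("beamform", "active_window"), ("metrics", "window")):
        w = cfg[sec][key]
        if not (_EPOCH[0] <= w[0] < w[1] <= _EPOCH[1]):
            problems.append(f"{sec}.{key} must lie within the epoch")
    ws = cfg["window_selection"]
    if ws["n_perm"] < 200:
        problems.append("window_selection.n_perm must be at least 200")
    if not 0 < ws["alpha"] < 1:
        problems.append("window_selection.alpha must be in (0, 1)")
    if cfg["stats"]["outlier_k"] <= 0:
        problems.append("stats.outlier_k must be positive")
    return problems


def validate_config(path) -> list[str]:
    """Schema and range checks; returns an empty list iff runnable."""
    try:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
    except OSError as e:
        raise OSError(f"cannot read config file: {e}") from e
    problems: list[str] = []
    merged = _merge(DEFAULTS, user, "", problems)
    problems += _check_values(merged)
    return problems


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _subject_paths(outdir: Path) -> list[Path]:
    return sorted((outdir / "subjects").glob("*.h5"))


def _load_leadfield(outdir: Path) -> LeadFieldModel:
    z = np.load(outdir / "leadfield.npz")
    return LeadFieldModel(z["grid_coords"], z["gains"], z["sensor_coords"], int(z["seed"]))


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    lf_cfg = cfg["leadfield"]
    rng = np.random.default_rng([cfg.master_seed, 11])
    from .synth import make_grid

    grid = make_grid(tuple(lf_cfg["shape"]), float(lf_cfg["spacing_mm"]))
    leadfield = build_leadfield(
        grid, n_sensors=int(lf_cfg["n_sensors"]), seed=int(rng.integers(2**31 - 1))
    )
    np.savez(
        outdir / "leadfield.npz",
        grid_coords=leadfield.grid_coords,
        gains=leadfield.gains,
        sensor_coords=leadfield.sensor_coords,
        seed=leadfield.seed,
    )
    records, gt = simulate_cohort(cfg.synthetic_config(), leadfield)
    (outdir / "subjects").mkdir(exist_ok=True)
    for rec in records:
        save_subject(outdir / "subjects" / f"{rec.subject_id}.h5", rec)
    gt.to_csv(outdir / "ground_truth.csv", index=False, float_format="%.10g")
    gt[["subject_id", "group", "score"]].to_csv(
        outdir / "covariates.csv", index=False, float_format="%.10g"
    )
    logger.info("simulated %d subjects", len(records))


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    pp = cfg["preprocess"]
    rows = []
    for path in _subject_paths(outdir):
        rec = load_subject(path)
        epochs, report = reject_artifacts(
            rec.epochs, k_amp=float(pp["k_amp"]), k_grad=float(pp["k_grad"])
        )
        rec.epochs = epochs
        save_subject(path, rec)
        rows.append({"subject_id": rec.subject_id, "group": rec.group, **report.as_dict()})
    pd.DataFrame(rows).to_csv(outdir / "rejection.csv", index=False, float_format="%.10g")


def stage_tfr(cfg: PipelineConfig, outdir: Path) -> None:
    """Sensor-mean relative spectrograms and permutation window selection."""
    ws = cfg["window_selection"]
    maps = []
    freqs = times = None
    for path in _subject_paths(outdir):
        rec = load_subject(path)
        tfr = complex_demodulate(rec.epochs.kept(), fs=rec.epochs.fs)
        power = tfr.power().mean(axis=0)  # trial-avg -> (sensor, freq, time)
        rel = baseline_normalize(power, tfr.times_ms)
        maps.append(rel.mean(axis=0))  # sensor mean -> (freq, time)
        freqs, times = tfr.freqs, tfr.times_ms
    maps = np.asarray(maps)
    np.save(outdir / "sensor_maps.npy", maps)
    seed = int(np.random.default_rng([cfg.master_seed, 17]).integers(2**31 - 1))
    mask = select_entrainment_window(
        maps,
        alpha=float(ws["alpha"]),
        n_perm=int(ws["n_perm"]),
        seed=seed,
        cluster_alpha=float(ws["cluster_alpha"]),
        freqs=freqs,
        times_ms=times,
    )
    fgrid, tgrid = np.meshgrid(freqs, times, indexing="ij")
    pd.DataFrame(
        {
            "freq": fgrid.ravel(),
            "time_ms": tgrid.ravel(),
            "selected": mask.mask.ravel().astype(int),
        }
    ).to_csv(outdir / "significance_mask.csv", index=False, float_format="%.10g")


def stage_beamform(cfg: PipelineConfig, outdir: Path) -> None:
    bf = cfg["beamform"]
    leadfield = _load_leadfield(outdir)
    band = tuple(bf["band"])
    maps, filters_per_subject, ids = [], [], []
    for path in _subject_paths(outdir):
        rec = load_subject(path)
        csd_act = compute_csd(rec.epochs, band, tuple(bf["active_window"]))
        csd_base = compute_csd(rec.epochs, band, tuple(bf["baseline_window"]))
        filt = dics_filters(csd_act, leadfield, float(bf["lambda_frac"]))
        maps.append(source_power_map(filt, csd_act, csd_base))
        filters_per_subject.append(filt)
        ids.append(rec.subject_id)
    peak, grand = find_peak_voxel(maps)
    coords = leadfield.grid_coords
    pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "pseudo_t": grand,
        }
    ).to_csv(outdir / "source_map.csv", index=False, float_format="%.10g")
    (outdir / "derived").mkdir(exist_ok=True)
    for path, filt, sid in zip(_subject_paths(outdir), filters_per_subject, ids):
        rec = load_subject(path)
        vs = virtual_sensor(filt, peak, rec.epochs)
        np.savez(
            outdir / "derived" / f"{sid}_vs.npz",
            vs=vs.astype(np.float32),
            weights=filt.weights[peak],
            peak_voxel=peak,
            fs=rec.epochs.fs,
        )
    with open(outdir / "peak_voxel.json", "w") as f:
        json.dump({"peak_voxel": int(peak)}, f)


def _vs_tfr(outdir: Path, sid: str):
    z = np.load(outdir / "derived" / f"{sid}_vs.npz")
    return complex_demodulate(z["vs"].astype(float), fs=float(z["fs"]))


def stage_metrics(cfg: PipelineConfig, outdir: Path) -> None:
    mc = cfg["metrics"]
    rows = []
    for path in _subject_paths(outdir):
        rec = load_subject(path)
        tfr = _vs_tfr(outdir, rec.subject_id)
        np.savez(
            outdir / "derived" / f"{rec.subject_id}_vstfr.npz",
            coeffs=tfr.coeffs.astype(np.complex64),
            freqs=tfr.freqs,
            times_ms=tfr.times_ms,
        )
        summ = summarize_entrainment(
            tfr,
            band=tuple(mc["band"]),
            window_ms=tuple(mc["window"]),
            baseline_ms=tuple(mc["baseline"]),
        )
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "abs_amp": summ.abs_amp,
            "rel_amp": summ.rel_amp,
            "base_amp": summ.base_amp,
            "itpl": summ.itpl,
            "cv": summ.cv,
        }
        for f, v in zip(tfr.freqs, summ.per_freq_rel):
            row[f"relf_{f:g}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")


def stage_specparam(cfg: PipelineConfig, outdir: Path) -> None:
    sp = cfg["specparam"]
    settings = SpecparamSettings(
        peak_width_limits=tuple(sp["peak_width_limits"]),
        max_n_peaks=int(sp["max_n_peaks"]),
        min_peak_height=float(sp["min_peak_height"]),
        peak_threshold_sd=float(sp["peak_threshold_sd"]),
    )
    band = tuple(cfg["metrics"]["band"])
    rows = []
    from .tfr import TFRTensor

    for path in _subject_paths(outdir):
        rec = load_subject(path)
        z = np.load(outdir / "derived" / f"{rec.subject_id}_vstfr.npz")
        tfr = TFRTensor(z["coeffs"].astype(complex), z["freqs"], z["times_ms"])
        fit = fit_spectrum(baseline_psd(tfr), settings)
        row = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "offset": fit.offset,
            "exponent": fit.exponent,
            "n_peaks": len(fit.peaks),
            "r_squared": fit.r_squared,
            "base_full": component_band_value(fit, band, "full"),
            "base_aperiodic": component_band_value(fit, band, "aperiodic"),
            "base_periodic": component_band_value(fit, band, "periodic"),
        }
        for i, (cf, pw, bw) in enumerate(fit.peaks[:3]):
            row.update({f"peak{i}_cf": cf, f"peak{i}_pw": pw, f"peak{i}_bw": bw})
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        outdir / "spectrum_fits.csv", index=False, float_format="%.10g"
    )


def stage_stats(cfg: PipelineConfig, outdir: Path) -> None:
    metrics = pd.read_csv(outdir / "metrics.csv")
    fits = pd.read_csv(outdir / "spectrum_fits.csv")
    covariates = pd.read_csv(outdir / "covariates.csv")
    table = metrics.merge(
        fits[["subject_id", "base_full", "base_aperiodic", "base_periodic", "r_squared"]],
        on="subject_id",
    )
    report = cohort_report(
        table,
        covariates[["subject_id", "score"]],
        outlier_k=float(cfg["stats"]["outlier_k"]),
    )
    write_report(report, outdir / "stats.csv", outdir / "stats.json")
    if report["per_freq"] is not None:
        report["per_freq"].to_csv(
            outdir / "per_freq_contrasts.csv", index=False, float_format="%.10g"
        )


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "tfr": stage_tfr,
    "beamform": stage_beamform,
    "metrics": stage_metrics,
    "specparam": stage_specparam,
    "stats": stage_stats,
}


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    stages: list[str] | None = None,
) -> Path:
    """Run the pipeline (or a subset of stages) into ``out_dir``.

    Returns the output directory.  A manifest echoing the configuration,
    seed and per-stage wall time is written alongside the artifacts.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = stages or list(STAGES)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    timings = {}
    for name in STAGES:
        if name not in todo:
            continue
        t0 = time.perf_counter()
        try:
            STAGES[name](config, outdir)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e
        timings[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s done in %.1fs", name, timings[name])
    manifest = {
        "version": __version__,
        "master_seed": config.master_seed,
        "config": config.sections,
        "stages_run": [s for s in STAGES if s in todo],
        "timings_sec": timings,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True, default=str)
    return outdir
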