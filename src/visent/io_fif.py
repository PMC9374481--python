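"""Experimental FIF adapter (real-data ingestion).

Converts an MNE-readable epochs FIF file into the subject HDF5 container
used by the pipeline.  This adapter is experimental: it has not been
exercised against vendor data and real recordings additionally need the
vendor preprocessing (noise reduction, head-motion and physiological
artifact correction) that the synthetic generator does not model.
Requires ``mne`` at call time; the rest of the package does not.
"""

from __future__ import annotations

from .preprocess import SensorEpochs
from .synth import SubjectRecord, save_subject

__all__ = ["import_fif"]


def import_fif(fif_path, out_h5, subject_id: str = "S000", group: str = "HC"):
    """Convert an `*-epo.fif` file into a subject container (experimental)."""
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("the FIF adapter requires the optional 'mne' package") from e
    ep = mne.read_epochs(fif_path, preload=True, verbose="error")
    ep.pick("grad")
    data = ep.get_data()
    fs = float(ep.info["sfreq"])
    t0_index = int(round(-ep.tmin * fs))
    rec = SubjectRecord(
        subject_id=subject_id,
        group=group,
        epochs=SensorEpochs(
            data=data,
            fs=fs,
            t0_index=t0_index,
            window_ms=(ep.tmin * 1000.0, ep.tmax * 1000.0),
        ),
        ground_truth={
            "source_voxel": -1,
            "A_trial": data.mean(axis=(1, 2)) * 0.0,
            "A_mean": 0.0,
            "A_subject": 0.0,
            "baseline_amp": 0.0,
            "aperiodic_offset": 0.0,
            "aperiodic_exponent": 0.0,
            "phase": 0.0,
            "artifact_trials": [],
            "subject_seed": -1,
        },
        score=float("nan"),
    )
    save_subject(out_h5, rec)
    return rec
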