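"""File I/O: NIfTI volumes, GIFTI surfaces, BIDS-style TSVs and JSON
sidecars. Every writer has a matching reader that round-trips data and
metadata exactly."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import AcquisitionParams, GroundTruth, InterleavedSeries, TaskDesign
from .preprocess import ContrastSeries


def save_nifti(data: np.ndarray, affine: np.ndarray, path):
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_surface(vertices: np.ndarray, faces: np.ndarray, path):
    """GIFTI surface (.surf.gii) with POINTSET + TRIANGLE arrays."""
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            np.asarray(vertices, dtype=np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            np.asarray(faces, dtype=np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    nib.save(img, str(path))


def load_surface(path):
    img = nib.load(str(path))
    vertices = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return np.asarray(vertices, dtype=float), np.asarray(faces, dtype=int)


def save_events(design: TaskDesign, path):
    df = pd.DataFrame(
        [{"onset": o, "duration": d, "trial_type": c} for o, d, c in design.events]
    )
    df.to_csv(path, sep="\t", index=False)


def load_events(path) -> TaskDesign:
    df = pd.read_csv(path, sep="\t")
    events = [
        (float(r.onset), float(r.duration), str(r.trial_type))
        for r in df.itertuples()
    ]
    n = sum(1 for *_, c in events if c == "memory")
    return TaskDesign(events=events, n_trials_per_condition=n)


def save_interleaved(series: InterleavedSeries, affine, nifti_path, json_path):
    save_nifti(series.data, affine, nifti_path)
    meta = {
        "contrast_tag": list(series.contrast_tag),
        "timestamp_ms": series.timestamp_ms.tolist(),
        "params": series.params.__dict__,
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def load_interleaved(nifti_path, json_path) -> InterleavedSeries:
    data, _ = load_nifti(nifti_path)
    meta = json.loads(Path(json_path).read_text())
    return InterleavedSeries(
        data=np.asarray(data, dtype=float),
        contrast_tag=meta["contrast_tag"],
        timestamp_ms=np.asarray(meta["timestamp_ms"], dtype=float),
        params=AcquisitionParams(**meta["params"]),
    )


def save_contrast_series(series: ContrastSeries, affine, nifti_path, json_path):
    save_nifti(series.data, affine, nifti_path)
    meta = {
        "contrast": series.contrast,
        "timestamp_ms": series.timestamp_ms.tolist(),
        "provenance": series.provenance,
    }
    Path(json_path).write_text(json.dumps(meta, indent=1))


def load_contrast_series(nifti_path, json_path) -> ContrastSeries:
    data, _ = load_nifti(nifti_path)
    meta = json.loads(Path(json_path).read_text())
    return ContrastSeries(
        data=np.asarray(data, dtype=float),
        contrast=meta["contrast"],
        timestamp_ms=np.asarray(meta["timestamp_ms"], dtype=float),
        provenance=meta["provenance"],
    )


def save_ground_truth(truth: GroundTruth, params: AcquisitionParams, path):
    payload = {
        "cbv_profile": {k: np.asarray(v).tolist() for k, v in truth.cbv_profile.items()},
        "bold_profile": {k: np.asarray(v).tolist() for k, v in truth.bold_profile.items()},
        "drift_coeffs": list(truth.drift_coeffs),
        "noise_sd": truth.noise_sd,
        "inflow_amplitude_at_unit_power": truth.inflow_amplitude_at_unit_power,
        "baseline": truth.baseline,
        "acquisition_params": params.__dict__,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path):
    payload = json.loads(Path(path).read_text())
    params = AcquisitionParams(**payload.pop("acquisition_params"))
    truth = GroundTruth(
        cbv_profile={k: np.asarray(v) for k, v in payload["cbv_profile"].items()},
        bold_profile={k: np.asarray(v) for k, v in payload["bold_profile"].items()},
        drift_coeffs=tuple(payload["drift_coeffs"]),
        noise_sd=payload["noise_sd"],
        inflow_amplitude_at_unit_power=payload["inflow_amplitude_at_unit_power"],
        baseline=payload["baseline"],
    )
    return truth, params


def save_nuisance_tsv(nuisance_set, path):
    nuisance_set.to_frame().to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError("motion file must have exactly 6 columns")
    return df.to_numpy(dtype=float)
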