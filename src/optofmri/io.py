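"""Readers and writers for the on-disk formats shared by all stages.

BOLD runs and label/mask volumes travel as NIfTI-1 (4D float data, 3D
integer labels) with the voxel size carried in the affine and the protocol
in a JSON sidecar.  Field potentials, EEG, spikes and event/test tables
travel as CSV; configurations and run manifests as JSON/YAML.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .protocol import StimulusProtocol
from .simulate import BoldDataset, LfpRecording, SloEvent, SpikeTrain

__all__ = [
    "save_bold",
    "load_bold",
    "save_labels",
    "load_mask",
    "save_spikes",
    "load_spikes",
    "save_lfp",
    "load_lfp",
    "save_events",
    "load_config",
    "write_manifest",
]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_bold(ds: BoldDataset, path: str | Path) -> None:
    """Write a BOLD run as NIfTI plus a JSON sidecar with timing metadata."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(ds.data, dtype=np.float32), _affine(ds.voxel_size_mm))
    img.header.set_zooms(tuple(ds.voxel_size_mm) + (ds.tr_s,))
    nib.save(img, path)
    sidecar = {
        "tr_s": ds.tr_s,
        "voxel_size_mm": list(ds.voxel_size_mm),
        "n_baseline_frames": ds.n_baseline_frames,
        "protocol": ds.protocol.to_dict(),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_bold(path: str | Path) -> BoldDataset:
    path = Path(path)
    img = nib.load(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return BoldDataset(
        data=np.asarray(img.dataobj, dtype=float),
        tr_s=meta["tr_s"],
        voxel_size_mm=tuple(meta["voxel_size_mm"]),
        protocol=StimulusProtocol.from_dict(meta["protocol"]),
        n_baseline_frames=meta["n_baseline_frames"],
    )


def save_labels(labels: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    """Write a 3D integer label/mask volume as NIfTI."""
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_size_mm))
    nib.save(img, Path(path))


def load_mask(path: str | Path, reference_shape=None, reference_affine=None) -> np.ndarray:
    """Load a 3D mask/label volume, checking it shares the reference grid."""
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if reference_shape is not None and tuple(data.shape) != tuple(reference_shape):
        raise ValueError(
            f"mask grid {tuple(data.shape)} does not match data grid {tuple(reference_shape)}"
        )
    if reference_affine is not None and not np.allclose(img.affine, reference_affine, atol=1e-4):
        raise ValueError("mask affine does not match the data affine")
    return data


def save_spikes(trains: list[SpikeTrain], path: str | Path) -> None:
    """Spike tables as CSV: unit, trial, condition, time_s (full float precision)."""
    rows = [
        {"unit": tr.unit_id, "trial": tr.trial_id, "condition": tr.condition, "time_s": t}
        for tr in trains
        for t in tr.spike_times_s
    ]
    pd.DataFrame(rows, columns=["unit", "trial", "condition", "time_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def load_spikes(path: str | Path, trial_layout_s=(20.0, 20.0, 20.0)) -> list[SpikeTrain]:
    df = pd.read_csv(path, float_precision="round_trip")
    trains = []
    for (unit, trial, cond), grp in df.groupby(["unit", "trial", "condition"], sort=True):
        trains.append(
            SpikeTrain(
                unit_id=int(unit),
                trial_id=int(trial),
                condition=str(cond),
                spike_times_s=np.sort(grp["time_s"].to_numpy()),
                trial_layout_s=tuple(trial_layout_s),
            )
        )
    return trains


def save_lfp(rec: LfpRecording, path: str | Path) -> None:
    """LFP as long-format CSV (channel, trial, sample, value_uv) + JSON sidecar."""
    path = Path(path)
    ch, tr, s = np.meshgrid(
        np.arange(rec.n_channels),
        np.arange(rec.n_trials),
        np.arange(rec.traces.shape[-1]),
        indexing="ij",
    )
    pd.DataFrame(
        {
            "channel": ch.ravel(),
            "trial": tr.ravel(),
            "sample": s.ravel(),
            "value_uv": rec.traces.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.17g")
    sidecar = {"fs_hz": rec.fs_hz, "stim_window_s": list(rec.stim_window_s)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_lfp(path: str | Path) -> LfpRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    n_ch = df["channel"].max() + 1
    n_tr = df["trial"].max() + 1
    n_s = df["sample"].max() + 1
    traces = np.full((n_ch, n_tr, n_s), np.nan)
    traces[df["channel"], df["trial"], df["sample"]] = df["value_uv"]
    return LfpRecording(
        fs_hz=meta["fs_hz"], traces=traces, stim_window_s=tuple(meta["stim_window_s"])
    )


def save_events(events: list[SloEvent], path: str | Path) -> None:
    pd.DataFrame([asdict(ev) for ev in events],
                 columns=["channel", "trial", "onset_s"]).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: str | Path, parameters: dict, inputs: list = ()) -> Path:
    """Write a machine-readable run manifest next to the results."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "optofmri",
        "version": __version__,
        "python": platform.python_version(),
        "parameters": parameters,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
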