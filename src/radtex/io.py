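"""Readers and writers: patch/stack archives, record tables, NIfTI, sidecars.

Cohort patches live in one compressed npz archive with keys
``patch/<lesion_id>/<channel>``; records are CSV with a fixed header;
GLCM stacks are archived per lesion with a JSON sidecar recording the
extraction settings. Every derived artifact gets a sidecar with a config
hash and seed so reruns are attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glcm import GLCMStack
from .phantoms import RECORD_COLUMNS
from .preprocess import CHANNEL_NAMES, VolumetricPatch

__all__ = ["save_cohort", "load_cohort", "save_records", "load_records",
           "save_stacks", "load_stacks", "save_features", "load_features",
           "read_patch_nifti", "export_patch_nifti", "config_hash",
           "write_sidecar"]


def config_hash(config: dict) -> str:
    """Stable sha256 over a JSON-serializable configuration dict."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_sidecar(path, config: dict, seed: int | None = None, **extra) -> None:
    payload = {"config": config, "config_hash": config_hash(config),
               "seed": seed, **extra}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def save_cohort(archive_path, patches: list[VolumetricPatch],
                records: pd.DataFrame | None = None,
                records_path=None) -> None:
    arrays = {}
    for p in patches:
        for name, ch in zip(CHANNEL_NAMES, p.channels):
            arrays[f"patch/{p.lesion_id}/{name}"] = ch
    np.savez_compressed(archive_path, **arrays)
    if records is not None and records_path is not None:
        save_records(records_path, records)


def load_cohort(archive_path) -> list[VolumetricPatch]:
    patches = {}
    with np.load(archive_path) as data:
        for key in data.files:
            _, lesion_id, channel = key.split("/")
            patches.setdefault(lesion_id, {})[channel] = data[key]
    return [VolumetricPatch(lid, chans["t2w"], chans["adc"])
            for lid, chans in sorted(patches.items())]


def save_records(path, records: pd.DataFrame) -> None:
    records.reindex(columns=RECORD_COLUMNS).to_csv(path, index=False)


def load_records(path) -> pd.DataFrame:
    records = pd.read_csv(path, keep_default_na=False,
                          dtype={"split": str, "lesion_id": str, "patient_id": str})
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records file is missing columns: {sorted(missing)}")
    return records


def save_stacks(archive_path, stacks: list[GLCMStack], seed: int | None = None) -> None:
    arrays = {}
    for s in stacks:
        arrays[f"stack/{s.lesion_id}"] = s.matrices
        arrays[f"counts/{s.lesion_id}"] = s.pair_counts
    np.savez_compressed(archive_path, **arrays)
    first = stacks[0]
    write_sidecar(Path(archive_path).with_suffix(".json"),
                  {"n_levels": first.n_levels,
                   "directions": [list(d) for d in first.directions],
                   "normalized": first.normalized},
                  seed=seed)


def load_stacks(archive_path) -> list[GLCMStack]:
    sidecar = json.loads(Path(archive_path).with_suffix(".json").read_text())
    cfg = sidecar["config"]
    directions = tuple(tuple(d) for d in cfg["directions"])
    stacks = []
    with np.load(archive_path) as data:
        ids = sorted(k.split("/")[1] for k in data.files if k.startswith("stack/"))
        for lid in ids:
            stacks.append(GLCMStack(data[f"stack/{lid}"], data[f"counts/{lid}"],
                                    normalized=cfg["normalized"],
                                    n_levels=cfg["n_levels"],
                                    directions=directions, lesion_id=lid))
    return stacks


def save_features(path, features: pd.DataFrame, labels=None) -> None:
    out = features.copy()
    if labels is not None:
        out["label"] = np.asarray(labels)
    out.to_csv(path, index_label="lesion_id")


def load_features(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="lesion_id")


def read_patch_nifti(t2w_path, adc_path, mask_path=None, margin: int = 2,
                     lesion_id: str | None = None) -> VolumetricPatch:
    """Crop a two-channel lesion patch from NIfTI volumes.

    With a mask, the patch is the tight bounding box of the nonzero mask
    voxels dilated by ``margin`` voxels per side and clipped to the volume;
    without one, the whole volume is the patch. Channel grids must match.
    """
    t2w_img = nib.load(str(t2w_path))
    adc_img = nib.load(str(adc_path))
    t2w = np.asarray(t2w_img.dataobj, dtype=np.float64)
    adc = np.asarray(adc_img.dataobj, dtype=np.float64)
    if t2w.shape != adc.shape or not np.allclose(t2w_img.affine, adc_img.affine):
        raise ValueError("channel volumes must share a grid (shape and affine)")
    if lesion_id is None:
        lesion_id = Path(t2w_path).name.split(".")[0]
    if mask_path is None:
        return VolumetricPatch(lesion_id, t2w, adc)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    if mask.shape != t2w.shape:
        raise ValueError("mask must share the channel grid")
    if not mask.any():
        raise ValueError("mask is empty")
    slices = []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        nz = np.flatnonzero(proj)
        lo = max(int(nz[0]) - margin, 0)
        hi = min(int(nz[-1]) + 1 + margin, mask.shape[ax])
        slices.append(slice(lo, hi))
    slices = tuple(slices)
    return VolumetricPatch(lesion_id, t2w[slices], adc[slices])


def export_patch_nifti(patch: VolumetricPatch, out_dir) -> list[Path]:
    """One NIfTI file per channel (identity affine), for interoperability."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, ch in zip(CHANNEL_NAMES, patch.channels):
        path = out_dir / f"{patch.lesion_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(ch.astype(np.float32), np.eye(4)), str(path))
        written.append(path)
    return written
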