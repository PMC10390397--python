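"""File formats: NIfTI volumes, 32-bit TIFF maps, CSV tables, JSON sidecars.

Every repo type has a lossless write->read round trip; schema violations
are rejected naming the offending field.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .decomp import ABMDMap, SpectralProjectionPair
from .phantom import LabeledVolume
from .quantify import COHORT_SCHEMA
from .register import AffineTransform2D

__all__ = [
    "save_labeled_volume",
    "load_labeled_volume",
    "save_projection_pair",
    "load_projection_pair",
    "save_abmd_map",
    "load_abmd_map",
    "save_cohort_table",
    "load_cohort_table",
    "save_transform",
    "load_transform",
]


class IOError_(ValueError):
    """Raised on schema or format violations."""


def _affine(spacing) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    return aff


def save_labeled_volume(volume: LabeledVolume, directory, stem: str = "phantom") -> dict:
    """Write water/hydroxyapatite/label NIfTI trio plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    aff = _affine(volume.voxel_spacing)
    paths = {}
    for name, arr in (
        ("water", volume.water_density),
        ("hydroxyapatite", volume.hydroxyapatite_density),
        ("labels", volume.labels.astype(np.int16)),
    ):
        p = directory / f"{stem}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(arr), aff), p)
        paths[name] = str(p)
    sidecar = directory / f"{stem}_labels.json"
    sidecar.write_text(
        json.dumps(
            {"label_names": volume.label_names, "voxel_spacing": list(volume.voxel_spacing)},
            indent=2,
        )
    )
    paths["sidecar"] = str(sidecar)
    return paths


def load_labeled_volume(directory, stem: str = "phantom") -> LabeledVolume:
    directory = Path(directory)
    arrays = {}
    for name in ("water", "hydroxyapatite", "labels"):
        img = nib.load(directory / f"{stem}_{name}.nii")
        arrays[name] = np.asarray(img.dataobj)
    meta = json.loads((directory / f"{stem}_labels.json").read_text())
    return LabeledVolume(
        water_density=arrays["water"].astype(float),
        hydroxyapatite_density=arrays["hydroxyapatite"].astype(float),
        labels=arrays["labels"].astype(np.int16),
        voxel_spacing=tuple(meta["voxel_spacing"]),
        label_names=meta["label_names"],
    )


def save_projection_pair(pair: SpectralProjectionPair, path) -> None:
    """Two-page 32-bit float TIFF (photoelectric, Compton) + JSON metadata."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack([pair.photoelectric_epl, pair.compton_epl]).astype(np.float32),
    )
    meta = {"pixel_spacing": list(pair.pixel_spacing), "qc": pair.qc}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))


def load_projection_pair(path) -> SpectralProjectionPair:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise IOError_(f"{path} is not a two-page spectral projection TIFF")
    meta = json.loads(path.with_suffix(".json").read_text())
    return SpectralProjectionPair(
        photoelectric_epl=pages[0].astype(float),
        compton_epl=pages[1].astype(float),
        pixel_spacing=tuple(meta["pixel_spacing"]),
        qc=meta.get("qc", {}),
    )


def save_abmd_map(abmd: ABMDMap, path) -> None:
    path = Path(path)
    if not np.all(np.isfinite(abmd.abmd)):
        raise IOError_("aBMD map contains non-finite values; refusing to write")
    tifffile.imwrite(path, abmd.abmd.astype(np.float32))
    meta = {
        "pixel_spacing": list(abmd.pixel_spacing),
        "provenance": abmd.provenance,
        "denoised": abmd.denoised,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_abmd_map(path) -> ABMDMap:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return ABMDMap(
        abmd=tifffile.imread(path).astype(float),
        pixel_spacing=tuple(meta["pixel_spacing"]),
        provenance=meta["provenance"],
        denoised=meta["denoised"],
    )


def save_cohort_table(table: pd.DataFrame, path) -> None:
    path = Path(path)
    missing = [c for c in ("patient_id", "vertebra", "vbmd", "status") if c not in table.columns]
    if missing:
        raise IOError_(f"cohort table missing required columns: {missing}")
    table.to_csv(path, index=False)
    path.with_suffix(".schema.json").write_text(json.dumps(COHORT_SCHEMA, indent=2))


def load_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "vertebra", "vbmd", "status") if c not in df.columns]
    if missing:
        raise IOError_(f"cohort table missing required columns: {missing}")
    return df


def save_transform(transform: AffineTransform2D, path) -> None:
    Path(path).write_text(json.dumps(transform.as_dict(), indent=2))


def load_transform(path) -> AffineTransform2D:
    return AffineTransform2D.from_dict(json.loads(Path(path).read_text()))
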