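"""Reading and writing fluence maps and cohort manifests.

Conventions
-----------
* 16-bit grayscale TIFF, stored integer = dose in cGy x 100 (0.01 cGy
  quantisation); the scale, pixel pitch and provenance ride along in a
  JSON ImageDescription tag.
* DICOM RT Image is read-only: pixel values are rescaled through
  RescaleSlope/Intercept and the pitch comes from ImagePlanePixelSpacing
  (or PixelSpacing), unless overridden.
* Manifests are UTF-8 CSV with a header, one row per map, exactly one
  baseline row per patient.
* Image origin is top-left, row-major; rows run along the SI imager
  axis, columns along the in-plane axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ErrorVector, FluenceMap
from .labeling import LabelSet, assign_labels
from .synthetic_data import CohortRecord

#: stored integer units per cGy in written TIFFs
TIFF_DOSE_SCALE = 100.0

MANIFEST_COLUMNS = [
    "patient_id", "path", "role", "serial", "lr_mm", "si_mm", "ap_mm",
    "isocenter_mm", "type1", "type2_lr", "type2_si", "type2_ap", "type3",
    "noise_seed",
]


def write_map(path: str | Path, fluence: FluenceMap) -> Path:
    """Write a fluence map as 16-bit TIFF with JSON sidecar metadata."""
    path = Path(path)
    stored = np.round(fluence.pixels * TIFF_DOSE_SCALE)
    if stored.max() > np.iinfo(np.uint16).max:
        raise ValueError("dose exceeds the 16-bit storage range (655 cGy)")
    desc = {
        "dose_scale": TIFF_DOSE_SCALE,
        "pitch_mm": fluence.pitch_mm,
        "patient_id": fluence.patient_id,
        "error_mm": list(fluence.error.as_tuple()) if fluence.error else None,
    }
    tifffile.imwrite(
        path, stored.astype(np.uint16), description=json.dumps(desc)
    )
    return path


def _read_tiff(path: Path, pitch_override: float | None) -> FluenceMap:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        pixels = page.asarray().astype(np.float64)
        desc = {}
        if page.description:
            try:
                desc = json.loads(page.description)
            except (ValueError, TypeError):
                desc = {}
    scale = float(desc.get("dose_scale", TIFF_DOSE_SCALE))
    pitch = pitch_override or desc.get("pitch_mm")
    if pitch is None:
        raise ValueError(
            f"{path}: no pixel-pitch metadata; pass an explicit override"
        )
    err = desc.get("error_mm")
    return FluenceMap(
        pixels=pixels / scale,
        pitch_mm=float(pitch),
        patient_id=str(desc.get("patient_id", "")),
        error=ErrorVector(*err) if err else None,
        meta={"source": str(path)},
        validate=False,
    )


def _read_dicom(path: Path, pitch_override: float | None) -> FluenceMap:
    import pydicom

    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pitch = pitch_override
    if pitch is None:
        spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(
            ds, "PixelSpacing", None
        )
        if spacing is None:
            raise ValueError(f"{path}: DICOM has no pixel spacing; pass an override")
        pitch = float(spacing[0])
    return FluenceMap(
        pixels=np.maximum(pixels * slope + intercept, 0.0),
        pitch_mm=float(pitch),
        patient_id=str(getattr(ds, "PatientID", "")),
        meta={"source": str(path)},
        validate=False,
    )


def read_map(path: str | Path, pitch_mm_override: float | None = None) -> FluenceMap:
    """Read a 16-bit TIFF or DICOM RT Image as a fluence map in cGy."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return _read_tiff(path, pitch_mm_override)
    return _read_dicom(path, pitch_mm_override)


def write_cohort(
    records: list[CohortRecord], out_dir: str | Path
) -> Path:
    """Write every map as TIFF plus a CSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.patient_id}_s{rec.serial:02d}.tif"
        write_map(out_dir / fname, rec.map)
        err = rec.map.error or ErrorVector()
        lab = rec.labels
        rows.append(
            {
                "patient_id": rec.patient_id,
                "path": fname,
                "role": rec.role,
                "serial": rec.serial,
                "lr_mm": err.lr_mm,
                "si_mm": err.si_mm,
                "ap_mm": err.ap_mm,
                "isocenter_mm": lab.isocenter_mm if lab else "",
                "type1": lab.type1 if lab else "",
                "type2_lr": lab.type2_lr if lab else "",
                "type2_si": lab.type2_si if lab else "",
                "type2_ap": lab.type2_ap if lab else "",
                "type3": lab.type3 if lab else "",
                "noise_seed": rec.noise_seed,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    _validate_manifest(manifest)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def _validate_manifest(manifest: pd.DataFrame) -> None:
    baselines = manifest[manifest["role"] == "baseline"]
    per_patient = baselines.groupby("patient_id").size()
    extra = per_patient[per_patient != 1]
    if len(extra):
        raise ValueError(
            f"patients must have exactly one baseline, got {dict(extra)}"
        )
    missing = set(manifest["patient_id"]) - set(baselines["patient_id"])
    if missing:
        raise ValueError(f"patients without a baseline: {sorted(missing)}")


def read_manifest(manifest_path: str | Path) -> list[CohortRecord]:
    """Load a cohort written by :func:`write_cohort` (lossless round trip)."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path)
    _validate_manifest(table)
    base = manifest_path.parent
    records = []
    for row in table.itertuples(index=False):
        fm = read_map(base / row.path)
        fm.patient_id = row.patient_id
        labels: LabelSet | None = None
        if row.role != "baseline":
            labels = assign_labels(ErrorVector(row.lr_mm, row.si_mm, row.ap_mm))
        records.append(
            CohortRecord(
                map=fm,
                serial=int(row.serial),
                role=row.role,
                labels=labels,
                noise_seed=int(row.noise_seed),
                patient_id=row.patient_id,
            )
        )
    return records
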