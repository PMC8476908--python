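"""Cohort-level orchestration: maps -> comparison maps -> features/stacks.

One feature-matrix row per (patient, error position).  Feature columns
are namespaced ``<source map>_<family>_<Feature>`` so the three ML input
configurations are column subsets of one matrix: ML1 = DD-map features
(94 columns), ML2 = luminance+contrast+structure features (282), ML3 =
all four source maps (376).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import SsimConfig, dd_map, ssim_components
from .labeling import LabelSet
from .radiomics_features import (
    DiscretizationConfig,
    ML_CONFIG_SOURCES,
    center_crop,
    extract_features,
)
from .synthetic_data import CohortRecord, SimulationConfig, iter_patients

#: pipeline default discretization: SSIM component maps live in [-1, 1],
#: so a fixed bin count is the scale-free choice that suits every source map
PIPELINE_DISCRETIZATION = DiscretizationConfig(method="count", bin_count=32)


@dataclass
class CohortFeatures:
    """Feature matrix plus optional CNN input stacks for one cohort."""

    matrix: pd.DataFrame
    cnn_stacks: np.ndarray | None = None  # (n_rows, 4, size, size)


def _meta_row(patient_id: str, serial: int, labels: LabelSet, err) -> dict:
    return {
        "patient_id": patient_id,
        "serial": serial,
        "lr_mm": err.lr_mm,
        "si_mm": err.si_mm,
        "ap_mm": err.ap_mm,
        "isocenter_mm": labels.isocenter_mm,
        "type1": labels.type1,
        "type2_lr": labels.type2_lr,
        "type2_si": labels.type2_si,
        "type2_ap": labels.type2_ap,
        "type3": labels.type3,
    }


def patient_feature_rows(
    records: list[CohortRecord],
    sources: tuple[str, ...],
    ssim_cfg: SsimConfig | None = None,
    disc_cfg: DiscretizationConfig | None = None,
    crop_side: int = 512,
    cnn_size: int | None = None,
) -> tuple[list[dict], list[np.ndarray]]:
    """Feature rows (and optional CNN stacks) for one patient's records."""
    from .cnn import normalize_stack

    ssim_cfg = ssim_cfg or SsimConfig()
    disc_cfg = disc_cfg or PIPELINE_DISCRETIZATION
    baselines = [r for r in records if r.role == "baseline"]
    if len(baselines) != 1:
        raise ValueError(
            f"patient {records[0].patient_id!r}: need exactly one baseline, "
            f"got {len(baselines)}"
        )
    baseline = baselines[0]
    need_ssim = cnn_size is not None or any(s != "dd" for s in sources)

    rows: list[dict] = []
    stacks: list[np.ndarray] = []
    for rec in records:
        if rec.role == "baseline":
            continue
        if rec.labels is None:
            raise ValueError(f"record serial {rec.serial} lacks labels")
        if need_ssim:
            maps = ssim_components(baseline.map, rec.map, ssim_cfg)
            by_name = maps.as_dict()
        else:
            by_name = {"dd": dd_map(baseline.map, rec.map)}
        row = _meta_row(rec.patient_id, rec.serial, rec.labels, rec.map.error)
        for source in sources:
            crop = center_crop(by_name[source], crop_side)
            for name, value in extract_features(crop, disc_cfg).items():
                row[f"{source}_{name}"] = value
        rows.append(row)
        if cnn_size is not None:
            cropped = type(maps)(
                **{k: center_crop(v, crop_side) for k, v in by_name.items()}
            )
            stacks.append(normalize_stack(cropped, size=cnn_size))
    return rows, stacks


def build_feature_matrix(
    cohort: list[CohortRecord],
    ml_config: str = "ml3",
    ssim_cfg: SsimConfig | None = None,
    disc_cfg: DiscretizationConfig | None = None,
    crop_side: int = 512,
) -> pd.DataFrame:
    """Feature matrix over an in-memory cohort (one row per error record)."""
    sources = ML_CONFIG_SOURCES[ml_config.lower()]
    by_patient: dict[str, list[CohortRecord]] = {}
    for rec in cohort:
        by_patient.setdefault(rec.patient_id, []).append(rec)
    rows: list[dict] = []
    for _pid, records in sorted(by_patient.items()):
        r, _ = patient_feature_rows(
            records, sources, ssim_cfg, disc_cfg, crop_side
        )
        rows.extend(r)
    return pd.DataFrame(rows)


def simulate_cohort_features(
    config: SimulationConfig,
    ml_config: str = "ml3",
    ssim_cfg: SsimConfig | None = None,
    disc_cfg: DiscretizationConfig | None = None,
    crop_side: int = 512,
    cnn_size: int | None = None,
) -> CohortFeatures:
    """Simulate a cohort and extract features patient by patient.

    Streams one patient at a time so full-cohort pixel data never needs
    to be resident; the per-patient projector stacks are released as each
    patient completes.
    """
    sources = ML_CONFIG_SOURCES[ml_config.lower()]
    rows: list[dict] = []
    stacks: list[np.ndarray] = []
    for _pid, records in iter_patients(config):
        r, s = patient_feature_rows(
            records, sources, ssim_cfg, disc_cfg, crop_side, cnn_size
        )
        rows.extend(r)
        stacks.extend(s)
    matrix = pd.DataFrame(rows)
    return CohortFeatures(
        matrix=matrix,
        cnn_stacks=np.stack(stacks) if stacks else None,
    )
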