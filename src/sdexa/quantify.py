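"""Per-vertebra BMD quantification and osteoporosis status assignment.

Volumetric BMD is the mean hydroxyapatite density over a vertebra's
trabecular voxels (mg/mL); areal BMD is the mean of an aBMD map over the
vertebra's registered 2D mask pixels (g/cm^2).  Status follows the QCT
thresholds: vBMD < 80 mg/mL osteoporotic, < 120 mg/mL osteopenic,
otherwise normal, with strict "<" so boundary values take the higher
class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "OSTEOPOROSIS_THRESHOLD",
    "OSTEOPENIA_THRESHOLD",
    "classify_status",
    "vertebra_vbmd",
    "vertebra_abmd",
    "build_cohort_table",
    "COHORT_SCHEMA",
]

OSTEOPOROSIS_THRESHOLD = 80.0  # mg/mL
OSTEOPENIA_THRESHOLD = 120.0  # mg/mL

#: column schema of the cohort table CSV
COHORT_SCHEMA = {
    "patient_id": "str",
    "vertebra": "str (L1..L4 or 'mean' for the per-patient aggregate)",
    "vbmd": "mg/mL",
    "abmd_measured_ap": "g/cm^2 (optional)",
    "abmd_projected_ap": "g/cm^2",
    "abmd_projected_lateral": "g/cm^2",
    "mask_pixel_count": "pixels",
    "qc_flags": "semicolon-separated flags",
    "status": "normal | osteopenic | osteoporotic",
}


class QuantifyError(ValueError):
    """Raised on empty masks or missing labels."""


def classify_status(vbmd: float) -> str:
    """Osteoporosis status from trabecular vBMD (mg/mL)."""
    if not np.isfinite(vbmd):
        raise QuantifyError(f"vBMD must be finite, got {vbmd}")
    if vbmd < OSTEOPOROSIS_THRESHOLD:
        return "osteoporotic"
    if vbmd < OSTEOPENIA_THRESHOLD:
        return "osteopenic"
    return "normal"


def vertebra_vbmd(material_volumes, labels3d: np.ndarray, label_value: int) -> float:
    """Mean hydroxyapatite density (mg/mL) over one trabecular label."""
    sel = labels3d == label_value
    if not sel.any():
        raise QuantifyError(f"3D label {label_value} is empty")
    return float(material_volumes.hydroxyapatite_density[sel].mean())


def vertebra_abmd(abmd_map, mask2d: np.ndarray, label_value: int) -> tuple[float, int, list]:
    """Mean aBMD (g/cm^2) over one vertebra's 2D mask.

    Returns ``(mean, pixel count, qc flags)``; a QC flag is raised when
    more than 20% of the mask pixels carry negative aBMD (noise floor).
    """
    sel = mask2d == label_value
    n = int(sel.sum())
    if n == 0:
        raise QuantifyError(f"2D mask label {label_value} is empty")
    vals = abmd_map.abmd[sel]
    flags = []
    if (vals < 0).mean() > 0.20:
        flags.append("negative_abmd_fraction_gt_20pct")
    return float(vals.mean()), n, flags


def build_cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-vertebra measurement rows into the cohort table.

    Adds one aggregate row per patient (vertebra='mean', value = mean over
    the available L1-L4 measurements) and assigns status from vBMD.
    """
    df = pd.DataFrame(rows)
    required = {"patient_id", "vertebra", "vbmd"}
    missing = required - set(df.columns)
    if missing:
        raise QuantifyError(f"cohort rows missing columns: {sorted(missing)}")
    value_cols = [
        c
        for c in (
            "vbmd",
            "abmd_measured_ap",
            "abmd_projected_ap",
            "abmd_projected_lateral",
        )
        if c in df.columns
    ]
    aggregates = []
    for pid, grp in df.groupby("patient_id", sort=False):
        agg = {"patient_id": pid, "vertebra": "mean"}
        for c in value_cols:
            agg[c] = grp[c].mean()
        agg["mask_pixel_count"] = int(grp.get("mask_pixel_count", pd.Series([0])).sum())
        agg["qc_flags"] = ";".join(sorted({f for fl in grp.get("qc_flags", []) for f in str(fl).split(";") if f}))
        aggregates.append(agg)
    out = pd.concat([df, pd.DataFrame(aggregates)], ignore_index=True)
    out["status"] = out["vbmd"].map(classify_status)
    return out
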