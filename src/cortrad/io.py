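"""File I/O: NIfTI volumes, FSL-style scheme files, and CSV tables.

Volumes are written as NIfTI-1 with RAS+ affines.  The tensor volume is a 4D
image with 6 volumes in the fixed component order (Dxx, Dxy, Dxz, Dyy, Dyz,
Dzz); the radial field is a 4D image with 3 volumes (x, y, z components).
CSV outputs use UTF-8, comma delimiter, dot decimal, and print floats at 6
significant digits.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .geometry import ProfileSet
from .metrics import ROIMetrics
from .stats import AnovaResult, CorrelationResult, battery_frame
from .volumes import RadialField, ScalarVolume, TensorVolume, TissueLabelVolume

FLOAT_FMT = "%.6g"


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def save_tensor(t: TensorVolume, path: str | Path) -> None:
    save_nifti(t.components, t.affine, path)


def load_tensor(path: str | Path, mask: np.ndarray | None = None) -> TensorVolume:
    data, affine = load_nifti(path)
    if mask is None:
        mask = np.abs(data).sum(axis=-1) > 0
    return TensorVolume(components=data, affine=affine, mask=mask)


def save_scalar(s: ScalarVolume, path: str | Path) -> None:
    save_nifti(s.data, s.affine, path)


def save_labels(labels: TissueLabelVolume, path: str | Path) -> None:
    save_nifti(labels.labels.astype(np.int16), labels.affine, path)


def load_labels(path: str | Path, voxel_size: float | None = None) -> TissueLabelVolume:
    data, affine = load_nifti(path)
    if voxel_size is None:
        voxel_size = float(np.abs(affine[0, 0]))
    return TissueLabelVolume(np.asarray(data).astype(np.int16), affine, voxel_size)


def save_radial_field(f: RadialField, path: str | Path) -> None:
    save_nifti(f.vectors, f.affine, path)


def profiles_to_csv(profiles: ProfileSet, path: str | Path) -> None:
    rows = []
    for pid, prof in enumerate(profiles):
        for k, (pt, pot) in enumerate(zip(prof.points, prof.potentials)):
            rows.append(
                {
                    "profile_id": pid,
                    "sample_index": k,
                    "x": pt[0],
                    "y": pt[1],
                    "z": pt[2],
                    "potential": pot,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def roi_metrics_to_csv(metrics: list[ROIMetrics], path: str | Path) -> None:
    pd.DataFrame([m.to_row() for m in metrics]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def correlations_to_csv(results: list[CorrelationResult], path: str | Path) -> None:
    battery_frame(results).to_csv(path, index=False, float_format=FLOAT_FMT)


def anova_to_csv(results: list[AnovaResult], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"effect": a.effect, "F": a.F, "df1": a.df1, "df2": a.df2, "p": a.p}
            for a in results
        ]
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def cohort_to_csv(table: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("subject", "group", "region", "measure", "value") if c in table]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, index=False, float_format=FLOAT_FMT)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    req = {"subject", "region", "measure", "value"}
    if not req.issubset(df.columns):
        raise ValueError(f"cohort CSV must contain columns {sorted(req)}")
    return df
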