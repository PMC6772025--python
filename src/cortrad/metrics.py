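"""Per-voxel radiality metrics and their profile/ROI aggregation.

Per voxel the principal diffusion component D_PDD = lambda1 * e1 is compared
with the local radial direction r (CRadial):

* ``AngleR``  theta_R = arccos(|e1 . r|), in [0, pi/2] radians — 0 means
  perfectly radial diffusion;
* ``ParlPD``  D1_par  = lambda1 * cos(theta_R) — projection of D_PDD onto r;
* ``PerpPD``  D1_perp = lambda1 * sin(theta_R) — projection onto the plane
  perpendicular to r.

Both projections are non-negative and satisfy ParlPD^2 + PerpPD^2 = lambda1^2.
All three are antipodally invariant: flipping the sign of e1 and/or r leaves
them bit-identical, so the arbitrary eigenvector sign convention upstream
cannot affect results.

Metrics are averaged arithmetically along each cortical profile (nearest-voxel
sampling by default), and profile means are averaged over the ROI, excluding
profiles seeded in the first and last slice of the ROI's slice range.
Diffusivities are reported in units of 1e-3 mm^2/s at the ROI interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import CorticalProfile, ProfileSet
from .tensor import QC_CLAMPED, QC_NON_SPD
from .volumes import EigenVolume, RadialField, ScalarVolume

logger = logging.getLogger(__name__)

DIFFUSIVITY_SCALE = 1e3  # mm^2/s -> 1e-3 mm^2/s at reporting interfaces


def _check_unit(v: np.ndarray, name: str) -> None:
    norms = np.linalg.norm(v, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError(f"{name} vectors must be unit-norm (tolerance 1e-6)")


def voxel_angleR(e1: np.ndarray, radial: np.ndarray) -> np.ndarray:
    """Angle of radiality arccos(|e1 . radial|) in [0, pi/2].

    Accepts single vectors or (..., 3) stacks; invariant to sign flips of
    either argument.
    """
    e1 = np.asarray(e1, dtype=float)
    radial = np.asarray(radial, dtype=float)
    _check_unit(e1, "e1")
    _check_unit(radial, "radial")
    dot = np.abs(np.sum(e1 * radial, axis=-1))
    return np.arccos(np.clip(dot, 0.0, 1.0))


def voxel_projections(
    lam1: np.ndarray | float, e1: np.ndarray, radial: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(ParlPD, PerpPD) = (lam1 cos theta_R, lam1 sin theta_R).

    ``lam1`` must be non-negative; negative principal eigenvalues are the
    caller's responsibility to flag and exclude.
    """
    lam1 = np.asarray(lam1, dtype=float)
    if np.any(lam1 < 0):
        raise ValueError("negative lambda1: voxel must be flagged and excluded")
    theta = voxel_angleR(e1, radial)
    return lam1 * np.cos(theta), lam1 * np.sin(theta)


def compute_voxel_metrics(
    eigen: EigenVolume,
    field: RadialField,
    fa: ScalarVolume,
    md: ScalarVolume,
    qc_flags: np.ndarray | None = None,
) -> dict[str, ScalarVolume]:
    """Maps of AngleR / ParlPD / PerpPD / FA / MD on a shared validity mask.

    The shared mask excludes voxels that are PDD-degenerate, radial-flagged,
    QC-flagged (clamped signal or non-SPD fit), or carry a negative lambda1.
    Angle in radians; diffusivities in mm^2/s (scaled only at reporting).
    """
    valid = eigen.mask & field.usable & ~eigen.degenerate
    if qc_flags is not None:
        valid &= (qc_flags & (QC_CLAMPED | QC_NON_SPD)) == 0
    lam1 = eigen.lambda1
    valid &= lam1 >= 0

    angle = np.zeros(valid.shape)
    parl = np.zeros(valid.shape)
    perp = np.zeros(valid.shape)
    e1 = eigen.principal_direction[valid]
    r = field.vectors[valid]
    angle[valid] = voxel_angleR(e1, r)
    parl[valid], perp[valid] = voxel_projections(lam1[valid], e1, r)

    aff = eigen.affine
    return {
        "AngleR": ScalarVolume(angle, aff, valid),
        "ParlPD": ScalarVolume(parl, aff, valid),
        "PerpPD": ScalarVolume(perp, aff, valid),
        "FA": ScalarVolume(np.where(valid, fa.data, 0.0), aff, valid),
        "MD": ScalarVolume(np.where(valid, md.data, 0.0), aff, valid),
    }


def profile_mean(
    metric: ScalarVolume,
    profile: CorticalProfile,
    interpolation: str = "nearest",
) -> float:
    """Arithmetic mean of the metric sampled at each profile point.

    ``nearest`` (default) samples each point's containing voxel; ``trilinear``
    interpolates, weighting by the valid mask.  Samples falling on flagged
    (invalid) voxels are skipped; returns NaN when every sample is flagged
    (the profile is then excluded from ROI averages).
    """
    pts = profile.points
    if len(pts) < 2:
        raise ValueError("profile must have at least 2 samples")
    if interpolation == "nearest":
        idx = np.clip(
            np.round(pts).astype(int), 0, np.asarray(metric.data.shape) - 1
        )
        ijk = tuple(idx.T)
        ok = metric.mask[ijk]
        if not ok.any():
            return float("nan")
        return float(metric.data[ijk][ok].mean())
    elif interpolation == "trilinear":
        from scipy import ndimage

        vals = ndimage.map_coordinates(metric.data, pts.T, order=1, mode="nearest")
        wts = ndimage.map_coordinates(
            metric.mask.astype(float), pts.T, order=1, mode="nearest"
        )
        ok = wts > 0.5
        if not ok.any():
            return float("nan")
        return float((vals[ok] / wts[ok]).mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


@dataclass
class ROIDefinition:
    """Cortical region of interest: a mask plus its slice extent.

    ``slice_axis`` is the anatomical stacking axis of the ROI (coronal in the
    real protocol); ``slice_range`` is the inclusive (first, last) slice index
    pair.  Profiles seeded in the terminal slices are excluded from ROI
    averages.  When ``slice_range`` is None it is derived from the mask.
    """

    mask: np.ndarray
    region: str
    slice_axis: int = 1
    slice_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.region!r} has an empty mask")
        if self.slice_range is None:
            occupied = np.nonzero(self.mask.any(axis=tuple(
                ax for ax in range(3) if ax != self.slice_axis
            )))[0]
            self.slice_range = (int(occupied[0]), int(occupied[-1]))


@dataclass
class ROIMetrics:
    """Per-subject, per-region means over included profiles.

    ``angleR`` in radians; ``perpPD``/``parlPD``/``md`` in 1e-3 mm^2/s;
    ``fa`` dimensionless.
    """

    subject: str
    region: str
    angleR: float
    perpPD: float
    parlPD: float
    fa: float
    md: float
    n_profiles: int
    n_voxels: int

    def to_row(self) -> dict:
        return {
            "subject": self.subject,
            "region": self.region,
            "angleR_rad": self.angleR,
            "perpPD": self.perpPD,
            "parlPD": self.parlPD,
            "FA": self.fa,
            "MD": self.md,
            "n_profiles": self.n_profiles,
            "n_voxels": self.n_voxels,
        }


def roi_summarize(
    metric_maps: dict[str, ScalarVolume],
    profiles: ProfileSet,
    roi: ROIDefinition,
    subject: str = "subject",
    interpolation: str = "nearest",
) -> ROIMetrics:
    """Average profile means over an ROI, excluding terminal slices.

    Profiles are included when their seed voxel lies inside the ROI mask and
    its slice index along ``roi.slice_axis`` is strictly inside the ROI's
    slice range (the single first and last slices are excluded).  Profiles
    whose samples are all flagged are dropped and logged.
    """
    lo, hi = roi.slice_range
    included: list[CorticalProfile] = []
    for prof in profiles:
        seed = prof.seed_voxel
        if not roi.mask[seed]:
            continue
        s = seed[roi.slice_axis]
        if s <= lo or s >= hi:
            continue
        included.append(prof)
    if not included:
        raise ValueError(
            f"ROI {roi.region!r}: no profiles remain after terminal-slice exclusion"
        )

    means: dict[str, list[float]] = {name: [] for name in metric_maps}
    n_excluded = 0
    n_used = 0
    for prof in included:
        vals = {
            name: profile_mean(vol, prof, interpolation)
            for name, vol in metric_maps.items()
        }
        if any(np.isnan(v) for v in vals.values()):
            n_excluded += 1
            continue
        for name, v in vals.items():
            means[name].append(v)
        n_used += 1
    if n_used == 0:
        raise ValueError(f"ROI {roi.region!r}: every profile was flagged out")
    if n_excluded:
        logger.info("ROI %s: excluded %d fully-flagged profiles", roi.region, n_excluded)

    valid_any = next(iter(metric_maps.values())).mask
    n_voxels = int((roi.mask & valid_any).sum())
    return ROIMetrics(
        subject=subject,
        region=roi.region,
        angleR=float(np.mean(means["AngleR"])),
        perpPD=float(np.mean(means["PerpPD"])) * DIFFUSIVITY_SCALE,
        parlPD=float(np.mean(means["ParlPD"])) * DIFFUSIVITY_SCALE,
        fa=float(np.mean(means["FA"])),
        md=float(np.mean(means["MD"])) * DIFFUSIVITY_SCALE,
        n_profiles=n_used,
        n_voxels=n_voxels,
    )
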