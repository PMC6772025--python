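"""Synthetic cortical phantoms and cohorts with known ground truth.

The phantom emulates what the real analysis assumes about cortex: a ribbon of
grey matter bounded by white matter on one side and pial CSF on the other, in
which the dominant diffusion axis is radial (minicolumnar) up to an axially
symmetric orientation scatter.  Two geometries are provided: a flat slab
(analytic radial direction = slab normal) and a spherical annulus (radial
direction = outward radius).  Orientation scatter follows a Watson-type axial
distribution with concentration ``kappa`` (kappa = inf: no scatter; kappa = 0:
uniformly random axes).  An optional tangential layer at mid-depth emulates a
myelinated band running parallel to the surface (stria of Gennari), which
deflects the principal axis away from radial.

The cohort generator plants a linear-plus-noise link between each subject's
orientation concentration and scalar histology measures (minicolumn width,
axon-bundle spacing, ...), so that the downstream correlation machinery can be
validated against a known monotone association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .acquisition import AcquisitionScheme
from .volumes import (
    CORTEX,
    OUTSIDE,
    PIAL_CSF,
    WHITE_MATTER,
    TensorVolume,
    TissueLabelVolume,
    default_affine,
)

HISTOLOGY_MEASURES = (
    "minicolumn_width",
    "neuropil_spacing",
    "core_width",
    "microsegment_number",
    "cell_density",
    "bundle_spacing",
    "bundle_width",
)

#: the six measures entering the correlation battery (cell density is
#: tabulated but not part of the 5 x 6 x 3 battery)
BATTERY_HISTOLOGY = (
    "minicolumn_width",
    "neuropil_spacing",
    "core_width",
    "microsegment_number",
    "bundle_spacing",
    "bundle_width",
)

DIFFUSION_METRICS = ("FA", "MD", "AngleR", "PerpPD", "ParlPD")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single synthetic cortical volume.

    eigenvalues are in mm^2/s, descending; ``dispersion_kappa`` is the Watson
    concentration about the radial axis (np.inf = perfectly radial, 0 =
    uniformly random axes); ``snr`` is the b=0 signal-to-noise ratio used by
    :func:`synthesize_dwi` (np.inf = noiseless).
    """

    geometry: str = "flat_slab"
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: float = 1.0
    cortex_thickness: float = 10.0
    eigenvalues: tuple[float, float, float] = (0.8e-3, 0.2e-3, 0.2e-3)
    dispersion_kappa: float = 5.0
    tangential_layer: tuple[float, float] | None = None
    snr: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("flat_slab", "spherical_annulus"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        lam = self.eigenvalues
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("eigenvalues must be strictly positive and non-increasing")
        if self.cortex_thickness < 3 * self.voxel_size:
            raise ValueError(
                "degenerate geometry: cortex_thickness must span at least 3 voxels"
            )
        if self.dispersion_kappa < 0:
            raise ValueError("dispersion_kappa must be non-negative")
        if self.tangential_layer is not None:
            lo, hi = self.tangential_layer
            if not (0.0 < lo < hi < 1.0):
                raise ValueError("tangential_layer must be an interval within (0, 1)")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf for noiseless)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom tensor field."""

    labels: TissueLabelVolume
    radial_truth: np.ndarray  # (X, Y, Z, 3) unit vectors inside cortex
    orientation_field: np.ndarray  # (X, Y, Z, 3) realized principal axes
    expected_angleR: np.ndarray  # (X, Y, Z) radians, NaN outside cortex
    depth_fraction: np.ndarray  # (X, Y, Z) in [0, 1] inside cortex
    seed: int = 0


# ---------------------------------------------------------------------------
# Watson-type axial orientation model
# ---------------------------------------------------------------------------

def sample_watson_cosines(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample |cos(theta)| between axis samples and the mean axis.

    Density on t in [-1, 1] proportional to exp(kappa * t^2), sampled by
    rejection against a uniform envelope; returned as t in [-1, 1].
    """
    if np.isinf(kappa):
        return np.ones(n)
    if kappa == 0:
        return rng.uniform(-1.0, 1.0, size=n)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(1024, 2 * (n - filled))
        t = rng.uniform(-1.0, 1.0, size=m)
        accept = rng.uniform(size=m) <= np.exp(kappa * (t * t - 1.0))
        take = t[accept][: n - filled]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def _orthonormal_complement(axes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit fields orthogonal to ``axes`` (shape (n, 3)), deterministic."""
    helper = np.zeros_like(axes)
    smallest = np.argmin(np.abs(axes), axis=1)
    helper[np.arange(len(axes)), smallest] = 1.0
    e1 = np.cross(axes, helper)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(axes, e1)
    return e1, e2


def sample_watson_axes(
    mean_axes: np.ndarray, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one axis per row of ``mean_axes`` from a Watson distribution."""
    n = len(mean_axes)
    t = sample_watson_cosines(kappa, n, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    e1, e2 = _orthonormal_complement(mean_axes)
    s = np.sqrt(np.maximum(0.0, 1.0 - t * t))
    u = (
        t[:, None] * mean_axes
        + (s * np.cos(phi))[:, None] * e1
        + (s * np.sin(phi))[:, None] * e2
    )
    return u / np.linalg.norm(u, axis=1, keepdims=True)


def expected_angle(kappa: float, mean_axis_angle: float = 0.0) -> float:
    """Expected angle-to-radial arccos|u . r| under the Watson model.

    ``mean_axis_angle`` is the angle (radians) between the distribution's mean
    axis and the radial reference.  Evaluated by spherical product quadrature;
    for kappa = 0 this reduces to the closed form
    ``int_0^1 arccos(c) dc = 1`` rad regardless of the mean axis.
    """
    if np.isinf(kappa):
        return float(np.arccos(abs(np.cos(mean_axis_angle))))
    n_theta, n_phi = 512, 256
    theta = (np.arange(n_theta) + 0.5) * np.pi / n_theta
    phi = (np.arange(n_phi) + 0.5) * 2.0 * np.pi / n_phi
    ct, st = np.cos(theta)[:, None], np.sin(theta)[:, None]
    ca, sa = np.cos(mean_axis_angle), np.sin(mean_axis_angle)
    # u . r with the mean axis tilted by mean_axis_angle from the reference
    dot = ct * ca + st * np.cos(phi)[None, :] * sa
    w = np.broadcast_to(np.exp(kappa * ct * ct) * st, dot.shape)  # density x area
    return float(np.sum(np.arccos(np.abs(dot)) * w) / np.sum(w))


# ---------------------------------------------------------------------------
# Geometry construction
# ---------------------------------------------------------------------------

def _slab_geometry(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    t_vox = int(round(spec.cortex_thickness / spec.voxel_size))
    if t_vox < 3 or t_vox > nz - 2:
        raise ValueError("degenerate geometry: slab cortex does not fit the grid")
    z0 = (nz - t_vox) // 2
    labels = np.full(spec.grid_shape, WHITE_MATTER, dtype=np.int16)
    labels[:, :, z0 : z0 + t_vox] = CORTEX
    labels[:, :, z0 + t_vox :] = PIAL_CSF
    zz = np.broadcast_to(np.arange(nz)[None, None, :], spec.grid_shape)
    depth = np.full(spec.grid_shape, np.nan)
    cortex = labels == CORTEX
    depth[cortex] = (zz[cortex] - z0 + 0.5) / t_vox
    radial = np.zeros(spec.grid_shape + (3,))
    radial[cortex] = (0.0, 0.0, 1.0)
    return labels, radial, depth


def _annulus_geometry(spec: PhantomSpec):
    shape = spec.grid_shape
    center = (np.asarray(shape) - 1) / 2.0
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    rel = (coords - center) * spec.voxel_size
    r = np.linalg.norm(rel, axis=-1)
    b = (min(shape) / 2.0 - 2.0) * spec.voxel_size
    a = b - spec.cortex_thickness
    if a < 3 * spec.voxel_size:
        raise ValueError("degenerate geometry: annulus inner radius too small")
    labels = np.full(shape, OUTSIDE, dtype=np.int16)
    labels[r < a] = WHITE_MATTER
    labels[(r >= a) & (r < b)] = CORTEX
    labels[(r >= b) & (r < b + 2.0 * spec.voxel_size)] = PIAL_CSF
    cortex = labels == CORTEX
    depth = np.full(shape, np.nan)
    depth[cortex] = (r[cortex] - a) / (b - a)
    radial = np.zeros(shape + (3,))
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = rel / np.maximum(r[..., None], 1e-12)
    radial[cortex] = unit[cortex]
    return labels, radial, depth, (a, b, center)


def _tangential_axes(radial: np.ndarray) -> np.ndarray:
    """A deterministic unit field perpendicular to the radial direction."""
    e1, _ = _orthonormal_complement(radial)
    return e1


def make_phantom(spec: PhantomSpec) -> tuple[PhantomTruth, TensorVolume]:
    """Build the label volume, ground-truth orientations, and tensor field.

    Cortical voxels carry tensors whose principal axis is drawn from the
    Watson model about the local radial direction (or about a tangential axis
    inside ``tangential_layer``); eigenvalues are as specified.  Voxels
    outside the cortex are masked out of the tensor field.  Deterministic
    given ``spec.seed``.
    """
    if spec.geometry == "flat_slab":
        labels_arr, radial, depth = _slab_geometry(spec)
    else:
        labels_arr, radial, depth, _ = _annulus_geometry(spec)

    affine = default_affine(spec.voxel_size)
    labels = TissueLabelVolume(labels_arr, affine, voxel_size=spec.voxel_size)
    cortex = labels.cortex_mask
    n = int(cortex.sum())

    mean_axes = radial[cortex].copy()
    tang_mask_flat = np.zeros(n, dtype=bool)
    if spec.tangential_layer is not None:
        lo, hi = spec.tangential_layer
        d = depth[cortex]
        tang_mask_flat = (d >= lo) & (d < hi)
        tang = _tangential_axes(radial[cortex])
        mean_axes[tang_mask_flat] = tang[tang_mask_flat]

    rng = np.random.default_rng(spec.seed)
    axes = sample_watson_axes(mean_axes, spec.dispersion_kappa, rng)

    lam1, lam2, lam3 = spec.eigenvalues
    e1, _ = _orthonormal_complement(axes)
    # D = lam3 I + (lam1 - lam3) u u^T + (lam2 - lam3) v v^T, v ⟂ u
    mats = lam3 * np.eye(3)[None] + (lam1 - lam3) * (
        axes[:, :, None] * axes[:, None, :]
    )
    if lam2 != lam3:
        mats = mats + (lam2 - lam3) * (e1[:, :, None] * e1[:, None, :])

    components = np.zeros(spec.grid_shape + (6,))
    comp_flat = np.stack(
        [mats[:, 0, 0], mats[:, 0, 1], mats[:, 0, 2], mats[:, 1, 1], mats[:, 1, 2], mats[:, 2, 2]],
        axis=1,
    )
    components[cortex] = comp_flat

    orientation = np.zeros(spec.grid_shape + (3,))
    orientation[cortex] = axes

    exp_angle = np.full(spec.grid_shape, np.nan)
    vals = np.full(n, expected_angle(spec.dispersion_kappa, 0.0))
    if tang_mask_flat.any():
        vals[tang_mask_flat] = expected_angle(spec.dispersion_kappa, np.pi / 2)
    exp_angle[cortex] = vals

    truth = PhantomTruth(
        labels=labels,
        radial_truth=radial,
        orientation_field=orientation,
        expected_angleR=exp_angle,
        depth_fraction=depth,
        seed=spec.seed,
    )
    tensors = TensorVolume(components=components, affine=affine, mask=cortex)
    return truth, tensors


# ---------------------------------------------------------------------------
# DWI synthesis
# ---------------------------------------------------------------------------

def synthesize_dwi(
    tensors: TensorVolume,
    scheme: AcquisitionScheme,
    s0: float = 1000.0,
    snr: float = math.inf,
    seed: int | None = None,
) -> np.ndarray:
    """Forward-simulate the single-tensor DWI signal, optionally with Rician noise.

    Noiseless signal per volume: ``S = s0 * exp(-b g^T D g)``.  When ``snr``
    is finite, magnitude (Rician) noise is applied: the complex Gaussian
    channels each have sd ``s0 / snr``.  Voxels outside the tensor mask return
    zero signal.  Reproducible given ``seed``.
    """
    if not s0 > 0:
        raise ValueError("s0 must be positive")
    mask = tensors.mask
    mats = tensors.as_matrices()[mask]  # (n, 3, 3)
    lam = np.linalg.eigvalsh(mats)
    if lam.min() <= 0:
        raise ValueError("tensors must be positive-definite inside the mask")
    g = scheme.bvecs  # (m, 3)
    b = scheme.bvals  # (m,)
    # g^T D g for every voxel/direction pair
    quad = np.einsum("mi,nij,mj->nm", g, mats, g)
    signal_flat = s0 * np.exp(-quad * b[None, :])
    out = np.zeros(tensors.shape + (len(scheme),))
    out[mask] = signal_flat
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = s0 / snr
        n1 = rng.normal(0.0, sigma, size=signal_flat.shape)
        n2 = rng.normal(0.0, sigma, size=signal_flat.shape)
        out[mask] = np.sqrt((signal_flat + n1) ** 2 + n2**2)
    return out


# ---------------------------------------------------------------------------
# Synthetic cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HistologyLink:
    """Linear-plus-noise link from subject concentration kappa to a measure."""

    intercept: float
    slope: float
    noise_sd: float

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def _default_histology_model() -> dict[str, HistologyLink]:
    # Signs mirror the observed associations: wider minicolumns / bundles go
    # with larger AngleR, i.e. with *lower* concentration kappa.
    return {
        "minicolumn_width": HistologyLink(40.0, -1.2, 2.0),
        "neuropil_spacing": HistologyLink(17.5, -0.35, 1.2),
        "core_width": HistologyLink(31.0, -0.6, 2.5),
        "microsegment_number": HistologyLink(170.0, 9.0, 45.0),
        "cell_density": HistologyLink(110.0, 2.5, 40.0),
        "bundle_spacing": HistologyLink(52.0, -1.6, 3.0),
        "bundle_width": HistologyLink(10.5, -0.35, 0.9),
    }


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Specification of a two-group synthetic cohort.

    ``dispersion_model`` maps group label -> (mean, sd) of the per-subject
    Watson concentration kappa (truncated below at ``kappa_floor``);
    ``histology_model`` maps measure name -> :class:`HistologyLink`.  Age is
    drawn per group from ``age_model``; disease duration only for the first
    (case) group, linearly linked to age so that the two covariates correlate.
    """

    n_subjects_per_group: tuple[int, int] = (9, 6)
    groups: tuple[str, str] = ("MS", "HC")
    regions: tuple[str, ...] = ("BA9", "BA41", "V1")
    dispersion_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"MS": (2.0, 0.8), "HC": (6.0, 1.2)}
    )
    histology_model: dict[str, HistologyLink] = field(
        default_factory=_default_histology_model
    )
    age_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"MS": (70.0, 11.0), "HC": (71.0, 13.0)}
    )
    duration_model: tuple[float, float, float] = (33.0, 1.1, 6.5)  # base, age slope, sd
    base_phantom: PhantomSpec = field(default_factory=PhantomSpec)
    kappa_floor: float = 0.1
    #: per-subject biological variability of the tensor eigenvalues:
    #: lognormal sd of the overall diffusivity scale and Gaussian sd of the
    #: anisotropy factor multiplying (lambda1 - lambda3)
    diffusivity_scale_sd: float = 0.10
    anisotropy_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        for g in self.groups:
            if g not in self.dispersion_model or g not in self.age_model:
                raise ValueError(f"missing model entries for group {g!r}")


def noise_sd_for_planted_spearman(
    target_spearman: float, slope: float, kappa_sd: float
) -> float:
    """Noise sd giving a population Spearman of ``target_spearman``.

    For jointly Gaussian (kappa, measure) the Spearman and Pearson
    correlations relate by rho_s = (6/pi) asin(rho/2); invert and solve the
    linear-model variance decomposition for the noise sd.
    """
    if not 0 < abs(target_spearman) < 1:
        raise ValueError("target Spearman must be in (0, 1) in magnitude")
    rho = 2.0 * math.sin(math.pi * abs(target_spearman) / 6.0)
    return abs(slope) * kappa_sd * math.sqrt(1.0 / rho**2 - 1.0)


def make_cohort(spec: SyntheticCohortSpec) -> tuple[list[PhantomSpec], pd.DataFrame]:
    """Draw a cohort of per-subject phantom specs plus a tidy histology table.

    Returns phantom specifications (one per subject, kappa drawn from the
    group model) and a long-format table with one row per
    (subject, region, measure): histology measures per region plus the
    ``age`` / ``disease_duration`` covariates repeated per row.  Deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    seeds = np.random.SeedSequence(spec.seed).generate_state(
        sum(spec.n_subjects_per_group)
    ) % (2**31)

    specs: list[PhantomSpec] = []
    rows: list[dict] = []
    idx = 0
    for group, n_sub in zip(spec.groups, spec.n_subjects_per_group):
        k_mean, k_sd = spec.dispersion_model[group]
        a_mean, a_sd = spec.age_model[group]
        for _ in range(n_sub):
            subject = f"{group}{idx + 1:02d}"
            kappa = max(spec.kappa_floor, rng.normal(k_mean, k_sd))
            age = rng.normal(a_mean, a_sd)
            if group == spec.groups[0]:
                base, slope, sd = spec.duration_model
                duration = max(1.0, base + slope * (age - a_mean) + rng.normal(0, sd))
            else:
                duration = np.nan
            l1, l2, l3 = spec.base_phantom.eigenvalues
            scale = float(np.exp(rng.normal(0.0, spec.diffusivity_scale_sd)))
            aniso = max(0.05, rng.normal(1.0, spec.anisotropy_jitter_sd))
            lam3 = scale * l3
            lam2 = scale * l2
            lam1 = max(lam2 * 1.001, scale * (l3 + aniso * (l1 - l3)))
            specs.append(
                replace(
                    spec.base_phantom,
                    dispersion_kappa=kappa,
                    eigenvalues=(lam1, lam2, lam3),
                    seed=int(seeds[idx]),
                )
            )
            for region in spec.regions:
                for measure, link in spec.histology_model.items():
                    value = link.intercept + link.slope * kappa
                    if link.noise_sd > 0:
                        value += rng.normal(0.0, link.noise_sd)
                    rows.append(
                        {
                            "subject": subject,
                            "group": group,
                            "age": age,
                            "disease_duration": duration,
                            "region": region,
                            "measure": measure,
                            "value": value,
                            "dispersion_kappa": kappa,
                        }
                    )
            idx += 1
    return specs, pd.DataFrame(rows)
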