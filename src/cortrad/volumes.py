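"""Core volumetric containers shared across the pipeline.

All volumes carry a 4x4 voxel-to-world affine (RAS+ by convention) and, where
meaningful, a boolean analysis mask.  Diffusivities are stored in mm^2/s
internally; reporting interfaces rescale to the conventional 1e-3 mm^2/s.

Tensor components are stored in the fixed order
``(Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)`` — this order is part of the on-disk
contract and must not change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Tissue label encoding used throughout.
OUTSIDE = 0
WHITE_MATTER = 1
CORTEX = 2
PIAL_CSF = 3

LABEL_NAMES = {
    OUTSIDE: "outside",
    WHITE_MATTER: "white_matter",
    CORTEX: "cortex",
    PIAL_CSF: "pial_csf",
}

#: index pairs mapping the 6-component storage order into a 3x3 symmetric matrix
TENSOR_COMPONENT_ORDER = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")
_TRI = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))


def default_affine(voxel_size: float) -> np.ndarray:
    """Diagonal RAS+ affine for an isotropic grid with the origin at voxel 0."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size)
    return aff


def tensors_to_matrices(components: np.ndarray) -> np.ndarray:
    """(..., 6) component array -> (..., 3, 3) symmetric matrices."""
    out = np.zeros(components.shape[:-1] + (3, 3), dtype=components.dtype)
    for k, (i, j) in enumerate(_TRI):
        out[..., i, j] = components[..., k]
        out[..., j, i] = components[..., k]
    return out


def matrices_to_tensors(matrices: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) component array."""
    out = np.empty(matrices.shape[:-2] + (6,), dtype=matrices.dtype)
    for k, (i, j) in enumerate(_TRI):
        out[..., k] = matrices[..., i, j]
    return out


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor field.

    ``components`` has shape (X, Y, Z, 6) in the documented storage order,
    units mm^2/s.  ``mask`` selects the voxels where the field is defined.
    """

    components: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    qc_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.ndim != 4 or self.components.shape[-1] != 6:
            raise ValueError("tensor components must have shape (X, Y, Z, 6)")
        if self.mask.shape != self.components.shape[:3]:
            raise ValueError("mask shape does not match tensor grid")
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValueError("non-finite tensor components inside mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.components.shape[:3]

    def as_matrices(self) -> np.ndarray:
        return tensors_to_matrices(self.components)


@dataclass
class EigenVolume:
    """Sorted eigensystem of a tensor field.

    ``eigenvalues`` (X, Y, Z, 3) descending; ``eigenvectors`` (X, Y, Z, 3, 3)
    with ``eigenvectors[..., :, k]`` the unit eigenvector for eigenvalue k.
    The principal diffusion direction (PDD) is ``eigenvectors[..., :, 0]``,
    defined only up to sign.  ``degenerate`` flags voxels where the PDD is
    ill-defined (near-equal leading eigenvalues).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = np.zeros(self.mask.shape, dtype=bool)

    @property
    def principal_direction(self) -> np.ndarray:
        """Unit PDD per voxel, shape (X, Y, Z, 3)."""
        return self.eigenvectors[..., :, 0]

    @property
    def lambda1(self) -> np.ndarray:
        return self.eigenvalues[..., 0]


@dataclass
class ScalarVolume:
    """One scalar per voxel with affine and mask (FA, MD, potential, ...)."""

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")


@dataclass
class TissueLabelVolume:
    """Integer tissue labels: outside / white_matter / cortex / pial_csf."""

    labels: np.ndarray
    affine: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-coded")
        bad = set(np.unique(self.labels)) - set(LABEL_NAMES)
        if bad:
            raise ValueError(f"unknown tissue labels: {sorted(bad)}")

    @property
    def cortex_mask(self) -> np.ndarray:
        return self.labels == CORTEX


@dataclass
class RadialField:
    """Unit radial-direction (CRadial) vectors on cortical voxels.

    Oriented from the white-matter boundary toward the pial surface.
    ``flagged`` marks cortical voxels where the direction could not be
    estimated (vanishing potential gradient); those voxels carry zeros.
    """

    vectors: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    flagged: np.ndarray

    def __post_init__(self) -> None:
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("radial field must have shape (X, Y, Z, 3)")
        usable = self.mask & ~self.flagged
        norms = np.linalg.norm(self.vectors[usable], axis=-1)
        if usable.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("radial vectors must be unit-norm on usable voxels")

    @property
    def usable(self) -> np.ndarray:
        return self.mask & ~self.flagged
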