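"""Diffusion tensor estimation and scalar maps.

The fit is ordinary log-linear least squares: per voxel, solve

    ln S_m = ln S0 - b_m g_m^T D g_m

for the 7 unknowns (ln S0 and the 6 independent tensor components) over all
acquired volumes.  On noiseless single-tensor data this recovers the input
tensor exactly (the model class is exact), which is the property the phantom
tests rely on.  Non-positive signals are floored at ``clamp_eps * S0`` before
the log and the voxel is flagged in the QC mask; fitted tensors that are not
positive-definite are retained but flagged rather than silently repaired.

QC flag bits: 1 = signal clamped before log; 2 = fitted tensor non-SPD;
4 = PDD degenerate (lambda1 ~= lambda2).
"""

from __future__ import annotations

import numpy as np

from .acquisition import AcquisitionScheme
from .volumes import EigenVolume, ScalarVolume, TensorVolume

QC_CLAMPED = 1
QC_NON_SPD = 2
QC_PDD_DEGENERATE = 4


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """(m, 7) design: columns [1, -b gx^2, -2b gxgy, -2b gxgz, -b gy^2, -2b gygz, -b gz^2].

    Unknown vector is (ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) in the package's
    tensor storage order.
    """
    g = scheme.bvecs
    b = scheme.bvals
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -b * gy * gy,
            -2 * b * gy * gz,
            -b * gz * gz,
        ]
    )


def fit_tensor_loglinear(
    dwi: np.ndarray,
    scheme: AcquisitionScheme,
    mask: np.ndarray,
    affine: np.ndarray | None = None,
    clamp_eps: float = 1e-6,
) -> TensorVolume:
    """Fit the diffusion tensor per voxel by log-linear least squares.

    ``dwi`` is (X, Y, Z, m) with m matching the scheme.  Signals that are not
    positive are floored at ``clamp_eps`` times the voxel's mean b=0 signal
    before taking the log; affected voxels get the ``QC_CLAMPED`` flag and are
    meant to be excluded from downstream ROI averages.
    """
    dwi = np.asarray(dwi, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dwi.ndim != 4 or dwi.shape[-1] != len(scheme):
        raise ValueError("dwi volume count does not match the acquisition scheme")
    if dwi.shape[-1] < 7:
        raise ValueError("need at least 7 volumes (1 b=0 + 6 directions) to fit")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "singular design matrix: gradient scheme has collinear/insufficient directions"
        )
    if affine is None:
        affine = np.eye(4)

    signals = dwi[mask]  # (n, m)
    s0 = signals[:, scheme.b0_mask].mean(axis=1)
    s0 = np.where(s0 > 0, s0, 1.0)
    floor = clamp_eps * s0[:, None]
    clamped = signals <= 0
    signals = np.where(clamped, floor, signals)

    pinv = np.linalg.pinv(X)
    beta = (pinv @ np.log(signals).T).T  # (n, 7)

    components = np.zeros(mask.shape + (6,))
    components[mask] = beta[:, 1:]

    qc = np.zeros(mask.shape, dtype=np.int16)
    qc_flat = np.where(clamped.any(axis=1), QC_CLAMPED, 0).astype(np.int16)
    lam = np.linalg.eigvalsh(
        TensorVolume(components, affine, mask).as_matrices()[mask]
    )
    qc_flat |= np.where(lam[:, 0] <= 0, QC_NON_SPD, 0).astype(np.int16)
    qc[mask] = qc_flat
    return TensorVolume(components=components, affine=affine, mask=mask, qc_flags=qc)


def eigendecompose(t: TensorVolume, degeneracy_rtol: float = 1e-6) -> EigenVolume:
    """Sorted eigensystem per voxel with a deterministic sign convention.

    Eigenvalues descend; each eigenvector's first nonzero component is made
    non-negative (the PDD is only defined up to sign, and every downstream
    quantity is antipodally invariant).  Voxels whose two leading eigenvalues
    agree within ``degeneracy_rtol`` (relative) are flagged PDD-degenerate.
    """
    mats = t.as_matrices()[t.mask]
    if not np.all(np.isfinite(mats)):
        bad = np.argwhere(t.mask)[~np.isfinite(mats).all(axis=(1, 2))]
        voxel = tuple(int(v) for v in bad[0])
        raise ValueError(f"non-finite tensor inside mask at voxel {voxel}")
    w, v = np.linalg.eigh(mats)  # ascending
    w = w[:, ::-1]
    v = v[:, :, ::-1]
    # sign convention: first component of each eigenvector with |.| > tol non-negative
    for k in range(3):
        vec = v[:, :, k]
        first = np.where(
            np.abs(vec[:, 0]) > 1e-12,
            vec[:, 0],
            np.where(np.abs(vec[:, 1]) > 1e-12, vec[:, 1], vec[:, 2]),
        )
        v[:, :, k] = vec * np.where(first < 0, -1.0, 1.0)[:, None]

    eigenvalues = np.zeros(t.mask.shape + (3,))
    eigenvectors = np.zeros(t.mask.shape + (3, 3))
    eigenvalues[t.mask] = w
    eigenvectors[t.mask] = v

    scale = np.maximum(np.abs(w[:, 0]), 1e-300)
    degen_flat = (w[:, 0] - w[:, 1]) <= degeneracy_rtol * scale
    degenerate = np.zeros(t.mask.shape, dtype=bool)
    degenerate[t.mask] = degen_flat
    return EigenVolume(
        eigenvalues=eigenvalues,
        eigenvectors=eigenvectors,
        affine=t.affine,
        mask=t.mask,
        degenerate=degenerate,
    )


def md_map(e: EigenVolume) -> ScalarVolume:
    """Mean diffusivity (lambda1 + lambda2 + lambda3) / 3, in mm^2/s."""
    md = e.eigenvalues.mean(axis=-1)
    md[~e.mask] = 0.0
    return ScalarVolume(data=md, affine=e.affine, mask=e.mask)


def fa_map(e: EigenVolume) -> ScalarVolume:
    """Fractional anisotropy sqrt(3/2) ||lambda - mean|| / ||lambda||.

    The all-zero tensor is assigned FA = 0 rather than NaN.
    """
    lam = e.eigenvalues
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa[den == 0] = 0.0
    fa[~e.mask] = 0.0
    return ScalarVolume(data=fa, affine=e.affine, mask=e.mask)
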