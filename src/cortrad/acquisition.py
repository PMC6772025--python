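"""Diffusion acquisition schemes (b-values and gradient directions).

The default scheme mirrors a high-b postmortem protocol: 54 approximately
isotropically distributed directions at b = 4500 s/mm^2 plus six b = 0
volumes.  Text I/O follows the FSL dialect: a one-row ``bval`` file and a
three-row ``bvec`` file (x, y, z gradient components in columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class AcquisitionScheme:
    """b-values (s/mm^2) and unit gradient directions, one row per volume."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if len(bvals) != len(bvecs):
            raise ValueError("bvals and bvecs must have the same length")
        dw = bvals > 0
        if dw.any():
            norms = np.linalg.norm(bvecs[dw], axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("b>0 gradient directions must be unit-norm")
        if not (bvals == 0).any():
            raise ValueError("scheme requires at least one b=0 volume")
        if _n_noncollinear(bvecs[dw]) < 6:
            raise ValueError("scheme requires >=6 unique non-collinear b>0 directions")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0


def _n_noncollinear(vecs: np.ndarray) -> int:
    """Count directions that are pairwise non-collinear (sign-invariant)."""
    kept: list[np.ndarray] = []
    for v in vecs:
        if all(abs(abs(v @ u) - 1.0) > 1e-6 for u in kept):
            kept.append(v)
        elif not kept:
            kept.append(v)
    return len(kept)


def fibonacci_directions(n: int) -> np.ndarray:
    """n near-uniform unit directions on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + 5.0**0.5) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_scheme(n_directions: int = 54, b: float = 4500.0, n_b0: int = 6) -> AcquisitionScheme:
    """Isotropic single-shell scheme: ``n_b0`` b=0 volumes first, then the shell."""
    dirs = fibonacci_directions(n_directions)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_scheme(scheme: AcquisitionScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write FSL-style text files (bvals one row; bvecs three rows x/y/z)."""
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.10g")


def read_scheme(bval_path: str | Path, bvec_path: str | Path) -> AcquisitionScheme:
    """Read FSL-style bval/bvec text files."""
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3) and len(bvals) == 3:
        # ambiguous 3x3; FSL convention stores components in rows
        bvecs = bvecs.T
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)
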