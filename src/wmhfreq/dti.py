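"""Diffusion tensor fitting and fractional anisotropy.

The mono-exponential diffusion model for volume i with b-value b_i and unit
gradient direction g_i is

    S_i = S0 * exp(-b_i * g_i^T D g_i)

with D the symmetric 3x3 diffusion tensor (mm^2/s). Taking logs makes the six
unique tensor elements plus log(S0) linear in the design matrix, so the tensor
is estimated per voxel by ordinary least squares on the log-signal. FA is the
normalized standard deviation of the tensor eigenvalues,

    FA = sqrt(3/2) * sqrt(sum_i (l_i - lbar)^2) / sqrt(sum_i l_i^2),

a scalar in [0, 1]: 0 for isotropic diffusion, approaching 1 for a single
dominant direction. Negative eigenvalues (a noise artifact of the linear fit)
are clamped to zero before FA so the bound holds; FA is NaN outside the brain
mask so masked means cannot be diluted by background zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DwiDataset",
    "TensorField",
    "design_matrix",
    "fit_tensor_lls",
    "eigenvalues",
    "fa_from_eigenvalues",
    "fa_map",
    "tensor_matrices",
]

#: floor applied to signals (relative to the per-voxel b0 estimate) before log
SIGNAL_FLOOR_EPS = 1e-6


class RankDeficientDesignError(ValueError):
    """Raised when the gradient scheme cannot determine all 6 tensor elements."""


@dataclass
class DwiDataset:
    """A 4D diffusion-weighted acquisition on a single grid.

    signal : (x, y, z, n_volumes) non-negative array
    bvals  : (n_volumes,) b-values in s/mm^2
    bvecs  : (n_volumes, 3) unit directions; zero vector exactly for b=0
    brain_mask : (x, y, z) boolean
    voxel_size_mm : 3-tuple
    """

    signal: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    brain_mask: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        n = self.signal.shape[-1]
        if len(self.bvals) != n or self.bvecs.shape != (n, 3):
            raise ValueError(
                f"{n} volumes but {len(self.bvals)} b-values / bvecs {self.bvecs.shape}"
            )
        if self.signal.shape[:3] != self.brain_mask.shape:
            raise ValueError("signal grid and brain mask grid differ")
        if not np.any(self.bvals == 0):
            raise ValueError("dataset has no b=0 volume")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-b0 gradient directions must have unit norm")
        if np.any(np.linalg.norm(self.bvecs[~dw], axis=1) > 1e-12):
            raise ValueError("b=0 volumes must carry the zero direction")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[-1]


@dataclass
class TensorField:
    """Voxelwise tensor estimates: d holds (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""

    d: np.ndarray          # (x, y, z, 6), NaN outside mask
    log_s0: np.ndarray     # (x, y, z), NaN outside mask
    mask: np.ndarray       # boolean
    n_clamped_signals: int = 0
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Log-linear DTI design, one row per volume.

    Row i is (-b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz, 1)
    so that row @ (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, log S0) = log S_i.
    """
    bvals = np.asarray(bvals, dtype=float).ravel()
    g = np.asarray(bvecs, dtype=float)
    b = bvals[:, None]
    X = np.column_stack(
        [
            -b[:, 0] * g[:, 0] ** 2,
            -b[:, 0] * g[:, 1] ** 2,
            -b[:, 0] * g[:, 2] ** 2,
            -2 * b[:, 0] * g[:, 0] * g[:, 1],
            -2 * b[:, 0] * g[:, 0] * g[:, 2],
            -2 * b[:, 0] * g[:, 1] * g[:, 2],
            np.ones(len(bvals)),
        ]
    )
    return X


def fit_tensor_lls(dwi: DwiDataset) -> TensorField:
    """Ordinary least-squares tensor fit on log-signals, inside the brain mask.

    Signals are floored at ``SIGNAL_FLOOR_EPS`` times the per-voxel mean b0
    signal before the log, guarding against near-zero magnitudes from Rician
    noise. Raises :class:`RankDeficientDesignError` for collinear directions.
    """
    X = design_matrix(dwi.bvals, dwi.bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise RankDeficientDesignError(
            "gradient scheme is rank deficient: need >= 6 non-collinear "
            "directions plus a b=0 volume to determine the 6 tensor elements"
        )
    mask = dwi.brain_mask
    sig = dwi.signal[mask]                       # (n_vox, n_volumes)
    b0 = sig[:, dwi.bvals == 0].mean(axis=1)
    b0 = np.where(b0 > 0, b0, 1.0)
    floor = SIGNAL_FLOOR_EPS * b0[:, None]
    n_clamped = int(np.sum(sig < floor))
    logs = np.log(np.maximum(sig, floor))

    # one shared design => a single pseudo-inverse applied to all voxels
    coef = np.linalg.pinv(X) @ logs.T            # (7, n_vox)

    shape = mask.shape
    d = np.full(shape + (6,), np.nan)
    log_s0 = np.full(shape, np.nan)
    d[mask] = coef[:6].T
    log_s0[mask] = coef[6]
    return TensorField(d=d, log_s0=log_s0, mask=mask,
                       n_clamped_signals=n_clamped, voxel_size_mm=dwi.voxel_size_mm)


def tensor_matrices(d6: np.ndarray) -> np.ndarray:
    """Expand (..., 6) unique elements into (..., 3, 3) symmetric matrices."""
    d6 = np.asarray(d6, dtype=float)
    out = np.empty(d6.shape[:-1] + (3, 3))
    dxx, dyy, dzz, dxy, dxz, dyz = (d6[..., i] for i in range(6))
    out[..., 0, 0] = dxx
    out[..., 1, 1] = dyy
    out[..., 2, 2] = dzz
    out[..., 0, 1] = out[..., 1, 0] = dxy
    out[..., 0, 2] = out[..., 2, 0] = dxz
    out[..., 1, 2] = out[..., 2, 1] = dyz
    return out


def eigenvalues(d6: np.ndarray) -> np.ndarray:
    """Sorted (descending) eigenvalues of symmetric tensors given as (..., 6)."""
    mats = tensor_matrices(d6)
    evals = np.linalg.eigvalsh(mats)             # ascending
    return evals[..., ::-1]


def fa_from_eigenvalues(l1, l2, l3) -> np.ndarray:
    """FA from three eigenvalues; 0 by convention when all are (near) zero.

    Negative inputs are clamped to zero, keeping FA within [0, 1].
    """
    lam = np.stack(np.broadcast_arrays(
        np.asarray(l1, float), np.asarray(l2, float), np.asarray(l3, float)), axis=-1)
    lam = np.maximum(lam, 0.0)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(np.sum((lam - mean) ** 2, axis=-1))
    den = np.sqrt(np.sum(lam ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(tensors: TensorField, brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Voxelwise FA of a fitted tensor field; NaN outside the brain mask."""
    mask = tensors.mask if brain_mask is None else np.asarray(brain_mask, bool)
    d6 = tensors.d[mask]
    evals = eigenvalues(d6)
    fa_vals = fa_from_eigenvalues(evals[..., 0], evals[..., 1], evals[..., 2])
    out = np.full(mask.shape, np.nan)
    out[mask] = fa_vals
    return out
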