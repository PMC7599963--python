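"""Diffusion-tensor fitting and the four DTI scalar maps.

The tensor is fit per voxel by linear least squares on the
log-attenuation, with one reweighting pass (weights = squared predicted
signal) by default -- the common WLS scheme.  Scalars follow the
standard eigenvalue definitions: MD = (l1+l2+l3)/3, AD = l1,
RD = (l2+l3)/2 and FA the normalized eigenvalue dispersion.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import DWIStack, ScalarMap, ValidationError, VolumeGrid

logger = logging.getLogger("dwimicro")

#: eigenvalue floor in mm^2/s; prevents the tensor-route EAP scalars,
#: which invert eigenvalues, from producing infinities on noisy fits
EPS_LAMBDA = 1e-6

#: signal-ratio clipping window applied before the log transform;
#: the Rician noise floor can push a measured signal above S0
RATIO_CLIP = (1e-6, 1.0)


@dataclass(frozen=True)
class TensorField:
    """Per-voxel symmetric diffusion tensor (mm^2/s) with S0 and mask."""

    grid: VolumeGrid
    tensors: np.ndarray  # (x, y, z, 3, 3)
    s0: np.ndarray       # (x, y, z)
    mask: np.ndarray     # (x, y, z) bool

    def __post_init__(self):
        t = np.asarray(self.tensors, dtype=float)
        if t.shape != self.grid.shape + (3, 3):
            raise ValidationError("tensor array shape does not match grid")
        asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
        if asym > 1e-10:
            raise ValidationError(f"tensors are not symmetric (max asymmetry {asym:g})")
        object.__setattr__(self, "tensors", t)
        object.__setattr__(self, "mask", np.asarray(self.mask, bool))


@dataclass(frozen=True)
class EigenSystem:
    """Sorted per-voxel eigendecomposition: l1 >= l2 >= l3.

    ``evecs[..., :, k]`` is the unit eigenvector of ``evals[..., k]``;
    ``n_clamped`` counts eigenvalues raised to the floor.
    """

    grid: VolumeGrid
    evals: np.ndarray   # (x, y, z, 3), descending
    evecs: np.ndarray   # (x, y, z, 3, 3), columns are eigenvectors
    mask: np.ndarray
    n_clamped: int = 0

    @property
    def e1(self) -> np.ndarray:
        """Principal diffusion direction, shape (x, y, z, 3)."""
        return self.evecs[..., :, 0]


def design_matrix(scheme) -> np.ndarray:
    """Log-signal design: columns [1, -b gx^2, -b gy^2, -b gz^2,
    -2b gx gy, -2b gx gz, -2b gy gz]."""
    b = scheme.bvals
    g = scheme.bvecs
    X = np.empty((len(scheme), 7))
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2 * b * g[:, 1] * g[:, 2]
    return X


def _coeffs_to_tensors(coef: np.ndarray) -> np.ndarray:
    """Map (V, 7) design coefficients to (V, 3, 3) symmetric tensors."""
    D = np.empty(coef.shape[:-1] + (3, 3))
    D[..., 0, 0] = coef[..., 1]
    D[..., 1, 1] = coef[..., 2]
    D[..., 2, 2] = coef[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = coef[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = coef[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = coef[..., 6]
    return D


def fit_tensor(dwi: DWIStack, mask: np.ndarray | None = None,
               method: str = "wls") -> TensorField:
    """Fit the diffusion tensor per voxel.

    Parameters
    ----------
    dwi : DWIStack
        At least 7 volumes (>= 6 diffusion directions + 1 baseline).
    mask : bool array, optional
        Voxels to fit; defaults to voxels with positive baseline signal.
        All-zero voxels are dropped from the mask.
    method : {"wls", "ols"}
        Ordinary linear LS on the log-signal, optionally followed by one
        reweighting pass with weights equal to the squared predicted
        signal (default).
    """
    if method not in ("wls", "ols"):
        raise ValueError(f"unknown fit method {method!r}")
    scheme = dwi.scheme
    n_dw = int(np.sum(scheme.dw_mask))
    if len(scheme) < 7 or n_dw < 6 or scheme.n_b0 < 1:
        raise ValidationError(
            "tensor fit needs >= 7 volumes with >= 6 directions and a baseline"
        )
    shape = dwi.grid.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, bool)
        if mask.shape != shape:
            raise ValidationError("mask shape does not match the DWI grid")

    data = dwi.data
    s0_obs = data[..., scheme.b0_mask].mean(axis=-1)
    dead = mask & ~(s0_obs > 0)
    n_dead = int(dead.sum())
    if n_dead:
        logger.warning("excluding %d voxel(s) with zero signal from the mask", n_dead)
        mask = mask & ~dead

    X = design_matrix(scheme)
    sig = data[mask]                           # (V, n)
    ratio = np.clip(sig / s0_obs[mask][:, None], *RATIO_CLIP)
    y = np.log(ratio)

    coef = y @ np.linalg.pinv(X).T             # OLS, (V, 7)
    if method == "wls":
        pred = coef @ X.T
        w = np.exp(2.0 * np.clip(pred, np.log(RATIO_CLIP[0]), 0.0))
        Xw = X[None, :, :] * w[:, :, None]     # (V, n, 7)
        A = np.einsum("vni,nj->vij", Xw, X)
        rhs = np.einsum("vni,vn->vi", Xw, y)
        coef = np.linalg.solve(A, rhs[..., None])[..., 0]

    tensors = np.zeros(shape + (3, 3))
    tensors[mask] = _coeffs_to_tensors(coef)
    s0 = np.zeros(shape)
    s0[mask] = s0_obs[mask] * np.exp(coef[:, 0])
    return TensorField(dwi.grid, tensors, s0, mask)


def eigendecompose(tf: TensorField, floor: float = EPS_LAMBDA) -> EigenSystem:
    """Sorted eigensystem of a fitted tensor field.

    Eigenvalues below ``floor`` are clamped and counted (the count is
    logged); non-finite tensors raise, naming an offending voxel.
    """
    t_mask = tf.tensors[tf.mask]
    bad = ~np.isfinite(t_mask).all(axis=(-1, -2))
    if bad.any():
        vox = np.argwhere(tf.mask)[bad][0]
        raise ValidationError(f"non-finite tensor at voxel {tuple(int(i) for i in vox)}")
    vals, vecs = np.linalg.eigh(t_mask)        # ascending
    vals = vals[:, ::-1]
    vecs = vecs[:, :, ::-1]
    n_clamped = int(np.sum(vals < floor))
    if n_clamped:
        logger.info("clamped %d eigenvalue(s) below %g", n_clamped, floor)
        vals = np.maximum(vals, floor)
    shape = tf.grid.shape
    evals = np.zeros(shape + (3,))
    evecs = np.zeros(shape + (3, 3))
    evals[tf.mask] = vals
    evecs[tf.mask] = vecs
    return EigenSystem(tf.grid, evals, evecs, tf.mask, n_clamped)


def dti_scalars(eigen: EigenSystem) -> dict:
    """FA, MD, AD, RD maps from a sorted eigensystem.

    FA = sqrt(3/2) * ||l - MD|| / ||l||, defined as 0 where all
    eigenvalues vanish.
    """
    lam = eigen.evals
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = 0.5 * (lam[..., 1] + lam[..., 2])
    norm = np.sqrt(np.sum(lam ** 2, axis=-1))
    dev = np.sqrt(np.sum((lam - md[..., None]) ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(norm > 0, dev / np.where(norm > 0, norm, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    g = eigen.grid
    m = eigen.mask
    return {
        "FA": ScalarMap(g, "FA", np.where(m, fa, 0.0)),
        "MD": ScalarMap(g, "MD", np.where(m, md, 0.0)),
        "AD": ScalarMap(g, "AD", np.where(m, ad, 0.0)),
        "RD": ScalarMap(g, "RD", np.where(m, rd, 0.0)),
    }
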