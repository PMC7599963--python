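"""Shared construction helpers for the test suite."""
from __future__ import annotations

import numpy as np

from dwimicro import DWIStack, VolumeGrid
from dwimicro.dti import TensorField


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n Haar-ish random rotation matrices via QR of Gaussian matrices."""
    a = rng.normal(size=(n, 3, 3))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diagonal(r, axis1=1, axis2=2))[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1.0
    return q


def random_spd_tensors(n: int, rng: np.random.Generator,
                       lam_range=(0.2e-3, 2.2e-3)):
    """Random positive-definite tensors: sorted eigenvalues + rotations.

    Returns (tensors (n,3,3), evals (n,3) descending, evecs (n,3,3)).
    """
    lam = np.sort(rng.uniform(*lam_range, size=(n, 3)), axis=1)[:, ::-1]
    q = random_rotations(n, rng)
    tensors = np.einsum("nik,nk,njk->nij", q, lam, q)
    return tensors, lam, q


def voxel_list_grid(n: int) -> VolumeGrid:
    """Degenerate (n, 1, 1) grid used to treat a tensor list as a volume."""
    return VolumeGrid.isotropic((n, 1, 1), 2.0)


def tensor_field(tensors: np.ndarray, s0: float = 100.0) -> TensorField:
    """Wrap a (n, 3, 3) tensor list as a TensorField on a voxel-list grid."""
    n = tensors.shape[0]
    grid = voxel_list_grid(n)
    return TensorField(
        grid,
        tensors.reshape(n, 1, 1, 3, 3),
        np.full(grid.shape, s0),
        np.ones(grid.shape, bool),
    )


def noise_free_signal(tensors: np.ndarray, scheme, s0: float = 100.0) -> np.ndarray:
    """Closed-form Gaussian DWI signal for a (n, 3, 3) tensor list."""
    quad = np.einsum("vij,ni,nj->vn", tensors, scheme.bvecs, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def dwi_from_tensors(tensors: np.ndarray, scheme, s0: float = 100.0,
                     sigma: float = 0.0, rng=None) -> DWIStack:
    """Voxel-list DWIStack from tensors, optionally with Rician noise."""
    sig = noise_free_signal(tensors, scheme, s0)
    if sigma > 0:
        rng = rng or np.random.default_rng(0)
        sig = np.hypot(sig + rng.normal(0, sigma, sig.shape),
                       rng.normal(0, sigma, sig.shape))
    n = tensors.shape[0]
    return DWIStack(voxel_list_grid(n), sig.reshape(n, 1, 1, -1), scheme)
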