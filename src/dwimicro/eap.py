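"""Return-to-origin/axis/plane probabilities from single-shell data.

Two routes are implemented.

*Gaussian closed forms* invert the tensor eigenvalues directly:
RTOP = (4 pi tau)^(-3/2) (l1 l2 l3)^(-1/2),
RTPP = (4 pi tau l1)^(-1/2),
RTAP = (4 pi tau)^(-1) (l2 l3)^(-1/2).
Because RTOP and RTAP invert the smallest eigenvalues, this route is
very sensitive to noise and outliers in anisotropic tissue.

*Apparent (AMURA-style) scalars* avoid the tensor: the shell signal
defines a directional ADC, D(u) = -ln(E(u))/b, expanded in even real
spherical harmonics, and the signal is extended radially as a
mono-exponential, E(q u) = exp(-4 pi^2 tau q^2 D(u)).  Under that
extension the q-space integrals reduce to angular averages of powers of
D(u): a spherical mean of D^(-3/2) (RTOP), the value at the principal
direction (RTPP), and an equatorial mean of D^(-1) (RTAP).  For a
noise-free Gaussian signal D(u) is the exact quadratic form u'Du, so
both routes agree; they diverge -- by design -- on real data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import sph_harm_y

from .data_io import DWIStack, ScalarMap, ValidationError, VolumeGrid
from .dti import EPS_LAMBDA, EigenSystem, RATIO_CLIP

logger = logging.getLogger("dwimicro")


@dataclass(frozen=True)
class EAPConfig:
    """Knobs of the apparent-EAP computation.

    tau : effective diffusion time in s.  The acquisition does not fix
        it; all cross-route comparisons pass the same tau through both
        sides, so its value only rescales the maps.
    sh_order : even spherical-harmonic order of the D(u) expansion;
        (L+1)(L+2)/2 coefficients must not exceed the direction count.
    equator_samples : points on the great circle for the RTAP integral.
    n_polar : Gauss-Legendre polar nodes of the spherical quadrature
        (azimuth gets 2*n_polar uniform nodes).
    """

    tau: float = 0.025
    sh_order: int = 6
    equator_samples: int = 48
    n_polar: int = 24

    def __post_init__(self):
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.sh_order < 0 or self.sh_order % 2:
            raise ValidationError("sh_order must be even and >= 0")
        if self.equator_samples < 16:
            raise ValidationError("equator_samples must be >= 16")

    @property
    def n_coeffs(self) -> int:
        return (self.sh_order + 1) * (self.sh_order + 2) // 2


def sh_degrees(order: int) -> list:
    """(l, m) pairs of the even real SH basis up to ``order``."""
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def real_sh_basis(order: int, dirs: np.ndarray) -> np.ndarray:
    """Real even spherical-harmonic basis sampled at unit directions.

    Returns shape (n_dirs, n_coeffs).  Convention: for m < 0 the basis
    function is sqrt(2) (-1)^m Im(Y_l^|m|), for m > 0 it is
    sqrt(2) (-1)^m Re(Y_l^m), and Y_l^0 for m = 0 (antipodally
    symmetric by the restriction to even l).
    """
    dirs = np.asarray(dirs, dtype=float)
    flat = dirs.reshape(-1, 3)
    theta = np.arccos(np.clip(flat[:, 2], -1.0, 1.0))
    phi = np.arctan2(flat[:, 1], flat[:, 0])
    cols = []
    for l, m in sh_degrees(order):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
        elif m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        else:
            cols.append(y.real)
    return np.stack(cols, axis=-1).reshape(dirs.shape[:-1] + (len(cols),))


def sphere_quadrature(n_polar: int = 24) -> tuple:
    """Deterministic product quadrature on the unit sphere.

    Gauss-Legendre nodes in cos(theta) crossed with a uniform azimuth
    grid; returns (dirs (N, 3), weights (N,)) with weights summing to 1,
    so ``f @ weights`` is the spherical mean of ``f``.
    """
    x, w = leggauss(n_polar)              # cos(theta) nodes
    n_phi = 2 * n_polar
    phi = 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    ct, ph = np.meshgrid(x, phi, indexing="ij")
    st = np.sqrt(1.0 - ct ** 2)
    dirs = np.stack(
        [st * np.cos(ph), st * np.sin(ph), np.broadcast_to(ct, ph.shape)], axis=-1
    ).reshape(-1, 3)
    weights = np.repeat(w / 2.0 / n_phi, n_phi)
    return dirs, weights


@dataclass(frozen=True)
class ADCProfile:
    """Directional ADC D(u) on the shell as even real SH coefficients."""

    grid: VolumeGrid
    bval: float
    sh_order: int
    coeffs: np.ndarray          # (x, y, z, n_coeffs)
    mask: np.ndarray
    n_clipped: int = 0
    n_floored: int = field(default=0)

    def evaluate(self, dirs: np.ndarray) -> np.ndarray:
        """Evaluate D(u) at fixed directions for all masked voxels.

        ``dirs`` has shape (n, 3); returns (n_masked_voxels, n).
        """
        basis = real_sh_basis(self.sh_order, np.asarray(dirs))
        return self.coeffs[self.mask] @ basis.T


def directional_adc(dwi: DWIStack, s0: np.ndarray | None = None,
                    config: EAPConfig | None = None,
                    mask: np.ndarray | None = None) -> ADCProfile:
    """Fit the even-SH expansion of D(u) = -ln(S(u)/S0)/b on the shell.

    Signal ratios are clipped to [1e-6, 1] before the log and the
    resulting D(u) samples floored at the eigenvalue floor; both events
    are counted on the returned profile.
    """
    config = config or EAPConfig()
    scheme = dwi.scheme
    if not scheme.is_single_shell:
        raise ValidationError("single-shell scheme required for the apparent route")
    n_dirs = int(np.sum(scheme.dw_mask))
    if config.n_coeffs > n_dirs:
        raise ValidationError(
            f"sh_order {config.sh_order} needs {config.n_coeffs} coefficients "
            f"but only {n_dirs} directions are available"
        )
    b = scheme.shell_bval
    shape = dwi.grid.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if s0 is None:
        s0 = dwi.data[..., scheme.b0_mask].mean(axis=-1)
    if np.any(s0[mask] <= 0):
        raise ValidationError("S0 must be positive inside the mask")

    sig = dwi.data[mask][:, scheme.dw_mask]
    ratio = sig / s0[mask][:, None]
    n_clipped = int(np.sum((ratio < RATIO_CLIP[0]) | (ratio > RATIO_CLIP[1])))
    if n_clipped:
        logger.info("clipped %d signal ratio(s) to %s", n_clipped, RATIO_CLIP)
    adc = -np.log(np.clip(ratio, *RATIO_CLIP)) / b
    n_floored = int(np.sum(adc < EPS_LAMBDA))
    adc = np.maximum(adc, EPS_LAMBDA)

    basis = real_sh_basis(config.sh_order, scheme.bvecs[scheme.dw_mask])
    coeffs = np.zeros(shape + (config.n_coeffs,))
    coeffs[mask] = adc @ np.linalg.pinv(basis).T
    return ADCProfile(dwi.grid, b, config.sh_order, coeffs, np.asarray(mask, bool),
                      n_clipped, n_floored)


def _check_floor(evals: np.ndarray, floor: float = EPS_LAMBDA) -> None:
    if np.any(evals < floor * (1 - 1e-9)):
        raise ValidationError(
            f"eigenvalues below the {floor:g} floor; run eigendecompose first"
        )


def gaussian_eap_from_eigenvalues(eigen: EigenSystem,
                                  config: EAPConfig | None = None) -> dict:
    """Closed-form RTOP/RTAP/RTPP of a Gaussian propagator."""
    config = config or EAPConfig()
    tau = config.tau
    lam = eigen.evals[eigen.mask]
    _check_floor(lam)
    c = 4 * np.pi * tau
    rtop = c ** -1.5 * (lam[:, 0] * lam[:, 1] * lam[:, 2]) ** -0.5
    rtpp = (c * lam[:, 0]) ** -0.5
    rtap = c ** -1.0 * (lam[:, 1] * lam[:, 2]) ** -0.5
    out = {}
    for name, vec in (("RTOP", rtop), ("RTAP", rtap), ("RTPP", rtpp)):
        vol = np.zeros(eigen.grid.shape)
        vol[eigen.mask] = vec
        out[name] = ScalarMap(eigen.grid, name, vol)
    return out


def _perpendicular_frame(e1: np.ndarray) -> tuple:
    """Two unit vectors spanning the plane perpendicular to each e1."""
    ref = np.zeros_like(e1)
    use_z = np.abs(e1[:, 2]) < 0.9
    ref[use_z, 2] = 1.0
    ref[~use_z, 0] = 1.0
    a = np.cross(e1, ref)
    a /= np.linalg.norm(a, axis=-1, keepdims=True)
    b = np.cross(e1, a)
    return a, b


def apparent_eap_scalars(adc: ADCProfile, e1: np.ndarray,
                         config: EAPConfig | None = None,
                         measures=("RTOP", "RTAP", "RTPP")) -> dict:
    """RTOP/RTAP/RTPP under mono-exponential radial extension.

    Parameters
    ----------
    adc : ADCProfile
        Directional ADC expansion from :func:`directional_adc`.
    e1 : array (x, y, z, 3)
        Per-voxel unit principal direction (normally the tensor fit's
        first eigenvector); only the RTPP line and RTAP equator use it.
    measures : subset of {"RTOP", "RTAP", "RTPP"} to compute.
    """
    config = config or EAPConfig()
    tau = config.tau
    c = 4 * np.pi * tau
    mask = adc.mask
    e1m = np.asarray(e1, float)[mask]
    norms = np.linalg.norm(e1m, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValidationError("missing or non-unit principal direction in the mask")
    coeffs = adc.coeffs[mask]
    n_floored = 0
    results = {}

    if "RTOP" in measures:
        # spherical mean of D(u)^(-3/2)
        qdirs, qw = sphere_quadrature(config.n_polar)
        d_sphere = coeffs @ real_sh_basis(adc.sh_order, qdirs).T
        n_floored += int(np.sum(d_sphere < EPS_LAMBDA))
        d_sphere = np.maximum(d_sphere, EPS_LAMBDA)
        results["RTOP"] = c ** -1.5 * (d_sphere ** -1.5) @ qw

    if "RTPP" in measures:
        # D at the principal direction
        b1 = real_sh_basis(adc.sh_order, e1m)
        d1 = np.sum(b1 * coeffs, axis=-1)
        n_floored += int(np.sum(d1 < EPS_LAMBDA))
        d1 = np.maximum(d1, EPS_LAMBDA)
        results["RTPP"] = (c * d1) ** -0.5

    if "RTAP" in measures:
        # equatorial mean of D(u)^(-1) on the circle perpendicular to e1
        a, bvec = _perpendicular_frame(e1m)
        phi = (2 * np.pi * np.arange(config.equator_samples)
               / config.equator_samples)
        u_eq = (a[:, None, :] * np.cos(phi)[None, :, None]
                + bvec[:, None, :] * np.sin(phi)[None, :, None])
        b_eq = real_sh_basis(adc.sh_order, u_eq)      # (V, E, n_coeffs)
        d_eq = np.einsum("vec,vc->ve", b_eq, coeffs)
        n_floored += int(np.sum(d_eq < EPS_LAMBDA))
        d_eq = np.maximum(d_eq, EPS_LAMBDA)
        results["RTAP"] = c ** -1.0 * np.mean(d_eq ** -1.0, axis=-1)

    if n_floored:
        logger.info("floored %d D(u) quadrature value(s)", n_floored)
    out = {}
    for name in ("RTOP", "RTAP", "RTPP"):
        if name not in results:
            continue
        vol = np.zeros(adc.grid.shape)
        vol[mask] = results[name]
        out[name] = ScalarMap(adc.grid, name, vol)
    return out
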