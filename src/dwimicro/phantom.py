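"""Synthetic tensor-field phantoms and a three-group cohort generator.

The phantoms stand in for co-registered white matter: straight tubes
and curved arcs of anisotropic tensors embedded in an isotropic
background, labelled like an atlas.  A cohort draws per-subject copies
with a seeded group effect (multiplicative eigenvalue change inside
chosen regions), global inter-subject eigenvalue jitter, Rician noise
on the simulated signal, and a demographics table whose marginals
mirror a three-group migraine study (healthy controls, episodic and
chronic migraine).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .data_io import (
    CohortTable, DWIStack, GradientScheme, LabelMap, ValidationError, VolumeGrid,
)
from .dti import TensorField

logger = logging.getLogger("dwimicro")

__all__ = [
    "TubeTract", "ArcTract", "PhantomSpec", "NoiseSpec", "GroupEffectSpec",
    "GroupDemographics", "CohortStudy",
    "uniform_directions", "make_scheme", "phantom_eigensystem",
    "build_tensor_phantom", "simulate_dwi", "sample_demographics",
    "table1_demographics", "default_phantom", "generate_cohort",
]


def uniform_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors (deterministic Fibonacci sphere)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    s = np.sqrt(1.0 - z ** 2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)


def make_scheme(n_dirs: int = 61, bval: float = 1000.0, n_b0: int = 1) -> GradientScheme:
    """Single-shell scheme: ``n_b0`` baselines plus ``n_dirs`` directions."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), uniform_directions(n_dirs)])
    return GradientScheme(bvals, bvecs)


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeTract:
    """Straight cylinder; ``start``/``end`` in mm in the grid frame."""

    name: str
    start: tuple
    end: tuple
    radius_mm: float
    evals: tuple  # (l1, l2, l3) in mm^2/s


@dataclass(frozen=True)
class ArcTract:
    """Circular arc in the plane spanned by ``u``/``v`` around ``center``."""

    name: str
    center: tuple
    arc_radius_mm: float
    radius_mm: float       # tube radius around the centreline
    u: tuple = (1.0, 0.0, 0.0)
    v: tuple = (0.0, 1.0, 0.0)
    angle_range: tuple = (0.0, np.pi / 2)
    evals: tuple = (1.7e-3, 0.3e-3, 0.3e-3)


@dataclass(frozen=True)
class PhantomSpec:
    grid: VolumeGrid
    tracts: Sequence
    background_diffusivity: float = 0.7e-3
    s0: float = 100.0
    blend: str = "error"    # or "first": keep the first tract on overlap

    def __post_init__(self):
        for t in self.tracts:
            l1, l2, l3 = t.evals
            if not (l1 >= l2 >= l3 > 0):
                raise ValidationError(f"tract {t.name!r}: need l1 >= l2 >= l3 > 0")
            if t.radius_mm < 2 * float(np.min(self.grid.voxel_size)):
                raise ValidationError(
                    f"tract {t.name!r}: radius must span >= 2 voxels for a skeleton"
                )
        if self.background_diffusivity <= 0:
            raise ValidationError("background diffusivity must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Rician magnitude noise of width sigma (intensity units)."""

    sigma: float
    seed: int = 0
    model: str = "rician"

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.model != "rician":
            raise ValidationError(f"unknown noise model {self.model!r}")


@dataclass(frozen=True)
class GroupEffectSpec:
    """Multiplicative eigenvalue change in selected regions of one group."""

    group: str
    labels: tuple
    lambda1_factor: float = 1.0
    lambda23_factor: float = 1.0

    def __post_init__(self):
        if self.group not in ("EM", "CM"):
            raise ValidationError("effects target the EM or CM group")
        if self.lambda1_factor <= 0 or self.lambda23_factor <= 0:
            raise ValidationError("eigenvalue factors must be positive")


def _voxel_centers(grid: VolumeGrid) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=float)
    return np.moveaxis(idx, 0, -1) * grid.voxel_size


def _tract_geometry(tract, pts: np.ndarray):
    """(inside mask, unit tangent per point) for one tract."""
    if isinstance(tract, TubeTract):
        p0 = np.asarray(tract.start, float)
        p1 = np.asarray(tract.end, float)
        axis = p1 - p0
        length = np.linalg.norm(axis)
        tangent = axis / length
        rel = pts - p0
        t = np.clip(rel @ tangent, 0.0, length)
        dist = np.linalg.norm(rel - t[..., None] * tangent, axis=-1)
        inside = dist <= tract.radius_mm
        tangents = np.broadcast_to(tangent, pts.shape)
        return inside, tangents
    if isinstance(tract, ArcTract):
        c = np.asarray(tract.center, float)
        u = np.asarray(tract.u, float)
        u = u / np.linalg.norm(u)
        v = np.asarray(tract.v, float)
        v = v - (v @ u) * u
        v /= np.linalg.norm(v)
        rel = pts - c
        x = rel @ u
        y = rel @ v
        w = rel - x[..., None] * u - y[..., None] * v   # out-of-plane part
        phi = np.arctan2(y, x)
        r = np.hypot(x, y)
        in_angle = (phi >= tract.angle_range[0]) & (phi <= tract.angle_range[1])
        dist = np.sqrt((r - tract.arc_radius_mm) ** 2
                       + np.sum(w ** 2, axis=-1))
        inside = in_angle & (dist <= tract.radius_mm)
        tangents = (-np.sin(phi)[..., None] * u + np.cos(phi)[..., None] * v)
        return inside, tangents
    raise TypeError(f"unknown tract type {type(tract).__name__}")


def phantom_eigensystem(spec: PhantomSpec):
    """Per-voxel eigenvalues, eigenvectors and labels of the phantom.

    Returns (evals (x,y,z,3) descending, evecs (x,y,z,3,3) columns,
    labels int array).  Background voxels are isotropic.
    """
    shape = spec.grid.shape
    pts = _voxel_centers(spec.grid)
    d0 = spec.background_diffusivity
    evals = np.full(shape + (3,), d0)
    evecs = np.broadcast_to(np.eye(3), shape + (3, 3)).copy()
    labels = np.zeros(shape, dtype=np.int32)

    for k, tract in enumerate(spec.tracts, start=1):
        inside, tangents = _tract_geometry(tract, pts)
        overlap = inside & (labels > 0)
        if overlap.any():
            if spec.blend == "first":
                logger.warning(
                    "tract %r overlaps %d voxel(s); keeping first tract",
                    tract.name, int(overlap.sum()),
                )
                inside = inside & (labels == 0)
            else:
                raise ValidationError(
                    f"tract {tract.name!r} overlaps an earlier tract on "
                    f"{int(overlap.sum())} voxel(s); set blend='first' to allow"
                )
        e1 = tangents[inside]
        e1 = e1 / np.linalg.norm(e1, axis=-1, keepdims=True)
        ref = np.zeros_like(e1)
        use_z = np.abs(e1[:, 2]) < 0.9
        ref[use_z, 2] = 1.0
        ref[~use_z, 0] = 1.0
        e2 = np.cross(e1, ref)
        e2 /= np.linalg.norm(e2, axis=-1, keepdims=True)
        e3 = np.cross(e1, e2)
        evals[inside] = np.asarray(tract.evals, float)
        evecs[inside] = np.stack([e1, e2, e3], axis=-1)
        labels[inside] = k
    return evals, evecs, labels


def _assemble_tensors(evals: np.ndarray, evecs: np.ndarray) -> np.ndarray:
    return np.einsum("...ik,...k,...jk->...ij", evecs, evals, evecs)


def build_tensor_phantom(spec: PhantomSpec):
    """Deterministic (TensorField, LabelMap) realisation of a spec."""
    evals, evecs, labels = phantom_eigensystem(spec)
    tensors = _assemble_tensors(evals, evecs)
    mask = np.ones(spec.grid.shape, dtype=bool)
    s0 = np.full(spec.grid.shape, spec.s0)
    lookup = {k: t.name for k, t in enumerate(spec.tracts, start=1)}
    return (
        TensorField(spec.grid, tensors, s0, mask),
        LabelMap(spec.grid, labels, lookup),
    )


def simulate_dwi(tensors: TensorField, scheme: GradientScheme,
                 s0: np.ndarray | float | None = None,
                 noise: NoiseSpec | None = None) -> DWIStack:
    """Gaussian forward signal S(g, b) = S0 exp(-b g'Dg), plus Rician noise.

    With ``noise`` given, the output is |S + N(0, sigma^2) + i N(0, sigma^2)|,
    seeded from ``noise.seed``.
    """
    if s0 is None:
        s0 = tensors.s0
    s0 = np.broadcast_to(np.asarray(s0, float), tensors.grid.shape)
    b = scheme.bvals
    g = scheme.bvecs
    quad = np.einsum("...ij,ni,nj->...n", tensors.tensors, g, g)
    signal = s0[..., None] * np.exp(-b * quad)
    if noise is not None and noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        re = signal + rng.normal(0.0, noise.sigma, signal.shape)
        im = rng.normal(0.0, noise.sigma, signal.shape)
        signal = np.hypot(re, im)
    return DWIStack(tensors.grid, signal, scheme)


# --------------------------------------------------------------------------
# demographics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDemographics:
    """Marginal distributions of one group's table fields.

    Continuous fields are truncated normals (mean, sd, bounds);
    binary fields are Bernoulli probabilities.  Patient-only fields may
    be None for HC.
    """

    age: tuple = (36.0, 10.0)
    age_bounds: tuple = (18.0, 60.0)
    male_p: float = 0.2
    duration: tuple | None = None          # years
    duration_bounds: tuple = (0.0, 45.0)
    cm_onset_months: tuple | None = None
    cm_onset_bounds: tuple = (0.0, 240.0)
    headache_freq: tuple | None = None     # days/month
    migraine_freq: tuple | None = None
    freq_bounds: tuple = (0.0, 31.0)
    aura_p: float | None = None
    overuse_p: float | None = None


def table1_demographics() -> dict:
    """Per-group marginals matching the study cohort's summary table."""
    return {
        "HC": GroupDemographics(age=(36.1, 13.2), male_p=11 / 50),
        "EM": GroupDemographics(
            age=(37.1, 8.2), male_p=9 / 54,
            duration=(14.1, 11.1),
            headache_freq=(3.6, 1.9), migraine_freq=(3.6, 1.9),
            aura_p=9 / 54, overuse_p=0.0,
        ),
        "CM": GroupDemographics(
            age=(38.1, 8.7), male_p=6 / 56,
            duration=(19.6, 10.4),
            cm_onset_months=(24.5, 32.9),
            headache_freq=(23.3, 6.3), migraine_freq=(13.9, 6.9),
            aura_p=1 / 56, overuse_p=42 / 56,
        ),
    }


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_demographics(demographics: dict, n_per_group: dict,
                        rng: np.random.Generator) -> CohortTable:
    """Draw a cohort table; fields are sampled independently per group."""
    rows = []
    for group in ("HC", "EM", "CM"):
        n = int(n_per_group[group])
        if n <= 1:
            raise ValidationError(f"group {group} needs n > 1")
        d = demographics[group]
        age = _trunc_normal(rng, *d.age, *d.age_bounds, size=n)
        male = rng.random(n) < d.male_p
        rec: dict = {
            "id": [f"{group}{i + 1:03d}" for i in range(n)],
            "group": group,
            "sex": np.where(male, "male", "female"),
            "age": np.round(age, 1),
            "duration": np.nan, "cm_onset_months": np.nan,
            "headache_freq": np.nan, "migraine_freq": np.nan,
            "aura": pd.NA, "overuse": pd.NA,
        }
        if group != "HC":
            rec["duration"] = np.round(
                _trunc_normal(rng, *d.duration, *d.duration_bounds, size=n), 1)
            rec["headache_freq"] = np.round(
                _trunc_normal(rng, *d.headache_freq, *d.freq_bounds, size=n), 1)
            mig = _trunc_normal(rng, *d.migraine_freq, *d.freq_bounds, size=n)
            # migraine days are a subset of headache days
            rec["migraine_freq"] = np.round(np.minimum(mig, rec["headache_freq"]), 1)
            rec["aura"] = rng.random(n) < d.aura_p
            rec["overuse"] = rng.random(n) < d.overuse_p
        if group == "CM":
            rec["cm_onset_months"] = np.round(
                _trunc_normal(rng, *d.cm_onset_months, *d.cm_onset_bounds, size=n), 1)
        rows.append(pd.DataFrame(rec))
    return CohortTable(pd.concat(rows, ignore_index=True))


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortStudy:
    """A generated cohort: one DWI stack per table row, plus the atlas."""

    subjects: tuple            # of DWIStack, aligned with table rows
    table: CohortTable
    labels: LabelMap
    scheme: GradientScheme
    subject_scales: np.ndarray  # per-subject global eigenvalue factor


def default_phantom(shape=(28, 28, 10), voxel_mm: float = 2.0) -> PhantomSpec:
    """Two parallel tubes in an isotropic background.

    Tract 1 is the conventional target of seeded group effects; tract 2
    stays untouched as a specificity control.
    """
    grid = VolumeGrid.isotropic(shape, voxel_mm)
    ext = np.asarray(shape) * voxel_mm
    y1, y2 = 0.26 * ext[1], 0.74 * ext[1]
    z = 0.5 * ext[2]
    radius = min(2.6 * voxel_mm, 0.22 * ext[1])
    tube = dict(radius_mm=radius, evals=(1.7e-3, 0.4e-3, 0.4e-3))
    return PhantomSpec(
        grid=grid,
        tracts=(
            TubeTract("tract_A", (0.08 * ext[0], y1, z), (0.92 * ext[0], y1, z), **tube),
            TubeTract("tract_B", (0.08 * ext[0], y2, z), (0.92 * ext[0], y2, z), **tube),
        ),
    )


def _apply_effects(evals: np.ndarray, labels: np.ndarray, group: str,
                   effects: Sequence[GroupEffectSpec],
                   label_lookup: dict) -> np.ndarray:
    out = evals.copy()
    for eff in effects:
        if eff.group != group:
            continue
        missing = set(eff.labels) - set(label_lookup)
        if missing:
            raise ValidationError(f"effect labels not in phantom: {sorted(missing)}")
        sel = np.isin(labels, eff.labels)
        out[sel] = out[sel] * np.array(
            [eff.lambda1_factor, eff.lambda23_factor, eff.lambda23_factor]
        )
        if np.any(out[sel][:, 0] < out[sel][:, 1] - 1e-18):
            raise ValidationError(
                f"effect on group {group} breaks the eigenvalue ordering"
            )
    return out


def generate_cohort(phantom: PhantomSpec,
                    effects: Sequence[GroupEffectSpec],
                    demographics: dict | None,
                    n_per_group: dict,
                    scheme: GradientScheme | None = None,
                    noise_sigma: float = 5.0,
                    seed: int = 0,
                    subject_scale_sd: float = 0.02,
                    subject_scale_bounds: tuple = (0.9, 1.1)) -> CohortStudy:
    """Generate a reproducible three-group cohort of noisy DWI stacks.

    Each subject's tensor field is the phantom with its group effect
    applied and all eigenvalues scaled by a per-subject factor drawn
    from a truncated Normal(1, subject_scale_sd^2); Rician noise of
    width ``noise_sigma`` is added to the simulated signal.  Everything
    is a pure function of ``seed``.
    """
    demographics = demographics or table1_demographics()
    scheme = scheme or make_scheme()
    rng = np.random.default_rng(seed)
    table = sample_demographics(demographics, n_per_group, rng)
    base_evals, evecs, labels = phantom_eigensystem(phantom)
    lookup = {k: t.name for k, t in enumerate(phantom.tracts, start=1)}
    label_map = LabelMap(phantom.grid, labels, lookup)
    mask = np.ones(phantom.grid.shape, bool)
    s0 = np.full(phantom.grid.shape, phantom.s0)

    group_evals = {
        g: _apply_effects(base_evals, labels, g, effects, lookup)
        for g in ("HC", "EM", "CM")
    }
    n_total = len(table)
    scales = _trunc_normal(rng, 1.0, subject_scale_sd, *subject_scale_bounds,
                           size=n_total)
    noise_seeds = rng.integers(0, 2 ** 31 - 1, size=n_total)

    subjects = []
    for i, group in enumerate(table.groups):
        evals_i = group_evals[group] * scales[i]
        tensors = TensorField(
            phantom.grid, _assemble_tensors(evals_i, evecs), s0, mask
        )
        noise = NoiseSpec(noise_sigma, seed=int(noise_seeds[i]))
        subjects.append(simulate_dwi(tensors, scheme, s0, noise))
    return CohortStudy(tuple(subjects), table, label_map, scheme, scales)
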