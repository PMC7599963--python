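"""On-disk formats and validated in-memory containers.

Every other module consumes the types defined here; nothing downstream
touches files directly.  Volumes are NIfTI-1 (via nibabel), gradient
tables are FSL-style ``.bval``/``.bvec`` text files, and the cohort
table is a TSV.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("dwimicro")

__all__ = [
    "FormatError",
    "ValidationError",
    "B0_THRESHOLD",
    "GradientScheme",
    "VolumeGrid",
    "DWIStack",
    "ScalarMap",
    "LabelMap",
    "CohortTable",
    "read_gradient_scheme",
    "write_gradient_scheme",
    "read_volume",
    "write_volume",
    "read_cohort_table",
    "write_cohort_table",
    "write_manifest",
]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """Data are well-formed but violate a domain invariant."""


#: b-values below this (s/mm^2) count as baseline; scanner bval files
#: often carry small nonzero values on the b=0 volumes.
B0_THRESHOLD = 50.0

GROUPS = ("HC", "EM", "CM")
SEXES = ("male", "female")

#: units per scalar measure ("" for the dimensionless FA)
SCALAR_UNITS = {
    "FA": "",
    "MD": "mm^2/s",
    "AD": "mm^2/s",
    "RD": "mm^2/s",
    "RTOP": "mm^-3",
    "RTAP": "mm^-2",
    "RTPP": "mm^-1",
}


# --------------------------------------------------------------------------
# gradient scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScheme:
    """b-values and unit gradient directions of a diffusion acquisition.

    ``bvals`` has shape (n,), in s/mm^2; ``bvecs`` has shape (n, 3).
    Directions with b > 0 are renormalized to unit length on
    construction (idempotent); b = 0 entries may be the zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise FormatError(f"bvecs must have shape (n, 3), got {bvecs.shape}")
        if bvals.size != bvecs.shape[0]:
            raise FormatError(
                f"bvals ({bvals.size}) and bvecs ({bvecs.shape[0]}) length mismatch"
            )
        if bvals.size < 2:
            raise ValidationError("a gradient scheme needs at least 2 volumes")
        if np.any(bvals < 0) or not np.all(np.isfinite(bvals)):
            raise ValidationError("b-values must be finite and non-negative")
        dw = bvals >= B0_THRESHOLD
        if not np.any(~dw):
            raise ValidationError("no b=0 (baseline) entry in the scheme")
        norms = np.linalg.norm(bvecs, axis=1)
        if np.any(norms[dw] == 0):
            raise ValidationError("zero-norm gradient direction with b > 0")
        bvecs = bvecs.copy()
        # only touch vectors off unit norm, so normalization is idempotent
        renorm = dw & (np.abs(norms - 1.0) > 1e-12)
        bvecs[renorm] /= norms[renorm, None]
        bvals.flags.writeable = False
        bvecs.flags.writeable = False
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals < B0_THRESHOLD

    @property
    def dw_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def is_single_shell(self) -> bool:
        b = self.bvals[self.dw_mask]
        return b.size > 0 and (b.max() - b.min()) <= 1e-3 * b.max()

    @property
    def shell_bval(self) -> float:
        """The shell b-value of a single-shell scheme."""
        if not self.is_single_shell:
            raise ValidationError("scheme is not single-shell")
        return float(np.mean(self.bvals[self.dw_mask]))


def read_gradient_scheme(bval_path, bvec_path) -> GradientScheme:
    """Read an FSL-style .bval (one row) / .bvec (three rows) pair."""
    bvals = np.atleast_1d(np.loadtxt(bval_path, dtype=float))
    if bvals.ndim != 1:
        raise FormatError(f"{bval_path}: expected a single row of b-values")
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] == 3 and bvecs.shape[0] != 3:
        logger.warning(
            "%s: 3-column (transposed) bvec layout detected; accepting", bvec_path
        )
    elif bvecs.shape == (3, 3):
        # ambiguous square case: FSL convention is rows = x,y,z components
        bvecs = bvecs.T
    else:
        raise FormatError(f"{bvec_path}: cannot interpret shape {bvecs.shape}")
    if bvecs.shape[0] != bvals.size:
        raise FormatError(
            f"bval has {bvals.size} entries but bvec encodes {bvecs.shape[0]} volumes"
        )
    return GradientScheme(bvals, bvecs)


def write_gradient_scheme(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


# --------------------------------------------------------------------------
# volumes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D sampling grid: shape, voxel size (mm), affine."""

    shape: tuple
    voxel_size: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        voxel_size = np.asarray(self.voxel_size, dtype=float).ravel()
        affine = np.asarray(self.affine, dtype=float)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValidationError(f"grid shape must be 3 positive ints, got {shape}")
        if voxel_size.size != 3 or np.any(voxel_size <= 0):
            raise ValidationError("voxel_size must be 3 positive values (mm)")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")
        voxel_size.flags.writeable = False
        affine.flags.writeable = False
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel_size)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape, voxel_mm: float = 2.0) -> "VolumeGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), np.full(3, float(voxel_mm)), aff)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map 0-based voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VolumeGrid)
            and self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=1e-6)
        )

    def __hash__(self):
        return hash(self.shape)


def _check_finite(values: np.ndarray, what: str) -> None:
    bad = int(np.size(values) - np.count_nonzero(np.isfinite(values)))
    if bad:
        raise ValidationError(f"{what} contains {bad} non-finite voxel value(s)")


@dataclass(frozen=True)
class DWIStack:
    """4-D diffusion-weighted volume with its gradient scheme."""

    grid: VolumeGrid
    data: np.ndarray
    scheme: GradientScheme

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise FormatError(f"DWI data must be 4-D, got {data.ndim}-D")
        if data.shape[:3] != self.grid.shape:
            raise ValidationError("DWI spatial shape does not match grid")
        if data.shape[3] != len(self.scheme):
            raise ValidationError(
                f"{data.shape[3]} volumes but scheme lists {len(self.scheme)}"
            )
        _check_finite(data, "DWI stack")
        if np.any(data < 0):
            raise ValidationError("DWI intensities must be non-negative")
        object.__setattr__(self, "data", data)


@dataclass(frozen=True)
class ScalarMap:
    """One named per-voxel measure (FA, MD, AD, RD, RTOP, RTAP, RTPP)."""

    grid: VolumeGrid
    name: str
    values: np.ndarray

    def __post_init__(self):
        if self.name not in SCALAR_UNITS:
            raise ValidationError(
                f"unknown measure {self.name!r}; expected one of {sorted(SCALAR_UNITS)}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise FormatError("ScalarMap values must be 3-D")
        if values.shape != self.grid.shape:
            raise ValidationError("ScalarMap shape does not match grid")
        _check_finite(values, f"{self.name} map")
        if self.name == "FA":
            if values.min() < -1e-8 or values.max() > 1 + 1e-8:
                raise ValidationError("FA values must lie in [0, 1]")
        elif values.min() < -1e-12:
            raise ValidationError(f"{self.name} values must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def units(self) -> str:
        return SCALAR_UNITS[self.name]


@dataclass(frozen=True)
class LabelMap:
    """Integer region labels (0 = background) with a name lookup."""

    grid: VolumeGrid
    labels: np.ndarray
    lookup: Mapping[int, str]

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise FormatError("LabelMap labels must be 3-D")
        if labels.shape != self.grid.shape:
            raise ValidationError("LabelMap shape does not match grid")
        if not np.issubdtype(labels.dtype, np.integer):
            as_int = labels.astype(np.int64)
            if not np.array_equal(as_int, labels):
                raise ValidationError("labels must be integers")
            labels = as_int
        if labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(int(k) for k in self.lookup)
        if missing:
            raise ValidationError(f"labels missing from lookup: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(
            self, "lookup", {int(k): str(v) for k, v in dict(self.lookup).items()}
        )

    def region_names(self) -> list:
        return [self.lookup[k] for k in sorted(self.lookup)]


def read_volume(path, *, scheme: GradientScheme | None = None,
                name: str | None = None,
                lookup: Mapping[int, str] | None = None):
    """Read a NIfTI volume and dispatch on dimensionality.

    4-D data require ``scheme`` and yield a :class:`DWIStack`; 3-D data
    yield a :class:`LabelMap` when ``lookup`` is given, otherwise a
    :class:`ScalarMap` named ``name``.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim not in (3, 4):
        raise FormatError(f"{path}: unsupported dimensionality {data.ndim}")
    zooms = img.header.get_zooms()[:3]
    grid = VolumeGrid(data.shape[:3], np.asarray(zooms, float), np.asarray(img.affine))
    if data.ndim == 4:
        if scheme is None:
            raise FormatError(f"{path}: 4-D volume requires a gradient scheme")
        return DWIStack(grid, data.astype(float), scheme)
    _check_finite(data, str(path))
    if lookup is not None:
        return LabelMap(grid, np.rint(data).astype(np.int32), lookup)
    if name is None:
        raise FormatError(f"{path}: 3-D volume requires a measure name or a lookup")
    return ScalarMap(grid, name, data.astype(float))


def write_volume(obj, path) -> None:
    """Write a DWIStack, ScalarMap, or LabelMap as NIfTI-1."""
    if isinstance(obj, DWIStack):
        data = obj.data.astype(np.float32)
    elif isinstance(obj, ScalarMap):
        data = obj.values.astype(np.float32)
    elif isinstance(obj, LabelMap):
        data = obj.labels.astype(np.int32)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, obj.grid.affine)
    img.header.set_zooms(
        tuple(obj.grid.voxel_size) + ((1.0,) if data.ndim == 4 else ())
    )
    if isinstance(obj, ScalarMap):
        desc = f"{obj.name} [{obj.units}]" if obj.units else obj.name
        img.header["descrip"] = desc.encode()[:79]
    nib.save(img, str(path))


# --------------------------------------------------------------------------
# cohort table
# --------------------------------------------------------------------------

_PATIENT_FIELDS = ("duration", "headache_freq", "migraine_freq", "aura", "overuse")
_CM_FIELDS = ("cm_onset_months",)
COHORT_COLUMNS = (
    "id", "group", "sex", "age",
    "duration", "cm_onset_months", "headache_freq", "migraine_freq",
    "aura", "overuse",
)


def _to_bool(v):
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise ValidationError(f"cannot interpret {v!r} as a boolean")
    return bool(v)


@dataclass(frozen=True)
class CohortTable:
    """Per-subject demographics and clinical covariates.

    Groups are HC (healthy control), EM (episodic migraine, < 15
    headache days/month) and CM (chronic migraine, >= 15).  Migraine
    history fields exist only for patient groups; the CM-onset field
    only for CM.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in COHORT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing column(s): {missing}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise ValidationError(f"duplicate subject id(s): {dups}")
        df["group"] = df["group"].astype(str).str.strip().str.upper()
        bad = sorted(set(df["group"]) - set(GROUPS))
        if bad:
            raise ValidationError(f"unknown group label(s): {bad}")
        df["sex"] = df["sex"].astype(str).str.strip().str.lower()
        bad = sorted(set(df["sex"]) - set(SEXES))
        if bad:
            raise ValidationError(f"unknown sex label(s): {bad}")
        for col in ("aura", "overuse"):
            df[col] = df[col].map(lambda v: _to_bool(v) if pd.notna(v) else v)

        is_hc = df["group"] == "HC"
        is_cm = df["group"] == "CM"
        for col in _PATIENT_FIELDS:
            bad_rows = df.loc[~is_hc, col].isna()
            if bad_rows.any():
                raise ValidationError(
                    f"patient row(s) missing required field {col!r}: "
                    f"{df.loc[~is_hc].loc[bad_rows, 'id'].tolist()}"
                )
            if df.loc[is_hc, col].notna().any():
                raise ValidationError(f"HC rows must not carry field {col!r}")
        for col in _CM_FIELDS:
            bad_rows = df.loc[is_cm, col].isna()
            if bad_rows.any():
                raise ValidationError(
                    f"CM row(s) missing required field {col!r}: "
                    f"{df.loc[is_cm].loc[bad_rows, 'id'].tolist()}"
                )
            if df.loc[~is_cm, col].notna().any():
                raise ValidationError(f"only CM rows may carry field {col!r}")

        if (df["age"] <= 0).any():
            raise ValidationError("ages must be positive")
        if (df.loc[~is_hc, "duration"] < 0).any():
            raise ValidationError("durations must be non-negative")
        for col in ("headache_freq", "migraine_freq"):
            vals = df.loc[~is_hc, col]
            if ((vals < 0) | (vals > 31)).any():
                raise ValidationError(f"{col} must lie in [0, 31] days/month")
        object.__setattr__(self, "df", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def groups(self) -> np.ndarray:
        return self.df["group"].to_numpy()

    def counts(self) -> dict:
        c = self.df["group"].value_counts()
        return {g: int(c.get(g, 0)) for g in GROUPS}

    def group_sizes(self) -> tuple:
        c = self.counts()
        return (c["HC"], c["EM"], c["CM"])

    def subset(self, *groups: str) -> "CohortTable":
        return CohortTable(self.df[self.df["group"].isin(groups)].copy())


def read_cohort_table(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def write_manifest(run_dir, inputs: dict, seed: int) -> Path:
    """Write a machine-readable manifest of a run (inputs, seed, version)."""
    from . import __version__

    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": "dwimicro",
        "version": __version__,
        "seed": int(seed),
        "inputs": {k: str(v) for k, v in inputs.items()},
    }
    out = run_dir / "manifest.json"
    out.write_text(json.dumps(manifest, indent=2))
    return out
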