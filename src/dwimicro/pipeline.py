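"""End-to-end conveniences composing the module-level operations.

These are thin orchestration helpers used by the examples, the CLI and
the acceptance script; every step is an ordinary public function from
the per-stage modules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import DWIStack
from .dti import dti_scalars, eigendecompose, fit_tensor
from .eap import EAPConfig, apparent_eap_scalars, directional_adc
from .phantom import CohortStudy
from .tbss import (
    InferenceConfig, SkeletonModel, StatMaps, build_skeleton, permutation_fwe,
    project_cohort, roi_report,
)

ALL_MEASURES = ("FA", "MD", "AD", "RD", "RTOP", "RTAP", "RTPP")


def compute_subject_scalars(dwi: DWIStack, mask: np.ndarray | None = None,
                            eap_config: EAPConfig | None = None,
                            measures=ALL_MEASURES) -> dict:
    """All requested scalar maps for one subject.

    DTI scalars come from the weighted-LS tensor fit; RTOP/RTAP/RTPP
    come from the apparent (single-shell) route, using the tensor fit's
    principal direction.
    """
    eap_config = eap_config or EAPConfig()
    tensors = fit_tensor(dwi, mask)
    eigen = eigendecompose(tensors)
    out = {k: v for k, v in dti_scalars(eigen).items() if k in measures}
    eap_measures = tuple(m for m in ("RTOP", "RTAP", "RTPP") if m in measures)
    if eap_measures:
        adc = directional_adc(dwi, s0=None, config=eap_config, mask=tensors.mask)
        out.update(apparent_eap_scalars(adc, eigen.e1, eap_config, eap_measures))
    return out


@dataclass(frozen=True)
class ContrastResult:
    measure: str
    stat_maps: list          # [A > B, A < B] StatMaps
    findings: dict           # contrast description -> list of RoiFinding
    skeleton: SkeletonModel


def compare_groups_on_skeleton(study: CohortStudy, measures, contrast: tuple,
                               config: InferenceConfig | None = None,
                               eap_config: EAPConfig | None = None,
                               mask: np.ndarray | None = None,
                               covariate_columns: tuple = ()) -> dict:
    """Skeletonized voxelwise comparison of two cohort groups.

    Computes per-subject scalar maps, builds the mean-FA skeleton from
    the full cohort, projects every measure, and runs TFCE permutation
    inference for each requested measure between ``contrast`` groups.
    Returns {measure: ContrastResult}.
    """
    config = config or InferenceConfig()
    per_subject = [
        compute_subject_scalars(dwi, mask=mask, eap_config=eap_config,
                                measures=tuple(set(measures) | {"FA"}))
        for dwi in study.subjects
    ]
    fa_maps = [m["FA"] for m in per_subject]
    skeleton = build_skeleton(fa_maps, config)
    non_fa = {m: [s[m] for s in per_subject] for m in measures if m != "FA"}
    projected = project_cohort(skeleton, fa_maps, non_fa,
                               config.search_radius_mm)

    groups = study.table.groups
    in_contrast = np.isin(groups, list(contrast))
    covs = None
    if covariate_columns:
        covs = study.table.df.loc[in_contrast, list(covariate_columns)].to_numpy(float)

    results = {}
    for measure in measures:
        maps = permutation_fwe(projected[measure][in_contrast],
                               groups[in_contrast], skeleton, config,
                               covariates=covs, contrast=contrast)
        findings = {
            sm.contrast: roi_report(sm, study.labels, skeleton, config)
            for sm in maps
        }
        results[measure] = ContrastResult(measure, maps, findings, skeleton)
    return results
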