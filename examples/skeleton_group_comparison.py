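"""Full group comparison: cohort -> scalar maps -> skeleton -> TFCE FWE.

Generates a cohort in which the chronic-migraine group carries a -10%
axial-eigenvalue effect in tract_A, then runs the skeletonized
voxelwise comparison for AD (DTI) and RTPP (apparent EAP) between the
episodic and chronic groups with TFCE permutation inference, and prints
the region-level report.
"""
from scipy import ndimage

from dwimicro import (
    GroupEffectSpec, InferenceConfig, build_tensor_phantom,
    compare_groups_on_skeleton, default_phantom, generate_cohort,
)

spec = default_phantom((28, 28, 10))
effects = [GroupEffectSpec("CM", labels=(1,), lambda1_factor=0.9)]
study = generate_cohort(spec, effects, None,
                        {"HC": 2, "EM": 15, "CM": 15},
                        noise_sigma=5.0, seed=3)

_, labels = build_tensor_phantom(spec)
fit_mask = ndimage.binary_dilation(labels.labels > 0, iterations=2)

config = InferenceConfig(n_permutations=1000, seed=4)
results = compare_groups_on_skeleton(
    study, measures=("AD", "RTPP"), contrast=("EM", "CM"),
    config=config, mask=fit_mask)

sk = results["AD"].skeleton
print(f"skeleton: {sk.n_voxels} voxels "
      f"(mean-FA threshold {sk.fa_threshold})")

for measure in ("AD", "RTPP"):
    res = results[measure]
    print(f"\n=== {measure} ===")
    for stat in res.stat_maps:
        findings = res.findings[stat.contrast]
        n_sig = int((stat.p_corrected < config.alpha).sum())
        print(f"{stat.contrast}: {n_sig} significant skeleton voxel(s)")
        for f in findings:
            print(f"   {f.region}: volume {f.volume_mm3:.0f} mm^3, "
                  f"min corrected p = {f.min_p:.4f}, "
                  f"peak at {f.peak_mm} mm")

print("\nExpected: the EM > CM AD contrast and the EM < CM RTPP contrast "
      "localize to tract_A\n(lower AD and higher RTPP both reflect the "
      "reduced axial eigenvalue); tract_B is a\nnegative control and "
      "should stay empty.")
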