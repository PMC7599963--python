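"""Generate a synthetic three-group cohort and inspect its structure.

The generator builds a tensor-field phantom (two anisotropic tubes in
an isotropic background), applies a seeded group effect (here: 10%
lower axial eigenvalue in tract_A for the chronic-migraine group), adds
Rician noise to the simulated single-shell signal, and samples a
demographics table whose marginals mirror a three-group migraine study.
"""
import numpy as np

from dwimicro import GroupEffectSpec, default_phantom, generate_cohort

spec = default_phantom((24, 24, 8))
effects = [GroupEffectSpec("CM", labels=(1,), lambda1_factor=0.9)]
study = generate_cohort(spec, effects, demographics=None,
                        n_per_group={"HC": 5, "EM": 5, "CM": 5},
                        noise_sigma=5.0, seed=7)

print("group sizes:", study.table.counts())
print("volumes per subject:", study.subjects[0].data.shape[3],
      "| shell b-value:", study.scheme.shell_bval, "s/mm^2")
print("tract labels:", study.labels.lookup)

df = study.table.df
for group in ("HC", "EM", "CM"):
    sub = df[df.group == group]
    line = f"{group}: age {sub.age.mean():.1f} +/- {sub.age.std():.1f} y"
    if group != "HC":
        line += (f", duration {sub.duration.mean():.1f} y, "
                 f"headache {sub.headache_freq.mean():.1f} d/month")
    print(line)

print("\nper-subject global eigenvalue scales (inter-subject jitter):")
print(np.round(study.subject_scales, 3))
print("\nThe CM subjects carry a -10% lambda1 effect inside tract_A only;"
      "\neverything is reproducible from the seed.")
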