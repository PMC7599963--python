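"""Compute DTI and EAP scalar maps for one synthetic subject.

Shows the two EAP routes side by side: the Gaussian closed forms (which
invert the tensor eigenvalues, unstable under noise) and the apparent
single-shell route (directional ADC + mono-exponential radial
extension).  On a noise-free Gaussian signal both routes agree.
"""
import numpy as np

from dwimicro import (
    NoiseSpec, apparent_eap_scalars, build_tensor_phantom, default_phantom,
    directional_adc, dti_scalars, eigendecompose, fit_tensor,
    gaussian_eap_from_eigenvalues, make_scheme, simulate_dwi,
)

spec = default_phantom((24, 24, 8))
tensors, labels = build_tensor_phantom(spec)
scheme = make_scheme(n_dirs=61, bval=1000.0)     # study-like acquisition
in_tract = labels.labels == 1

for sigma, tag in ((0.0, "noise-free"), (5.0, "SNR 20")):
    noise = NoiseSpec(sigma=sigma, seed=1) if sigma else None
    dwi = simulate_dwi(tensors, scheme, noise=noise)
    fitted = fit_tensor(dwi)
    eigen = eigendecompose(fitted)
    dti = dti_scalars(eigen)
    gaussian = gaussian_eap_from_eigenvalues(eigen)
    apparent = apparent_eap_scalars(directional_adc(dwi), eigen.e1)

    print(f"\n--- {tag} (mean over tract_A voxels) ---")
    print(f"FA {dti['FA'].values[in_tract].mean():.3f}   "
          f"MD {dti['MD'].values[in_tract].mean():.2e} mm^2/s   "
          f"AD {dti['AD'].values[in_tract].mean():.2e}   "
          f"RD {dti['RD'].values[in_tract].mean():.2e}")
    for name in ("RTOP", "RTAP", "RTPP"):
        a = apparent[name].values[in_tract].mean()
        g = gaussian[name].values[in_tract].mean()
        print(f"{name}: apparent {a:.4g} {apparent[name].units}, "
              f"tensor closed form {g:.4g} "
              f"(ratio {a / g:.3f})")

print("\nNoise-free, the apparent route reproduces the closed forms "
      "(ratios ~1); with noise the \ntensor route inherits the "
      "instability of inverted small eigenvalues while the\n"
      "apparent route stays stable -- the reason it exists.")
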