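# Model-eye measurement conditions of the virtual bench.
#
# condition1: monochromatic 546 nm, aberration-neutral corneal model
#             (achromatic doublet, f = 36 mm).
# condition2: polychromatic V(lambda)-weighted spectrum, corneal model with a
#             population level of spherical aberration (+0.27 um Z(4,0) at a
#             6 mm normalization diameter) and 1 D of longitudinal chromatic
#             aberration across the modelled band (singlet, f = 39 mm).
conditions:
  condition1:
    corneal_sa_um: 0.0
    sa_norm_diameter_mm: 6.0
    lca_total_D: 0.0
    lca_band_nm: [480.0, 640.0]
    corneal_focal_length_mm: 36.0
    plane_factor: 1.3333333333333333
    retinal_scale_mm_per_deg: 0.30
    spectrum:
      kind: monochromatic
      wavelength_nm: 546.0
  condition2:
    corneal_sa_um: 0.27
    sa_norm_diameter_mm: 6.0
    lca_total_D: 1.0
    lca_band_nm: [480.0, 640.0]
    corneal_focal_length_mm: 39.0
    plane_factor: 1.3333333333333333
    retinal_scale_mm_per_deg: 0.30
    spectrum:
      kind: photopic
      band_nm: [480.0, 640.0]
      n_wavelengths: 9
      reference_wavelength_nm: 546.0
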