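# Parametric descriptions of the five trifocal IOL models of the study.
#
# Add powers, energy splits, asphericity, Abbe numbers, refractive indices and
# diffractive-zone extents are the published/manufacturer figures; step heights
# and apodization tapers are NOT transcribed (groove blueprints are
# proprietary) but fitted at load time so that the scalar-diffraction unit-cell
# efficiencies reproduce the printed splits.
#
# split_normalization:
#   relative - the printed split is the share of light over the three design
#              orders (the figures sum to 100%, which a phase-only profile
#              cannot deliver in absolute terms).
#   absolute - the printed figures are absolute pupil-averaged fractions
#              (Trinova, whose far share is unpublished).
presets:
  triumf:
    label: "FineVision Triumf POD L GF"
    base_power_D: 20.0
    add_intermediate_D: 1.75
    add_near_D: 3.50
    profile_family: sawtooth_trifocal
    n_step_heights: 2
    order_map: {far: 0, intermediate: 1, near: 2}
    diffractive_extent_mm: 6.0
    peripheral_family: none        # full-diffractive, pupil independent
    apodization: none
    sa_correction_um: -0.11
    abbe_number: 42.0
    refractive_index: 1.53
    target_split: [0.50, 0.30, 0.20]
    split_normalization: relative
    achromatization: 0.7           # proprietary chromatic correction; strength inferred
    inferred: [achromatization]
  at_lisa:
    label: "AT Lisa Tri 839 MP"
    base_power_D: 20.0
    add_intermediate_D: 1.665
    add_near_D: 3.33
    profile_family: sawtooth_trifocal
    n_step_heights: 2
    order_map: {far: 0, intermediate: 1, near: 2}
    diffractive_extent_mm: 4.34
    peripheral_family: bifocal     # turns bifocal (far/near) above 4.34 mm
    apodization: none
    sa_correction_um: -0.18
    abbe_number: 56.5
    refractive_index: 1.46
    target_split: [0.48, 0.21, 0.31]
    split_normalization: relative
    achromatization: 0.0
    inferred: []
  synergy:
    label: "Tecnis Synergy"
    base_power_D: 20.0
    add_intermediate_D: 1.85       # manufacturer publishes no adds; see below
    add_near_D: 3.70
    profile_family: sawtooth_trifocal
    n_step_heights: 2
    order_map: {far: 0, intermediate: 1, near: 2}
    diffractive_extent_mm: 5.0     # refractive periphery beyond ~5 mm
    peripheral_family: none
    apodization: none
    sa_correction_um: -0.27
    abbe_number: 55.0
    refractive_index: 1.47
    target_split: [0.44, 0.22, 0.34]
    split_normalization: relative
    achromatization: 0.7
    # adds chosen so the simulated intermediate/near peaks sit at 72/37 cm, the
    # clinically reported preferred distances for this lens; split chosen
    # near-dominant. All are estimates, not manufacturer data.
    inferred: [add_intermediate_D, add_near_D, target_split, achromatization]
  panoptix:
    label: "AcrySof IQ PanOptix"
    base_power_D: 20.0
    add_intermediate_D: 2.17
    add_near_D: 3.25
    profile_family: zone_limited_trifocal
    n_step_heights: 3
    # quadrifocal-style base period (1.083 D); the 1.08 D order carries only
    # residual energy after the fit, emulating its redirection to far
    order_map: {far: 0, intermediate: 2, near: 3}
    diffractive_extent_mm: 4.5     # outer part monofocal
    peripheral_family: none
    apodization: none
    sa_correction_um: -0.10
    abbe_number: 37.0
    refractive_index: 1.55
    target_split: [0.50, 0.25, 0.25]
    split_normalization: relative
    achromatization: 0.0
    inferred: []
  trinova:
    label: "Acriva Trinova Pro C Pupil Adaptive"
    base_power_D: 20.0
    add_intermediate_D: 1.80
    add_near_D: 3.60
    profile_family: sinusoidal
    n_step_heights: 3              # (A, B, delta) of the two-harmonic sinusoid
    order_map: {far: -1, intermediate: 0, near: 1}
    diffractive_extent_mm: 6.0
    peripheral_family: none
    apodization: pupil_adaptive
    sa_correction_um: -0.10
    abbe_number: 58.0
    refractive_index: 1.46
    target_split: [0.21, 0.36]     # intermediate, near at 3 mm (far unpublished)
    target_split_large: [0.28, 0.28]   # intermediate, near at 4.5 mm
    split_normalization: absolute
    achromatization: 0.0
    inferred: []
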