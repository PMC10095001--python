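# Mapping from the (normalized) area under the MTF to simulated visual acuity.
#
#   simVA(x) = a + b * exp(-c * x)        [logMAR]
#
# The published acuity-from-MTFa fit uses an unnormalized area; these
# coefficients re-express the same exponential form for MTFa normalized by the
# diffraction-limited area, calibrated so that a diffraction-limited monofocal
# (x = 1) maps to about -0.10 logMAR and a fully degraded optic (x = 0) to
# about +0.28 logMAR.
default:
  name: normalized-mtfa-exponential
  variant: monocular
  a: -0.12
  b: 0.40
  c: 3.0
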