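# Methods

This note records the physical model, the calibration choices and the known
limitations of the virtual trifocal-IOL bench.

## Optical model

**Single-plane thin-screen propagation.** The cornea and the IOL are
collapsed into one phase screen at the pupil; imaging is scalar Fourier
optics (PSF = |FT(pupil)|², OTF = FT(PSF), MTF = |OTF| along the two
principal frequency axes). There is no surface-to-surface Fresnel
propagation, no vector diffraction and no tilt/decentration tolerancing. For
MTF purposes the bench geometry reduces to effective defocus and aberration
at the pupil, which keeps every piece testable against closed forms
(diffraction-limited MTF, kinoform efficiencies).

**Pupil phase terms.**

* Defocus: W(r) = D_total·r²/2 with D_total = (4/3)·d_spectacle +
  D_chromatic(λ). The 4/3 spectacle↔IOL plane factor is calibrated to the
  printed correspondence −3.5 ↔ −4.67 D; a full vergence propagation through
  the model eye would add parameters the data do not constrain.
* Corneal spherical aberration: a Z(4,0) Zernike surface whose coefficient
  (+0.27 µm in condition 2) is quoted at a 6.0 mm normalization diameter —
  the convention under which IOL asphericities such as −0.27 µm are usually
  stated. A smaller pupil crops this fixed surface rather than rescaling it,
  so the effective sub-aperture coefficient falls as (d/6 mm)⁴.
* Lens asphericity: the same Z(4,0) form with the preset's (negative)
  correction value. It is applied in both conditions; in condition 1 the
  lens's own asphericity is therefore uncompensated, which is why strongly
  corrected designs test worse under the aberration-neutral cornea.
* Diffractive profile: see below.

**Image-plane calibration.** Spatial frequency in lp/mm maps to visual angle
through a retinal scale of 0.30 mm/deg (50 lp/mm ↔ 15 cyc/deg, 100 ↔ 30),
implying an image focal length of ≈17.2 mm. The 36 vs 39 mm focal lengths of
the two physical corneal models are carried as metadata only; the simulation
works in defocus-diopter space at the pupil. This choice is consequential
for one result (the near-point shift, below).

**Chromatic model.** Condition 2 uses nine wavelengths, 480–640 nm at 20 nm
spacing, weighted by the CIE photopic luminosity function and renormalized.
Ocular chromatic defocus is linear in wavenumber, anchored to 0 at 546 nm,
with exactly 1 D between the band edges; shorter wavelengths are myopic.
Polychromatic PSFs are computed per wavelength on a common image-plane pixel
pitch (the pupil array width scales with λ) and summed with the spectral
weights before the OTF is taken. Diffractive order powers scale with λ
automatically because the zone geometry is fixed in r²; kinoform step
heights scale as λ_ref/λ. Designs with proprietary chromatic correction
carry a phenomenological `achromatization` factor (default 0.7 where
claimed) that attenuates the ocular chromatic defocus term; no mechanism is
asserted.

**Grids.** Default pupil grid 1024² with pad factor 2 (the OTF then resolves
≈0.6 lp/mm per sample at 3 mm); the suite verifies <0.005 change in MTF at
50 lp/mm when doubling the grid for every preset. 512² is used for
best-focus searches and most tests.

**Best-focus referencing.** The 0 D point of every through-focus sweep is
the spectacle-plane defocus maximizing far-focus MTFa, found by bounded
scalar search before the sweep — mirroring how a bench focuses before
measuring. The criterion is switchable to MTF-at-50 lp/mm or to the nominal
0 D (`far_reference=`), since instruments differ.

## Lens presets

Manufacturers publish add powers and energy splits but not groove
blueprints; each preset therefore stores the printed parameters and *fits*
its step heights so the model reproduces the printed split. Printed splits
that sum to 100% (Triumf 50/30/20, AT Lisa 48/21/31, PanOptix 50/25/25) are
treated as relative shares over the three design orders — a phase-only
profile cannot put all light into three orders, and the fits leave the
physical 13–30% in higher orders. Trinova's 21%/36% (far unpublished) are
treated as absolute pupil-averaged fractions.

The fits target the *aperture-averaged* efficiency at the 3 mm quoting
pupil: these lenses have only 2–4 Fresnel zones inside 3 mm, and the cropped
outer zone shifts the balance by several points, which the bench also sees.
All fits are derivative-free (Nelder–Mead) from a fixed multi-start list and
are therefore deterministic; they run at first preset use (seconds).

* **Triumf** — two stacked sawtooth harmonics (periods T, T/2), orders
  0/1/2 → far/intermediate/near, adds 1.75/3.50 D, full 6 mm pattern.
* **AT Lisa** — same family, adds 1.66/3.33 D, trifocal to 4.34 mm and an
  equal-split far/near bifocal cell (half-wave step on the doubled-frequency
  harmonic) beyond.
* **Synergy** — no adds or splits are published. The preset uses 1.85/3.70 D
  (intermediate ≈72 cm, near ≈37 cm, the clinically reported preferred
  distances for this lens) and a near-dominant split; every derived number is
  flagged `inferred`.
* **PanOptix** — modelled on its actual 1.083 D base period with order map
  0/2/3 → far/intermediate/near, so the printed 2.17/3.25 D adds are exact.
  About 6% of light remains in the unused 1.08 D order after the fit,
  emulating (imperfectly) its redirection to far. Pattern stops at 4.5 mm;
  the periphery is plain refractive.
* **Trinova** — a smooth two-harmonic sinusoid (A·sin + B·sin(2·) with a
  relative phase), orders −1/0/+1 remapped to far/intermediate/near through
  a +1.8 D refractive offset, plus a raised-cosine radial amplitude taper
  ("pupil adaptive"): full amplitude out to ≈1.8 mm radius, falling to ≈0.3
  at 2.25 mm. Cell and taper are fitted jointly to the printed 3 mm and
  4.5 mm splits. The best reachable fit leaves ≈0.04 residuals on the two
  near shares (intermediate is within 0.02); a third harmonic does not help.
  The taper reproduces the design's signature pupil behaviour: intermediate
  dominance at large apertures.

## Metrics

**MTFa** is the trapezoidal area under the meridian-averaged MTF on
[0, 50 lp/mm], divided by the same area of the diffraction-limited MTF at
the matching aperture and the reference wavelength — a dimensionless value
in [0, 1]. The acuity literature often uses the raw area in lp/mm units;
the normalized convention is flagged in all outputs because the two differ
by a constant that depends on aperture.

**Simulated acuity** uses simVA(x) = a + b·exp(−c·x) logMAR with packaged
defaults (−0.12, 0.40, 3.0), calibrated so a diffraction-limited monofocal
(x = 1) maps to ≈−0.10 logMAR and a fully degraded optic to ≈+0.28. The
cited empirical mapping is published for unnormalized MTFa, so the
coefficients here are a re-expression, shipped as config data
(`data/simva.yaml`), not code. The mapping is monocular; no binocular
summation is modelled.

**Foci** are discrete local maxima of the defocus curve (minima of acuity)
with prominence ≥0.02 normalized-MTFa units (≥0.01 logMAR for acuity
curves — the same threshold mapped through the acuity-model slope). Far
claims the peak nearest 0 D; near and intermediate claim peaks nearest
−add/(4/3), far and near first, so a merged pair reports its weaker member
`present=False`. Viewing distances come from the reciprocal spectacle-plane
vergence of the detected peak, which quantizes distances to the 0.25 D grid
(hence exactly 80 cm for a −1.25 D peak).

## Synthetic bench

`synthetic_bench` emulates instrument output: per-sample through-focus
tables (two samples per lens by default) equal to the noiseless simulated
truth plus independent Gaussian noise per cell (σ = 0.01 MTF units by
default) and a small sagittal/tangential asymmetry term, clipped to [0, 1];
the zero-frequency column stays at 1 because the instrument normalizes
there. All randomness is seeded; the same seed reproduces tables bitwise.
Real crosshair-derived MTF noise is structured and correlated, and
sample-to-sample manufacturing variability has no published magnitude, so
this is the simplest parametric stand-in: passing tests show the pipeline's
statistical behaviour (1/√n averaging, noise-robust peak finding), not that
the noise model matches the instrument.

## Known limitations

* The near-point shift between conditions. On the physical bench the near
  peak moves by one 0.25 D grid step between monochromatic and polychromatic
  conditions. In this model the near diffractive order is nearly achromatic —
  its dispersion (≈0.98 D across the band, since order power scales with λ)
  opposes the 1 D ocular chromatic aberration almost exactly — so the
  simulated near peak does not move. The bench's two corneal models also
  differ in focal length (36 vs 39 mm), which rescales its diopter axis
  between conditions; that instrument-geometry effect is deliberately outside
  this model, and the simulated shift of 0.00 D should be read with that in
  mind. The depth-of-focus *extension* beyond the near focus under
  polychromatic light does reproduce and is tested.
* At 3 mm the PanOptix preset has ~2.2 zone periods; its intermediate and
  near foci merge into one broad peak, as on the bench, but the surviving
  peak sits nearest the intermediate position, whereas the bench reads the
  merged peak as the reading peak. Which label survives is not meaningful at
  this zone count.
* AT Lisa's within-lens near-over-far dominance at 5 mm is not reproduced:
  with −0.18 µm of uncorrected lens asphericity in condition 1, the far peak
  keeps the advantage at 50 lp/mm for any peripheral bifocal balance. The
  reproducible parts — collapse of its intermediate focus beyond the bifocal
  transition, and Trinova's intermediate dominance at 5 mm — are tested.
* Absolute MTFa magnitudes and percent polychromatic losses depend on
  proprietary surface details and are not reproduction targets; directions
  and rankings are.
* No material dispersion (Abbe numbers are metadata), no stray light or
  halo model, no wet-cell window, no ray tracing of the corneal doublet.
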