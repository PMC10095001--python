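"""Scalar Fourier-optics propagation: PSF, meridian MTF and through-focus sweeps.

The cornea and the IOL are collapsed into a single thin phase screen at the
pupil (their wavefront contributions coadd), and the point-spread function is
the squared modulus of the Fourier transform of the pupil function.  The OTF
is the Fourier transform of the PSF; its modulus along the two principal
frequency axes gives the sagittal and tangential MTF, with the frequency axis
calibrated in lp/mm at the image plane of the model eye (focal length implied
by the retinal scale, ≈17.2 mm).

Polychromatic imaging sums the monochromatic PSFs of the condition's spectrum
on a common image-plane sampling grid (the pupil array width is scaled with
wavelength so that all PSFs share one pixel pitch) before the OTF is taken.

Defocus enters as the quadratic wavefront ``W(r) = D_total · r²/2`` with
``D_total`` combining the spectacle-plane sweep value (converted to the IOL
plane), the chromatic defocus of the model eye at the wavelength, and — for
designs with a remapped order convention — the refractive offset built into
the phase profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import minimize_scalar

from . import model_eye
from .iol_designs import IOLDesign, build_phase_profile
from .model_eye import ModelEyeCondition

__all__ = [
    "PupilSpec",
    "PupilGrid",
    "MeridianMTF",
    "ThroughFocusMTF",
    "DEFAULT_DEFOCUS_GRID",
    "pupil_function",
    "mtf_meridians",
    "meridian_average",
    "polychromatic_mtf",
    "through_focus",
    "diffraction_limited_mtf",
    "cutoff_frequency_lpmm",
    "focus_energy_fractions",
]

#: spectacle-plane defocus grid of the standard bench sweep: +1 to −3.5 D, 0.25 D step
DEFAULT_DEFOCUS_GRID = np.round(np.arange(-3.5, 1.0 + 1e-9, 0.25), 10)

_PAPER_APERTURES = (2.0, 3.0, 4.0, 4.5, 5.0)


@dataclass(frozen=True)
class PupilSpec:
    """Sampling and state of one pupil-plane evaluation."""

    aperture_diameter: float              # mm
    grid_size: int = 1024                 # samples per side, power of two
    pad_factor: float = 2.0
    defocus_spec: float = 0.0             # D at the spectacle plane
    wavelength: float = 546.0             # nm

    def __post_init__(self):
        n = self.grid_size
        if n < 512 or (n & (n - 1)) != 0:
            raise ValueError("grid_size must be a power of two ≥ 512")
        if self.pad_factor < 2:
            raise ValueError("pad_factor must be ≥ 2 (OTF support)")
        if self.aperture_diameter <= 0:
            raise ValueError("aperture must be positive")
        if not np.isfinite(self.defocus_spec):
            raise ValueError("defocus must be finite")


@dataclass(frozen=True)
class PupilGrid:
    """Complex pupil amplitude with its physical sampling."""

    amplitude: np.ndarray                 # complex, grid_size × grid_size
    sample_spacing: float                 # m per sample at the pupil
    wavelength: float                     # nm
    aperture_diameter: float              # mm

    @property
    def width(self) -> float:
        return self.amplitude.shape[0] * self.sample_spacing


@dataclass(frozen=True)
class MeridianMTF:
    frequencies: np.ndarray               # lp/mm
    sagittal: np.ndarray
    tangential: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return meridian_average(self)


def cutoff_frequency_lpmm(aperture_mm: float, wavelength_nm: float,
                          eye: ModelEyeCondition) -> float:
    """Incoherent diffraction cutoff D/(λ f) at the model-eye image plane."""
    f = eye.image_focal_length_mm * 1e-3
    return (aperture_mm * 1e-3) / (wavelength_nm * 1e-9 * f) / 1000.0


def diffraction_limited_mtf(frequencies_lpmm, aperture_mm: float,
                            wavelength_nm: float, eye: ModelEyeCondition
                            ) -> np.ndarray:
    """Closed-form MTF of an unaberrated circular pupil."""
    nu = np.asarray(frequencies_lpmm, dtype=float)
    x = np.clip(nu / cutoff_frequency_lpmm(aperture_mm, wavelength_nm, eye), 0.0, 1.0)
    return (2.0 / np.pi) * (np.arccos(x) - x * np.sqrt(1.0 - x**2))


# ---------------------------------------------------------------------------
# pupil construction and monochromatic MTF
# ---------------------------------------------------------------------------

def pupil_function(eye: ModelEyeCondition, design: IOLDesign | None,
                   spec: PupilSpec) -> PupilGrid:
    """Complex pupil amplitude for one design/condition/defocus/wavelength.

    Unit amplitude inside the aperture, zero outside; the phase coadds the
    corneal wavefront, the lens asphericity, the diffractive profile and the
    defocus term.
    """
    if design is not None and spec.aperture_diameter > design.optic_diameter:
        raise ValueError("aperture exceeds the lens optic")
    n = spec.grid_size
    d_m = spec.aperture_diameter * 1e-3
    width = spec.pad_factor * d_m
    dx = width / n
    x = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    inside = r2 <= (d_m / 2.0) ** 2
    lam_m = spec.wavelength * 1e-9

    chrom = model_eye.chromatic_defocus(spec.wavelength, eye)
    if design is not None and design.achromatization:
        chrom = chrom * (1.0 - design.achromatization)
    d_total = model_eye.spectacle_to_iol_defocus(spec.defocus_spec, eye) + chrom
    phase = np.pi * d_total * r2 / lam_m

    r_mm = np.sqrt(r2) * 1e3
    if eye.corneal_sa != 0.0:
        w_um = np.zeros_like(r_mm)
        w_um[inside] = eye.corneal_sa * model_eye.zernike_z40(
            r_mm[inside] / (eye.sa_norm_diameter / 2.0))
        phase = phase + 2 * np.pi * w_um * 1e-6 / lam_m
    if design is not None:
        if design.sa_correction != 0.0:
            w_um = np.zeros_like(r_mm)
            w_um[inside] = design.sa_correction * model_eye.zernike_z40(
                r_mm[inside] / (eye.sa_norm_diameter / 2.0))
            phase = phase + 2 * np.pi * w_um * 1e-6 / lam_m
        profile = build_phase_profile(design, spec.wavelength)
        lens_ph = np.zeros_like(r_mm)
        lens_ph[inside] = profile(r_mm[inside])
        phase = phase + lens_ph

    amp = np.where(inside, np.exp(1j * phase), 0.0)
    return PupilGrid(amp, dx, spec.wavelength, spec.aperture_diameter)


def _psf(pupil: PupilGrid) -> np.ndarray:
    """PSF intensity in FFT layout (DC at [0, 0])."""
    field_img = np.fft.fft2(np.fft.ifftshift(pupil.amplitude))
    return np.abs(field_img) ** 2


def _otf_meridians(psf_fftlayout: np.ndarray, dx_pupil: float,
                   wavelength_nm: float, eye: ModelEyeCondition,
                   aperture_mm: float, f_max_ratio: float = 1.1) -> MeridianMTF:
    otf = np.fft.fft2(psf_fftlayout)
    otf = otf / otf[0, 0]
    n = otf.shape[0]
    f = eye.image_focal_length_mm * 1e-3
    dnu_lpmm = dx_pupil / (wavelength_nm * 1e-9 * f) / 1000.0
    nu = np.arange(n // 2) * dnu_lpmm
    cut = cutoff_frequency_lpmm(aperture_mm, wavelength_nm, eye)
    if nu[-1] + dnu_lpmm < cut:
        need = int(2 ** math.ceil(math.log2(n * cut / nu[-1])))
        raise ValueError(f"frequency axis does not reach the pupil cutoff "
                         f"({cut:.0f} lp/mm): increase grid size to ≥ {need}")
    keep = nu <= f_max_ratio * cut
    return MeridianMTF(nu[keep], np.abs(otf[0, : n // 2])[keep],
                       np.abs(otf[: n // 2, 0])[keep])


def mtf_meridians(eye: ModelEyeCondition, design: IOLDesign | None,
                  spec: PupilSpec) -> MeridianMTF:
    """Monochromatic sagittal/tangential MTF vs lp/mm for one pupil state."""
    pupil = pupil_function(eye, design, spec)
    return _otf_meridians(_psf(pupil), pupil.sample_spacing, spec.wavelength,
                          eye, spec.aperture_diameter)


def meridian_average(mtf: MeridianMTF | None = None, sagittal=None,
                     tangential=None, frequencies=None) -> np.ndarray:
    """Pointwise arithmetic mean of the sagittal and tangential MTF."""
    if mtf is not None:
        return 0.5 * (mtf.sagittal + mtf.tangential)
    sagittal = np.asarray(sagittal, dtype=float)
    tangential = np.asarray(tangential, dtype=float)
    if sagittal.shape != tangential.shape:
        raise ValueError("meridian curves must share one frequency axis")
    return 0.5 * (sagittal + tangential)


def polychromatic_mtf(eye: ModelEyeCondition, design: IOLDesign | None,
                      spec: PupilSpec) -> MeridianMTF:
    """Spectrum-weighted MTF: per-λ PSFs summed on a common image-plane grid.

    The pupil array width is scaled ∝ λ so that every wavelength's PSF shares
    the same pixel pitch; the common frequency axis is set by the shortest
    wavelength.  Reduces exactly to :func:`mtf_meridians` for a monochromatic
    spectrum.
    """
    sp = eye.spectrum
    if len(sp.wavelengths) == 0:
        raise ValueError("empty spectrum")
    lam_min = min(sp.wavelengths)
    psf_sum = None
    dx_ref = None
    for lam, w in zip(sp.wavelengths, sp.weights):
        s = replace(spec, wavelength=lam, pad_factor=spec.pad_factor * lam / lam_min)
        pupil = pupil_function(eye, design, s)
        p = _psf(pupil)
        p = p / p.sum()
        psf_sum = w * p if psf_sum is None else psf_sum + w * p
        dx_ref = pupil.sample_spacing / (lam / lam_min)  # λ-invariant by construction
    return _otf_meridians(psf_sum, dx_ref, lam_min, eye, spec.aperture_diameter)


# ---------------------------------------------------------------------------
# through-focus sweeps
# ---------------------------------------------------------------------------

@dataclass
class ThroughFocusMTF:
    """Meridian-resolved MTF on a defocus × spatial-frequency grid."""

    defocus_grid: np.ndarray              # D, spectacle plane (reported axis)
    frequencies: np.ndarray               # lp/mm
    mtf_sagittal: np.ndarray              # n_defocus × n_freq
    mtf_tangential: np.ndarray
    condition: str
    lens: str
    aperture: float                       # mm
    samples: tuple[str, ...] = ("sim",)
    far_reference_offset: float = 0.0     # D added to the nominal grid before simulation

    def __post_init__(self):
        self.defocus_grid = np.asarray(self.defocus_grid, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.mtf_sagittal = np.asarray(self.mtf_sagittal, dtype=float)
        self.mtf_tangential = np.asarray(self.mtf_tangential, dtype=float)
        if np.any(np.diff(self.defocus_grid) <= 0):
            raise ValueError("defocus grid must be strictly increasing")
        for m in (self.mtf_sagittal, self.mtf_tangential):
            if m.shape != (self.defocus_grid.size, self.frequencies.size):
                raise ValueError("MTF matrix shape does not match the grids")
            if np.any(m < -1e-9) or np.any(m > 1 + 1e-9):
                raise ValueError("MTF values must lie in [0, 1]")

    @property
    def mtf_mean(self) -> np.ndarray:
        return 0.5 * (self.mtf_sagittal + self.mtf_tangential)

    def to_frame(self):
        """Long-format table in the shared bench-CSV dialect."""
        import pandas as pd

        nd, nf = self.defocus_grid.size, self.frequencies.size
        sample = self.samples[0] if len(self.samples) == 1 else "+".join(self.samples)
        return pd.DataFrame({
            "lens": np.repeat(self.lens, nd * nf),
            "sample_id": np.repeat(sample, nd * nf),
            "condition": np.repeat(self.condition, nd * nf),
            "aperture_mm": np.repeat(self.aperture, nd * nf),
            "defocus_spec_D": np.repeat(self.defocus_grid, nf),
            "frequency_lpmm": np.tile(self.frequencies, nd),
            "mtf_sagittal": self.mtf_sagittal.ravel(),
            "mtf_tangential": self.mtf_tangential.ravel(),
            "mtf_mean": self.mtf_mean.ravel(),
        })

    def mtf_at(self, frequency_lpmm: float) -> np.ndarray:
        """Meridian-averaged through-focus MTF at one frequency (interpolated)."""
        mean = self.mtf_mean
        return np.array([np.interp(frequency_lpmm, self.frequencies, row)
                         for row in mean])


def _mtfa_of(mtf: MeridianMTF, eye: ModelEyeCondition, aperture: float,
             cutoff: float = 50.0) -> float:
    ref_lam = eye.spectrum.reference_wavelength
    sel = mtf.frequencies <= cutoff
    nu = mtf.frequencies[sel]
    num = np.trapezoid(meridian_average(mtf)[sel], nu)
    den = np.trapezoid(diffraction_limited_mtf(nu, aperture, ref_lam, eye), nu)
    return float(num / den)


def find_far_reference(eye: ModelEyeCondition, design: IOLDesign | None,
                       aperture_mm: float, criterion: str = "mtfa",
                       grid_size: int = 512, pad_factor: float = 2.0,
                       halfwidth: float = 1.0, xatol: float = 5e-3) -> float:
    """Spectacle-plane defocus maximizing far-focus quality (bench best focus).

    ``criterion`` is 'mtfa' (area under the MTF to 50 lp/mm) or 'mtf50'
    (MTF at 50 lp/mm); both are exposed because the instrument's exact
    best-focus rule is a free choice.
    """
    if criterion not in ("mtfa", "mtf50"):
        raise ValueError("criterion must be 'mtfa' or 'mtf50'")

    def quality(d):
        spec = PupilSpec(aperture_mm, grid_size, pad_factor, float(d))
        mtf = polychromatic_mtf(eye, design, spec)
        if criterion == "mtfa":
            return _mtfa_of(mtf, eye, aperture_mm)
        return float(np.interp(50.0, mtf.frequencies, meridian_average(mtf)))

    res = minimize_scalar(lambda d: -quality(d), bounds=(-halfwidth, halfwidth),
                          method="bounded", options=dict(xatol=xatol))
    return float(res.x)


def through_focus(eye: ModelEyeCondition, design: IOLDesign | None,
                  aperture_mm: float, defocus_grid=None,
                  grid_size: int = 1024, pad_factor: float = 2.0,
                  far_reference: str | float = "mtfa",
                  ref_grid_size: int = 512) -> ThroughFocusMTF:
    """Meridian-resolved MTF across a spectacle-plane defocus sweep.

    The 0 D point of the reported grid corresponds to the best far focus,
    found before the sweep by maximizing the chosen criterion
    (``far_reference`` = 'mtfa' or 'mtf50'); pass ``far_reference='nominal'``
    or a float offset to skip or fix the search.
    """
    grid = DEFAULT_DEFOCUS_GRID if defocus_grid is None else np.asarray(defocus_grid, float)
    if isinstance(far_reference, str):
        if far_reference == "nominal":
            offset = 0.0
        else:
            offset = find_far_reference(eye, design, aperture_mm,
                                        criterion=far_reference,
                                        grid_size=min(ref_grid_size, grid_size),
                                        pad_factor=pad_factor)
    else:
        offset = float(far_reference)

    sag, tan, freqs = [], [], None
    for d in grid:
        spec = PupilSpec(aperture_mm, grid_size, pad_factor, float(d) + offset)
        mtf = polychromatic_mtf(eye, design, spec)
        if freqs is None:
            freqs = mtf.frequencies
        sag.append(mtf.sagittal)
        tan.append(mtf.tangential)
    return ThroughFocusMTF(
        defocus_grid=grid, frequencies=freqs,
        mtf_sagittal=np.clip(np.array(sag), 0.0, 1.0),
        mtf_tangential=np.clip(np.array(tan), 0.0, 1.0),
        condition=eye.name, lens=(design.name if design is not None else "open"),
        aperture=float(aperture_mm), far_reference_offset=offset)


# ---------------------------------------------------------------------------
# numeric cross-check of the order-energy split
# ---------------------------------------------------------------------------

def focus_energy_fractions(design: IOLDesign, aperture_mm: float,
                           wavelength_nm: float = 546.0, grid_size: int = 1024,
                           pad_factor: float = 2.0,
                           normalization: str | None = None) -> dict[str, float]:
    """Far-field energy fractions of the three foci by direct propagation.

    The bare diffractive profile (no cornea, no asphericity) is propagated to
    each focal plane in turn — refocusing by the focus's nominal IOL-plane add
    — and the on-axis PSF intensity, normalized by that of an ideal lens, is
    the standard estimate of the order efficiency.  Independent of the
    unit-cell algebra used to fit the step heights.
    """
    n = grid_size
    d_m = aperture_mm * 1e-3
    dx = pad_factor * d_m / n
    x = (np.arange(n) - n // 2) * dx
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    inside = r2 <= (d_m / 2.0) ** 2
    lam_m = wavelength_nm * 1e-9
    profile = build_phase_profile(design, wavelength_nm)
    r_mm = np.sqrt(r2) * 1e3

    def on_axis(phase):
        amp = np.where(inside, np.exp(1j * phase), 0.0)
        return np.abs(np.fft.fft2(np.fft.ifftshift(amp))[0, 0]) ** 2

    ideal = on_axis(np.zeros_like(r2))
    lens_ph = np.zeros_like(r2)
    lens_ph[inside] = profile(r_mm[inside])
    out = {}
    for focus in ("far", "intermediate", "near"):
        add = design.focus_add(focus)
        out[focus] = on_axis(lens_ph - np.pi * add * r2 / lam_m) / ideal
    norm = normalization or design.split_normalization
    if norm == "relative":
        tot = sum(out.values())
        out = {k: v / tot for k, v in out.items()}
    return {k: float(v) for k, v in out.items()}
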