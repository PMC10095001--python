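"""Model-eye geometry, plane/unit conversions and corneal aberration models.

The virtual bench evaluates intraocular lenses in one of two measurement
conditions:

* ``condition1`` — monochromatic 546 nm light behind an aberration-neutral
  corneal model (achromatic doublet, f = 36 mm).
* ``condition2`` — polychromatic, photopically weighted light behind a corneal
  model carrying a population level of primary spherical aberration
  (+0.27 µm of Z(4,0) at a 6 mm normalization diameter) and 1 D of
  longitudinal chromatic aberration across the modelled band (singlet,
  f = 39 mm).

Defocus is specified in diopters at the *spectacle plane*; manufacturer add
powers refer to the *IOL plane*.  The two are linked by a fixed plane factor
(4/3), calibrated to the instrument's printed correspondence
(−3.5 D ↔ −4.67 D).  Image-plane spatial frequencies in lp/mm map to visual
angle through a retinal scale of 0.30 mm/deg (50 lp/mm ↔ 15 cyc/deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
import numpy as np
import yaml

__all__ = [
    "SpectralModel",
    "ModelEyeCondition",
    "condition",
    "condition_names",
    "load_conditions",
    "spectacle_to_iol_defocus",
    "iol_to_spectacle_defocus",
    "add_to_viewing_distance",
    "lpmm_to_cpd",
    "corneal_wavefront",
    "chromatic_defocus",
    "zernike_z40",
]

#: CIE 1924 photopic luminosity function V(λ), 400–700 nm at 10 nm spacing.
_VLAMBDA_NM = np.arange(400.0, 701.0, 10.0)
_VLAMBDA = np.array([
    0.000396, 0.00121, 0.00400, 0.0116, 0.0230, 0.0380, 0.0600, 0.09098,
    0.13902, 0.20802, 0.32300, 0.50300, 0.71000, 0.86200, 0.95400, 0.99495,
    0.99500, 0.95200, 0.87000, 0.75700, 0.63100, 0.50300, 0.38100, 0.26500,
    0.17500, 0.10700, 0.06100, 0.03200, 0.01700, 0.00821, 0.004102,
])


def photopic_weight(wavelength_nm):
    """Interpolated CIE photopic luminosity V(λ) for wavelengths in nm."""
    return np.interp(wavelength_nm, _VLAMBDA_NM, _VLAMBDA)


@dataclass(frozen=True)
class SpectralModel:
    """A discrete illumination spectrum with normalized weights."""

    wavelengths: tuple[float, ...]
    weights: tuple[float, ...]
    reference_wavelength: float = 546.0

    def __post_init__(self):
        if len(self.wavelengths) == 0:
            raise ValueError("spectrum must contain at least one wavelength")
        if len(self.wavelengths) != len(self.weights):
            raise ValueError("wavelengths and weights must have equal length")
        wl = np.asarray(self.wavelengths, dtype=float)
        if np.any(wl < 400.0) or np.any(wl > 700.0):
            raise ValueError("wavelengths must lie within 400-700 nm")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative and not all zero")
        object.__setattr__(self, "wavelengths", tuple(float(v) for v in wl))
        object.__setattr__(self, "weights", tuple(float(v) for v in w / w.sum()))

    @property
    def is_monochromatic(self) -> bool:
        return len(self.wavelengths) == 1

    @classmethod
    def monochromatic(cls, wavelength_nm: float = 546.0) -> "SpectralModel":
        return cls((float(wavelength_nm),), (1.0,), float(wavelength_nm))

    @classmethod
    def photopic(cls, band_nm: tuple[float, float] = (480.0, 640.0),
                 n: int = 9, reference_wavelength: float = 546.0) -> "SpectralModel":
        """Evenly spaced wavelengths across ``band_nm`` weighted by V(λ)."""
        wl = np.linspace(band_nm[0], band_nm[1], n)
        return cls(tuple(wl), tuple(photopic_weight(wl)), reference_wavelength)


@dataclass(frozen=True)
class ModelEyeCondition:
    """Cornea + spectrum + geometry of one virtual-bench measurement condition."""

    name: str
    corneal_sa: float                     # Z(4,0) coefficient, µm, at sa_norm_diameter
    lca_total: float                      # longitudinal chromatic aberration, D, across lca_band
    spectrum: SpectralModel
    sa_norm_diameter: float = 6.0         # mm
    lca_band: tuple[float, float] = (480.0, 640.0)   # nm
    corneal_focal_length: float = 36.0    # mm (metadata; not used by the propagation)
    plane_factor: float = 4.0 / 3.0       # spectacle-to-IOL defocus ratio
    retinal_scale: float = 0.30           # mm per degree of visual angle

    def __post_init__(self):
        if self.plane_factor <= 1:
            raise ValueError("plane_factor must exceed 1")
        if self.retinal_scale <= 0:
            raise ValueError("retinal_scale must be positive")
        if self.lca_band[0] >= self.lca_band[1]:
            raise ValueError("lca_band must be an increasing (lo, hi) pair in nm")

    @property
    def image_focal_length_mm(self) -> float:
        """Effective image-space focal length implied by the retinal scale."""
        return self.retinal_scale * 180.0 / math.pi


def _spectrum_from_cfg(cfg: dict) -> SpectralModel:
    kind = cfg.get("kind", "monochromatic")
    if kind == "monochromatic":
        return SpectralModel.monochromatic(cfg["wavelength_nm"])
    if kind == "photopic":
        return SpectralModel.photopic(tuple(cfg["band_nm"]), cfg["n_wavelengths"],
                                      cfg.get("reference_wavelength_nm", 546.0))
    raise ValueError(f"unknown spectrum kind {kind!r}")


def load_conditions(path=None) -> dict[str, ModelEyeCondition]:
    """Load model-eye conditions from a YAML config (built-in file by default)."""
    if path is None:
        text = (resources.files("trifocal_bench") / "data" / "conditions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["conditions"]
    out = {}
    for name, c in raw.items():
        out[name] = ModelEyeCondition(
            name=name,
            corneal_sa=float(c["corneal_sa_um"]),
            sa_norm_diameter=float(c["sa_norm_diameter_mm"]),
            lca_total=float(c["lca_total_D"]),
            lca_band=tuple(float(v) for v in c["lca_band_nm"]),
            spectrum=_spectrum_from_cfg(c["spectrum"]),
            corneal_focal_length=float(c["corneal_focal_length_mm"]),
            plane_factor=float(c["plane_factor"]),
            retinal_scale=float(c["retinal_scale_mm_per_deg"]),
        )
    return out


@lru_cache(maxsize=1)
def _builtin_conditions() -> dict[str, ModelEyeCondition]:
    return load_conditions()


def condition(name: str) -> ModelEyeCondition:
    """Return a built-in measurement condition (``condition1`` or ``condition2``)."""
    conds = _builtin_conditions()
    key = str(name).lower()
    if key in ("1", "2"):
        key = f"condition{key}"
    if key not in conds:
        raise KeyError(f"unknown condition {name!r}; available: {sorted(conds)}")
    return conds[key]


def condition_names() -> list[str]:
    return sorted(_builtin_conditions())


# ---------------------------------------------------------------------------
# plane and unit conversions
# ---------------------------------------------------------------------------

def spectacle_to_iol_defocus(d_spec, eye: ModelEyeCondition):
    """Convert defocus in diopters at the spectacle plane to the IOL plane."""
    d = np.asarray(d_spec, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("spectacle-plane defocus must be finite")
    out = d * eye.plane_factor
    return float(out) if np.isscalar(d_spec) else out


def iol_to_spectacle_defocus(d_iol, eye: ModelEyeCondition):
    """Inverse of :func:`spectacle_to_iol_defocus`."""
    d = np.asarray(d_iol, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("IOL-plane defocus must be finite")
    out = d / eye.plane_factor
    return float(out) if np.isscalar(d_iol) else out


def add_to_viewing_distance(add_iol: float, eye: ModelEyeCondition) -> float:
    """Object distance in cm corresponding to an IOL-plane add power.

    The add is first expressed at the spectacle plane (divide by the plane
    factor), then inverted as a vergence: ``100 / (add / plane_factor)`` cm.
    """
    if not np.isfinite(add_iol) or add_iol <= 0:
        raise ValueError("add power must be positive and finite "
                         "(viewing distance undefined otherwise)")
    return 100.0 / (add_iol / eye.plane_factor)


def lpmm_to_cpd(f_lpmm, eye: ModelEyeCondition):
    """Convert image-plane spatial frequency (lp/mm) to cycles per degree."""
    f = np.asarray(f_lpmm, dtype=float)
    if np.any(f < 0):
        raise ValueError("spatial frequency must be non-negative")
    out = f * eye.retinal_scale
    return float(out) if np.isscalar(f_lpmm) else out


# ---------------------------------------------------------------------------
# corneal wavefront and chromatic defocus
# ---------------------------------------------------------------------------

def zernike_z40(rho):
    """Primary spherical aberration polynomial Z(4,0) = √5 (6ρ⁴ − 6ρ² + 1)."""
    rho = np.asarray(rho, dtype=float)
    return math.sqrt(5.0) * (6.0 * rho**4 - 6.0 * rho**2 + 1.0)


def corneal_wavefront(eye: ModelEyeCondition, aperture_diameter: float, radial_grid_mm):
    """Corneal wavefront height (µm) sampled at radii ``radial_grid_mm``.

    The spherical-aberration surface is the Z(4,0) polynomial whose coefficient
    equals ``eye.corneal_sa`` at the normalization diameter; a smaller aperture
    crops that fixed surface (it does not rescale it).
    """
    if aperture_diameter > eye.sa_norm_diameter:
        raise ValueError(
            f"aperture {aperture_diameter} mm exceeds the modelled corneal "
            f"domain ({eye.sa_norm_diameter} mm)")
    r = np.asarray(radial_grid_mm, dtype=float)
    if np.any(r > aperture_diameter / 2.0 + 1e-12):
        raise ValueError("radial grid extends beyond the aperture")
    if eye.corneal_sa == 0.0:
        return np.zeros_like(r)
    rho = r / (eye.sa_norm_diameter / 2.0)
    return eye.corneal_sa * zernike_z40(rho)


def chromatic_defocus(wavelength_nm, eye: ModelEyeCondition):
    """Longitudinal chromatic defocus (D) of the model eye at a wavelength.

    Linear in wavenumber (1/λ), anchored to zero at the spectral reference
    wavelength; the difference between the band edges equals ``lca_total``.
    Shorter wavelengths focus in front of the retina (positive defocus).
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    lo, hi = eye.lca_band
    if np.any(wl < lo - 1e-9) or np.any(wl > hi + 1e-9):
        raise ValueError(f"wavelength outside the modelled band [{lo}, {hi}] nm")
    if eye.lca_total == 0.0:
        out = np.zeros_like(wl)
    else:
        scale = eye.lca_total / (1.0 / lo - 1.0 / hi)
        out = (1.0 / wl - 1.0 / eye.spectrum.reference_wavelength) * scale
    return float(out) if np.isscalar(wavelength_nm) else out
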